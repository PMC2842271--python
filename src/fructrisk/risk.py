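"""Statistical layer: weighted descriptives, many-to-one mean comparisons,
logistic risk models, goodness of fit, and power.

Descriptive statistics honour survey weights (weighted mean, median and SD
that reduce exactly to their unweighted forms under equal weights).  Group
means of serum uric acid are compared with a linear model — unadjusted or
covariate-adjusted — using many-to-one (Dunnett-type) multiplicity-adjusted
p-values against the lowest intake group.  Hyperuricemia risk is modelled by
maximum-likelihood logistic regression with the lowest level of every
categorical as reference, Wald 95% confidence limits on the odds-ratio
scale, a likelihood-ratio p for the exposure, and a Hosmer-Lemeshow
goodness-of-fit test.  Regressions are unweighted by default (weights enter
the descriptives); a frequency-weighted option is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .cohort import _weighted_quantiles
from .errors import DomainError, SingularFitError

#: Covariates of the fully adjusted risk model (13 explanatory variables
#: including the exposure): demographics plus quartiled dietary intakes and
#: the alcohol level.
ADJUSTMENT_COVARIATES = (
    "sex",
    "age_group",
    "race",
    "education",
    "bmi_category",
    "q_energy",
    "q_protein",
    "q_fat",
    "q_vitamin_c",
    "q_fiber",
    "q_caffeine",
    "alcohol_level",
)

_MVT_SEED = 20130525  # fixed QMC seed so adjusted p-values are reproducible


@dataclass
class MeanTable:
    """Group means of a response with many-to-one comparisons."""

    grouping: str
    reference: object
    groups: pd.DataFrame  # level, n, mean, sd, adj_mean, p_vs_ref
    model_p: float
    covariates: tuple = ()


@dataclass
class RiskResult:
    """Odds ratios for one exposure from one logistic model."""

    exposure: str
    model_type: str  # "unadjusted" | "adjusted"
    reference: object
    levels: pd.DataFrame  # level, n, odds_ratio, ci_low, ci_high, p
    model_p: float
    gof_stat: float = float("nan")
    gof_p: float = float("nan")
    covariates: tuple = ()
    unstable: bool = False
    formula: str = ""


def _weighted_stats(x: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted mean, median, SD; equal weights give the unweighted values."""
    w = np.asarray(w, dtype=float)
    w = w * (len(w) / w.sum())  # normalise to mean 1: ddof-1 SD is recovered
    mean = float(np.sum(w * x) / np.sum(w))
    var = float(np.sum(w * (x - mean) ** 2) / (np.sum(w) - 1.0)) if len(x) > 1 else 0.0
    median = float(_weighted_quantiles(np.asarray(x, float), w, [0.5])[0])
    return mean, median, np.sqrt(var)


def descriptives(
    cohort: pd.DataFrame,
    by: str = "hyperuricemic",
    variables: list[str] | None = None,
    weights: str | None = "weight",
) -> pd.DataFrame:
    """Survey-weighted descriptive statistics per stratum of ``by``.

    Returns a long table (stratum, variable, n, mean, median, sd).  An empty
    stratum (a ``by`` level with no subjects, e.g. no hyperuricemic cases)
    yields rows of NaN rather than an error.
    """
    if variables is None:
        variables = [
            c
            for c in cohort.columns
            if pd.api.types.is_numeric_dtype(cohort[c])
            and not pd.api.types.is_bool_dtype(cohort[c])
            and c not in ("subject_id", "weight")
        ]
    strata = sorted(cohort[by].unique().tolist())
    if pd.api.types.is_bool_dtype(cohort[by]):
        strata = [False, True]
    rows = []
    for s in strata:
        sub = cohort[cohort[by] == s]
        w = (
            sub[weights].to_numpy()
            if weights is not None and weights in sub.columns
            else np.ones(len(sub))
        )
        for var in variables:
            if len(sub) == 0:
                rows.append((s, var, 0, np.nan, np.nan, np.nan))
                continue
            x = sub[var].to_numpy(dtype=float)
            mean, median, sd = _weighted_stats(x, w)
            rows.append((s, var, len(sub), mean, median, sd))
    return pd.DataFrame(
        rows, columns=["stratum", "variable", "n", "mean", "median", "sd"]
    )


def _check_full_rank(exog: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, rr = np.linalg.qr(exog)
        diag = np.abs(np.diag(rr))
        tol = diag.max() * max(exog.shape) * np.finfo(float).eps
        bad = [names[j] for j in np.flatnonzero(diag < tol)]
        raise SingularFitError(bad or names)


def _dunnett_p(tstats: np.ndarray, corr: np.ndarray, df: int) -> np.ndarray:
    """Many-to-one adjusted p-values: P(max_j |T_j| >= |t_i|) under the joint
    multivariate t with the contrast correlation matrix."""
    mvt = stats.multivariate_t(shape=corr, df=df, allow_singular=True)
    out = np.empty(len(tstats))
    for i, t in enumerate(np.abs(tstats)):
        lo = np.full(len(tstats), -t)
        hi = np.full(len(tstats), t)
        inside = mvt.cdf(
            hi, lower_limit=lo, random_state=np.random.default_rng(_MVT_SEED)
        )
        out[i] = min(1.0, max(0.0, 1.0 - float(inside)))
    return out


def compare_means(
    cohort: pd.DataFrame,
    grouping: str,
    value: str = "uric_mg_dl",
    covariates: list[str] | None = None,
) -> MeanTable:
    """Compare group means of ``value`` against the lowest group.

    Fits an OLS model ``value ~ C(grouping) [+ C(covariate)...]``; each
    non-reference group's p-value against group 1 is multiplicity-adjusted
    in the Dunnett many-to-one sense via the joint multivariate-t
    distribution of the contrast statistics.  Adjusted group means are
    G-computation averages (mean prediction with every subject assigned to
    the group).  ``model_p`` is the Wald F-test of all group terms.
    """
    covariates = list(covariates or ())
    levels = sorted(cohort[grouping].unique().tolist())
    if len(levels) < 2:
        raise DomainError(f"grouping {grouping!r} needs >= 2 levels")
    ref = levels[0]

    terms = [f"C({grouping})"] + [f"C({c})" for c in covariates]
    formula = f"{value} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=cohort)
    _check_full_rank(model.exog, list(model.exog_names))
    res = model.fit()

    gnames = [n for n in res.params.index if n.startswith(f"C({grouping})")]
    t = (res.params[gnames] / res.bse[gnames]).to_numpy()
    vc = res.cov_params().loc[gnames, gnames].to_numpy()
    d = np.sqrt(np.diag(vc))
    corr = vc / np.outer(d, d)
    p_adj = _dunnett_p(t, corr, int(res.df_resid))

    rmat = np.zeros((len(gnames), len(res.params)))
    for i, name in enumerate(gnames):
        rmat[i, list(res.params.index).index(name)] = 1.0
    model_p = float(res.f_test(rmat).pvalue)

    rows = []
    for lev in levels:
        sub = cohort.loc[cohort[grouping] == lev, value]
        counterfactual = cohort.copy()
        counterfactual[grouping] = lev
        adj_mean = float(res.predict(counterfactual).mean())
        rows.append((lev, len(sub), float(sub.mean()), float(sub.std()), adj_mean))
    groups = pd.DataFrame(rows, columns=["level", "n", "mean", "sd", "adj_mean"])
    pmap = dict(zip(levels[1:], p_adj)) if len(gnames) == len(levels) - 1 else {}
    groups["p_vs_ref"] = groups["level"].map(pmap)
    return MeanTable(
        grouping=grouping,
        reference=ref,
        groups=groups,
        model_p=model_p,
        covariates=tuple(covariates),
    )


def goodness_of_fit(y, p_hat, g: int = 10) -> tuple[float, float, int]:
    """Hosmer-Lemeshow test over ``g`` risk bins.

    Observations are binned by deciles of predicted probability; the
    statistic sums (O-E)^2 / (E (1 - E/n)) over bins and is referred to a
    chi-square with (bins - 2) degrees of freedom.  Ties that collapse bins
    raise a warning and reduce the degrees of freedom accordingly.

    Returns (statistic, p-value, degrees of freedom).
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    bins = pd.qcut(pd.Series(p), g, duplicates="drop")
    n_bins = bins.cat.categories.size
    if n_bins < g:
        warnings.warn(
            f"bin collapse: {n_bins} distinct risk bins instead of {g}",
            stacklevel=2,
        )
    if n_bins < 3:
        return np.nan, np.nan, 0
    stat = 0.0
    for _, idx in pd.Series(np.arange(len(p))).groupby(bins, observed=True):
        obs = float(y[idx].sum())
        exp = float(p[idx].sum())
        ng = len(idx)
        denom = exp * (1.0 - exp / ng)
        if denom > 0:
            stat += (obs - exp) ** 2 / denom
    df = n_bins - 2
    return float(stat), float(stats.chi2.sf(stat, df)), df


def fit_logit(
    cohort: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
    outcome: str = "hyperuricemic",
    weights: str | None = None,
) -> RiskResult:
    """Logistic regression of hyperuricemia on a categorical exposure.

    The lowest observed level of the exposure (and of every categorical
    covariate) is the reference; odds ratios are exponentiated coefficients
    with Wald 95% confidence limits.  ``model_p`` is the likelihood-ratio
    test of the exposure (full model vs. the model without it).  Goodness of
    fit is Hosmer-Lemeshow with 10 bins.  Quasi-separated or non-converged
    fits are returned with ``unstable=True`` rather than raised.
    """
    covariates = list(covariates or ())
    data = cohort.copy()
    data["_y"] = data[outcome].astype(int)

    observed = sorted(data[exposure].unique().tolist())
    expected = [1, 2, 3, 4]
    if pd.api.types.is_integer_dtype(cohort[exposure]) and set(observed) < set(expected):
        warnings.warn(
            f"exposure {exposure!r}: level(s) "
            f"{sorted(set(expected) - set(observed))} absent and dropped",
            stacklevel=2,
        )
    ref = observed[0]

    terms = [f"C({exposure})"] + [f"C({c})" for c in covariates]
    rhs = " + ".join(terms)
    formula = f"_y ~ {rhs}"

    model_type = "adjusted" if covariates else "unadjusted"
    empty_levels = pd.DataFrame(
        columns=["level", "n", "odds_ratio", "ci_low", "ci_high", "p"]
    )
    freq = data[weights].to_numpy() if weights else None
    unstable = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if freq is not None:
                model = smf.glm(
                    formula, data=data, family=sm.families.Binomial(), freq_weights=freq
                )
                res = model.fit()
            else:
                model = smf.logit(formula, data=data)
                res = model.fit(disp=0, maxiter=200)
                unstable = not res.mle_retvals.get("converged", True)
        except Exception:  # separation / singular Hessian and friends
            return RiskResult(
                exposure=exposure,
                model_type=model_type,
                reference=ref,
                levels=empty_levels,
                model_p=np.nan,
                covariates=tuple(covariates),
                unstable=True,
                formula=formula,
            )
        # reduced model without the exposure, for the likelihood-ratio test;
        # a singular reduced fit (few cases, many covariates) only costs the
        # model-level p, not the odds ratios
        model_p = np.nan
        try:
            reduced_rhs = " + ".join(terms[1:]) if covariates else "1"
            if freq is not None:
                red = smf.glm(
                    f"_y ~ {reduced_rhs}",
                    data=data,
                    family=sm.families.Binomial(),
                    freq_weights=freq,
                ).fit()
            else:
                red = smf.logit(f"_y ~ {reduced_rhs}", data=data).fit(
                    disp=0, maxiter=200
                )
            lr = 2.0 * (res.llf - red.llf)
            df_lr = res.df_model - red.df_model
            if df_lr > 0:
                model_p = float(stats.chi2.sf(max(lr, 0.0), df_lr))
        except Exception:
            unstable = True

    if np.abs(res.params).max() > 15:
        unstable = True

    enames = [n for n in res.params.index if n.startswith(f"C({exposure})")]
    rows = [(ref, int((data[exposure] == ref).sum()), 1.0, np.nan, np.nan, np.nan)]
    try:
        ci = res.conf_int().loc[enames]
    except Exception:
        ci = pd.DataFrame(np.nan, index=enames, columns=[0, 1])
        unstable = True
    with np.errstate(over="ignore"):
        for name in enames:
            lev_str = name.split("[T.")[1].rstrip("]")
            try:
                lev = type(ref)(lev_str)
            except (TypeError, ValueError):
                lev = lev_str
            rows.append(
                (
                    lev,
                    int((data[exposure] == lev).sum()),
                    float(np.exp(res.params[name])),
                    float(np.exp(ci.loc[name, 0])),
                    float(np.exp(ci.loc[name, 1])),
                    float(res.pvalues[name]),
                )
            )
    levels_df = pd.DataFrame(
        rows, columns=["level", "n", "odds_ratio", "ci_low", "ci_high", "p"]
    )

    gof_stat, gof_p = np.nan, np.nan
    if not unstable:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gof_stat, gof_p, _ = goodness_of_fit(data["_y"], res.predict(data))

    return RiskResult(
        exposure=exposure,
        model_type="adjusted" if covariates else "unadjusted",
        reference=ref,
        levels=levels_df,
        model_p=model_p,
        gof_stat=gof_stat,
        gof_p=gof_p,
        covariates=tuple(covariates),
        unstable=unstable,
        formula=formula,
    )


def power_two_group(
    prevalence_ref: float, odds_ratio: float, alpha: float = 0.05, n_per_group: int = 1000
) -> float:
    """Normal-approximation power for a two-proportion comparison.

    The comparison group's outcome probability is obtained by scaling the
    reference group's odds by ``odds_ratio``.  Two-sided test of equal
    proportions with ``n_per_group`` subjects per arm; at an odds ratio of 1
    the power equals ``alpha`` by construction.
    """
    if not 0.0 < prevalence_ref < 1.0:
        raise DomainError("prevalence must be strictly between 0 and 1")
    if odds_ratio <= 0:
        raise DomainError("odds ratio must be positive")
    if n_per_group < 2:
        raise DomainError("need at least 2 subjects per group")
    p1 = prevalence_ref
    odds2 = p1 / (1.0 - p1) * odds_ratio
    p2 = odds2 / (1.0 + odds2)
    se = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / n_per_group)
    delta = abs(p2 - p1)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(delta / se - z) + stats.norm.cdf(-delta / se - z))
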