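"""Analysis-cohort construction: exclusions, outcome classification, coding.

Subjects enter the analysis if they are 20-80 years old, free of diabetes,
cancer and heart disease, and have a reliable dietary recall.  Hyperuricemia
is a strict sex-specific threshold on serum uric acid; dietary exposures are
coded as quartiles of the analysis cohort's distribution, alcohol by fixed
gram cut-offs, and demographics by fixed clinical groupings.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

from .config import MG_DL_TO_UMOL_L, CutoffScheme
from .errors import DegenerateDistributionError, DomainError, EmptyCohortError

DISEASE_COLUMNS = ("diabetes", "cancer", "heart_disease")

#: Dietary variables quartiled for exposure/covariate coding, as
#: (source column, quartile-label column) pairs.
QUARTILE_VARIABLES = (
    ("added_unbound_g", "q_added_unbound"),
    ("all_added_g", "q_all_added"),
    ("total_g", "q_total_fructose"),
    ("added_unbound_pct_energy", "q_added_unbound_pct"),
    ("all_added_pct_energy", "q_all_added_pct"),
    ("total_pct_energy", "q_total_fructose_pct"),
    ("fiber_density", "q_fiber"),
    ("energy_kcal", "q_energy"),
    ("protein_g", "q_protein"),
    ("fat_pct_energy", "q_fat"),
    ("vitamin_c_mg", "q_vitamin_c"),
    ("caffeine_mg", "q_caffeine"),
)


def exclude(
    subjects: pd.DataFrame,
    recalls: pd.DataFrame,
    age_range: tuple[float, float] = (20.0, 80.0),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the cohort exclusion rules.

    Removes subjects outside ``age_range``, with any disease flag set, or
    whose recall records are flagged unreliable.  Returns the filtered
    subject and recall tables plus an audit dict with per-reason counts
    (a subject may count toward several reasons).

    Raises
    ------
    EmptyCohortError
        If no subject survives.
    """
    subjects = subjects.copy()
    lo, hi = age_range
    bad_age = (subjects["age"] < lo) | (subjects["age"] > hi)

    diseased = pd.Series(False, index=subjects.index)
    for col in DISEASE_COLUMNS:
        if col in subjects.columns:
            diseased |= subjects[col].astype(bool)

    if "reliable" in recalls.columns:
        unreliable_ids = set(recalls.loc[~recalls["reliable"].astype(bool), "subject_id"])
    else:
        unreliable_ids = set()
    unreliable = subjects["subject_id"].isin(unreliable_ids)

    removed = bad_age | diseased | unreliable
    audit = {
        "n_input": int(len(subjects)),
        "removed_age": int(bad_age.sum()),
        "removed_disease": int(diseased.sum()),
        "removed_unreliable_recall": int(unreliable.sum()),
        "removed_total": int(removed.sum()),
        "n_retained": int((~removed).sum()),
    }
    kept = subjects[~removed].reset_index(drop=True)
    if len(kept) == 0:
        raise EmptyCohortError(f"no subjects retained; audit: {audit}")
    kept_recalls = recalls[recalls["subject_id"].isin(set(kept["subject_id"]))]
    return kept, kept_recalls.reset_index(drop=True), audit


def classify_hyperuricemia(uric_mg_dl, sex, scheme: CutoffScheme):
    """Strict comparison of serum uric acid against the sex-specific cut-off.

    Accepts scalars or aligned array-likes; returns bool or boolean array.
    """
    if np.isscalar(uric_mg_dl) or isinstance(uric_mg_dl, numbers.Number):
        if uric_mg_dl <= 0:
            raise DomainError("uric acid concentration must be positive")
        return uric_mg_dl > scheme.cutoff_for(sex)
    uric = np.asarray(uric_mg_dl, dtype=float)
    sex = np.asarray(sex)
    if (uric <= 0).any():
        raise DomainError("uric acid concentrations must be positive")
    bad = ~np.isin(sex, ("male", "female"))
    if bad.any():
        raise DomainError(f"unknown sex value(s): {sorted(set(sex[bad]))}")
    cut = np.where(sex == "male", scheme.male_cutoff, scheme.female_cutoff)
    return uric > cut


def to_si(uric_mg_dl):
    """Convert serum uric acid from mg/dL to umol/L (1 mg/dL = 59.48 umol/L)."""
    arr = np.asarray(uric_mg_dl, dtype=float)
    if (arr < 0).any():
        raise DomainError("concentration must be non-negative")
    out = arr * MG_DL_TO_UMOL_L
    return float(out) if np.isscalar(uric_mg_dl) or arr.ndim == 0 else out


def _weighted_quantiles(values: np.ndarray, weights: np.ndarray, probs) -> np.ndarray:
    """Linear-interpolation quantiles with weights.

    Plotting positions are (cumw_i - w_i) / (W - w_last) over the sorted
    sample, which reduces exactly to numpy's default linear (type-7)
    quantiles when all weights are equal.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order].astype(float)
    cw = np.cumsum(w)
    denom = cw[-1] - w[-1]
    if denom <= 0:
        return np.full(len(np.atleast_1d(probs)), v[0])
    pos = (cw - w) / denom
    return np.interp(probs, pos, v)


def assign_quartiles(values, weights=None) -> tuple[np.ndarray, tuple]:
    """Quartile labels 1-4 from the 25th/50th/75th percentiles.

    Intervals are half-open on the left and closed on the right, so a value
    equal to a cutpoint takes the lower label.  Cutpoints use linear
    interpolation between order statistics (numpy's default); pass
    ``weights`` for survey-weighted cutpoints.

    Returns ``(labels, cutpoints)`` with cutpoints the (c25, c50, c75)
    triple actually used.

    Raises
    ------
    DegenerateDistributionError
        If all values are equal (no quartile structure exists).
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise DegenerateDistributionError("empty vector")
    if np.isnan(v).any():
        raise DomainError("quartile input contains NaN")
    if np.all(v == v[0]):
        raise DegenerateDistributionError("all values equal; quartiles undefined")
    probs = (0.25, 0.5, 0.75)
    if weights is None:
        cuts = np.quantile(v, probs)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any():
            raise DomainError("weights must be non-negative")
        cuts = _weighted_quantiles(v, w, probs)
    labels = np.searchsorted(cuts, v, side="left") + 1
    return labels.astype(int), tuple(float(c) for c in cuts)


def assign_alcohol_level(grams_per_day):
    """Alcohol level 1-4 for 0, >0-15, >15-30, >30 g/day."""
    g = np.asarray(grams_per_day, dtype=float)
    if (g < 0).any():
        raise DomainError("alcohol grams must be non-negative")
    level = np.ones(g.shape, dtype=int)
    level[g > 0] = 2
    level[g > 15] = 3
    level[g > 30] = 4
    return int(level) if g.ndim == 0 else level


def assign_bmi_category(bmi):
    """BMI category: 1 normal (<25), 2 overweight (25 <= BMI < 30), 3 obese (>=30)."""
    b = np.asarray(bmi, dtype=float)
    if (b <= 0).any():
        raise DomainError("BMI must be positive")
    cat = np.ones(b.shape, dtype=int)
    cat[b >= 25] = 2
    cat[b >= 30] = 3
    return int(cat) if b.ndim == 0 else cat


def assign_age_group(age):
    """Age group: 1 for 20-30, 2 for 31-40, 3 for 41-50, 4 for >50 (years)."""
    a = np.asarray(age, dtype=float)
    if (a < 20).any():
        raise DomainError("age below 20 should have been excluded upstream")
    grp = np.full(a.shape, 4, dtype=int)
    grp[a <= 50] = 3
    grp[a <= 40] = 2
    grp[a <= 30] = 1
    return int(grp) if a.ndim == 0 else grp


def build_cohort(
    subjects: pd.DataFrame,
    intakes: pd.DataFrame,
    scheme: CutoffScheme,
    weighted_quartiles: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the analysis-ready cohort table.

    Merges fructose components into the (already excluded) subject table,
    derives fiber density (g/1000 kcal), classifies hyperuricemia under
    ``scheme``, and codes every exposure and demographic categorically.

    Returns ``(cohort, meta)`` where ``meta`` records the quartile cutpoints
    per variable, the scheme label and the quartile weighting convention —
    everything needed to reproduce the coding.
    """
    cohort = subjects.merge(
        intakes.drop(columns=["energy_kcal"], errors="ignore"),
        on="subject_id",
        how="inner",
    )
    if len(cohort) == 0:
        raise EmptyCohortError("no overlap between subject table and intake table")
    cohort["fiber_density"] = 1000.0 * cohort["fiber_g"] / cohort["energy_kcal"]
    cohort["hyperuricemic"] = classify_hyperuricemia(
        cohort["uric_mg_dl"].to_numpy(), cohort["sex"].to_numpy(), scheme
    )
    w = cohort["weight"].to_numpy() if weighted_quartiles else None
    cutpoints: dict[str, tuple] = {}
    for src, label in QUARTILE_VARIABLES:
        labels, cuts = assign_quartiles(cohort[src].to_numpy(), weights=w)
        cohort[label] = labels
        cutpoints[label] = cuts
    cohort["alcohol_level"] = assign_alcohol_level(cohort["alcohol_g"].to_numpy())
    cohort["bmi_category"] = assign_bmi_category(cohort["bmi"].to_numpy())
    cohort["age_group"] = assign_age_group(cohort["age"].to_numpy())
    meta = {
        "cutoff_scheme": scheme.label,
        "male_cutoff": scheme.male_cutoff,
        "female_cutoff": scheme.female_cutoff,
        "weighted_quartiles": bool(weighted_quartiles),
        "quartile_estimator": "linear interpolation between order statistics",
        "cutpoints": {k: list(v) for k, v in cutpoints.items()},
    }
    return cohort, meta
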