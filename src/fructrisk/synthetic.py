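"""Synthetic dietary-survey scenario generator with known ground truth.

Emulates the four tables the pipeline consumes — day-1 dietary recalls, a
food-to-commodity composition table, a commodity nutrient reference, and a
subject table — so every downstream stage can be tested against planted
truth without any external survey data.

Construction guarantees:

* **Exact intake consistency.**  Per-subject fructose components are
  computed from the same per-gram commodity rates used to lay down the
  recall records, so re-estimating intakes from the generated tables
  reproduces the ground truth to floating-point accuracy.
* **Known risk structure.**  Hyperuricemia status is drawn from a logistic
  model on the planted exposure levels (total-fructose quartile, alcohol
  level, fiber-density quartile) with configured log-odds increments; the
  serum concentration is then drawn from a sex-specific truncated normal on
  the matching side of the cut-off, so status and concentration can never
  disagree.
* **Correlated sweet diet.**  A shared latent factor scales each subject's
  sweetened-food consumption and feeds total sugars, inducing the strong
  fructose/total-sugar correlation seen in dietary data (target
  configurable, default 0.94).

What it does not emulate: real survey file layouts, food coding systems,
cluster/stratum sampling designs (weights are i.i.d. log-normal with mean
1), or day-to-day intake variation (a single recall day).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .config import ScenarioConfig, SweetenerMix
from .cohort import assign_alcohol_level, assign_quartiles
from .errors import InvalidConfigError

_ADDED_COMMODITIES = [
    # id, sweetener_class, fructose/100g, carb/100g, sucrose/100g
    ("ADD_CANE_BEET", "cane_beet", 0.0, 100.0, 100.0),
    # corn sweeteners carry 0 direct free fructose in the profile; their
    # fructose yield comes from the disappearance-share partition instead
    ("ADD_CORN_SYRUP", "corn_sweetener", 0.0, 100.0, 0.0),
    ("ADD_CORN_SYRUP_BABY", "corn_sweetener", 0.0, 100.0, 0.0),
    ("ADD_HONEY", "honey", 41.0, 82.0, 1.0),
    ("ADD_MAPLE", "maple", 1.0, 67.0, 60.0),
    ("ADD_SORGHUM", "sorghum", 25.0, 75.0, 25.0),
]

_MIN_COMMODITIES = len(_ADDED_COMMODITIES) + 4


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one generated scenario.

    Attributes
    ----------
    components
        Per-subject true fructose components (same columns as the intake
        estimator's output masses).
    log_odds
        Per-subject true hyperuricemia log-odds.
    planted_or
        exposure name -> per-level odds ratios (level 1 = 1.0).
    exposure_levels
        Per-subject planted exposure levels used in the logistic model.
    """

    components: pd.DataFrame
    log_odds: pd.Series
    planted_or: dict = field(default_factory=dict)
    exposure_levels: pd.DataFrame = None


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stream,))
    )


def generate_food_db(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the composition table and the commodity nutrient reference.

    The commodity vocabulary always contains the five added-sugar classes
    (cane/beet sugar, corn sweeteners — two entries, as composition tables
    name them — honey, maple, sorghum); the remainder are natural
    commodities, a configurable fraction of whose fructose-bearing members
    have their direct fructose value withheld and replaced by a family link
    to a member with both fructose and carbohydrate values (exercising ratio
    imputation).  Every food maps to one to four commodities with positive
    mass fractions summing to less than 1 (the rest is water).
    """
    if config.commodity_db_size < _MIN_COMMODITIES:
        raise InvalidConfigError(
            f"commodity_db_size must be at least {_MIN_COMMODITIES} "
            f"(got {config.commodity_db_size})"
        )
    if config.food_db_size < 1:
        raise InvalidConfigError("food_db_size must be at least 1")
    rng = _rng(config, 0)

    n_nat = config.commodity_db_size - len(_ADDED_COMMODITIES)
    nat_ids = [f"NAT_{i:03d}" for i in range(n_nat)]
    carb = rng.uniform(5.0, 30.0, size=n_nat)
    bearing = rng.random(n_nat) < 0.7
    bearing[0] = True  # guarantee at least one resolvable family head
    fructose = np.where(bearing, carb * rng.uniform(0.15, 0.5, size=n_nat), 0.0)

    withheld = bearing & (rng.random(n_nat) < config.missing_fructose_fraction)
    withheld[0] = False
    head_idx = np.flatnonzero(bearing & ~withheld)
    family = np.array([None] * n_nat, dtype=object)
    for i in np.flatnonzero(withheld):
        family[i] = nat_ids[rng.choice(head_idx)]

    nutrients = pd.DataFrame(
        {
            "commodity_id": nat_ids + [c[0] for c in _ADDED_COMMODITIES],
            "fructose_per_100g": np.concatenate(
                [np.where(withheld, np.nan, fructose), [c[2] for c in _ADDED_COMMODITIES]]
            ),
            "carb_per_100g": np.concatenate(
                [carb, [c[3] for c in _ADDED_COMMODITIES]]
            ),
            "sucrose_per_100g": np.concatenate(
                [np.zeros(n_nat), [c[4] for c in _ADDED_COMMODITIES]]
            ),
            "is_added_sugar": [False] * n_nat + [True] * len(_ADDED_COMMODITIES),
            "sweetener_class": ["none"] * n_nat + [c[1] for c in _ADDED_COMMODITIES],
            "family_id": list(family) + [None] * len(_ADDED_COMMODITIES),
        }
    )

    added_ids = [c[0] for c in _ADDED_COMMODITIES]
    rows = []
    for f in range(config.food_db_size):
        food_id = f"FOOD_{f:03d}"
        k = 1 + int(rng.binomial(3, 0.4))
        sweetened = rng.random() < 0.45
        chosen: list[str] = []
        if sweetened:
            chosen.append(added_ids[rng.integers(len(added_ids))])
        n_more = max(k - len(chosen), 1 if not chosen else k - 1)
        if n_more > 0:
            chosen.extend(
                rng.choice(nat_ids, size=min(n_more, n_nat), replace=False)
            )
        scale = rng.uniform(0.15, 0.95)
        fracs = rng.dirichlet(np.ones(len(chosen))) * scale
        fracs = np.maximum(fracs, 1e-4)
        for cid, frac in zip(chosen, fracs):
            rows.append((food_id, cid, float(frac)))
    composition = pd.DataFrame(rows, columns=["food_id", "commodity_id", "fraction"])
    return composition, nutrients


def _commodity_rates(nutrients: pd.DataFrame, mix: SweetenerMix) -> pd.DataFrame:
    """Per-gram fructose delivery rates per commodity (generator-side).

    Kept independent of the estimation module on purpose: the consistency
    between this arithmetic and the pipeline's is itself a tested claim.
    """
    ref = nutrients.set_index("commodity_id")
    nat_rate, add_unb, add_bnd = {}, {}, {}
    for cid, row in ref.iterrows():
        if bool(row["is_added_sugar"]):
            if row["sweetener_class"] == "corn_sweetener":
                free = mix.unbound_fructose_fraction
            else:
                fru = row["fructose_per_100g"]
                free = 0.0 if pd.isna(fru) else float(fru) / 100.0
            add_unb[cid] = free
            add_bnd[cid] = 0.5 * float(row["sucrose_per_100g"]) / 100.0
            nat_rate[cid] = 0.0
        else:
            fru = row["fructose_per_100g"]
            if not pd.isna(fru):
                frac = float(fru) / 100.0
            else:
                fam = row["family_id"]
                frac = 0.0
                if fam is not None and not pd.isna(fam) and fam in ref.index:
                    ff = ref.loc[fam, "fructose_per_100g"]
                    fc = ref.loc[fam, "carb_per_100g"]
                    if not pd.isna(ff) and not pd.isna(fc) and fc != 0:
                        frac = float(row["carb_per_100g"]) / 100.0 * (
                            float(ff) / float(fc)
                        )
            nat_rate[cid] = frac
            add_unb[cid] = 0.0
            add_bnd[cid] = 0.0
    out = pd.DataFrame(
        {
            "natural_rate": pd.Series(nat_rate),
            "added_unbound_rate": pd.Series(add_unb),
            "added_bound_rate": pd.Series(add_bnd),
        }
    )
    out.index.name = "commodity_id"
    return out


def _food_rates(composition: pd.DataFrame, crates: pd.DataFrame) -> pd.DataFrame:
    m = composition.merge(crates, on="commodity_id", how="left")
    for col in ("natural_rate", "added_unbound_rate", "added_bound_rate"):
        m[col] = m[col] * m["fraction"]
    return m.groupby("food_id", sort=True)[
        ["natural_rate", "added_unbound_rate", "added_bound_rate"]
    ].sum()


def generate_cohort(
    config: ScenarioConfig,
    composition: pd.DataFrame,
    nutrients: pd.DataFrame,
    mix: SweetenerMix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate recalls, the subject table, and the planted ground truth.

    See the module docstring for the generative model.  Determinism: the
    same config (and mix) always yields byte-identical tables.
    """
    if mix is None:
        mix = SweetenerMix()
    rng = _rng(config, 1)
    n = config.n_subjects
    subject_ids = [f"S{i:05d}" for i in range(n)]

    frates = _food_rates(composition, _commodity_rates(nutrients, mix))
    food_ids = frates.index.to_numpy()
    sweet_food = (
        frates["added_unbound_rate"] + frates["added_bound_rate"]
    ).to_numpy() > 0
    n_foods = len(food_ids)

    sweet = rng.normal(0.0, 1.0, size=n)

    rec_subj, rec_food, rec_grams = [], [], []
    nat = np.zeros(n)
    add_unb = np.zeros(n)
    add_bnd = np.zeros(n)
    nat_r = frates["natural_rate"].to_numpy()
    unb_r = frates["added_unbound_rate"].to_numpy()
    bnd_r = frates["added_bound_rate"].to_numpy()
    for i in range(n):
        k = int(rng.integers(3, min(9, n_foods + 1)))
        idx = rng.choice(n_foods, size=k, replace=False)
        grams = np.exp(rng.normal(4.3, 0.6, size=k))
        grams[sweet_food[idx]] *= np.exp(0.45 * sweet[i] - 0.1)
        rec_subj.extend([subject_ids[i]] * k)
        rec_food.extend(food_ids[idx])
        rec_grams.extend(grams)
        nat[i] = float(np.sum(grams * nat_r[idx]))
        add_unb[i] = float(np.sum(grams * unb_r[idx]))
        add_bnd[i] = float(np.sum(grams * bnd_r[idx]))
    all_added = add_unb + add_bnd
    total = all_added + nat

    # --- covariates ------------------------------------------------------
    sex = np.where(rng.random(n) < 0.467, "male", "female")
    age = rng.integers(20, 81, size=n)
    race = rng.choice(
        ["white", "black", "hispanic", "other"],
        size=n,
        p=[0.483, 0.193, 0.295, 0.029],
    )
    education = rng.choice([1, 2, 3], size=n, p=[0.296, 0.237, 0.467])
    bmi = np.exp(rng.normal(np.log(27.0), 0.21, size=n))
    energy = np.exp(rng.normal(7.62, 0.35, size=n) + 0.10 * sweet)
    protein = energy * rng.uniform(0.10, 0.20, size=n) / 4.0
    fat_pct = np.clip(rng.normal(33.0, 9.0, size=n), 5.0, 65.0)
    fiber = np.exp(rng.normal(np.log(14.0), 0.55, size=n))
    vitc = np.exp(rng.normal(np.log(60.0), 0.9, size=n))
    caffeine = np.exp(rng.normal(np.log(130.0), 1.0, size=n))
    drinker = rng.random(n) < 0.272
    alcohol = np.where(drinker, np.exp(rng.normal(np.log(26.0), 1.0, size=n)), 0.0)
    lactose = np.exp(rng.normal(np.log(11.0), 0.8, size=n))

    # total sugars tied to fructose through the sweet-diet factor, with the
    # noise scale chosen to hit the configured correlation
    slope = 2.2
    sd_f = float(np.std(total))
    r = config.fructose_sugar_corr
    sd_eps = slope * sd_f * np.sqrt(1.0 / r**2 - 1.0)
    total_sugars = np.maximum(
        slope * total + lactose + rng.normal(0.0, sd_eps, size=n), total
    )

    # --- planted risk structure -----------------------------------------
    fructose_q, _ = assign_quartiles(total)
    fiber_density = 1000.0 * fiber / energy
    fiber_q, _ = assign_quartiles(fiber_density)
    alcohol_level = assign_alcohol_level(alcohol)
    levels = {"fructose": fructose_q, "alcohol": alcohol_level, "fiber": fiber_q}

    eta = np.full(n, logit(config.prevalence_target))
    for name, incr in config.effect_log_odds.items():
        eta += np.asarray(incr)[levels[name] - 1]
    status = rng.random(n) < expit(eta)

    male_cut, female_cut = config.sex_cutoffs
    cut = np.where(sex == "male", male_cut, female_cut)
    loc = np.where(sex == "male", 6.0, 4.6)
    scale = np.where(sex == "male", 1.1, 1.0)
    lo = np.where(status, cut, 0.5)
    hi = np.where(status, cut + 6.0, cut)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    uric = truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)

    weight = np.exp(rng.normal(-0.125, 0.5, size=n))
    diabetes = rng.random(n) < config.disease_fraction
    cancer = rng.random(n) < config.disease_fraction
    heart = rng.random(n) < config.disease_fraction
    unreliable = rng.random(n) < config.unreliable_fraction

    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "sex": sex,
            "age": age,
            "race": race,
            "education": education,
            "bmi": bmi,
            "uric_mg_dl": uric,
            "weight": weight,
            "energy_kcal": energy,
            "protein_g": protein,
            "fat_pct_energy": fat_pct,
            "fiber_g": fiber,
            "vitamin_c_mg": vitc,
            "caffeine_mg": caffeine,
            "alcohol_g": alcohol,
            "total_sugars_g": total_sugars,
            "lactose_g": lactose,
            "diabetes": diabetes,
            "cancer": cancer,
            "heart_disease": heart,
        }
    )
    reliable_by_subject = dict(zip(subject_ids, ~unreliable))
    recalls = pd.DataFrame(
        {
            "subject_id": rec_subj,
            "food_id": rec_food,
            "grams_consumed": rec_grams,
        }
    )
    recalls["reliable"] = recalls["subject_id"].map(reliable_by_subject)

    components = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "natural_unbound_g": nat,
            "added_unbound_g": add_unb,
            "added_bound_g": add_bnd,
            "all_added_g": all_added,
            "total_g": total,
        }
    )
    planted_or = {
        name: [float(np.exp(v)) for v in incr]
        for name, incr in config.effect_log_odds.items()
    }
    truth = GroundTruth(
        components=components,
        log_odds=pd.Series(eta, index=subject_ids, name="log_odds"),
        planted_or=planted_or,
        exposure_levels=pd.DataFrame(
            {
                "subject_id": subject_ids,
                "fructose_q": fructose_q,
                "alcohol_level": alcohol_level,
                "fiber_q": fiber_q,
            }
        ),
    )
    return recalls, subjects, truth


def generate_scenario(
    config: ScenarioConfig, mix: SweetenerMix | None = None
) -> dict:
    """Generate all four tables plus ground truth for one scenario."""
    composition, nutrients = generate_food_db(config)
    recalls, subjects, truth = generate_cohort(config, composition, nutrients, mix)
    return {
        "composition": composition,
        "nutrients": nutrients,
        "recalls": recalls,
        "subjects": subjects,
        "truth": truth,
    }
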