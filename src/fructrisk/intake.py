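"""Individual fructose-intake estimation from dietary recalls.

The estimator decomposes each recalled food into its agricultural
commodities, resolves a fructose content for every commodity (directly from
the nutrient reference, or by ratio imputation from a family member when the
direct value is missing), splits added sugars into their free (monosaccharide)
and bound (sucrose-moiety) fructose, and apportions the aggregate
corn-sweetener commodity into HFCS-55 / HFCS-42 / corn syrup using
disappearance shares.  Per subject it reports:

* ``natural_unbound_g`` — free fructose from commodities that are not added
  sweeteners (fruit, vegetables, juices, ...);
* ``added_unbound_g``  — free fructose from corn sweeteners plus the direct
  free fructose of honey / maple / sorghum / molasses profiles;
* ``added_bound_g``    — half the mass of sucrose contributed by added-sugar
  commodities (the fructose moiety of sucrose);
* ``all_added_g``      — added unbound + added bound;
* ``total_g``          — all added + natural unbound;

and each component as a percentage of the subject's energy intake at
4 kcal per gram of fructose.

Naturally-occurring *bound* fructose (the fructose half of natural sucrose)
is not estimable from these inputs; :func:`natural_bound_underestimate`
bounds the resulting underestimation from population sugar means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import KCAL_PER_G_FRUCTOSE, SweetenerMix
from .errors import (
    DomainError,
    InvalidMixError,
    UnknownFoodError,
    UnresolvedCommodityError,
)

PROVENANCE_DIRECT = "direct"
PROVENANCE_RATIO = "ratio_imputed"
PROVENANCE_UNRESOLVED = "unresolved"

COMPONENT_COLUMNS = (
    "natural_unbound_g",
    "added_unbound_g",
    "added_bound_g",
    "all_added_g",
    "total_g",
)


def decompose(recalls: pd.DataFrame, composition: pd.DataFrame) -> pd.DataFrame:
    """Convert recall records into per-subject commodity masses.

    Parameters
    ----------
    recalls
        Columns ``subject_id``, ``food_id``, ``grams_consumed``.  Unreliable
        records must already have been excluded upstream.
    composition
        Columns ``food_id``, ``commodity_id``, ``fraction`` (grams of
        commodity per gram of food; per-food fractions may sum to < 1, the
        remainder being water and other non-commodity mass).

    Returns
    -------
    DataFrame with columns ``subject_id``, ``commodity_id``, ``mass_g``,
    where ``mass_g`` sums ``grams_consumed * fraction`` over all recalled
    foods containing the commodity.

    Raises
    ------
    UnknownFoodError
        If any recalled food id is absent from the composition table.
    """
    if len(recalls) == 0:
        return pd.DataFrame(columns=["subject_id", "commodity_id", "mass_g"])
    if (recalls["grams_consumed"] < 0).any():
        raise DomainError("grams_consumed must be non-negative")
    known = set(composition["food_id"])
    unknown = set(recalls["food_id"]) - known
    if unknown:
        raise UnknownFoodError(unknown)
    merged = recalls.merge(composition, on="food_id", how="left")
    merged["mass_g"] = merged["grams_consumed"] * merged["fraction"]
    out = (
        merged.groupby(["subject_id", "commodity_id"], sort=True)["mass_g"]
        .sum()
        .reset_index()
    )
    return out


def resolve_fructose_fraction(profile, reference: pd.DataFrame) -> tuple[float, str]:
    """Resolve grams of fructose per gram of commodity, with provenance.

    A direct ``fructose_per_100g`` value wins.  Otherwise the commodity's
    carbohydrate content is scaled by the fructose-to-carbohydrate ratio of
    its designated family member (e.g. orange juice inheriting the ratio of
    orange), provenance ``ratio_imputed``.

    Parameters
    ----------
    profile
        Mapping or Series with ``fructose_per_100g``, ``carb_per_100g`` and
        ``family_id`` entries.
    reference
        Nutrient reference indexed by ``commodity_id`` (or carrying that
        column), used to look up the family member.

    Raises
    ------
    UnresolvedCommodityError
        If neither route yields a value (missing family, family without a
        direct fructose value, or family carbohydrate of zero).
    """
    fru = profile["fructose_per_100g"]
    if fru is not None and not pd.isna(fru):
        return float(fru) / 100.0, PROVENANCE_DIRECT

    cid = profile.get("commodity_id", "<unknown>")
    fam = profile.get("family_id")
    if fam is None or pd.isna(fam):
        raise UnresolvedCommodityError(cid)
    ref = reference
    if "commodity_id" in getattr(ref, "columns", ()):
        ref = ref.set_index("commodity_id")
    if fam not in ref.index:
        raise UnresolvedCommodityError(cid, f"family member {fam!r} not in reference")
    fam_row = ref.loc[fam]
    fam_fru = fam_row["fructose_per_100g"]
    fam_carb = fam_row["carb_per_100g"]
    if pd.isna(fam_fru):
        raise UnresolvedCommodityError(
            cid, f"family member {fam!r} has no direct fructose value"
        )
    if pd.isna(fam_carb) or fam_carb == 0:
        raise UnresolvedCommodityError(
            cid, f"family member {fam!r} has zero/missing carbohydrate"
        )
    fraction = float(profile["carb_per_100g"]) / 100.0 * (float(fam_fru) / float(fam_carb))
    return fraction, PROVENANCE_RATIO


def build_fraction_audit(reference: pd.DataFrame) -> pd.DataFrame:
    """Resolve every commodity in the reference, producing the audit table.

    Returns a DataFrame ``commodity_id, fraction, provenance``; unresolved
    commodities get fraction 0 and provenance ``unresolved`` (they contribute
    no fructose and are counted, mirroring partial nutrient coverage).
    Added-sugar commodities are listed with their direct free-fructose value
    (0 if absent) — ratio imputation only applies to natural commodities.
    """
    ref_ix = reference.set_index("commodity_id", drop=False)
    rows = []
    for cid, row in ref_ix.iterrows():
        if bool(row["is_added_sugar"]):
            fru = row["fructose_per_100g"]
            frac = 0.0 if pd.isna(fru) else float(fru) / 100.0
            rows.append((cid, frac, PROVENANCE_DIRECT))
            continue
        try:
            frac, prov = resolve_fructose_fraction(row, ref_ix)
        except UnresolvedCommodityError:
            frac, prov = 0.0, PROVENANCE_UNRESOLVED
        rows.append((cid, frac, prov))
    return pd.DataFrame(rows, columns=["commodity_id", "fraction", "provenance"])


def partition_corn_sweetener(mass_g: float, mix: SweetenerMix) -> float:
    """Free fructose (g) delivered by ``mass_g`` of aggregate corn sweetener.

    The mass is split across HFCS-55 / HFCS-42 / corn syrup by the mix's
    disappearance shares; each component contributes its free-fructose
    fraction.  The remainder is non-fructose sugar (glucose), tracked by the
    caller for conservation.
    """
    if mass_g < 0:
        raise DomainError("corn sweetener mass must be non-negative")
    if not isinstance(mix, SweetenerMix):
        mix = SweetenerMix(**mix)  # raises InvalidMixError on bad shares
    total = mix.share_hfcs55 + mix.share_hfcs42 + mix.share_corn_syrup
    if abs(total - 1.0) > 1e-9:
        raise InvalidMixError(f"shares sum to {total}, expected 1")
    return mass_g * mix.unbound_fructose_fraction


def added_bound_fructose(added_sucrose_g: float) -> float:
    """Bound fructose: one half of the sucrose mass from added sugars."""
    if added_sucrose_g < 0:
        raise DomainError("added sucrose mass must be non-negative")
    return 0.5 * added_sucrose_g


def estimate_intakes(
    recalls: pd.DataFrame,
    composition: pd.DataFrame,
    reference: pd.DataFrame,
    mix: SweetenerMix,
    energy_kcal,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate per-subject fructose intake components.

    Parameters
    ----------
    recalls, composition, reference
        The three input tables (see module docstring).
    mix
        Corn-sweetener apportionment.
    energy_kcal
        Mapping or Series: subject_id -> daily energy intake (kcal), used
        for the percent-of-energy columns.

    Returns
    -------
    (intakes, audit)
        ``intakes`` has one row per subject appearing in ``recalls`` with
        the five mass components, their %-energy counterparts, the energy
        used and a ``zero_energy`` flag (True when %-energy is undefined).
        ``audit`` is the commodity-level provenance table from
        :func:`build_fraction_audit`.
    """
    audit = build_fraction_audit(reference)
    masses = decompose(recalls, composition)

    ref = reference.copy()
    natural_frac = audit.set_index("commodity_id")["fraction"]

    subjects = pd.Index(sorted(recalls["subject_id"].unique()), name="subject_id")
    natural = pd.Series(0.0, index=subjects)
    added_unbound = pd.Series(0.0, index=subjects)
    added_bound = pd.Series(0.0, index=subjects)

    if len(masses):
        m = masses.merge(
            ref[["commodity_id", "is_added_sugar", "sweetener_class", "sucrose_per_100g"]],
            on="commodity_id",
            how="left",
        )
        m["res_fraction"] = m["commodity_id"].map(natural_frac)

        nat = m[~m["is_added_sugar"].astype(bool)]
        if len(nat):
            contrib = nat["mass_g"] * nat["res_fraction"]
            natural = natural.add(
                contrib.groupby(nat["subject_id"]).sum(), fill_value=0.0
            )

        add = m[m["is_added_sugar"].astype(bool)]
        if len(add):
            corn = add["sweetener_class"] == "corn_sweetener"
            corn_free = add.loc[corn, "mass_g"] * mix.unbound_fructose_fraction
            other_free = add.loc[~corn, "mass_g"] * add.loc[~corn, "res_fraction"]
            free = pd.concat([corn_free, other_free])
            added_unbound = added_unbound.add(
                free.groupby(add["subject_id"]).sum(), fill_value=0.0
            )
            # bound fructose: half the sucrose mass of each added-sugar
            # commodity; corn sweeteners carry no sucrose by convention
            sucrose = add["mass_g"] * add["sucrose_per_100g"].fillna(0.0) / 100.0
            bound = 0.5 * sucrose
            added_bound = added_bound.add(
                bound.groupby(add["subject_id"]).sum(), fill_value=0.0
            )

    out = pd.DataFrame(
        {
            "natural_unbound_g": natural,
            "added_unbound_g": added_unbound,
            "added_bound_g": added_bound,
        }
    )
    out["all_added_g"] = out["added_unbound_g"] + out["added_bound_g"]
    out["total_g"] = out["all_added_g"] + out["natural_unbound_g"]

    energy = pd.Series(energy_kcal)
    out["energy_kcal"] = energy.reindex(out.index)
    zero = ~(out["energy_kcal"] > 0)
    out["zero_energy"] = zero.fillna(True)
    with np.errstate(divide="ignore", invalid="ignore"):
        for col in COMPONENT_COLUMNS:
            pct = 100.0 * KCAL_PER_G_FRUCTOSE * out[col] / out["energy_kcal"]
            pct[out["zero_energy"]] = np.nan
            out[col.removesuffix("_g") + "_pct_energy"] = pct
    return out.reset_index(), audit


def natural_bound_underestimate(
    total_sugars_g: float,
    added_sugars_g: float,
    lactose_g: float,
    sucrose_to_sugar_ratio: float,
) -> float:
    """Upper bound on unaccounted naturally-occurring bound fructose (g/d).

    Subtracting added sugars and dairy lactose from total sugars leaves the
    natural (mostly fruit/vegetable) sugars; scaling by the supply-side
    sucrose-to-total-sugar ratio and halving (the fructose moiety of
    sucrose) bounds the bound fructose the estimator cannot see.  A negative
    remainder clamps to zero — the quantity is a bound, not a balance.
    """
    if not 0.0 <= sucrose_to_sugar_ratio <= 1.0:
        raise DomainError(
            f"sucrose_to_sugar_ratio must be in [0, 1], got {sucrose_to_sugar_ratio}"
        )
    remainder = max(0.0, total_sugars_g - added_sugars_g - lactose_g)
    return remainder * sucrose_to_sugar_ratio * 0.5


@dataclass(frozen=True)
class FructoseIntake:
    """Per-subject intake components (grams/day and % of energy)."""

    subject_id: object
    natural_unbound_g: float
    added_unbound_g: float
    added_bound_g: float
    all_added_g: float
    total_g: float
    energy_kcal: float
    natural_unbound_pct_energy: float = float("nan")
    added_unbound_pct_energy: float = float("nan")
    added_bound_pct_energy: float = float("nan")
    all_added_pct_energy: float = float("nan")
    total_pct_energy: float = float("nan")
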