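"""Configuration objects shared across the pipeline.

The scenario configuration fixes every stochastic choice the synthetic cohort
generator makes; together with the seed it is a complete recipe for the four
input tables.  The sweetener mix and cut-off scheme are small value objects
used by the intake estimator and the hyperuricemia classifier respectively.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import InvalidConfigError, InvalidMixError

#: Sweetener classes recognised in the commodity reference.  ``none`` marks a
#: commodity that is not an added caloric sweetener.
SWEETENER_CLASSES = ("none", "cane_beet", "corn_sweetener", "honey", "maple", "sorghum")

#: Exposures for which the generator can plant per-level log-odds effects.
PLANTABLE_EXPOSURES = ("fructose", "alcohol", "fiber")

#: Serum uric acid unit conversion: 1 mg/dL = 59.48 umol/L.
MG_DL_TO_UMOL_L = 59.48

#: Energy density of fructose, kcal per gram (standard carbohydrate factor).
KCAL_PER_G_FRUCTOSE = 4.0


class SweetenerMix(BaseModel):
    """Apportionment of the aggregate corn-sweetener commodity.

    Food composition tables name corn sweeteners as a single commodity, so
    the free-fructose yield of a gram of "corn sweetener" is the disappearance
    -share-weighted average over HFCS-55, HFCS-42 and plain corn syrup.  The
    per-component free-fructose fractions default to the nominal 55% / 42% /
    0% of sugars; the shares default to an even HFCS split, and both are
    plain parameters because no single authoritative split is claimed.
    """

    model_config = ConfigDict(frozen=True)

    share_hfcs55: float = Field(default=0.5, ge=0.0, le=1.0)
    share_hfcs42: float = Field(default=0.4, ge=0.0, le=1.0)
    share_corn_syrup: float = Field(default=0.1, ge=0.0, le=1.0)
    frac_hfcs55: float = Field(default=0.55, ge=0.0, le=1.0)
    frac_hfcs42: float = Field(default=0.42, ge=0.0, le=1.0)
    frac_corn_syrup: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _shares_sum_to_one(self) -> "SweetenerMix":
        total = self.share_hfcs55 + self.share_hfcs42 + self.share_corn_syrup
        if abs(total - 1.0) > 1e-9:
            raise InvalidMixError(f"sweetener shares sum to {total!r}, expected 1")
        return self

    @property
    def unbound_fructose_fraction(self) -> float:
        """Grams of free fructose per gram of aggregate corn sweetener."""
        return (
            self.share_hfcs55 * self.frac_hfcs55
            + self.share_hfcs42 * self.frac_hfcs42
            + self.share_corn_syrup * self.frac_corn_syrup
        )


class CutoffScheme(BaseModel):
    """Sex-specific serum uric acid cut-offs defining hyperuricemia (mg/dL)."""

    model_config = ConfigDict(frozen=True)

    male_cutoff: float = Field(gt=0.0)
    female_cutoff: float = Field(gt=0.0)
    label: str

    @model_validator(mode="after")
    def _ordered(self) -> "CutoffScheme":
        if not self.male_cutoff > self.female_cutoff:
            raise InvalidConfigError(
                f"male cut-off ({self.male_cutoff}) must exceed female "
                f"cut-off ({self.female_cutoff})"
            )
        return self

    def cutoff_for(self, sex: str) -> float:
        from .errors import DomainError

        if sex == "male":
            return self.male_cutoff
        if sex == "female":
            return self.female_cutoff
        raise DomainError(f"unknown sex {sex!r}; expected 'male' or 'female'")


#: Upper limits of the clinical normal reference range (>8.4 men, >7.5 women).
CDC_SCHEME = CutoffScheme(male_cutoff=8.4, female_cutoff=7.5, label="cdc")
#: Lower cut-offs used by older studies (>7 men, >6 women), for sensitivity.
LEGACY_SCHEME = CutoffScheme(male_cutoff=7.0, female_cutoff=6.0, label="legacy_7_6")

SCHEMES = {s.label: s for s in (CDC_SCHEME, LEGACY_SCHEME)}


class ScenarioConfig(BaseModel):
    """Recipe for one synthetic cohort scenario.

    Parameters
    ----------
    n_subjects
        Cohort size before exclusions (minimum 40).
    seed
        Root seed; all randomness in the generator derives from it.
    prevalence_target
        Hyperuricemia probability for a subject at the reference level of
        every planted exposure.  Default 0.025 (2.5%).
    effect_log_odds
        Map exposure name -> length-4 list of per-level log-odds increments
        relative to level 1 (first entry must be 0).  Allowed names:
        ``fructose`` (total fructose quartile), ``alcohol`` (intake level),
        ``fiber`` (density quartile).
    sex_cutoffs
        (male, female) uric acid cut-offs, mg/dL, used when drawing
        concentrations consistent with sampled hyperuricemia status.
    food_db_size, commodity_db_size
        Sizes of the synthetic food and commodity vocabularies.
    missing_fructose_fraction
        Fraction of fructose-bearing natural commodities whose direct
        fructose value is withheld, forcing ratio imputation via a family
        member.
    fructose_sugar_corr
        Target correlation between per-subject total fructose and total
        sugars, induced through the shared sweet-diet latent factor.
    unreliable_fraction
        Fraction of subjects whose dietary recall is flagged unreliable.
    disease_fraction
        Per-disease probability of each exclusion flag (diabetes, cancer,
        heart disease).
    """

    model_config = ConfigDict(frozen=True)

    n_subjects: int = Field(default=2000, ge=40)
    seed: int = Field(default=0, ge=0)
    prevalence_target: float = Field(default=0.025, gt=0.0, lt=1.0)
    effect_log_odds: dict[str, tuple[float, float, float, float]] = Field(
        default_factory=dict
    )
    sex_cutoffs: tuple[float, float] = (8.4, 7.5)
    food_db_size: int = Field(default=60, ge=0)
    commodity_db_size: int = Field(default=80, ge=0)
    missing_fructose_fraction: float = Field(default=0.2, ge=0.0, lt=1.0)
    fructose_sugar_corr: float = Field(default=0.94, gt=0.0, lt=1.0)
    unreliable_fraction: float = Field(default=0.02, ge=0.0, lt=1.0)
    disease_fraction: float = Field(default=0.02, ge=0.0, lt=1.0)

    @model_validator(mode="after")
    def _check_effects(self) -> "ScenarioConfig":
        for name, levels in self.effect_log_odds.items():
            if name not in PLANTABLE_EXPOSURES:
                raise InvalidConfigError(
                    f"unknown exposure {name!r} in effect_log_odds; "
                    f"allowed: {', '.join(PLANTABLE_EXPOSURES)}"
                )
            if len(levels) != 4:
                raise InvalidConfigError(
                    f"effect_log_odds[{name!r}] must have 4 per-level entries"
                )
            if levels[0] != 0.0:
                raise InvalidConfigError(
                    f"effect_log_odds[{name!r}][0] is the reference level and "
                    "must be 0"
                )
        if not self.sex_cutoffs[0] > self.sex_cutoffs[1] > 0:
            raise InvalidConfigError(
                "sex_cutoffs must satisfy male > female > 0, got "
                f"{self.sex_cutoffs}"
            )
        return self

    @property
    def cutoff_scheme(self) -> CutoffScheme:
        return CutoffScheme(
            male_cutoff=self.sex_cutoffs[0],
            female_cutoff=self.sex_cutoffs[1],
            label="scenario",
        )


class RunConfig(BaseModel):
    """End-to-end pipeline run configuration.

    Exactly one of ``scenario`` (synthetic inputs) or ``input_dir`` (a
    directory holding the four delimited input tables) must be given.
    """

    model_config = ConfigDict(frozen=True)

    scenario: Optional[ScenarioConfig] = None
    input_dir: Optional[str] = None
    cutoff_scheme: str = "cdc"
    sweetener_mix: SweetenerMix = SweetenerMix()
    seed: int = Field(default=0, ge=0)
    output_dir: str = "fructrisk-out"
    weighted_quartiles: bool = False

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.scenario is None) == (self.input_dir is None):
            raise InvalidConfigError(
                "exactly one of 'scenario' and 'input_dir' must be provided"
            )
        if self.cutoff_scheme not in SCHEMES:
            raise InvalidConfigError(
                f"unknown cutoff scheme {self.cutoff_scheme!r}; "
                f"known: {', '.join(SCHEMES)}"
            )
        return self
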