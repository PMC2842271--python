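"""Exception hierarchy.

Every error raised by the package derives from :class:`FructriskError`, so
callers can catch one type at a pipeline boundary.  Errors that signal a
violated numeric domain (negative mass, ratio outside [0, 1]) derive from
``ValueError`` as well.
"""


class FructriskError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(FructriskError):
    """A scenario or run configuration is internally inconsistent.

    Deliberately not a ``ValueError`` so that pydantic validators propagate
    it unwrapped.
    """


class UnknownFoodError(FructriskError, KeyError):
    """A recall record references a food id absent from the composition table."""

    def __init__(self, food_ids):
        self.food_ids = sorted(map(str, food_ids))
        super().__init__(
            "food id(s) missing from composition table: " + ", ".join(self.food_ids)
        )


class UnresolvedCommodityError(FructriskError, LookupError):
    """A commodity has neither a direct fructose value nor a usable family link."""

    def __init__(self, commodity_id, reason="no direct value and no resolvable family"):
        self.commodity_id = commodity_id
        super().__init__(f"commodity {commodity_id!r}: {reason}")


class InvalidMixError(FructriskError):
    """Corn-sweetener mix shares do not form a valid partition."""


class DomainError(FructriskError, ValueError):
    """A scalar input lies outside its physical or logical domain."""


class EmptyCohortError(FructriskError):
    """All subjects were removed by the exclusion rules."""


class DegenerateDistributionError(FructriskError, ValueError):
    """A vector with no spread cannot be split into quartiles."""


class SingularFitError(FructriskError, ValueError):
    """Design matrix is rank deficient (perfectly collinear covariates)."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "singular fit; collinear or constant design columns: "
            + ", ".join(map(str, self.columns))
        )


class PipelineStageError(FructriskError):
    """Wraps an error with the pipeline stage in which it occurred."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage!r} failed: {original}")
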