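"""Exception hierarchy for skinperm.

Every hard failure raises a subclass of :class:`SkinpermError` so callers
(and the CLI) can catch one base class and still discriminate on type.
"""


class SkinpermError(Exception):
    """Base class for all skinperm errors."""


class MissingDescriptorError(SkinpermError):
    """A required descriptor value is absent from a record."""

    def __init__(self, descriptor: str, record_id: str | None = None):
        self.descriptor = descriptor
        self.record_id = record_id
        where = f" for record '{record_id}'" if record_id else ""
        super().__init__(f"missing descriptor '{descriptor}'{where}")


class DescriptorMismatchError(SkinpermError):
    """Model coefficient keys do not line up with the supplied values."""

    def __init__(self, missing: list[str], model_name: str | None = None):
        self.missing = list(missing)
        which = f" for model '{model_name}'" if model_name else ""
        super().__init__(
            f"descriptor values missing{which}: {', '.join(self.missing)}"
        )


class UnitError(SkinpermError):
    """Unknown permeability unit token or unit mismatch between series."""


class ConfigurationError(SkinpermError):
    """A required piece of configuration was not supplied or is invalid."""


class CollinearityError(SkinpermError):
    """The regression design matrix is rank deficient."""

    def __init__(self, columns: list[str]):
        self.columns = list(columns)
        super().__init__(
            "rank-deficient design matrix; linearly dependent columns: "
            + ", ".join(self.columns)
        )


class SampleSizeError(SkinpermError):
    """Too few records for the requested fit or validation scheme."""


class DegenerateDataError(SkinpermError):
    """Data that defeat a resampling procedure (persistent rank deficiency)."""


class SplitError(SkinpermError):
    """A train/validation split would leave one side empty."""


class FoldError(SkinpermError):
    """Invalid cross-validation fold specification (e.g. k > n)."""


class ZeroVarianceError(SkinpermError):
    """A constant column was passed where variance is required."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"column '{column}' has zero variance")


class DuplicateIdError(SkinpermError):
    """Duplicate chemical identifiers in an input table."""

    def __init__(self, ids: list[str]):
        self.ids = list(ids)
        super().__init__(f"duplicate record ids: {', '.join(self.ids)}")


class TableFormatError(SkinpermError):
    """Structural problem with an input table (missing id column, ...)."""


class AlignmentError(SkinpermError):
    """Prediction vector ids do not align with the target table."""
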