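"""Exception hierarchy shared across the package.

Validation errors (bad input data, broken invariants) are kept distinct from
computation errors (undefined indices, solver failures) so the CLI can map
them to different exit codes.
"""


class CasemixError(Exception):
    """Base class for all package errors."""


class SchemaError(CasemixError):
    """An input table is missing required columns or has the wrong dtypes."""


class CohortValidationError(CasemixError):
    """A row-level or cohort-level invariant is violated."""


class StructuralError(CohortValidationError):
    """Unit structure is inconsistent (e.g. a team mapped to two centres)."""


class MissingAcgError(CasemixError):
    """A cohort contains ACG codes absent from the reference profile."""

    def __init__(self, codes):
        self.codes = sorted(codes)
        super().__init__(
            "ACG codes absent from the reference profile: "
            + ", ".join(map(str, self.codes))
        )


class UndefinedIndexError(CasemixError):
    """An observed/expected ratio is undefined (zero or negative denominator)."""


class ConfigError(CasemixError):
    """A generator or analysis configuration is invalid or infeasible."""


class PipelineError(CasemixError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
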