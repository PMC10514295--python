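"""Exception hierarchy shared across the analysis stages.

Everything derives from :class:`InhibkitError`; input-validation problems
derive from :class:`ValidationError`, which the CLI maps to exit code 2.
"""


class InhibkitError(Exception):
    """Base class for all package errors."""


class ValidationError(InhibkitError):
    """Invalid or malformed input data."""


class InvalidControlError(ValidationError):
    """Control absorbance is nonpositive, so percent inhibition is undefined."""


class InsufficientDataError(ValidationError):
    """Too few points (or too few distinct concentrations) to fit."""


class InsufficientReplicatesError(ValidationError):
    """Fewer than two replicates in a group submitted to a t-test."""


class NonInhibitorError(InhibkitError):
    """Logit slope is nonpositive: the dose-response is not inhibitory."""


class ExtrapolationError(InhibkitError):
    """Dose-response never crosses 50% inhibition within the clip band."""


class NonSaturatingDataError(InhibkitError):
    """Double-reciprocal intercept <= 0: velocities do not saturate."""


class NoInhibitionError(InhibkitError):
    """Km_app does not increase with inhibitor; Ki is undefined/infinite."""


class InvalidReplotError(InhibkitError):
    """Secondary-replot intercept <= 0: no meaningful uninhibited Km."""


class MissingBaselineError(ValidationError):
    """Titration lacks the ligand-free point that defines F0."""


class NoQuenchingError(InhibkitError):
    """No titration point is quenched below F0; the transform is empty."""


class InvalidBindingError(InhibkitError):
    """Quench-plot slope <= 0: no association constant can be extracted."""


class InvalidCompositionError(ValidationError):
    """Secondary-structure percentages do not sum to ~100%."""


class ModelViolationError(InhibkitError):
    """Mass-balance quadratic has no root in [0, 1)."""


class SchemaError(ValidationError):
    """CSV header or cell content does not match the expected schema."""


class EmptyInputError(ValidationError):
    """Input table contains no data rows."""


class EmptyReportError(ValidationError):
    """Report requested with no populated sections."""
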