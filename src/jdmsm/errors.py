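"""Exception hierarchy shared across the pipeline."""


class JdmsmError(Exception):
    """Base class for all package errors."""


class SchemaError(JdmsmError):
    """A required column is missing or an input file does not match the schema."""


class ValidationError(JdmsmError):
    """Data violate a documented invariant (range, ordering, consistency)."""


class EmptyCohortError(JdmsmError):
    """A filtering step removed every patient."""


class InsufficientDataError(JdmsmError):
    """Too little data to carry out the requested computation."""


class SeparationError(JdmsmError):
    """A logistic sub-model is (quasi-)separated; a covariate perfectly
    predicts the treatment state."""


class PositivityError(JdmsmError):
    """A predicted probability of treatment is 0 or 1, so inverse-probability
    weights do not exist."""
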