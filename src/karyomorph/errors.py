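"""Exception hierarchy."""


class KaryomorphError(ValueError):
    """Base class for all validation and schema failures raised by this package."""


class SchemaError(KaryomorphError):
    """A tabular input is missing required columns or has an unusable layout."""


class MeasurementError(KaryomorphError):
    """A measurement row or plate violates an invariant (nonpositive length,
    arm order, plate count mismatch in strict mode, ...)."""


class DegenerateInputError(KaryomorphError):
    """An operation is undefined on the given input (e.g. correlation of a
    constant distance matrix, PCoA of identical rows)."""
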