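"""Exception hierarchy for the pipeline.

Separate classes let the CLI map failure kinds onto distinct exit codes.
"""


class DtialpsError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DtialpsError):
    """A file could be read but its structure is inconsistent (e.g. volume
    count mismatch between image and gradient table)."""


class ValidationError(DtialpsError):
    """Input values violate a domain invariant (negative signal, unknown ROI
    name, sex code outside {M, F}, ...)."""


class SchemaError(DtialpsError):
    """A tabular input is missing required columns or has non-numeric
    entries where numbers are required."""


class EstimationError(DtialpsError):
    """Model fitting failed (rank-deficient diffusion-encoding design,
    empty mask, ...)."""
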