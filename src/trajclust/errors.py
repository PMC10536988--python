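"""Exception hierarchy shared across the package.

Three broad families map onto the CLI's distinct exit codes: usage errors
(handled by click itself), validation errors (bad data or bad parameter
values), and contract errors (a caller violated an API precondition).
"""


class TrajclustError(Exception):
    """Base class for all package errors."""


class ValidationError(TrajclustError):
    """Input data violates a documented invariant (bad file, bad value)."""


class ParseError(ValidationError):
    """A text input could not be parsed; message names the offending line."""


class StructureError(ValidationError):
    """Structurally inconsistent inputs (atom counts, symbol mismatches...)."""


class ReferenceError_(ValidationError):
    """A cross-reference (e.g. a trajectory id) could not be resolved."""


class ParameterError(ValidationError):
    """A parameter value is outside its legal domain."""


class GeometryError(ValidationError):
    """A geometric quantity is undefined for the given atom positions."""


class ContractError(TrajclustError):
    """An API precondition was violated by the caller."""


class SpecError(ValidationError):
    """A synthetic-ensemble specification is inconsistent."""


class FeatureUnavailableError(TrajclustError):
    """A requested analysis needs data the ensemble does not carry."""
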