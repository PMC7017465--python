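"""Exception hierarchy shared across the package."""


class CanSeqError(Exception):
    """Base class for all package errors."""


class InputError(CanSeqError):
    """Malformed or out-of-bounds input (file, position, argument)."""


class ModelValidationError(CanSeqError):
    """A gene model violates its structural invariants."""


class UnsupportedOperationError(CanSeqError):
    """Operation requires information the object does not carry."""


class ConsistencyError(CanSeqError):
    """Two inputs that must agree do not (e.g. call vs reference base)."""
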