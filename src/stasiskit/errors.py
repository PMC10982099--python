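"""Typed exceptions shared across the package."""


class StasisKitError(ValueError):
    """Base class for all domain errors raised by stasiskit."""


class DomainError(StasisKitError):
    """An input violates a mathematical precondition (sign, range, ordering)."""


class FlipFlopError(DomainError):
    """Absorption rate not faster than elimination (flip-flop kinetics excluded)."""


class ResistanceError(StasisKitError):
    """Tumour idiosyncratic resistance: g/d >= 1, no finite stasis dose exists."""


class StasisUnreachableError(StasisKitError):
    """The fitted IVIVC curve never reaches TGI = 100 (tgi_max <= 100)."""


class UndefinedTGIError(StasisKitError):
    """Control volume change is zero, so TGI is undefined."""


class FitError(StasisKitError):
    """IVIVC fit could not be performed (under-determined or non-convergent)."""


class SchemaError(StasisKitError):
    """A CSV table does not conform to the study-record schema."""
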