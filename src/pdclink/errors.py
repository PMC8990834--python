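"""Exception hierarchy for pdclink."""


class PdclinkError(Exception):
    """Base class for all pdclink errors."""


class SchemaError(PdclinkError):
    """An input table is missing required columns or carries forbidden ones."""


class ValidationError(PdclinkError):
    """A row or record violates a domain invariant."""


class MissingProductError(PdclinkError):
    """A product code referenced by an event is absent from the catalog."""


class DoseParseError(PdclinkError):
    """A free-text dose instruction does not match the supported grammar.

    Carries the offending text so callers can log it.
    """

    def __init__(self, text: str):
        self.text = text
        super().__init__(f"unparseable dose instruction: {text!r}")
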