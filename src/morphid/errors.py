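"""Exception types raised across the pipeline."""


class MorphidError(ValueError):
    """Base class for all morphid errors."""


class ParseError(MorphidError):
    """A table cell could not be parsed (non-numeric content)."""


class ValidationError(MorphidError):
    """A structural contract on a table, config or model was violated."""
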