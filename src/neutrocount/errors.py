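"""Exception hierarchy.

Exit-code mapping for the CLI: ValidationError (and subclasses) -> 1,
OSError -> 2, everything else is a bug.
"""


class ValidationError(ValueError):
    """Invalid input values or violated type invariants."""


class ParseError(ValidationError):
    """Malformed content in a label or table file; message names the line."""


class CapacityError(RuntimeError):
    """Object placement failed: the tile cannot hold the requested objects."""
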