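"""Exception hierarchy for activation/recognition grammars."""


class ArgramError(Exception):
    """Base class for all domain errors raised by this package."""


class GrammarSyntaxError(ArgramError):
    """Raised when grammar text cannot be tokenized or parsed.

    Carries the character offset of the offending token so callers can
    point at the exact position in the source text.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at character {position})"
        super().__init__(message)


class GrammarStructureError(ArgramError):
    """Raised when a grammar violates a structural invariant (duplicate
    heads, undefined nonterminals, empty alternates, unclassifiable
    terminals, non-injective renamings, ...)."""


class DescriptionError(ArgramError):
    """Raised when a quote/unquote description is malformed or a weight
    cannot be represented at the configured quote precision."""


class EnvironmentError_(ArgramError):
    """Raised on invalid environment operations (unknown actuator, reading
    past the end of a finite token stream snapshot, ...)."""
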