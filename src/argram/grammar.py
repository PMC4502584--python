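"""Data model, parser, serializer, and validator for probability-weighted
activation/recognition grammars.

The notation is a minimal subset of Wirth's syntax notation augmented with
probabilities.  A grammar is a sequence of rules, each terminated by ``.``;
a rule is a head nonterminal, ``=``, and one or more alternates separated by
``|``; an alternate is an optional numeric weight followed by one or more
symbols.  Terminals are either *actuators* (they produce output) or
*sensors* (they match/consume input); which is which is declared in an
explicit terminal registry, never inferred from spelling.  Symbols prefixed
``Quote``/``Unquote`` are the quotation operators used by describing
grammars and need no registry entry.

Example::

    A = .3 B | .7 C. B = DrawSquare. C = DrawCircle.

parses to a two-alternate rule for ``A`` with weights 0.3/0.7 and two
single-actuator rules.  Unweighted alternates are read as equipartition:
``A = B | C | D | E.`` assigns each alternate weight 0.25.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .errors import DescriptionError, GrammarStructureError, GrammarSyntaxError

__all__ = [
    "SymbolKind",
    "GrammarSymbol",
    "Alternate",
    "Rule",
    "Grammar",
    "Diagnostic",
    "DEFAULT_REGISTRY",
    "parse_grammar",
    "serialize_grammar",
    "validate",
    "rename_for_readability",
    "structurally_equal",
    "quote_name",
    "unquote_name",
    "encode_weight",
    "decode_weight",
    "load_registry",
    "format_weight",
]

QUOTE_PREFIX = "Quote"
UNQUOTE_PREFIX = "Unquote"
WEIGHT_QUOTE_PREFIX = "QuotePoint"

#: Terminal directions for every terminal used by the figure grammars.
#: ``0``/``1`` default to sensors (their Turing-machine role); grammars that
#: *produce* digits are parsed with a per-grammar override.
DEFAULT_REGISTRY: dict[str, str] = {
    # actuators
    "DrawSquare": "actuator",
    "DrawCircle": "actuator",
    "DrawTriangle": "actuator",
    "Look": "actuator",
    "Describe": "actuator",
    "PrintGreenPoint": "actuator",
    "PrintRedPoint": "actuator",
    "Pe": "actuator",
    "P0": "actuator",
    "P1": "actuator",
    "Px": "actuator",
    "R": "actuator",
    "L": "actuator",
    "E": "actuator",
    # sensors
    "SpotSquare": "sensor",
    "SpotCircle": "sensor",
    "SpotTriangle": "sensor",
    "See": "sensor",
    "SpotGreenPoint": "sensor",
    "SpotRedPoint": "sensor",
    "ReadGreenPoint": "sensor",
    "ReadRedPoint": "sensor",
    "0": "sensor",
    "1": "sensor",
    "None": "sensor",
    "x": "sensor",
    "e": "sensor",
    # class terminals of the root grammar: match any symbol / weight token
    "Symbol": "sensor",
    "Weight": "sensor",
}


class SymbolKind(Enum):
    NONTERMINAL = "nonterminal"
    SENSOR = "sensor-terminal"
    ACTUATOR = "actuator-terminal"
    QUOTED = "quoted"
    UNQUOTED = "unquoted"
    WEIGHT_LITERAL = "weight-literal"


_FORBIDDEN = set(" \t\r\n=|.")


@dataclass(frozen=True)
class GrammarSymbol:
    """A token of the grammar alphabet together with its role."""

    name: str
    kind: SymbolKind

    def __post_init__(self):
        if not self.name or any(c in _FORBIDDEN for c in self.name):
            raise GrammarStructureError(
                f"illegal symbol name {self.name!r}: must be non-empty and "
                "contain no whitespace, '=', '|', or '.'"
            )

    @property
    def is_terminal(self) -> bool:
        return self.kind is not SymbolKind.NONTERMINAL

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True)
class Alternate:
    """One weighted right-hand-side option of a rule.

    ``weight`` is the normalized probability (the parser divides raw
    weights by their per-rule sum); ``symbols`` is never empty — the
    grammars are context-free *without null symbol*.
    """

    weight: float
    symbols: tuple[GrammarSymbol, ...]

    def __post_init__(self):
        if not self.symbols:
            raise GrammarStructureError("empty alternate (null symbols are not supported)")
        if self.weight < 0:
            raise GrammarStructureError(f"negative weight {self.weight}")


@dataclass(frozen=True)
class Rule:
    head: GrammarSymbol
    alternates: tuple[Alternate, ...]

    def __post_init__(self):
        if self.head.kind is not SymbolKind.NONTERMINAL:
            raise GrammarStructureError(f"rule head {self.head.name!r} must be a nonterminal")
        if not self.alternates:
            raise GrammarStructureError(f"rule {self.head.name!r} has no alternates")


@dataclass(frozen=True)
class Grammar:
    """An ordered set of rules; the start symbol is the first rule's head."""

    rules: tuple[Rule, ...]

    def __post_init__(self):
        if not self.rules:
            raise GrammarStructureError("a grammar needs at least one rule")

    @property
    def start(self) -> GrammarSymbol:
        return self.rules[0].head

    @property
    def rule_map(self) -> dict[str, Rule]:
        return {r.head.name: r for r in self.rules}

    def nonterminals(self) -> list[str]:
        return [r.head.name for r in self.rules]

    def terminals(self) -> list[GrammarSymbol]:
        """Distinct terminal symbols in order of first appearance."""
        seen: dict[str, GrammarSymbol] = {}
        for rule in self.rules:
            for alt in rule.alternates:
                for sym in alt.symbols:
                    if sym.is_terminal and sym.name not in seen:
                        seen[sym.name] = sym
        return list(seen.values())


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning"
    rule_index: int | None
    message: str


# ---------------------------------------------------------------------------
# quote / weight-literal codecs
# ---------------------------------------------------------------------------

def quote_name(name: str) -> str:
    return QUOTE_PREFIX + name


def unquote_name(token: str) -> str:
    """Referent of a Quote/Unquote token (``QuoteB`` -> ``B``)."""
    if token.startswith(UNQUOTE_PREFIX):
        ref = token[len(UNQUOTE_PREFIX):]
    elif token.startswith(QUOTE_PREFIX):
        ref = token[len(QUOTE_PREFIX):]
    else:
        raise DescriptionError(f"{token!r} is not a quoted token")
    if not ref:
        raise DescriptionError(f"quoted token {token!r} has an empty referent")
    return ref


def encode_weight(weight: float, precision: int = 2) -> str:
    """Encode a probability as a ``QuotePointNN`` token.

    ``0.61 -> QuotePoint61``, ``0.6 -> QuotePoint6`` (trailing zeros are
    dropped, matching the printed descriptions).  Raises
    :class:`DescriptionError` if the weight is not representable at the
    configured decimal precision — no silent rounding.
    """
    scaled = weight * 10 ** precision
    nearest = round(scaled)
    if abs(scaled - nearest) > 1e-6 * 10 ** precision:
        raise DescriptionError(
            f"weight {weight!r} is not representable with {precision} decimal digits"
        )
    if not 0 <= nearest <= 10 ** precision:
        raise DescriptionError(f"weight {weight!r} outside [0, 1]")
    if nearest == 10 ** precision:
        raise DescriptionError("weight 1.0 is weight-silent in descriptions")
    # left-pad to the full precision, then drop trailing zeros:
    # 61 -> "61", 60 -> "6", 1 -> "01" (so QuotePoint01 is a hundredth)
    digits = str(nearest).zfill(precision).rstrip("0") or "0"
    return WEIGHT_QUOTE_PREFIX + digits


def decode_weight(token: str) -> float:
    """Inverse of :func:`encode_weight` (``QuotePoint61 -> 0.61``)."""
    if not token.startswith(WEIGHT_QUOTE_PREFIX):
        raise DescriptionError(f"{token!r} is not a weight-literal token")
    digits = token[len(WEIGHT_QUOTE_PREFIX):]
    if not digits.isdigit():
        raise DescriptionError(f"malformed weight literal {token!r}")
    return int(digits) / 10 ** len(digits)


def _is_weight_literal(token: str) -> bool:
    return token.startswith(WEIGHT_QUOTE_PREFIX) and token[len(WEIGHT_QUOTE_PREFIX):].isdigit()


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<eq>=)
  | (?P<bar>\|)
  | (?P<number>(?:\d+\.\d+|\.\d+|\d+)(?![\w.]))
  | (?P<name>[^\s=|.]+)
  | (?P<dot>\.)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise GrammarSyntaxError(f"cannot tokenize {text[pos:pos + 10]!r}", pos)
        kind = m.lastgroup
        if kind != "ws":
            tokens.append((kind, m.group(), pos))
        pos = m.end()
    return tokens


_NUMBER_RE = re.compile(r"^(?:\d+\.\d+|\.\d+|\d+)$")


# ---------------------------------------------------------------------------
# parser
# ---------------------------------------------------------------------------

def parse_grammar(
    text: str,
    terminal_registry: Mapping[str, str] | None = None,
) -> Grammar:
    """Parse grammar text into a validated :class:`Grammar`.

    ``terminal_registry`` maps terminal names to ``"sensor"`` or
    ``"actuator"``; it defaults to :data:`DEFAULT_REGISTRY`.  Rule heads
    shadow registry entries (``R`` is a move-right actuator in the Turing
    grammar but an ordinary nonterminal wherever a rule defines it).
    A numeric token is read as a weight when it is fractional, or when it
    is an integer that neither the registry nor the rule heads classify —
    so ``0`` and ``1`` stay sensors inside the Turing grammar while
    ``A = 3 B | 7 C.`` still parses as raw integer weights.

    Raw weights are normalized to sum to 1 per rule; alternates written
    without weights share the rule's mass equally.
    """
    if not text or not text.strip():
        raise GrammarSyntaxError("empty grammar text")
    registry = dict(DEFAULT_REGISTRY if terminal_registry is None else terminal_registry)
    tokens = _tokenize(text)

    # Split the token stream into raw rules at "." terminators.
    raw_rules: list[list[tuple[str, str, int]]] = []
    current: list[tuple[str, str, int]] = []
    for tok in tokens:
        if tok[0] == "dot":
            if not current:
                raise GrammarSyntaxError("stray '.'", tok[2])
            raw_rules.append(current)
            current = []
        else:
            current.append(tok)
    if current:
        raise GrammarSyntaxError("unterminated rule (missing '.')", current[0][2])
    if not raw_rules:
        raise GrammarSyntaxError("no rules found")

    # First pass: collect heads so RHS occurrences resolve to nonterminals.
    heads: list[str] = []
    for raw in raw_rules:
        if len(raw) < 3 or raw[0][0] not in ("name", "number") or raw[1][0] != "eq":
            pos = raw[0][2]
            raise GrammarSyntaxError("rule must start with '<head> ='", pos)
        head = raw[0][1]
        if head in heads:
            raise GrammarStructureError(f"duplicate rule head {head!r}")
        heads.append(head)
    head_set = set(heads)

    def classify(token: str, pos: int) -> GrammarSymbol:
        if token in head_set:
            return GrammarSymbol(token, SymbolKind.NONTERMINAL)
        if _is_weight_literal(token):
            return GrammarSymbol(token, SymbolKind.WEIGHT_LITERAL)
        if token.startswith(UNQUOTE_PREFIX) and len(token) > len(UNQUOTE_PREFIX):
            return GrammarSymbol(token, SymbolKind.UNQUOTED)
        if token.startswith(QUOTE_PREFIX) and len(token) > len(QUOTE_PREFIX):
            return GrammarSymbol(token, SymbolKind.QUOTED)
        direction = registry.get(token)
        if direction == "sensor":
            return GrammarSymbol(token, SymbolKind.SENSOR)
        if direction == "actuator":
            return GrammarSymbol(token, SymbolKind.ACTUATOR)
        raise GrammarSyntaxError(
            f"unclassifiable terminal {token!r}: not a rule head, not quoted, "
            "and not in the terminal registry",
            pos,
        )

    rules: list[Rule] = []
    for raw in raw_rules:
        head_tok = raw[0]
        body = raw[2:]
        # split body on "|"
        alt_tokens: list[list[tuple[str, str, int]]] = [[]]
        for tok in body:
            if tok[0] == "bar":
                alt_tokens.append([])
            else:
                alt_tokens[-1].append(tok)
        raw_weights: list[float | None] = []
        alt_symbols: list[tuple[GrammarSymbol, ...]] = []
        for alt in alt_tokens:
            if not alt:
                raise GrammarSyntaxError(
                    f"empty alternate in rule {head_tok[1]!r}", head_tok[2]
                )
            weight: float | None = None
            first_kind, first_text, first_pos = alt[0]
            if first_kind == "number":
                fractional = "." in first_text
                known = first_text in head_set or first_text in registry
                if fractional or not known:
                    weight = float(first_text)
                    alt = alt[1:]
            if not alt:
                raise GrammarSyntaxError(
                    f"alternate in rule {head_tok[1]!r} has a weight but no symbols",
                    first_pos,
                )
            symbols = tuple(classify(t[1], t[2]) for t in alt)
            raw_weights.append(weight)
            alt_symbols.append(symbols)

        weights = _normalize_weights(raw_weights, head_tok[1])
        head_sym = GrammarSymbol(head_tok[1], SymbolKind.NONTERMINAL)
        rules.append(
            Rule(
                head=head_sym,
                alternates=tuple(
                    Alternate(weight=w, symbols=s) for w, s in zip(weights, alt_symbols)
                ),
            )
        )

    grammar = Grammar(rules=tuple(rules))
    errors = [d for d in validate(grammar) if d.level == "error"]
    if errors:
        raise GrammarStructureError("; ".join(d.message for d in errors))
    return grammar


def _normalize_weights(raw: list[float | None], head: str) -> list[float]:
    k = len(raw)
    if all(w is None for w in raw):
        return [1.0 / k] * k
    # Missing weights among explicit ones are read as raw weight 1.
    filled = [1.0 if w is None else w for w in raw]
    total = sum(filled)
    if total <= 0:
        raise GrammarStructureError(f"rule {head!r}: weights sum to zero")
    return [w / total for w in filled]


# ---------------------------------------------------------------------------
# serializer
# ---------------------------------------------------------------------------

def format_weight(w: float) -> str:
    """Render a normalized weight the way the notation prints it (``.3``,
    ``.61``); weights are rounded at 9 decimals for stability."""
    s = f"{w:.9f}".rstrip("0")
    if s.endswith("."):
        return s[:-1]  # integral weight, e.g. "1"
    if s.startswith("0."):
        s = s[1:]
    return s


def serialize_grammar(g: Grammar) -> str:
    """Serialize to the plain-text notation.

    Weights are omitted when a rule's alternates are equiprobable (the
    notation reads unweighted alternates as equipartition), so the output
    matches the printed style; parsing the result reproduces a
    structurally identical grammar.
    """
    parts: list[str] = []
    for rule in g.rules:
        k = len(rule.alternates)
        equipartition = all(abs(a.weight - 1.0 / k) <= 1e-9 for a in rule.alternates)
        alt_texts = []
        for alt in rule.alternates:
            symbols = " ".join(s.name for s in alt.symbols)
            if equipartition:
                alt_texts.append(symbols)
            else:
                alt_texts.append(f"{format_weight(alt.weight)} {symbols}")
        parts.append(f"{rule.head.name} = {' | '.join(alt_texts)}.")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(g: Grammar) -> list[Diagnostic]:
    """Check every structural invariant; one diagnostic per violation.

    ``error`` diagnostics are invariant violations; a weight of exactly 0
    is accepted but flagged as a ``warning`` (the formalism describes
    inhibition as low probability, never as impossibility).
    """
    diags: list[Diagnostic] = []
    seen_heads: set[str] = set()
    head_names = {r.head.name for r in g.rules}
    for i, rule in enumerate(g.rules):
        if rule.head.name in seen_heads:
            diags.append(Diagnostic("error", i, f"duplicate head {rule.head.name!r}"))
        seen_heads.add(rule.head.name)
        total = sum(a.weight for a in rule.alternates)
        if abs(total - 1.0) > 1e-9:
            diags.append(
                Diagnostic(
                    "error", i,
                    f"rule {rule.head.name!r}: alternate weights sum to {total}, not 1",
                )
            )
        for alt in rule.alternates:
            if not 0 <= alt.weight <= 1 + 1e-9:
                diags.append(
                    Diagnostic(
                        "error", i,
                        f"rule {rule.head.name!r}: weight {alt.weight} outside [0, 1]",
                    )
                )
            elif alt.weight == 0:
                diags.append(
                    Diagnostic(
                        "warning", i,
                        f"rule {rule.head.name!r}: zero-weight alternate (dead branch)",
                    )
                )
            for sym in alt.symbols:
                if sym.kind is SymbolKind.NONTERMINAL and sym.name not in head_names:
                    diags.append(
                        Diagnostic(
                            "error", i,
                            f"rule {rule.head.name!r}: undefined nonterminal {sym.name!r}",
                        )
                    )
    return diags


# ---------------------------------------------------------------------------
# renaming & structural comparison
# ---------------------------------------------------------------------------

def rename_for_readability(g: Grammar, mapping: Mapping[str, str]) -> Grammar:
    """Substitute nonterminal names (e.g. recasting the root grammar's
    ``A`` as ``Rules``); derivation behavior is unchanged.

    The mapping must be injective on the grammar's nonterminals; unmapped
    nonterminals keep their names (and must not collide with new names).
    Quoted referents are left untouched — they point into a *described*
    grammar, not this one.
    """
    nts = g.nonterminals()
    effective = {n: mapping.get(n, n) for n in nts}
    if len(set(effective.values())) != len(effective):
        raise GrammarStructureError("renaming is not injective on the grammar's nonterminals")

    def rename_sym(sym: GrammarSymbol) -> GrammarSymbol:
        if sym.kind is SymbolKind.NONTERMINAL and sym.name in effective:
            return GrammarSymbol(effective[sym.name], SymbolKind.NONTERMINAL)
        return sym

    return Grammar(
        rules=tuple(
            Rule(
                head=rename_sym(rule.head),
                alternates=tuple(
                    Alternate(alt.weight, tuple(rename_sym(s) for s in alt.symbols))
                    for alt in rule.alternates
                ),
            )
            for rule in g.rules
        )
    )


def structurally_equal(a: Grammar, b: Grammar, tol: float = 1e-9) -> bool:
    """True when the two grammars have identical rule/alternate/symbol
    structure, with weights compared within ``tol``."""
    if len(a.rules) != len(b.rules):
        return False
    for ra, rb in zip(a.rules, b.rules):
        if ra.head != rb.head or len(ra.alternates) != len(rb.alternates):
            return False
        for aa, ab in zip(ra.alternates, rb.alternates):
            if abs(aa.weight - ab.weight) > tol or aa.symbols != ab.symbols:
                return False
    return True


def load_registry(path) -> dict[str, str]:
    """Load a terminal registry from a YAML/JSON ``{name: direction}`` map."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise GrammarStructureError(f"registry {path} is not a mapping")
    out: dict[str, str] = {}
    for key, value in data.items():
        if value not in ("sensor", "actuator"):
            raise GrammarStructureError(
                f"registry entry {key!r}: direction must be 'sensor' or 'actuator'"
            )
        out[str(key)] = value
    return out
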