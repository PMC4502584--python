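"""Quote/unquote self-description: grammars that describe grammars.

A describing grammar encodes another grammar's rules as quoted terminal
tokens (``QuoteA``, ``QuotePrintGreenPoint``, ``QuotePoint61`` for weight
0.61), so a pattern can be manipulated as data by other patterns.  On top
of the encoder/decoder this module provides:

* :func:`root_grammar` — the fixed point of description: the eight-rule
  grammar that recognizes (and can produce) the linearization of any
  grammar, including its own;
* :func:`retarget` — metaphor: a describing grammar that replays a pattern
  while redirecting chosen actuators to a new domain (``UnquoteDrawSquare
  DrawCircle`` counts circles with the square-counting circuit);
* :func:`compose` — dynamic composition: a describing grammar that splices
  a full guest production into a host pattern at a hook terminal, leaving
  both component grammars intact.

Unquote execution is implemented as event interception: the describing
grammar replays the described derivation and substitutes intercepted
actuator events — observably equivalent to the described grammar
forwarding the operation to its describer.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .environments import Environment, RecorderEnvironment
from .engine import Derivation, RecognitionResult, recognize, run
from .errors import DescriptionError, GrammarStructureError
from .grammar import (
    DEFAULT_REGISTRY,
    Alternate,
    Grammar,
    GrammarSymbol,
    Rule,
    SymbolKind,
    decode_weight,
    encode_weight,
    quote_name,
    unquote_name,
    validate,
)

__all__ = [
    "describe",
    "decode_description",
    "interpret_description",
    "DescribedProgram",
    "execute_description",
    "root_grammar",
    "ROOT_GRAMMAR_TEXT",
    "ROOT_READABLE_NAMES",
    "linearize",
    "weight_token",
    "recognizes_description",
    "retarget",
    "compose",
]

#: The printed eight-rule fixed-point grammar.  ``Symbol`` and ``Weight``
#: are class sensors: any symbol token, any weight token.
ROOT_GRAMMAR_TEXT = (
    "A = .5 B | .5 C. "
    "B = Symbol D. "
    "D = .5 E | .5 F. "
    "E = Weight G. "
    "G = .5 Symbol | .5 H. "
    "H = Symbol G. "
    "F = E D. "
    "C = B A."
)

#: Readable recasting of the root grammar's nonterminals.
ROOT_READABLE_NAMES = {
    "A": "Rules",
    "B": "Rule",
    "C": "RulesSequence",
    "D": "Alternates",
    "E": "Alternate",
    "F": "AlternatesSequence",
    "G": "Symbols",
    "H": "SymbolsSequence",
}


def root_grammar() -> Grammar:
    """The ultimate describing grammar: produces and recognizes the
    linearization of any grammar, including its own."""
    from .grammar import parse_grammar

    return parse_grammar(ROOT_GRAMMAR_TEXT)


# ---------------------------------------------------------------------------
# fresh-name allocation
# ---------------------------------------------------------------------------

def _letters(skip: set[str] | None = None) -> Iterator[str]:
    """Deterministic fresh nonterminals: A, B, ..., Z, AA, AB, ..."""
    skip = skip or set()
    import itertools
    import string

    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            name = "".join(combo)
            if name not in skip:
                yield name


# ---------------------------------------------------------------------------
# describe
# ---------------------------------------------------------------------------

def _quote(sym: GrammarSymbol) -> GrammarSymbol:
    return GrammarSymbol(quote_name(sym.name), SymbolKind.QUOTED)


def describe(g: Grammar, precision: int = 2) -> Grammar:
    """Encode ``g`` as a describing grammar (one level of description).

    The top rule sequences one branch per described rule; each branch
    emits the quoted head then, per alternate, ``QuotePointNN`` followed
    by the quoted symbols.  Weight-1 single alternates are weight-silent.
    ``g`` must be quote-free; towers of descriptions are built by calling
    :func:`describe` repeatedly.
    """
    return _describe_impl(g, precision, hook=None, guest=None)


def _describe_impl(
    g: Grammar,
    precision: int,
    hook: Mapping[str, tuple[GrammarSymbol, ...]] | None,
    guest: Grammar | None,
) -> Grammar:
    """Shared generator for describe/retarget/compose.

    ``hook`` maps terminal names to the replacement-body symbols emitted
    after the corresponding ``Unquote`` token; for compose the body is a
    single nonterminal rooting the embedded guest description.
    """
    for rule in g.rules:
        for alt in rule.alternates:
            for sym in alt.symbols:
                if sym.kind in (SymbolKind.QUOTED, SymbolKind.UNQUOTED, SymbolKind.WEIGHT_LITERAL):
                    raise DescriptionError(
                        "describe() takes a quote-free grammar; build towers by repeated calls"
                    )

    alloc = _letters()
    rules: list[Rule] = []
    hook = hook or {}

    def nt(name: str) -> GrammarSymbol:
        return GrammarSymbol(name, SymbolKind.NONTERMINAL)

    def chain_symbols(symbols: tuple[GrammarSymbol, ...]) -> tuple[GrammarSymbol, ...]:
        out: list[GrammarSymbol] = []
        for sym in symbols:
            if sym.is_terminal and sym.name in hook:
                out.append(GrammarSymbol("Unquote" + sym.name, SymbolKind.UNQUOTED))
                out.extend(hook[sym.name])
            else:
                out.append(_quote(sym))
        return tuple(out)

    def emit_branch(head_name: str, rule: Rule) -> None:
        payload_name = next(alloc)
        rules.append(
            Rule(
                head=nt(head_name),
                alternates=(Alternate(1.0, (_quote(rule.head), nt(payload_name))),),
            )
        )
        if len(rule.alternates) == 1:
            rules.append(
                Rule(
                    head=nt(payload_name),
                    alternates=(Alternate(1.0, chain_symbols(rule.alternates[0].symbols)),),
                )
            )
        else:
            alt_names = [next(alloc) for _ in rule.alternates]
            rules.append(
                Rule(
                    head=nt(payload_name),
                    alternates=(Alternate(1.0, tuple(nt(n) for n in alt_names)),),
                )
            )
            for name, alt in zip(alt_names, rule.alternates):
                weight_sym = GrammarSymbol(
                    encode_weight(alt.weight, precision), SymbolKind.WEIGHT_LITERAL
                )
                rules.append(
                    Rule(
                        head=nt(name),
                        alternates=(Alternate(1.0, (weight_sym,) + chain_symbols(alt.symbols)),),
                    )
                )

    if len(g.rules) == 1:
        top = next(alloc)
        emit_branch(top, g.rules[0])
    else:
        top = next(alloc)
        branch_names = [next(alloc) for _ in g.rules]
        rules.append(
            Rule(head=nt(top), alternates=(Alternate(1.0, tuple(nt(n) for n in branch_names)),))
        )
        for name, rule in zip(branch_names, g.rules):
            emit_branch(name, rule)

    if guest is not None:
        # embed the guest description, its top renamed to the hook body symbol
        guest_desc = describe(guest)
        from .grammar import rename_for_readability

        k_name = next(iter(hook.values()))[0].name
        mapping = {guest_desc.start.name: k_name}
        for old in guest_desc.nonterminals():
            if old not in mapping:
                mapping[old] = next(alloc)
        rules.extend(rename_for_readability(guest_desc, mapping).rules)

    out = Grammar(rules=tuple(rules))
    errors = [d for d in validate(out) if d.level == "error"]
    if errors:  # pragma: no cover - internal consistency
        raise DescriptionError("; ".join(d.message for d in errors))
    return out


# ---------------------------------------------------------------------------
# decode / interpret
# ---------------------------------------------------------------------------

Action = tuple[str, object]  # ("emit", name) | ("grammar", Grammar) | ("program", DescribedProgram)


@dataclass
class DescribedProgram:
    """A decoded description: the described grammar plus the unquote
    interceptions attached to its terminals."""

    base: Grammar
    interceptions: dict[str, tuple[Action, ...]] = field(default_factory=dict)


def decode_description(
    d: Grammar, registry: Mapping[str, str] | None = None
) -> Grammar:
    """Exact inverse of :func:`describe` on scheme-conformant input."""
    prog = interpret_description(d, registry)
    if prog.interceptions:
        raise DescriptionError(
            "description carries unquote interceptions; use interpret_description()"
        )
    return prog.base


def interpret_description(
    d: Grammar, registry: Mapping[str, str] | None = None
) -> DescribedProgram:
    """Decode a describing grammar, including unquote interceptions.

    Handles the printed chain style (a trailing nonterminal continues the
    quoted-symbol chain, as in ``F = Quote0 J. J = Unquote1 K.``) as well
    as the weight-explicit alternate encoding this package generates.
    """
    registry = dict(DEFAULT_REGISTRY if registry is None else registry)
    rule_map = d.rule_map
    interceptions: dict[str, tuple[Action, ...]] = {}

    def single_alt(rule: Rule) -> Alternate:
        if len(rule.alternates) != 1:
            raise DescriptionError(
                f"describing rule {rule.head.name!r} must have a single alternate"
            )
        return rule.alternates[0]

    top = d.rules[0]
    top_syms = single_alt(top).symbols
    if top_syms[0].kind is SymbolKind.QUOTED:
        branch_rules = [top]
    else:
        branch_rules = []
        for sym in top_syms:
            if sym.kind is not SymbolKind.NONTERMINAL:
                raise DescriptionError(
                    f"top rule must sequence branch nonterminals, found {sym.name!r}"
                )
            branch_rules.append(rule_map[sym.name])

    # first pass: described heads
    described: list[tuple[str, Rule]] = []
    for branch in branch_rules:
        syms = single_alt(branch).symbols
        if len(syms) != 2 or syms[0].kind is not SymbolKind.QUOTED or (
            syms[1].kind is not SymbolKind.NONTERMINAL
        ):
            raise DescriptionError(
                f"branch {branch.head.name!r} must be 'QuoteHead Payload'"
            )
        described.append((unquote_name(syms[0].name), rule_map[syms[1].name]))
    head_names = [h for h, _ in described]
    if len(set(head_names)) != len(head_names):
        raise DescriptionError("described heads are not unique")
    head_set = set(head_names)

    def referent_symbol(name: str) -> GrammarSymbol:
        if name in head_set:
            return GrammarSymbol(name, SymbolKind.NONTERMINAL)
        direction = registry.get(name)
        if direction == "sensor":
            return GrammarSymbol(name, SymbolKind.SENSOR)
        if direction == "actuator":
            return GrammarSymbol(name, SymbolKind.ACTUATOR)
        raise DescriptionError(f"quoted referent {name!r} is not a known terminal or head")

    def body_actions(symbols: list[GrammarSymbol]) -> tuple[Action, ...]:
        actions: list[Action] = []
        for sym in symbols:
            if sym.kind in (SymbolKind.ACTUATOR, SymbolKind.SENSOR):
                actions.append(("emit", sym.name))
            elif sym.kind is SymbolKind.NONTERMINAL:
                sub = _subgrammar(d, sym.name)
                try:
                    actions.append(("program", interpret_description(sub, registry)))
                except DescriptionError:
                    actions.append(("grammar", sub))
            else:
                raise DescriptionError(
                    f"unexpected {sym.name!r} in an unquote replacement body"
                )
        return actions

    def decode_chain(symbols: tuple[GrammarSymbol, ...]) -> tuple[float | None, tuple[GrammarSymbol, ...]]:
        """Decode one alternate's quoted-symbol chain."""
        weight: float | None = None
        out: list[GrammarSymbol] = []
        queue = list(symbols)
        i = 0
        while i < len(queue):
            sym = queue[i]
            if sym.kind is SymbolKind.WEIGHT_LITERAL:
                if out or weight is not None:
                    raise DescriptionError(f"weight token {sym.name!r} out of place")
                weight = decode_weight(sym.name)
                i += 1
            elif sym.kind is SymbolKind.QUOTED:
                out.append(referent_symbol(unquote_name(sym.name)))
                i += 1
            elif sym.kind is SymbolKind.UNQUOTED:
                name = unquote_name(sym.name)
                out.append(referent_symbol(name))
                i += 1
                # collect the replacement body: symbols up to the next quoted
                # token; a nonterminal whose rule resumes the quote chain is a
                # chain continuation instead
                body: list[GrammarSymbol] = []
                while i < len(queue):
                    nxt = queue[i]
                    if nxt.kind in (SymbolKind.QUOTED, SymbolKind.UNQUOTED, SymbolKind.WEIGHT_LITERAL):
                        break
                    if nxt.kind is SymbolKind.NONTERMINAL:
                        # an embedded description (e.g. the guest grammar of a
                        # composition) belongs to the body; a rule resuming the
                        # quote chain ends it
                        if not _is_description(d, nxt.name, registry) and _resumes_chain(
                            rule_map, nxt.name
                        ):
                            break
                    body.append(nxt)
                    i += 1
                if not body:
                    raise DescriptionError(
                        f"unquote {sym.name!r} without a replacement body"
                    )
                interceptions[name] = body_actions(body)
            elif sym.kind is SymbolKind.NONTERMINAL:
                # chain continuation via a trailing nonterminal
                cont = single_alt(rule_map[sym.name]).symbols
                queue[i:i + 1] = list(cont)
            else:
                raise DescriptionError(
                    f"raw terminal {sym.name!r} in a quoted-symbol chain"
                )
        return weight, tuple(out)

    rules: list[Rule] = []
    for head, payload in described:
        psyms = single_alt(payload).symbols
        child_rules = [
            rule_map.get(s.name) if s.kind is SymbolKind.NONTERMINAL else None
            for s in psyms
        ]
        is_alt_encoding = (
            len(psyms) >= 2
            and all(r is not None for r in child_rules)
            and all(
                r.alternates[0].symbols[0].kind is SymbolKind.WEIGHT_LITERAL
                for r in child_rules
                if len(r.alternates) == 1
            )
            and all(len(r.alternates) == 1 for r in child_rules)
        )
        alts: list[Alternate] = []
        if is_alt_encoding:
            for child in child_rules:
                weight, syms = decode_chain(child.alternates[0].symbols)
                if weight is None:
                    raise DescriptionError(
                        f"alternate rule {child.head.name!r} lacks a QuotePoint weight"
                    )
                if not syms:
                    raise DescriptionError(f"empty alternate under {head!r}")
                alts.append(Alternate(weight, syms))
        else:
            weight, syms = decode_chain(psyms)
            if weight is None:
                weight = 1.0
            if not syms:
                raise DescriptionError(f"empty description chain under {head!r}")
            alts.append(Alternate(weight, syms))
        rules.append(Rule(GrammarSymbol(head, SymbolKind.NONTERMINAL), tuple(alts)))

    base = Grammar(rules=tuple(rules))
    errors = [x for x in validate(base) if x.level == "error"]
    if errors:
        raise DescriptionError("decoded grammar invalid: " + "; ".join(x.message for x in errors))
    return DescribedProgram(base=base, interceptions=interceptions)


def _is_description(d: Grammar, name: str, registry) -> bool:
    try:
        interpret_description(_subgrammar(d, name), registry)
        return True
    except DescriptionError:
        return False


def _resumes_chain(rule_map: dict[str, Rule], name: str) -> bool:
    rule = rule_map.get(name)
    if rule is None or len(rule.alternates) != 1:
        return False
    first = rule.alternates[0].symbols[0]
    return first.kind in (SymbolKind.QUOTED, SymbolKind.UNQUOTED, SymbolKind.WEIGHT_LITERAL)


def _subgrammar(d: Grammar, start: str) -> Grammar:
    """Rules reachable from ``start``, with ``start``'s rule first."""
    rule_map = d.rule_map
    reachable: set[str] = set()
    frontier = [start]
    while frontier:
        name = frontier.pop()
        if name in reachable or name not in rule_map:
            continue
        reachable.add(name)
        for alt in rule_map[name].alternates:
            for sym in alt.symbols:
                if sym.kind is SymbolKind.NONTERMINAL:
                    frontier.append(sym.name)
    ordered = [rule_map[start]] + [
        r for r in d.rules if r.head.name in reachable and r.head.name != start
    ]
    return Grammar(rules=tuple(ordered))


# ---------------------------------------------------------------------------
# execution of descriptions (event interception)
# ---------------------------------------------------------------------------

class _LoggingEnv:
    """Records every effective emission while delegating to an inner env."""

    def __init__(self, inner: Environment):
        self.inner = inner
        self.tokens: list[str] = []

    def peek(self, sensor: str) -> bool:
        return self.inner.peek(sensor)

    def read(self, sensor: str) -> bool:
        return self.inner.read(sensor)

    def emit(self, actuator: str) -> None:
        self.tokens.append(actuator)
        self.inner.emit(actuator)

    def snapshot(self):
        return self.inner.snapshot()


class _InterceptEnv:
    """Replaces intercepted emissions by their replacement bodies."""

    def __init__(self, log_env: _LoggingEnv, interceptions, seed: int, max_apps: int):
        self.log_env = log_env
        self.interceptions = interceptions
        self._rng = random.Random(seed ^ 0x5EED)
        self.max_apps = max_apps

    def peek(self, sensor: str) -> bool:
        return self.log_env.peek(sensor)

    def read(self, sensor: str) -> bool:
        return self.log_env.read(sensor)

    def emit(self, actuator: str) -> None:
        actions = self.interceptions.get(actuator)
        if actions is None:
            self.log_env.emit(actuator)
            return
        for kind, payload in actions:
            if kind == "emit":
                self.log_env.emit(payload)
            elif kind == "grammar":
                run(payload, self.log_env, seed=self._rng.randrange(2**31),
                    max_rule_applications=self.max_apps)
            else:  # nested description
                _execute_program(payload, self.log_env,
                                 self._rng.randrange(2**31), self.max_apps)

    def snapshot(self):
        return self.log_env.snapshot()


def _execute_program(prog: DescribedProgram, log_env: _LoggingEnv, seed: int, max_apps: int) -> Derivation:
    env = _InterceptEnv(log_env, prog.interceptions, seed, max_apps)
    return run(prog.base, env, seed=seed, max_rule_applications=max_apps)


def execute_description(
    d: Grammar,
    env: Environment | None = None,
    seed: int = 0,
    max_rule_applications: int = 10_000,
    registry: Mapping[str, str] | None = None,
) -> tuple[list[str], Derivation]:
    """Execute a describing grammar as the grammar it describes.

    The described derivation is replayed with the grammar's own weights
    (under ``seed``, so it makes the same stochastic choices the described
    grammar would); unquote-intercepted actuator events are substituted by
    their replacement bodies.  Returns the effective emitted token
    sequence and the base derivation.
    """
    prog = interpret_description(d, registry)
    log_env = _LoggingEnv(env if env is not None else RecorderEnvironment())
    deriv = _execute_program(prog, log_env, seed, max_rule_applications)
    return log_env.tokens, deriv


# ---------------------------------------------------------------------------
# linearization & root recognition
# ---------------------------------------------------------------------------

def weight_token(w: float) -> str:
    """Canonical weight token: always carries a decimal point (``0.5``,
    ``1.0``) so the root grammar's Weight/Symbol classes are disjoint."""
    s = f"{round(w, 9):g}"
    if "." not in s and "e" not in s:
        s += ".0"
    return s


def linearize(g: Grammar) -> list[str]:
    """Token stream the root grammar recognizes: per rule, the head token;
    per alternate, a weight token then each symbol token."""
    tokens: list[str] = []
    for rule in g.rules:
        tokens.append(rule.head.name)
        for alt in rule.alternates:
            tokens.append(weight_token(alt.weight))
            tokens.extend(sym.name for sym in alt.symbols)
    return tokens


def recognizes_description(
    root: Grammar, g: Grammar, search_budget: int = 500_000
) -> bool:
    """True iff the root grammar accepts ``g``'s linearization."""
    return recognize(root, linearize(g), search_budget=search_budget).accepted


# ---------------------------------------------------------------------------
# metaphor & composition
# ---------------------------------------------------------------------------

def retarget(g: Grammar, mapping: Mapping[str, str]) -> Grammar:
    """Metaphor: a describing grammar that replays ``g`` with each mapped
    actuator redirected to a new one (``UnquoteOld New``).  ``g`` is not
    modified; execute the result with :func:`execute_description`."""
    actuators = {t.name for t in g.terminals() if t.kind is SymbolKind.ACTUATOR}
    sensors = {t.name for t in g.terminals() if t.kind is SymbolKind.SENSOR}
    for old in mapping:
        if old in sensors:
            raise GrammarStructureError(f"cannot retarget sensor {old!r}")
        if old not in actuators:
            raise GrammarStructureError(f"{old!r} is not an actuator of the grammar")
    hook = {
        old: (GrammarSymbol(new, SymbolKind.ACTUATOR),) for old, new in mapping.items()
    }
    return _describe_impl(g, precision=2, hook=hook, guest=None)


def compose(host: Grammar, hook: str, guest: Grammar) -> Grammar:
    """Dynamic composition: a describing grammar whose execution behaves
    as ``host`` with every ``hook`` event replaced by a full ``guest``
    production.  Host and guest remain intact and independently
    executable; the guest's description is embedded, not copied into the
    host's rules."""
    terminal_names = {t.name for t in host.terminals()}
    if hook not in terminal_names:
        raise GrammarStructureError(f"hook {hook!r} is not a terminal of the host")
    # body symbol K roots the embedded guest description; its concrete name
    # is chosen by the generator's allocator via a placeholder
    placeholder = GrammarSymbol("GuestRoot", SymbolKind.NONTERMINAL)
    hookmap = {hook: (placeholder,)}
    desc = _describe_impl(host, precision=2, hook=hookmap, guest=guest)
    # replace the placeholder with the guest description's actual top name:
    # _describe_impl renamed the guest top to "GuestRoot" already
    return desc
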