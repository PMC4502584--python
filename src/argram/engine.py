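"""Mixed-mode execution of activation/recognition grammars.

A derivation expands the start symbol depth-first, left to right.  At each
rule the alternate is chosen stochastically by weight, except where sensors
gate the choice: when one or more alternates *begin* with a reachable
sensor (directly, or through one level of nonterminal indirection as in
``Any = 0 | 1``), the alternates whose leading sensor matches the
environment are kept and one is sampled among them by renormalized weight.
This is how stochastic choice coexists with deterministic control — the
Turing grammar, whose alternates are all sensor-led with exactly one match
per step, runs deterministically whatever the seed.

Sequencing inside a rule does not convey temporal order; order is carried
by derivation depth (the number of rule applications from the start symbol
to a terminal), with recognition coming ahead of production at equal
depth.  :func:`event_order` exposes that partial order; the operational
left-to-right schedule is just the engine's traversal.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

from .environments import (
    Environment,
    TapeEnvironment,
    TapeState,
    token_matches,
)
from .errors import ArgramError
from .grammar import Alternate, Grammar, GrammarSymbol, Rule, SymbolKind

__all__ = [
    "DerivationEvent",
    "Derivation",
    "DerivationStatus",
    "RecognitionResult",
    "TuringRun",
    "run",
    "recognize",
    "event_order",
    "run_turing",
    "enumerate_derivations",
]

DEFAULT_MAX_RULE_APPLICATIONS = 10_000


class DerivationStatus(Enum):
    COMPLETE = "complete"            # no rules left to apply
    NO_MATCH = "no_match"            # sensor mismatch with no viable alternate
    BUDGET_EXHAUSTED = "budget"      # rule-application budget ran out (legal:
                                     # some grammars never terminate)
    STOPPED = "stopped"              # caller-supplied stop condition fired


@dataclass(frozen=True)
class DerivationEvent:
    terminal: GrammarSymbol
    direction: str  # "sensor" | "actuator"
    depth: int      # rule applications from start to this terminal, inclusive
    seq: int        # global emission index


@dataclass
class Derivation:
    events: tuple[DerivationEvent, ...]
    choices: tuple[tuple[str, int], ...]  # (rule head, alternate index) in order
    loglik: float
    status: DerivationStatus
    rule_applications: int
    failed_sensor: str | None = None

    def tokens(self) -> list[str]:
        return [e.terminal.name for e in self.events]

    def actuator_tokens(self) -> list[str]:
        return [e.terminal.name for e in self.events if e.direction == "actuator"]


def _leading_sensors(alt: Alternate, rule_map: dict[str, Rule]) -> tuple[str, ...]:
    """Sensors that can open this alternate (one level of indirection)."""
    first = alt.symbols[0]
    if first.kind is SymbolKind.SENSOR:
        return (first.name,)
    if first.kind is SymbolKind.NONTERMINAL:
        rule = rule_map.get(first.name)
        if rule is None:
            return ()
        sensors = []
        for sub in rule.alternates:
            head = sub.symbols[0]
            if head.kind is not SymbolKind.SENSOR:
                return ()  # mixed leads: not reliably gateable
            sensors.append(head.name)
        return tuple(sensors)
    return ()


def _select_alternate(
    rule: Rule,
    rule_map: dict[str, Rule],
    env: Environment,
    rng: random.Random,
) -> int | None:
    """Pick an alternate index, sensor-gated where possible.

    Returns ``None`` when every alternate is sensor-led and none matches
    (the rule does not apply).  When sensor-led alternates exist but none
    matches, the non-sensor alternates remain in play.
    """
    leads = [_leading_sensors(alt, rule_map) for alt in rule.alternates]
    if any(leads):
        matching = [
            i for i, ss in enumerate(leads) if ss and any(env.peek(s) for s in ss)
        ]
        candidates = matching if matching else [i for i, ss in enumerate(leads) if not ss]
    else:
        candidates = list(range(len(rule.alternates)))
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    weights = [rule.alternates[i].weight for i in candidates]
    total = sum(weights)
    if total <= 0:
        return candidates[rng.randrange(len(candidates))]
    r = rng.random() * total
    acc = 0.0
    for i, w in zip(candidates, weights):
        acc += w
        if r < acc:
            return i
    return candidates[-1]


def run(
    g: Grammar,
    env: Environment,
    seed: int = 0,
    max_rule_applications: int = DEFAULT_MAX_RULE_APPLICATIONS,
    stop: Callable[[], bool] | None = None,
) -> Derivation:
    """Execute one derivation of ``g`` against ``env``.

    Actuator (and quoted) terminals call ``env.emit``; sensor terminals
    consume via ``env.read``.  The derivation halts with status
    ``COMPLETE`` when the start symbol is fully expanded, ``NO_MATCH``
    when a sensor fails with no viable alternate (how a recognition loop
    legally ends), ``BUDGET_EXHAUSTED`` when ``max_rule_applications``
    runs out (grammars like ``A = DrawSquare A.`` never terminate), or
    ``STOPPED`` when the optional ``stop`` callback returns true.
    """
    if max_rule_applications <= 0:
        raise ValueError("max_rule_applications must be positive")
    rng = random.Random(seed)
    rule_map = g.rule_map
    events: list[DerivationEvent] = []
    choices: list[tuple[str, int]] = []
    loglik = 0.0
    applications = 0
    seq = 0
    failed: str | None = None
    status = DerivationStatus.COMPLETE

    # stack of (symbol, depth); depth = rule applications on the path
    stack: list[tuple[GrammarSymbol, int]] = [(g.start, 0)]
    while stack:
        sym, depth = stack.pop()
        if sym.kind is SymbolKind.NONTERMINAL:
            rule = rule_map.get(sym.name)
            if rule is None:
                raise ArgramError(f"undefined nonterminal {sym.name!r} at run time")
            if applications >= max_rule_applications:
                status = DerivationStatus.BUDGET_EXHAUSTED
                break
            applications += 1
            idx = _select_alternate(rule, rule_map, env, rng)
            if idx is None:
                status = DerivationStatus.NO_MATCH
                failed = rule.head.name
                break
            alt = rule.alternates[idx]
            choices.append((sym.name, idx))
            loglik += math.log(alt.weight) if alt.weight > 0 else float("-inf")
            for child in reversed(alt.symbols):
                stack.append((child, depth + 1))
        elif sym.kind is SymbolKind.SENSOR:
            if not env.read(sym.name):
                status = DerivationStatus.NO_MATCH
                failed = sym.name
                break
            events.append(DerivationEvent(sym, "sensor", depth, seq))
            seq += 1
            if stop is not None and stop():
                status = DerivationStatus.STOPPED
                break
        else:  # actuator, quoted, unquoted, weight-literal: all emit
            env.emit(sym.name)
            events.append(DerivationEvent(sym, "actuator", depth, seq))
            seq += 1
            if stop is not None and stop():
                status = DerivationStatus.STOPPED
                break

    return Derivation(
        events=tuple(events),
        choices=tuple(choices),
        loglik=loglik,
        status=status,
        rule_applications=applications,
        failed_sensor=failed,
    )


# ---------------------------------------------------------------------------
# recognition (backtracking search)
# ---------------------------------------------------------------------------

@dataclass
class RecognitionResult:
    accepted: bool
    loglik: float           # log of the summed probability of accepting derivations
    consumed: int
    indeterminate: bool = False
    probability: float = 0.0
    derivations: int = 0    # number of accepting derivations found


def recognize(
    g: Grammar,
    input_tokens: Sequence[str],
    search_budget: int = 200_000,
    matcher: Callable[[str, str], bool] = token_matches,
) -> RecognitionResult:
    """Backtracking recognition of a token sequence.

    Accepts iff some derivation consumes the entire input with every
    sensor matched; the reported likelihood sums over *all* accepting
    derivations found within the budget (bounded backtracking, not a
    chart parser — ample for the grammars at hand, a documented
    limitation for pathologically ambiguous ones).  Actuator terminals
    emit nothing here and do not consume input.  ``matcher`` decides
    sensor/token matches and defaults to equality plus the
    ``Symbol``/``Weight`` class sensors.
    """
    tokens = list(input_tokens)
    n = len(tokens)
    rule_map = g.rule_map
    total_prob = 0.0
    n_accepting = 0
    max_pos = 0
    steps = 0
    exhausted = False

    min_need = _min_tokens(g)

    def state_min(symbols: tuple[GrammarSymbol, ...]) -> float:
        return sum(min_need[s.name] if s.kind is SymbolKind.NONTERMINAL
                   else (1 if s.kind is SymbolKind.SENSOR else 0)
                   for s in symbols)

    # DFS over (remaining symbols, input position, probability)
    stack: list[tuple[tuple[GrammarSymbol, ...], int, float]] = [
        ((g.start,), 0, 1.0)
    ]
    while stack:
        if steps >= search_budget:
            exhausted = True
            break
        steps += 1
        symbols, pos, prob = stack.pop()
        # consume terminals greedily until a nonterminal or a dead end
        i = 0
        dead = False
        while i < len(symbols):
            sym = symbols[i]
            if sym.kind is SymbolKind.SENSOR:
                if pos < n and matcher(sym.name, tokens[pos]):
                    pos += 1
                    max_pos = max(max_pos, pos)
                    i += 1
                else:
                    dead = True
                    break
            elif sym.kind is SymbolKind.NONTERMINAL:
                break
            else:  # actuators and quoted symbols are silent in recognition
                i += 1
        if dead:
            continue
        if i == len(symbols):
            if pos == n:
                total_prob += prob
                n_accepting += 1
            continue
        rule = rule_map.get(symbols[i].name)
        if rule is None:
            raise ArgramError(f"undefined nonterminal {symbols[i].name!r}")
        rest = symbols[i + 1:]
        # push in reverse so the first alternate is explored first
        for alt in reversed(rule.alternates):
            if alt.weight <= 0 and prob > 0:
                continue
            child = alt.symbols + rest
            # shortest-yield pruning: a state that must consume more
            # tokens than remain can never accept (kills left recursion)
            if state_min(child) > n - pos:
                continue
            stack.append((child, pos, prob * alt.weight))

    accepted = total_prob > 0
    if not accepted:
        # report how far any derivation prefix got (the accepting search
        # prunes dead ends early, so measure the prefix separately)
        max_pos = _longest_prefix(g, tokens, min(search_budget, 20_000), matcher)
    return RecognitionResult(
        accepted=accepted,
        loglik=math.log(total_prob) if accepted else float("-inf"),
        consumed=n if accepted else max_pos,
        indeterminate=exhausted,
        probability=total_prob,
        derivations=n_accepting,
    )


def _longest_prefix(
    g: Grammar,
    tokens: list[str],
    budget: int,
    matcher: Callable[[str, str], bool],
) -> int:
    """Longest input prefix matched along any partial derivation."""
    rule_map = g.rule_map
    n = len(tokens)
    cap = n + 16  # bound state size: runaway expansions cannot match anyway
    max_pos = 0
    steps = 0
    stack: list[tuple[tuple[GrammarSymbol, ...], int]] = [((g.start,), 0)]
    while stack and steps < budget:
        steps += 1
        symbols, pos = stack.pop()
        i = 0
        while i < len(symbols):
            sym = symbols[i]
            if sym.kind is SymbolKind.SENSOR:
                if pos < n and matcher(sym.name, tokens[pos]):
                    pos += 1
                    max_pos = max(max_pos, pos)
                    i += 1
                else:
                    i = -1
                    break
            elif sym.kind is SymbolKind.NONTERMINAL:
                break
            else:
                i += 1
        if i < 0 or i >= len(symbols) or max_pos == n:
            if max_pos == n:
                break
            continue
        rest = symbols[i + 1:]
        for alt in reversed(rule_map[symbols[i].name].alternates):
            child = alt.symbols + rest
            if len(child) <= cap:
                stack.append((child, pos))
    return max_pos


def _min_tokens(g: Grammar) -> dict[str, float]:
    """Fewest sensor tokens each nonterminal must consume in any complete
    derivation (inf for nonterminals with no finite derivation)."""
    min_need: dict[str, float] = {r.head.name: float("inf") for r in g.rules}
    changed = True
    while changed:
        changed = False
        for rule in g.rules:
            best = min_need[rule.head.name]
            for alt in rule.alternates:
                total = 0.0
                for sym in alt.symbols:
                    if sym.kind is SymbolKind.SENSOR:
                        total += 1
                    elif sym.kind is SymbolKind.NONTERMINAL:
                        total += min_need[sym.name]
                if total < best:
                    best = total
            if best < min_need[rule.head.name]:
                min_need[rule.head.name] = best
                changed = True
    return min_need


# ---------------------------------------------------------------------------
# declarative event order
# ---------------------------------------------------------------------------

def event_order(d: Derivation) -> set[tuple[int, int]]:
    """The partial order the formalism assigns to a trace.

    Returns the set of ``(seq_a, seq_b)`` pairs meaning the event with
    emission index ``seq_a`` is ordered ahead of ``seq_b``: fewer rule
    applications order first, and at equal depth recognition (sensor)
    events come ahead of production (actuator) events.  Remaining pairs
    are mutually unordered.
    """
    order: set[tuple[int, int]] = set()
    for a in d.events:
        for b in d.events:
            if a.seq == b.seq:
                continue
            if a.depth < b.depth:
                order.add((a.seq, b.seq))
            elif a.depth == b.depth and a.direction == "sensor" and b.direction == "actuator":
                order.add((a.seq, b.seq))
    return order


# ---------------------------------------------------------------------------
# Turing execution
# ---------------------------------------------------------------------------

@dataclass
class TuringRun:
    tape: TapeState
    completed: bool          # figure target reached before the cap
    derivation: Derivation
    ops: tuple[str, ...]     # actuator history, for oracle comparison


def run_turing(
    g: Grammar,
    figure_target: int,
    cap: int = 200_000,
    seed: int = 0,
) -> TuringRun:
    """Run a Turing-transliteration grammar on an initially blank tape.

    Execution is fully sensor-gated, hence deterministic; it stops as soon
    as the tape holds ``figure_target`` binary figures, or after ``cap``
    rule applications (in which case the partial tape is returned with
    ``completed`` false).
    """
    if figure_target < 1:
        raise ValueError("figure_target must be >= 1")
    env = TapeEnvironment()
    deriv = run(
        g,
        env,
        seed=seed,
        max_rule_applications=cap,
        stop=lambda: env.tape.figure_count() >= figure_target,
    )
    completed = env.tape.figure_count() >= figure_target
    return TuringRun(
        tape=env.tape,
        completed=completed,
        derivation=deriv,
        ops=tuple(env.log),
    )


# ---------------------------------------------------------------------------
# exhaustive enumeration (used as an analysis tool and by tests)
# ---------------------------------------------------------------------------

def enumerate_derivations(
    g: Grammar,
    max_expansions: int = 100_000,
) -> list[tuple[tuple[str, ...], float]]:
    """All complete derivations of a finite grammar, as
    ``(terminal token sequence, probability)`` pairs.

    Sensor gating is ignored — this enumerates the unconstrained
    derivation tree, whose probabilities sum to 1 for any grammar with a
    finite tree.  Raises :class:`ArgramError` if the tree is larger than
    ``max_expansions`` (e.g. for recursive grammars).
    """
    rule_map = g.rule_map
    out: list[tuple[tuple[str, ...], float]] = []
    steps = 0
    stack: list[tuple[tuple[GrammarSymbol, ...], tuple[str, ...], float]] = [
        ((g.start,), (), 1.0)
    ]
    while stack:
        steps += 1
        if steps > max_expansions:
            raise ArgramError("derivation tree too large to enumerate (recursive grammar?)")
        symbols, emitted, prob = stack.pop()
        i = 0
        while i < len(symbols) and symbols[i].kind is not SymbolKind.NONTERMINAL:
            emitted = emitted + (symbols[i].name,)
            i += 1
        if i == len(symbols):
            out.append((emitted, prob))
            continue
        rule = rule_map.get(symbols[i].name)
        if rule is None:
            raise ArgramError(f"undefined nonterminal {symbols[i].name!r}")
        rest = symbols[i + 1:]
        for alt in reversed(rule.alternates):
            stack.append((alt.symbols + rest, emitted, prob * alt.weight))
    return out
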