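"""Swarm learning over probability grids.

A swarm is a single grammar whose top-level alternates instantiate the
same template at different probability vectors (e.g. three color grammars
at (.5,.5), (.6,.4), (.9,.1) over green/red).  Presented with a sample,
the branch *closest* to the sample's distribution recognizes it; closeness
is formalized as maximum average log-likelihood, i.e. minimum
cross-entropy — the measure under which the (.6,.4) branch is closest to a
.61/.39 orange mixture.  Weight recovery is the multinomial
maximum-likelihood estimate (relative frequencies), which is how a swarm
can concentrate on a reinforced color.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

from .engine import enumerate_derivations, run
from .environments import RecorderEnvironment
from .errors import ArgramError, DescriptionError, GrammarStructureError
from .grammar import (
    Alternate,
    Grammar,
    GrammarSymbol,
    Rule,
    SymbolKind,
    rename_for_readability,
    validate,
)
from .selfdescription import _letters, _subgrammar, interpret_description

__all__ = [
    "SwarmSpec",
    "expand_swarm",
    "instantiate_branch",
    "terminal_distribution",
    "branch_loglik",
    "select_branch",
    "estimate_weights",
    "reinforcement_step",
    "sample_tokens",
]


@dataclass(frozen=True)
class SwarmSpec:
    """A template grammar with one designated weighted rule plus a grid of
    probability vectors, one per swarm branch."""

    template: Grammar
    designated_rule: str
    grid: tuple[tuple[float, ...], ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        rule = self.template.rule_map.get(self.designated_rule)
        if rule is None:
            raise GrammarStructureError(
                f"designated rule {self.designated_rule!r} not in template"
            )
        arity = len(rule.alternates)
        if not self.grid:
            raise GrammarStructureError("swarm grid is empty")
        for vec in self.grid:
            if len(vec) != arity:
                raise GrammarStructureError(
                    f"grid vector {vec} does not match rule arity {arity}"
                )
            if abs(sum(vec) - 1.0) > 1e-9:
                raise GrammarStructureError(f"grid vector {vec} does not sum to 1")
        if self.labels and len(self.labels) != len(self.grid):
            raise GrammarStructureError("labels/grid length mismatch")

    @property
    def branch_labels(self) -> tuple[str, ...]:
        if self.labels:
            return self.labels
        return tuple(f"branch{i}" for i in range(len(self.grid)))


def instantiate_branch(spec: SwarmSpec, index: int) -> Grammar:
    """The template with the designated rule's weights set to one grid
    vector — the swarm branch as a standalone grammar."""
    vec = spec.grid[index]
    rules = []
    for rule in spec.template.rules:
        if rule.head.name == spec.designated_rule:
            rules.append(
                Rule(
                    head=rule.head,
                    alternates=tuple(
                        Alternate(w, alt.symbols)
                        for w, alt in zip(vec, rule.alternates)
                    ),
                )
            )
        else:
            rules.append(rule)
    return Grammar(rules=tuple(rules))


def expand_swarm(spec: SwarmSpec) -> Grammar:
    """One grammar holding the whole swarm: the top rule has an
    equiprobable alternate per branch, each instantiating the template
    with its grid vector (fresh nonterminal names per branch)."""
    alloc = _letters()
    top_name = next(alloc)
    branch_roots: list[str] = []
    rules: list[Rule] = []
    n = len(spec.grid)
    for i in range(n):
        branch = instantiate_branch(spec, i)
        mapping = {old: next(alloc) for old in branch.nonterminals()}
        renamed = rename_for_readability(branch, mapping)
        branch_roots.append(renamed.start.name)
        rules.extend(renamed.rules)
    top_rule = Rule(
        head=GrammarSymbol(top_name, SymbolKind.NONTERMINAL),
        alternates=tuple(
            Alternate(1.0 / n, (GrammarSymbol(r, SymbolKind.NONTERMINAL),))
            for r in branch_roots
        ),
    )
    out = Grammar(rules=(top_rule,) + tuple(rules))
    errors = [d for d in validate(out) if d.level == "error"]
    if errors:  # pragma: no cover
        raise GrammarStructureError("; ".join(d.message for d in errors))
    return out


# ---------------------------------------------------------------------------
# likelihood scoring
# ---------------------------------------------------------------------------

def terminal_distribution(g: Grammar, max_expansions: int = 10_000) -> dict[str, float]:
    """Distribution over the single terminal a branch emits/matches per
    derivation.  Raises if any derivation yields more than one terminal —
    swarm branches are per-token classifiers."""
    dist: dict[str, float] = {}
    for tokens, prob in enumerate_derivations(g, max_expansions):
        if len(tokens) != 1:
            raise ArgramError(
                f"branch derivation yields {len(tokens)} terminals, expected 1"
            )
        dist[tokens[0]] = dist.get(tokens[0], 0.0) + prob
    return dist


def branch_loglik(branch: Grammar, sample: Sequence[str]) -> float:
    """Average per-token log-likelihood of the sample under the branch's
    terminal distribution; −inf if any token is unreachable."""
    if not sample:
        raise ValueError("sample must be non-empty")
    dist = terminal_distribution(branch)
    total = 0.0
    for token in sample:
        p = dist.get(token, 0.0)
        if p <= 0:
            return float("-inf")
        total += math.log(p)
    return total / len(sample)


def select_branch(spec: SwarmSpec, sample: Sequence[str]) -> str:
    """Label of the arg-max branch (ties break to the lowest index)."""
    if not sample:
        raise ValueError("sample must be non-empty")
    logliks = branch_logliks(spec, sample)
    labels = spec.branch_labels
    best = max(range(len(labels)), key=lambda i: (logliks[labels[i]], -i))
    if logliks[labels[best]] == float("-inf"):
        raise ArgramError("no branch recognizes the sample")
    return labels[best]


def branch_logliks(spec: SwarmSpec, sample: Sequence[str]) -> dict[str, float]:
    return {
        label: branch_loglik(instantiate_branch(spec, i), sample)
        for i, label in enumerate(spec.branch_labels)
    }


# ---------------------------------------------------------------------------
# weight recovery (multinomial MLE)
# ---------------------------------------------------------------------------

def _alternate_terminal(g: Grammar, alt: Alternate) -> str:
    """The unique terminal an alternate resolves to through single-chain
    expansion (e.g. alternate ``B`` with ``B = PrintGreenPoint.``)."""
    symbols = list(alt.symbols)
    if len(symbols) != 1:
        raise GrammarStructureError("alternate must resolve to a single terminal")
    sym = symbols[0]
    if sym.is_terminal:
        return sym.name
    rule = g.rule_map.get(sym.name)
    if rule is None or len(rule.alternates) != 1:
        raise GrammarStructureError(
            f"alternate via {sym.name!r} does not resolve to a unique terminal"
        )
    return _alternate_terminal(g, rule.alternates[0])


def estimate_weights(skeleton: Grammar, sample: Sequence[str]) -> Grammar:
    """Multinomial maximum-likelihood re-estimation: replace the weights
    of the skeleton's designated rule (its first multi-alternate rule) by
    the relative frequencies of each alternate's terminal in the sample."""
    if not sample:
        raise ValueError("sample must be non-empty")
    designated = next(
        (r for r in skeleton.rules if len(r.alternates) > 1), None
    )
    if designated is None:
        raise GrammarStructureError("skeleton has no multi-alternate rule to estimate")
    terminals = [_alternate_terminal(skeleton, alt) for alt in designated.alternates]
    if len(set(terminals)) != len(terminals):
        raise GrammarStructureError("designated alternates must end in distinct sensors")
    counts = {t: 0 for t in terminals}
    for token in sample:
        if token in counts:
            counts[token] += 1
    total = sum(counts.values())
    if total == 0:
        raise ArgramError("no sample token matches any alternate terminal")
    rules = []
    for rule in skeleton.rules:
        if rule.head.name == designated.head.name:
            rules.append(
                Rule(
                    head=rule.head,
                    alternates=tuple(
                        Alternate(counts[t] / total, alt.symbols)
                        for t, alt in zip(terminals, rule.alternates)
                    ),
                )
            )
        else:
            rules.append(rule)
    return Grammar(rules=tuple(rules))


# ---------------------------------------------------------------------------
# reinforcement closure
# ---------------------------------------------------------------------------

def reinforcement_step(
    swarm_with_closure: Grammar,
    sample: Sequence[str],
    seed: int = 0,
) -> list[str]:
    """One pass of the reinforcement loop.

    The closure grammar pairs a recognition branch (a weighted sensor
    rule, the gate) with the description of a target producer.  The gate
    triggers when its probability vector is the maximum-likelihood
    assignment of its own probabilities to the sample's terminals — for a
    .6-green gate, the sample must lean green.  On trigger, the described
    producer executes and its emitted tokens are returned; otherwise the
    result is empty.
    """
    if not sample:
        raise ValueError("sample must be non-empty")
    top = swarm_with_closure.rules[0]
    if len(top.alternates) != 1 or len(top.alternates[0].symbols) != 2:
        raise DescriptionError(
            "closure grammar must pair a recognition branch with a description"
        )
    gate_sym, desc_sym = top.alternates[0].symbols
    if gate_sym.kind is not SymbolKind.NONTERMINAL or desc_sym.kind is not SymbolKind.NONTERMINAL:
        raise DescriptionError("closure top rule must reference two nonterminals")

    gate = _subgrammar(swarm_with_closure, gate_sym.name)
    gate_dist = terminal_distribution(gate)
    terminals = sorted(gate_dist)
    probs = [gate_dist[t] for t in terminals]

    counts = {t: 0 for t in terminals}
    for token in sample:
        if token not in counts:
            return []  # a token no gate terminal matches: no recognition
        counts[token] += 1

    def avg_loglik(assignment: Sequence[float]) -> float:
        total = 0.0
        for t, p in zip(terminals, assignment):
            if counts[t] and p <= 0:
                return float("-inf")
            if counts[t]:
                total += counts[t] * math.log(p)
        return total / len(sample)

    gate_score = avg_loglik(probs)
    for perm in set(permutations(probs)):
        if avg_loglik(perm) > gate_score + 1e-12:
            return []

    description = _subgrammar(swarm_with_closure, desc_sym.name)
    producer = interpret_description(description).base
    env = RecorderEnvironment()
    run(producer, env, seed=seed)
    return env.events


def sample_tokens(
    weights: Sequence[float], tokens: Sequence[str], n: int, seed: int
) -> list[str]:
    """Draw ``n`` i.i.d. tokens from a categorical mixture — the color
    stimulus generator used throughout the examples."""
    rng = random.Random(seed)
    return rng.choices(list(tokens), weights=list(weights), k=n)
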