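import random

import pytest

from argram import (
    Alternate,
    Grammar,
    GrammarSymbol,
    Rule,
    SymbolKind,
    load_fixture,
    root_grammar,
)

#: actuator vocabulary for generated grammars (all in the default registry)
GEN_TERMINALS = (
    "DrawSquare",
    "DrawCircle",
    "DrawTriangle",
    "Look",
    "Describe",
    "PrintGreenPoint",
    "PrintRedPoint",
)


def make_random_grammar(
    rng: random.Random,
    max_rules: int = 5,
    max_alternates: int = 3,
    max_symbols: int = 3,
    terminals: tuple[str, ...] = GEN_TERMINALS,
    nonterminal_prob: float = 0.35,
    leading_terminal: bool = False,
) -> Grammar:
    """A random valid quote-free production grammar.

    Multi-alternate weights are multiples of 0.01 (each >= 0.01) so the
    grammars are exactly representable by QuotePoint descriptions.
    ``leading_terminal`` forces every alternate to open with a terminal,
    which rules out left recursion and unit cycles (useful when the
    grammar's dual must be decidable by backtracking recognition).
    """
    n = rng.randint(1, max_rules)
    heads = [f"N{i}" for i in range(n)]
    rules = []
    for head in heads:
        k = rng.randint(1, max_alternates)
        if k == 1:
            weights = [1.0]
        else:
            cuts = sorted(rng.sample(range(1, 100), k - 1))
            parts = [b - a for a, b in zip([0] + cuts, cuts + [100])]
            weights = [p / 100 for p in parts]
        alternates = []
        for w in weights:
            m = rng.randint(1, max_symbols)
            symbols = []
            for j in range(m):
                if rng.random() < nonterminal_prob and not (leading_terminal and j == 0):
                    symbols.append(
                        GrammarSymbol(rng.choice(heads), SymbolKind.NONTERMINAL)
                    )
                else:
                    symbols.append(
                        GrammarSymbol(rng.choice(terminals), SymbolKind.ACTUATOR)
                    )
            alternates.append(Alternate(w, tuple(symbols)))
        rules.append(
            Rule(GrammarSymbol(head, SymbolKind.NONTERMINAL), tuple(alternates))
        )
    return Grammar(tuple(rules))


@pytest.fixture(scope="session")
def root():
    return root_grammar()


@pytest.fixture
def turing_grammar():
    return load_fixture("fig6_turing")


@pytest.fixture
def orange_grammar():
    return load_fixture("fig10_orange")
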