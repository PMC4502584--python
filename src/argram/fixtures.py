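"""The figure grammars, shipped as plain-text fixtures.

The worked-example grammars this package is built around, keyed by the
figure they belong to, with the terminal registry that classifies their
terminals.  ``0`` and ``1`` are
sensors by default (their Turing-machine role); the digit-*production*
grammars (figs 7 and 15) carry a per-fixture override marking them
actuators, since the same tokens are produced there.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import yaml

from .grammar import DEFAULT_REGISTRY, Grammar, parse_grammar

__all__ = [
    "FIXTURE_TEXTS",
    "REGISTRY_OVERRIDES",
    "FixtureSet",
    "fixture_names",
    "fixture_registry",
    "load_fixture",
    "load_all",
    "generate_fixtures",
]

FIXTURE_TEXTS: dict[str, str] = {
    # Activation/recognition basics
    "fig1_draw": "A = B C D. B = DrawSquare. C = DrawCircle. D = DrawTriangle.",
    "fig1_spot": "A = B C D. B = SpotSquare. C = SpotCircle. D = SpotTriangle.",
    "fig1_mix": "A = B C D. B = DrawSquare. C = SpotCircle. D = DrawTriangle.",
    # Ordering by rule count
    "fig2_a": "A = B C. B = DrawSquare. C = DrawCircle.",
    "fig2_b": "A = B C. B = DrawCircle. C = DrawSquare.",
    "fig2_c": "A = B C. B = DrawSquare. C = D. D = DrawCircle.",
    "fig2_d": "A = B C. B = D. D = DrawSquare. C = DrawCircle.",
    # Actions instead of figures
    "fig3_look": "A = Look B. B = See C. C = Describe.",
    # Probabilities & equipartition
    "fig4_a": "A = .3 B | .7 C. B = DrawSquare. C = DrawCircle.",
    "fig4_b": "A = .3 B | .7 C. B = SpotSquare. C = SpotCircle.",
    "fig4_c": "A = B | C | D | E. B = DrawSquare. C = DrawCircle. D = DrawTriangle. E = Look.",
    # Recursion / feedback
    "fig5_loop": "A = DrawSquare A.",
    "fig5_gated": "A = SpotCircle B. B = DrawSquare A.",
    # Turing transliteration
    "fig6_turing": (
        "b = Pe R Pe R P0 R R P0 L L o. "
        "o = 1 R Px L L L o | 0 q. "
        "q = Any R R q | None P1 L p. "
        "Any = 0 | 1. "
        "p = x E R q | e R f | None L L p. "
        "f = Any R R f | None P0 L L o."
    ),
    # Digit sequences and the digit->figure metaphor
    "fig7_digits": "A = B | C. B = 0 | 1. C = B A.",
    "fig7_mixed": "A = B | C. B = SpotSquare | DrawCircle. C = B A.",
    # Color gradients
    "fig8_yellow": "A = B A. B = .5 C | .5 D. C = PrintGreenPoint. D = PrintRedPoint.",
    "fig8_orange": "A = B A. B = .61 C | .39 D. C = PrintGreenPoint. D = PrintRedPoint.",
    "fig8_gold": "A = B A. B = .54 C | .46 D. C = PrintGreenPoint. D = PrintRedPoint.",
    # Simple description
    "fig9_simple": "A = PrintGreenPoint.",
    "fig9_desc": "A = QuoteA B. B = QuotePrintGreenPoint.",
    # Probabilistic description (simplified orange)
    "fig10_orange": "A = .61 B | .39 C. B = PrintGreenPoint. C = PrintRedPoint.",
    "fig10_desc": (
        "A = B C D. "
        "B = QuoteA E. E = F G. "
        "F = QuotePoint61 QuoteB. G = QuotePoint39 QuoteC. "
        "C = QuoteB H. H = QuotePrintGreenPoint. "
        "D = QuoteC I. I = QuotePrintRedPoint."
    ),
    # Swarm of three color grammars
    "fig11_swarm": (
        "A = B | C | D. "
        "B = .5 E | .5 F. E = SpotGreenPoint. F = SpotRedPoint. "
        "C = .6 G | .4 H. G = SpotGreenPoint. H = SpotRedPoint. "
        "D = .9 J | .1 K. J = SpotGreenPoint. K = SpotRedPoint."
    ),
    # Reinforcement closure: trigger branch + description of the producer
    "fig12_reinforce": (
        "A = B C. "
        "B = .6 D | .4 E. D = SpotGreenPoint. E = SpotRedPoint. "
        "C = F G H. "
        "F = QuoteA J. J = K L. "
        "K = QuotePoint6 QuoteC. L = QuotePoint4 QuoteD. "
        "G = QuoteC M. M = QuotePrintGreenPoint. "
        "H = QuoteD N. N = QuotePrintRedPoint."
    ),
    # The root grammar
    "fig13_root": (
        "A = .5 B | .5 C. "
        "B = Symbol D. "
        "D = .5 E | .5 F. "
        "E = Weight G. "
        "G = .5 Symbol | .5 H. "
        "H = Symbol G. "
        "F = E D. "
        "C = B A."
    ),
    # Metaphor: counting squares -> counting circles
    "fig14_counter": "A = B C. B = DrawSquare. C = DrawSquare.",
    "fig14_metaphor": (
        "A = B C D. "
        "B = QuoteA E. E = QuoteB QuoteC. "
        "C = QuoteB F. F = UnquoteDrawSquare DrawCircle. "
        "D = QuoteC G. G = UnquoteDrawSquare DrawCircle."
    ),
    # Composition: digit grammar + orange grammar
    "fig15_digit": "A = B | C. B = 0 | 1. C = B A.",
    "fig15_compose": (
        "A = B C D. "
        "B = QuoteA E. E = QuoteB QuoteC. "
        "C = QuoteB F. F = Quote0 J. J = Unquote1 K. "
        "D = QuoteC G. G = QuoteB H. H = QuoteA. "
        "K = L M N. "
        "L = QuoteD O. O = P Q. "
        "P = QuotePoint61 QuoteE. Q = QuotePoint39 QuoteF. "
        "M = QuoteE R. R = QuotePrintGreenPoint. "
        "N = QuoteF S. S = QuotePrintRedPoint."
    ),
    "fig15_orange": "A = .61 B | .39 C. B = PrintGreenPoint. C = PrintRedPoint.",
}

#: Per-fixture terminal-direction overrides (digit-producing grammars).
REGISTRY_OVERRIDES: dict[str, dict[str, str]] = {
    "fig7_digits": {"0": "actuator", "1": "actuator"},
    "fig15_digit": {"0": "actuator", "1": "actuator"},
}


@dataclass
class FixtureSet:
    grammars: dict[str, Grammar]
    registry: dict[str, str]
    outdir: str | None = None

    def __getitem__(self, name: str) -> Grammar:
        return self.grammars[name]


def fixture_names() -> list[str]:
    return list(FIXTURE_TEXTS)


def fixture_registry(name: str) -> dict[str, str]:
    registry = dict(DEFAULT_REGISTRY)
    registry.update(REGISTRY_OVERRIDES.get(name, {}))
    return registry


def load_fixture(name: str) -> Grammar:
    if name not in FIXTURE_TEXTS:
        raise KeyError(f"unknown fixture {name!r}")
    return parse_grammar(FIXTURE_TEXTS[name], fixture_registry(name))


def load_all() -> dict[str, Grammar]:
    return {name: load_fixture(name) for name in FIXTURE_TEXTS}


def generate_fixtures(outdir: str | os.PathLike) -> FixtureSet:
    """Write every fixture as a ``.arg`` file plus the registry YAML.

    Idempotent: re-running overwrites with identical content.
    """
    os.makedirs(outdir, exist_ok=True)
    grammars = load_all()
    for name, text in FIXTURE_TEXTS.items():
        with open(os.path.join(outdir, f"{name}.arg"), "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    with open(os.path.join(outdir, "registry.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(DEFAULT_REGISTRY, fh, sort_keys=True)
    with open(os.path.join(outdir, "registry_overrides.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(REGISTRY_OVERRIDES, fh, sort_keys=True)
    return FixtureSet(grammars=grammars, registry=dict(DEFAULT_REGISTRY), outdir=str(outdir))
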