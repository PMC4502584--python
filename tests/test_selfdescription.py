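"""Describe/decode, root-grammar fixed point, metaphor, and composition."""

import random
from collections import Counter

import pytest
from scipy.stats import chi2_contingency

from argram import (
    DEFAULT_REGISTRY,
    DescriptionError,
    RecorderEnvironment,
    compose,
    decode_description,
    describe,
    execute_description,
    fixture_names,
    fixture_registry,
    interpret_description,
    linearize,
    load_fixture,
    parse_grammar,
    recognize,
    recognizes_description,
    rename_for_readability,
    retarget,
    run,
    serialize_grammar,
    structurally_equal,
    validate,
)
from argram.selfdescription import ROOT_READABLE_NAMES

from conftest import make_random_grammar


def _describable(g):
    """Quote-free grammars whose weights fit two decimal digits."""
    try:
        describe(g)
        return True
    except DescriptionError:
        return False


class TestDescribe:
    def test_simplest_grammar_describes_as_printed(self):
        d = describe(load_fixture("fig9_simple"))
        assert structurally_equal(d, load_fixture("fig9_desc"))

    def test_orange_subset_describes_with_quoted_weights(self):
        d = describe(load_fixture("fig10_orange"))
        assert structurally_equal(d, load_fixture("fig10_desc"))

    def test_describe_refuses_quoted_input(self):
        with pytest.raises(DescriptionError):
            describe(load_fixture("fig9_desc"))

    def test_thirds_equipartition_not_representable_at_default_precision(self):
        # 1/3 has no finite decimal expansion: error, never silent rounding
        g = parse_grammar("A = B | C | D. B = Look. C = Describe. D = DrawSquare.")
        with pytest.raises(DescriptionError):
            describe(g)

    @pytest.mark.parametrize("base_seed", [0, 1])
    def test_decode_describe_roundtrip_on_random_grammars(self, base_seed):
        done = 0
        seed = base_seed
        while done < 100:
            g = make_random_grammar(random.Random(seed))
            seed += 2
            assert structurally_equal(decode_description(describe(g)), g)
            done += 1

    def test_decode_printed_fig10_description(self):
        decoded = decode_description(load_fixture("fig10_desc"))
        assert structurally_equal(decoded, load_fixture("fig10_orange"))

    def test_describe_decode_fixpoint_on_fig9(self):
        d = load_fixture("fig9_desc")
        assert structurally_equal(describe(decode_description(d)), d)

    def test_decode_rejects_malformed_description(self):
        with pytest.raises(DescriptionError):
            decode_description(load_fixture("fig4_a"))


class TestRootGrammar:
    def test_root_is_clean_and_serialization_stable(self, root):
        assert validate(root) == []
        reparsed = parse_grammar(serialize_grammar(root))
        assert structurally_equal(reparsed, root)

    def test_root_has_eight_rules(self, root):
        assert len(root.rules) == 8

    def test_readable_renaming(self, root):
        renamed = rename_for_readability(root, ROOT_READABLE_NAMES)
        assert renamed.start.name == "Rules"
        assert "Alternate = Weight Symbols." in serialize_grammar(renamed)

    def test_linearization_shape(self):
        g = parse_grammar("A = DrawSquare.")
        assert linearize(g) == ["A", "1.0", "DrawSquare"]

    def test_linearization_length_formula(self, root):
        # heads + one weight per alternate + one token per symbol occurrence
        for name in ("fig1_draw", "fig6_turing", "fig13_root"):
            g = load_fixture(name)
            n_alts = sum(len(r.alternates) for r in g.rules)
            n_syms = sum(
                len(a.symbols) for r in g.rules for a in r.alternates
            )
            assert len(linearize(g)) == len(g.rules) + n_alts + n_syms

    def test_root_recognizes_every_fixture(self, root):
        for name in fixture_names():
            g = load_fixture(name)
            assert recognizes_description(root, g), name

    def test_root_recognizes_itself(self, root):
        assert recognizes_description(root, root)

    def test_root_rejects_consecutive_weight_tokens(self, root):
        assert not recognize(root, ["A", "0.5", "0.5"]).accepted

    def test_root_rejects_headless_stream(self, root):
        assert not recognize(root, ["0.5", "DrawSquare"]).accepted


class TestRetarget:
    def test_counter_metaphor_matches_printed_describing_grammar(self):
        ret = retarget(load_fixture("fig14_counter"), {"DrawSquare": "DrawCircle"})
        assert structurally_equal(ret, load_fixture("fig14_metaphor"))

    def test_two_square_counter_emits_two_circles(self):
        ret = retarget(load_fixture("fig14_counter"), {"DrawSquare": "DrawCircle"})
        tokens, d = execute_description(ret, seed=0)
        assert tokens == ["DrawCircle", "DrawCircle"]

    def test_empty_mapping_is_the_identity_metaphor(self):
        g = load_fixture("fig4_a")
        for seed in range(5):
            env = RecorderEnvironment()
            run(g, env, seed=seed)
            tokens, _ = execute_description(retarget(g, {}), seed=seed)
            assert tokens == env.events

    def test_mapping_a_sensor_is_rejected(self):
        from argram import GrammarStructureError

        with pytest.raises(GrammarStructureError):
            retarget(load_fixture("fig5_gated"), {"SpotCircle": "SpotSquare"})

    @pytest.mark.parametrize("seed", [2, 7, 13])
    def test_retargeted_trace_is_the_mapped_trace(self, seed):
        g = make_random_grammar(random.Random(seed), max_rules=4)
        if not _describable(g):
            pytest.skip("weights exceed description precision")
        mapping = {"DrawSquare": "DrawTriangle", "DrawTriangle": "DrawSquare"}
        actuators = {t.name for t in g.terminals()}
        mapping = {k: v for k, v in mapping.items() if k in actuators}
        env = RecorderEnvironment()
        run(g, env, seed=seed, max_rule_applications=400)
        tokens, _ = execute_description(
            retarget(g, mapping), seed=seed, max_rule_applications=400
        )
        assert tokens == [mapping.get(t, t) for t in env.events]


class TestCompose:
    def setup_method(self):
        self.registry = fixture_registry("fig15_digit")
        self.digit = load_fixture("fig15_digit")
        self.orange = load_fixture("fig15_orange")

    def test_each_one_becomes_an_orange_point(self):
        comp = compose(self.digit, "1", self.orange)
        tokens, _ = execute_description(comp, seed=11, registry=self.registry)
        assert tokens  # nonempty production
        assert "1" not in tokens
        assert set(tokens) <= {"0", "PrintGreenPoint", "PrintRedPoint"}

    def test_components_remain_byte_unchanged(self):
        before = (serialize_grammar(self.digit), serialize_grammar(self.orange))
        compose(self.digit, "1", self.orange)
        after = (serialize_grammar(self.digit), serialize_grammar(self.orange))
        assert before == after

    def test_unknown_hook_rejected(self):
        from argram import GrammarStructureError

        with pytest.raises(GrammarStructureError):
            compose(self.digit, "NotATerminal", self.orange)

    def test_single_actuator_guest_degenerates_to_retarget(self):
        host = load_fixture("fig14_counter")
        guest = parse_grammar("A = DrawCircle.")
        comp = compose(host, "DrawSquare", guest)
        ret = retarget(host, {"DrawSquare": "DrawCircle"})
        for seed in range(5):
            t1, _ = execute_description(comp, seed=seed)
            t2, _ = execute_description(ret, seed=seed)
            assert t1 == t2 == ["DrawCircle", "DrawCircle"]

    def test_dynamic_composition_matches_static_substitution(self):
        # the inline substitution grammar produces the same trace
        # distribution as the dynamic composition (chi-square, alpha=.01)
        static = parse_grammar(
            "A = B | C. B = 0 | D. C = B A. "
            "D = .61 E | .39 F. E = PrintGreenPoint. F = PrintRedPoint.",
            self.registry,
        )
        comp = compose(self.digit, "1", self.orange)
        n = 4000
        dynamic_counts: Counter = Counter()
        static_counts: Counter = Counter()
        for i in range(n):
            tokens, _ = execute_description(
                comp, seed=2 * i, registry=self.registry, max_rule_applications=500
            )
            dynamic_counts[tuple(tokens)] += 1
            env = RecorderEnvironment()
            run(static, env, seed=2 * i + 1, max_rule_applications=500)
            static_counts[tuple(env.events)] += 1
        keys = set(dynamic_counts) | set(static_counts)
        # bin rare traces together to keep expected counts reasonable
        common = [k for k in keys if dynamic_counts[k] + static_counts[k] >= 10]
        table = [
            [dynamic_counts[k] for k in common]
            + [sum(v for k, v in dynamic_counts.items() if k not in common)],
            [static_counts[k] for k in common]
            + [sum(v for k, v in static_counts.items() if k not in common)],
        ]
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_printed_composition_grammar_is_interpretable(self):
        # the printed figure folds weights away; its interception still
        # routes every described `1` to the orange producer
        prog = interpret_description(
            load_fixture("fig15_compose"), fixture_registry("fig15_digit")
        )
        assert "1" in prog.interceptions
        (kind, guest_prog), = prog.interceptions["1"]
        assert kind == "program"
        green = guest_prog.base.rules[0].alternates[0].weight
        assert green == pytest.approx(0.61)
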