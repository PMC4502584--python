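"""Mixed-mode execution, recognition, event ordering, and the Turing run."""

import math
import random

import pytest

from argram import (
    DerivationStatus,
    RecorderEnvironment,
    TapeState,
    TokenStreamEnvironment,
    enumerate_derivations,
    event_order,
    load_fixture,
    parse_grammar,
    read_figures,
    recognize,
    run,
    run_turing,
)
from argram.environments import TapeEnvironment
from argram.errors import EnvironmentError_
from argram.grammar import Grammar, GrammarSymbol, SymbolKind, Rule, Alternate

from conftest import make_random_grammar


class TestProduction:
    def test_pure_production_emits_all_three_shapes(self):
        env = RecorderEnvironment()
        run(load_fixture("fig1_draw"), env, seed=0)
        assert env.events == ["DrawSquare", "DrawCircle", "DrawTriangle"]

    def test_mixed_mode_consumes_circle_and_produces_rest(self):
        env = TokenStreamEnvironment(["SpotCircle"])
        d = run(load_fixture("fig1_mix"), env, seed=0)
        assert d.status is DerivationStatus.COMPLETE
        assert env.emitted == ["DrawSquare", "DrawTriangle"]
        assert env.exhausted

    @pytest.mark.parametrize("n", [0, 1, 5, 23])
    def test_feedback_loop_draws_one_square_per_circle(self, n):
        g = load_fixture("fig5_gated")
        env = TokenStreamEnvironment(["SpotCircle"] * n)
        d = run(g, env, seed=0, max_rule_applications=10 * n + 10)
        assert env.emitted == ["DrawSquare"] * n
        # the loop ends on a failed sensor, which is how "rules no longer
        # apply" manifests for a gated loop
        assert d.status is DerivationStatus.NO_MATCH

    def test_infinite_production_reports_budget_exhaustion(self):
        env = RecorderEnvironment()
        d = run(load_fixture("fig5_loop"), env, seed=0, max_rule_applications=50)
        assert d.status is DerivationStatus.BUDGET_EXHAUSTED
        assert env.events == ["DrawSquare"] * 50

    def test_identical_seeds_give_identical_traces(self):
        g = load_fixture("fig8_orange")
        traces = []
        for _ in range(2):
            env = RecorderEnvironment()
            run(g, env, seed=123, max_rule_applications=200)
            traces.append(env.events)
        assert traces[0] == traces[1]

    def test_loglik_accumulates_chosen_alternate_weights(self):
        g = load_fixture("fig4_a")
        env = RecorderEnvironment()
        d = run(g, env, seed=1)
        expected = math.log(0.3) if env.events == ["DrawSquare"] else math.log(0.7)
        assert d.loglik == pytest.approx(expected)

    def test_sampling_matches_declared_probabilities(self):
        # 0.3/0.7 alternation at n=10,000: within 3 binomial SE
        g = load_fixture("fig4_a")
        squares = 0
        for i in range(10_000):
            env = RecorderEnvironment()
            run(g, env, seed=i)
            squares += env.events == ["DrawSquare"]
        se = math.sqrt(0.3 * 0.7 / 10_000)
        assert abs(squares / 10_000 - 0.3) < 3 * se


class TestRecognition:
    def test_sensor_sequence_accepted_with_zero_loglik(self):
        res = recognize(
            load_fixture("fig1_spot"),
            ["SpotSquare", "SpotCircle", "SpotTriangle"],
        )
        assert res.accepted and res.loglik == 0.0 and res.consumed == 3

    def test_incomplete_input_rejected(self):
        res = recognize(load_fixture("fig1_spot"), ["SpotSquare", "SpotCircle"])
        assert not res.accepted
        assert res.consumed == 2

    def test_digit_probabilities_match_dynamic_programming_oracle(self):
        # independent oracle: P_A(s) by recursion over the rule equations
        g = parse_grammar("A = B | C. B = 0 | 1. C = B A.")

        def p_b(s):
            return 0.5 if s in ("0", "1") else 0.0

        def p_a(s):
            if not s:
                return 0.0
            direct = 0.5 * p_b(s)
            rec = 0.5 * (p_b(s[0]) * p_a(s[1:])) if len(s) >= 2 else 0.0
            return direct + rec

        for length in (1, 2, 3, 4, 8):
            for i in range(2 ** length):
                s = format(i, f"0{length}b")
                res = recognize(g, list(s))
                assert res.accepted
                assert res.probability == pytest.approx(p_a(s), rel=1e-12)

    def test_budget_exhaustion_flags_indeterminate(self):
        g = parse_grammar("A = B | C. B = 0 | 1. C = B A.")
        res = recognize(g, list("0101"), search_budget=3)
        assert res.indeterminate

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_production_trace_accepted_by_sensor_dual(self, seed):
        # actuator grammar run in production; swap terminals to sensors and
        # the dual must recognize the emitted trace
        g = make_random_grammar(
            random.Random(seed), max_rules=3, nonterminal_prob=0.3,
            leading_terminal=True,
        )
        env = RecorderEnvironment()
        d = run(g, env, seed=seed, max_rule_applications=200)
        if d.status is not DerivationStatus.COMPLETE or len(env.events) > 20:
            g = parse_grammar("A = .4 B | .6 C. B = DrawSquare. C = DrawCircle B.")
            env = RecorderEnvironment()
            d = run(g, env, seed=seed)

        def to_sensor(sym):
            if sym.kind is SymbolKind.ACTUATOR:
                return GrammarSymbol(sym.name, SymbolKind.SENSOR)
            return sym

        dual = Grammar(
            tuple(
                Rule(
                    r.head,
                    tuple(
                        Alternate(a.weight, tuple(to_sensor(s) for s in a.symbols))
                        for a in r.alternates
                    ),
                )
                for r in g.rules
            )
        )
        assert recognize(dual, env.events, search_budget=100_000).accepted


class TestLikelihoodConservation:
    @pytest.mark.parametrize(
        "text",
        [
            "A = .3 B | .7 C. B = DrawSquare | DrawCircle. C = DrawTriangle.",
            "A = B | C | D | E. B = DrawSquare. C = DrawCircle. D = DrawTriangle. E = Look.",
            "A = .61 B | .39 C. B = PrintGreenPoint. C = PrintRedPoint.",
        ],
    )
    def test_complete_derivation_probabilities_sum_to_one(self, text):
        g = parse_grammar(text)
        total = sum(p for _, p in enumerate_derivations(g))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestEventOrder:
    def test_fewer_rule_applications_order_first(self):
        env = RecorderEnvironment()
        d = run(load_fixture("fig2_c"), env, seed=0)
        by_name = {e.terminal.name: e for e in d.events}
        square, circle = by_name["DrawSquare"], by_name["DrawCircle"]
        assert square.depth == 2 and circle.depth == 3
        assert (square.seq, circle.seq) in event_order(d)

    def test_equal_depth_events_are_unordered(self):
        env = RecorderEnvironment()
        d = run(load_fixture("fig2_a"), env, seed=0)
        assert event_order(d) == set()

    def test_recognition_precedes_production_at_equal_depth(self):
        env = TokenStreamEnvironment(["SpotCircle"])
        d = run(load_fixture("fig1_mix"), env, seed=0)
        sensor = next(e for e in d.events if e.direction == "sensor")
        actuators = [e for e in d.events if e.direction == "actuator"]
        order = event_order(d)
        assert all((sensor.seq, a.seq) in order for a in actuators)

    def test_single_event_derivation_is_trivially_unordered(self):
        env = RecorderEnvironment()
        d = run(parse_grammar("A = DrawSquare."), env, seed=0)
        assert event_order(d) == set()


# ---------------------------------------------------------------------------
# independent Turing-machine oracle (same quintuples, table-driven)
# ---------------------------------------------------------------------------

_ORACLE_TABLE = {
    # state -> list of (scanned-symbol predicate, ops, next state)
    "b": [(lambda s: True, ["Pe", "R", "Pe", "R", "P0", "R", "R", "P0", "L", "L"], "o")],
    "o": [
        (lambda s: s == "1", ["R", "Px", "L", "L", "L"], "o"),
        (lambda s: s == "0", [], "q"),
    ],
    "q": [
        (lambda s: s in ("0", "1"), ["R", "R"], "q"),
        (lambda s: s is None, ["P1", "L"], "p"),
    ],
    "p": [
        (lambda s: s == "x", ["E", "R"], "q"),
        (lambda s: s == "e", ["R"], "f"),
        (lambda s: s is None, ["L", "L"], "p"),
    ],
    "f": [
        (lambda s: s in ("0", "1"), ["R", "R"], "f"),
        (lambda s: s is None, ["P0", "L", "L"], "o"),
    ],
}

_WRITES = {"Pe": "e", "P0": "0", "P1": "1", "Px": "x"}


def oracle_turing_ops(min_ops: int) -> list[str]:
    """Run the quintuple table directly; return at least min_ops actuator ops."""
    cells: dict[int, str] = {}
    head = 0
    state = "b"
    ops: list[str] = []
    while len(ops) < min_ops:
        scanned = cells.get(head)
        for predicate, actions, nxt in _ORACLE_TABLE[state]:
            if predicate(scanned):
                for op in actions:
                    ops.append(op)
                    if op in _WRITES:
                        cells[head] = _WRITES[op]
                    elif op == "R":
                        head += 1
                    elif op == "L":
                        head -= 1
                    elif op == "E":
                        cells.pop(head, None)
                state = nxt
                break
        else:  # pragma: no cover - the machine never blocks
            raise AssertionError(f"oracle blocked in state {state} on {scanned!r}")
    return ops


class TestTuring:
    def test_first_fifteen_figures(self, turing_grammar):
        res = run_turing(turing_grammar, figure_target=15)
        assert res.completed
        assert read_figures(res.tape, 15) == "001011011101111"

    def test_two_figures_prefix(self, turing_grammar):
        res = run_turing(turing_grammar, figure_target=2)
        assert read_figures(res.tape, 2) == "00"

    def test_engine_matches_table_oracle_step_for_step(self, turing_grammar):
        res = run_turing(turing_grammar, figure_target=40)
        assert len(res.ops) >= 500
        oracle = oracle_turing_ops(len(res.ops))
        assert list(res.ops) == oracle[: len(res.ops)]

    def test_cap_returns_partial_tape_with_flag(self, turing_grammar):
        res = run_turing(turing_grammar, figure_target=1000, cap=200)
        assert not res.completed
        assert res.tape.figure_count() < 1000

    def test_execution_is_seed_independent(self, turing_grammar):
        a = run_turing(turing_grammar, 10, seed=1)
        b = run_turing(turing_grammar, 10, seed=999)
        assert a.ops == b.ops


class TestTape:
    def test_read_figures_skips_marker_cells(self):
        t = TapeState(cells={0: "e", 2: "0", 3: "x", 4: "0", 6: "1"})
        assert read_figures(t, 3) == "001"

    def test_blank_tape_has_no_figures(self):
        assert read_figures(TapeState(), 0) == ""
        with pytest.raises(EnvironmentError_):
            read_figures(TapeState(), 1)

    def test_tape_ops(self):
        env = TapeEnvironment()
        for op in ["P0", "R", "P1", "L"]:
            env.emit(op)
        assert env.tape.cells == {0: "0", 1: "1"}
        assert env.peek("0") and not env.peek("1")
        env.emit("E")
        assert env.peek("None")
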