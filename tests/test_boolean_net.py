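"""Synchronous Boolean dynamics, clamping, and the two circuit models."""

import itertools

import numpy as np
import pytest

from regloop.boolean_net import (
    SCENARIOS,
    BooleanNetwork,
    Rule,
    build_feedforward_model,
    build_linear_model,
    compare_models,
    parse_network,
    simulate_probability,
    synchronous_step,
)
from regloop.genomics_core import ValidationError


def brute_force_step(net, state):
    """Independent evaluator: apply each rule via explicit truth-table lookup."""
    new = {}
    for node in net.nodes:
        if node in net.clamps:
            new[node] = net.clamps[node]
        elif node in net.rules:
            rule = net.rules[node]
            table = {}
            for bits in itertools.product((0, 1), repeat=len(rule.inputs)):
                table[bits] = int(bool(rule.fn(*bits)))
            new[node] = table[tuple(state[i] for i in rule.inputs)]
        else:
            new[node] = state[node]
    return new


class TestGatesAndStep:
    def test_nand_truth_table(self):
        net = build_feedforward_model()
        rule = net.rules["lifespan"]
        vals = {
            bits: rule({"dFOXO": bits[0], "PNT": bits[1]})
            for bits in itertools.product((0, 1), repeat=2)
        }
        assert vals == {(0, 0): 1, (0, 1): 1, (1, 0): 1, (1, 1): 0}

    def test_feedforward_single_step(self):
        net = build_feedforward_model()
        state = {"dFOXO": 1, "AOP": 0, "PNT": 1, "lifespan": 0}
        new = synchronous_step(net, state)
        assert (new["AOP"], new["PNT"], new["lifespan"]) == (1, 1, 0)

    def test_linear_step_not_gate(self):
        net = build_linear_model()
        new = synchronous_step(net, {"dFOXO": 0, "AOP": 0, "PNT": 1, "lifespan": 1})
        assert new["lifespan"] == 0

    def test_clamp_overrides_rule(self):
        net = build_feedforward_model().with_clamps({"AOP": 0})
        new = synchronous_step(net, {"dFOXO": 1, "AOP": 1, "PNT": 0, "lifespan": 0})
        assert new["AOP"] == 0  # rule would say 1

    def test_free_node_holds_value(self):
        net = build_feedforward_model()
        s = {"dFOXO": 1, "AOP": 1, "PNT": 0, "lifespan": 1}
        for _ in range(5):
            s = synchronous_step(net, s)
            assert s["dFOXO"] == 1

    def test_incomplete_state_rejected(self):
        with pytest.raises(ValidationError):
            synchronous_step(build_linear_model(), {"dFOXO": 1})

    def test_exhaustive_agreement_with_brute_force(self):
        for net in (build_feedforward_model(), build_linear_model()):
            for bits in itertools.product((0, 1), repeat=4):
                state = dict(zip(net.nodes, bits))
                assert synchronous_step(net, state) == brute_force_step(net, state)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_networks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        nodes = tuple(f"n{i}" for i in range(n))
        rules = {}
        for node in nodes:
            if rng.random() < 0.7:
                k = int(rng.integers(1, min(3, n) + 1))
                inputs = tuple(rng.choice(nodes, size=k, replace=False))
                table = rng.integers(0, 2, size=2**k)

                def fn(*vals, table=table):
                    idx = int("".join(map(str, vals)), 2)
                    return int(table[idx])

                rules[node] = Rule(inputs, fn)
        net = BooleanNetwork(nodes, rules, {}, target=nodes[0])
        for _ in range(20):
            state = dict(zip(nodes, rng.integers(0, 2, size=n).tolist()))
            assert synchronous_step(net, state) == brute_force_step(net, state)


class TestFixedPoints:
    def test_feedforward_dfoxo_off_gives_long_life(self):
        net = build_feedforward_model().with_clamps({"dFOXO": 0})
        r = simulate_probability(net, n_transitions=1000, mode="exact")
        assert r.probability_target_active == 1.0  # PNT settles at 1, NAND(0,1) = 1

    def test_linear_dfoxo_clamped_active_attractor(self):
        net = build_linear_model().with_clamps({"dFOXO": 1})
        state = {"dFOXO": 1, "AOP": 0, "PNT": 1, "lifespan": 0}
        for _ in range(10):
            state = synchronous_step(net, state)
        assert (state["AOP"], state["PNT"], state["lifespan"]) == (1, 0, 1)


class TestSimulateProbability:
    def test_exact_scenario_probabilities(self):
        ff = build_feedforward_model()
        lin = build_linear_model()
        p = lambda net, clamps: simulate_probability(
            net, clamps=clamps, n_transitions=1000
        ).probability_target_active
        assert p(ff, {"dFOXO": 1, "PNT": 1}) == 0.0
        assert p(ff, {"dFOXO": 1}) == 1.0
        assert p(ff, {"PNT": 1}) == 0.5
        assert p(lin, {"PNT": 1}) == 0.0
        assert p(lin, {"dFOXO": 1, "PNT": 1}) == 0.0
        assert p(lin, {"dFOXO": 1}) == 1.0

    def test_clamped_target_is_certain(self):
        for net in (build_feedforward_model(), build_linear_model()):
            r = simulate_probability(net, clamps={"lifespan": 1}, n_transitions=1000)
            assert r.probability_target_active == 1.0

    def test_monte_carlo_within_three_standard_errors(self):
        for net in (build_feedforward_model(), build_linear_model()):
            for clamps in SCENARIOS.values():
                exact = simulate_probability(net, clamps=clamps).probability_target_active
                mc = simulate_probability(
                    net, clamps=clamps, mode="monte_carlo", n_runs=10_000, seed=1
                ).probability_target_active
                se = np.sqrt(max(exact * (1 - exact), 1e-12) / 10_000)
                assert abs(mc - exact) <= max(3 * se, 1e-9)

    def test_probability_stable_beyond_transient(self):
        """The transient is at most 2^4 states; step 1000 equals any later step."""
        for net in (build_feedforward_model(), build_linear_model()):
            for clamps in SCENARIOS.values():
                probs = {
                    n: simulate_probability(
                        net, clamps=clamps, n_transitions=n
                    ).probability_target_active
                    for n in (16, 17, 100, 1000)
                }
                assert len(set(probs.values())) == 1

    def test_mc_requires_positive_runs(self):
        with pytest.raises(ValidationError):
            simulate_probability(build_linear_model(), mode="monte_carlo", n_runs=0)


class TestCompareModels:
    def test_synergy_only_for_feedforward(self):
        table = compare_models(
            {"linear": build_linear_model(), "feedforward": build_feedforward_model()}
        )
        assert bool(table.loc["feedforward", "synergy"]) is True
        assert bool(table.loc["linear", "synergy"]) is False
        assert table.loc["feedforward", "both_active"] == 0.0
        assert table.loc["feedforward", "dFOXO_active"] == 1.0
        assert table.loc["feedforward", "PNT_active"] == 0.5
        assert table.loc["linear", "PNT_active"] == table.loc["linear", "both_active"]

    def test_constant_lifespan_rule_no_synergy(self):
        net = parse_network("dFOXO\nAOP <- dFOXO\nPNT <- NOT AOP\nlifespan <- 1\n")
        table = compare_models({"const": net})
        assert (table[["dFOXO_active", "PNT_active", "both_active"]] == 1.0).all().all()
        assert bool(table.loc["const", "synergy"]) is False


class TestParser:
    def test_round_trip_semantics(self):
        net = parse_network("a\nb <- NOT a\nc <- a AND b OR (NOT b)\n", target="c")
        assert set(net.nodes) == {"a", "b", "c"}
        assert "a" not in net.rules
        s = {"a": 1, "b": 0, "c": 0}
        out = synchronous_step(net, s)
        assert out["b"] == 0 and out["c"] == 1  # (1 AND 0) OR NOT 0 = 1

    def test_nand_infix(self):
        net = parse_network("x\ny\nz <- x NAND y\n", target="z")
        rule = net.rules["z"]
        assert [rule({"x": a, "y": b}) for a, b in itertools.product((0, 1), repeat=2)] == [1, 1, 1, 0]

    def test_malformed_lines_rejected(self):
        with pytest.raises(ValidationError):
            parse_network("a <- b AND\n", target="a")
        with pytest.raises(ValidationError):
            parse_network("a b c\n", target="a")

    def test_unknown_clamp_and_target_rejected(self):
        net = build_linear_model()
        with pytest.raises(ValidationError):
            net.with_clamps({"nope": 1})
        with pytest.raises(ValidationError):
            simulate_probability(net, target="nope")
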