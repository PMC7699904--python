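"""Mamdani engine: memberships, rule evaluation, centroid defuzzification."""

from __future__ import annotations

import numpy as np
import pytest

from hypoxalert.fuzzy import (
    ConfigurationError,
    DegenerateInferenceError,
    FuzzyRule,
    FuzzyVariable,
    InferenceSystemConfig,
    InputError,
    RuleAntecedent,
    TrapezoidLabel,
    aggregate_and_defuzzify,
    evaluate_rule,
    infer,
    membership_degree,
)

from conftest import brute_force_defuzzify


def make_label(knots, name="lab"):
    return TrapezoidLabel(name, tuple(float(k) for k in knots))


class TestMembership:
    @pytest.mark.parametrize(
        "knots,x,expected",
        [
            ((0, 2, 4, 6), 2, 1.0),  # plateau start
            ((0, 2, 4, 6), 4, 1.0),  # plateau end
            ((0, 2, 4, 6), -0.5, 0.0),  # outside support
            ((0, 2, 4, 6), 7, 0.0),
            ((0, 2, 4, 6), 1, 0.5),  # ramp midpoint
            ((0, 2, 4, 6), 5, 0.5),
            ((0, 0, 4, 6), 0, 1.0),  # left shoulder
            ((0, 2, 6, 6), 6, 1.0),  # right shoulder
            ((0, 3, 3, 6), 3, 1.0),  # degenerate triangle apex
        ],
    )
    def test_piecewise_values(self, knots, x, expected):
        assert membership_degree(x, make_label(knots)) == pytest.approx(expected)

    def test_continuity_on_dense_grid(self):
        lab = make_label((1, 2, 5, 9))
        x = np.linspace(0, 10, 10001)
        mu = lab.membership(x)
        assert np.all(np.abs(np.diff(mu)) < 2e-3)  # Lipschitz bound 1/(b-a) * dx

    def test_non_ascending_knots_rejected(self):
        with pytest.raises(ConfigurationError):
            make_label((5, 3, 8, 9))


def toy_config(rules, resolution=1001):
    x = FuzzyVariable(
        "x",
        (0.0, 10.0),
        (
            TrapezoidLabel("lo", (0, 0, 3, 6)),
            TrapezoidLabel("hi", (3, 6, 10, 10)),
        ),
    )
    out = FuzzyVariable(
        "y",
        (0.0, 100.0),
        (
            TrapezoidLabel("small", (0, 10, 20, 30)),
            TrapezoidLabel("large", (70, 80, 90, 100)),
        ),
    )
    return InferenceSystemConfig(inputs=(x,), output=out, rules=rules, resolution=resolution)


def rule(var, label, then, mode="is"):
    return FuzzyRule(
        antecedents=(RuleAntecedent(var, mode, label),), consequent_label=then
    )


class TestRuleEvaluation:
    def two_input_config(self):
        def onoff(name):
            return FuzzyVariable(
                name,
                (0.0, 1.0),
                (
                    TrapezoidLabel("off", (0, 0, 0.2, 0.4)),
                    TrapezoidLabel("on", (0, 0.4, 1, 1)),
                ),
            )

        a, b = onoff("a"), onoff("b")
        out = FuzzyVariable("y", (0.0, 1.0), (TrapezoidLabel("o", (0, 0, 1, 1)),))
        r = FuzzyRule(
            antecedents=(
                RuleAntecedent("a", "is", "on"),
                RuleAntecedent("b", "is", "on"),
            ),
            consequent_label="o",
        )
        return InferenceSystemConfig(inputs=(a, b), output=out, rules=(r,), resolution=101), r

    def test_min_of_antecedent_degrees(self):
        cfg, r = self.two_input_config()
        # 'on' degrees on the (0, 0.4) ramp: 0.32 -> 0.8, 0.12 -> 0.3
        assert evaluate_rule({"a": 0.32, "b": 0.12}, r, cfg) == pytest.approx(0.3)
        assert evaluate_rule({"a": 0.5, "b": 0.5}, r, cfg) == pytest.approx(1.0)
        assert evaluate_rule({"a": 0.5, "b": 0.0}, r, cfg) == pytest.approx(0.0)

    def test_is_not_uses_complement(self):
        cfg, _ = self.two_input_config()
        r = FuzzyRule(
            antecedents=(
                RuleAntecedent("a", "is_not", "on"),
                RuleAntecedent("b", "any"),
            ),
            consequent_label="o",
        )
        assert evaluate_rule({"a": 0.32, "b": 0.9}, r, cfg) == pytest.approx(0.2)

    def test_missing_input_raises(self):
        cfg, r = self.two_input_config()
        with pytest.raises(InputError):
            evaluate_rule({"a": 0.5}, r, cfg)


class TestDefuzzification:
    def test_symmetric_trapezoid_full_activation_gives_center(self):
        cfg = toy_config((rule("x", "lo", "small"),))
        out = aggregate_and_defuzzify({cfg.rules[0]: 1.0}, cfg)
        assert out == pytest.approx(15.0, abs=1e-9)  # (0,10,20,30) is symmetric

    def test_truncated_trapezoid_matches_dense_integration(self):
        # single rule at activation 0.5 truncating (0,10,20,30) on [0,30]
        x = FuzzyVariable("x", (0.0, 1.0), (TrapezoidLabel("on", (0, 0, 1, 1)),))
        out = FuzzyVariable("y", (0.0, 30.0), (TrapezoidLabel("t", (0, 10, 20, 30)),))
        cfg = InferenceSystemConfig(
            inputs=(x,), output=out, rules=(rule("x", "on", "t"),), resolution=3001
        )
        got = aggregate_and_defuzzify({cfg.rules[0]: 0.5}, cfg)
        oracle = brute_force_defuzzify([(0.5, (0, 10, 20, 30))], 0.0, 30.0)
        assert got == pytest.approx(oracle, abs=0.05)
        assert oracle == pytest.approx(15.0, abs=1e-6)  # symmetric shape

    def test_asymmetric_truncation_matches_dense_integration(self):
        x = FuzzyVariable("x", (0.0, 1.0), (TrapezoidLabel("on", (0, 0, 1, 1)),))
        out = FuzzyVariable("y", (0.0, 50.0), (TrapezoidLabel("t", (0, 5, 20, 50)),))
        cfg = InferenceSystemConfig(
            inputs=(x,), output=out, rules=(rule("x", "on", "t"),), resolution=5001
        )
        for act in (0.25, 0.5, 0.75, 1.0):
            got = aggregate_and_defuzzify({cfg.rules[0]: act}, cfg)
            oracle = brute_force_defuzzify([(act, (0, 5, 20, 50))], 0.0, 50.0)
            assert got == pytest.approx(oracle, abs=0.05)

    def test_mirror_symmetric_envelope_gives_universe_midpoint(self):
        cfg = toy_config((rule("x", "lo", "small"), rule("x", "hi", "large")))
        acts = {cfg.rules[0]: 0.6, cfg.rules[1]: 0.6}
        assert aggregate_and_defuzzify(acts, cfg) == pytest.approx(50.0, abs=1e-9)

    def test_no_rule_fires_raises(self):
        cfg = toy_config((rule("x", "lo", "small"),))
        with pytest.raises(DegenerateInferenceError):
            aggregate_and_defuzzify({cfg.rules[0]: 0.0}, cfg)

    def test_centroid_invariant_under_scaling_of_aggregated_function(self):
        # centroid(k*g) == centroid(g). With rectangular consequents,
        # min(k*act, mu) = k*min(act, mu), so scaling every activation by k
        # scales the aggregated envelope uniformly.
        x = FuzzyVariable("x", (0.0, 1.0), (TrapezoidLabel("on", (0, 0, 1, 1)),))
        out = FuzzyVariable(
            "y",
            (0.0, 100.0),
            (
                TrapezoidLabel("low", (0, 0, 20, 20)),
                TrapezoidLabel("high", (60, 60, 100, 100)),
            ),
        )
        cfg = InferenceSystemConfig(
            inputs=(x,),
            output=out,
            rules=(rule("x", "on", "low"), rule("x", "on", "high")),
            resolution=1001,
        )
        base = aggregate_and_defuzzify(
            {cfg.rules[0]: 0.8, cfg.rules[1]: 0.4}, cfg
        )
        for k in (0.5, 0.25):
            scaled = aggregate_and_defuzzify(
                {cfg.rules[0]: 0.8 * k, cfg.rules[1]: 0.4 * k}, cfg
            )
            assert scaled == pytest.approx(base, abs=1e-9)

    def test_resolution_convergence(self):
        for res in (1001, 2001):
            base = toy_config((rule("x", "lo", "small"), rule("x", "hi", "large")), res)
            dbl = toy_config(
                (rule("x", "lo", "small"), rule("x", "hi", "large")), 2 * res - 1
            )
            acts = lambda cfg: {cfg.rules[0]: 0.3, cfg.rules[1]: 0.9}
            a = aggregate_and_defuzzify(acts(base), base)
            b = aggregate_and_defuzzify(acts(dbl), dbl)
            assert abs(a - b) < 0.1


class TestInfer:
    def test_identity_style_config_returns_plateau_center(self):
        x = FuzzyVariable("x", (0.0, 100.0), (TrapezoidLabel("any", (0, 0, 100, 100)),))
        out = FuzzyVariable("y", (0.0, 100.0), (TrapezoidLabel("mid", (30, 40, 60, 70)),))
        cfg = InferenceSystemConfig(
            inputs=(x,), output=out, rules=(rule("x", "any", "mid"),), resolution=1001
        )
        assert infer({"x": 17.0}, cfg) == pytest.approx(50.0, abs=1e-9)

    def test_two_rule_config_matches_dense_oracle(self):
        cfg = toy_config((rule("x", "lo", "small"), rule("x", "hi", "large")))
        for xval in (1.0, 3.5, 4.5, 6.0, 9.0):
            got = infer({"x": xval}, cfg)
            lo_deg = cfg.inputs[0].label("lo").membership(xval)
            hi_deg = cfg.inputs[0].label("hi").membership(xval)
            shapes = []
            if lo_deg > 0:
                shapes.append((lo_deg, (0, 10, 20, 30)))
            if hi_deg > 0:
                shapes.append((hi_deg, (70, 80, 90, 100)))
            assert got == pytest.approx(
                brute_force_defuzzify(shapes, 0, 100), abs=0.05
            )

    def test_inputs_at_bounds_stay_inside_output_universe(self):
        cfg = toy_config((rule("x", "lo", "small"), rule("x", "hi", "large")))
        for xval in (0.0, 10.0):
            out = cfg.output.universe
            assert out[0] <= infer({"x": xval}, cfg) <= out[1]

    def test_out_of_universe_input_clamped_with_warning(self, caplog):
        cfg = toy_config((rule("x", "lo", "small"), rule("x", "hi", "large")))
        import logging

        with caplog.at_level(logging.WARNING, logger="hypoxalert.fuzzy"):
            assert infer({"x": 12.0}, cfg) == pytest.approx(infer({"x": 10.0}, cfg))
        assert any("clamped" in rec.message for rec in caplog.records)


class TestRandomizedOracleAgreement:
    def test_agreement_with_brute_force_on_random_configs(self):
        """>=20 random small systems agree with dense sampling within 0.05."""
        rng = np.random.default_rng(20201120)
        checked = 0
        while checked < 25:
            # one input, 2-4 labels partitioning [0, 10]
            n_in_labels = rng.integers(2, 5)
            edges = np.sort(rng.uniform(0.5, 9.5, size=2 * n_in_labels - 2))
            in_labels, lo_edge = [], 0.0
            for i in range(n_in_labels):
                a = 0.0 if i == 0 else edges[2 * i - 2]
                b = 0.0 if i == 0 else edges[2 * i - 1]
                c = 10.0 if i == n_in_labels - 1 else edges[2 * i]
                d = 10.0 if i == n_in_labels - 1 else edges[2 * i + 1]
                if not a <= b <= c <= d:
                    break
                in_labels.append(TrapezoidLabel(f"L{i}", (a, b, c, d)))
            else:
                try:
                    var = FuzzyVariable("x", (0.0, 10.0), tuple(in_labels))
                except ConfigurationError:
                    continue
                out_knots = [
                    (0.0, 0.0, 20.0, 35.0),
                    (25.0, 40.0, 55.0, 70.0),
                    (60.0, 80.0, 100.0, 100.0),
                ]
                out = FuzzyVariable(
                    "y",
                    (0.0, 100.0),
                    tuple(
                        TrapezoidLabel(f"O{i}", k) for i, k in enumerate(out_knots)
                    ),
                )
                rules = tuple(
                    rule("x", lab.name, f"O{rng.integers(0, 3)}") for lab in in_labels
                )
                cfg = InferenceSystemConfig(
                    inputs=(var,), output=out, rules=rules, resolution=2001
                )
                xval = float(rng.uniform(0, 10))
                shapes = []
                for r in rules:
                    deg = var.label(r.antecedents[0].label).membership(xval)
                    if deg > 0:
                        shapes.append(
                            (deg, out.label(r.consequent_label).knots)
                        )
                if not shapes:
                    continue
                got = infer({"x": xval}, cfg)
                oracle = brute_force_defuzzify(shapes, 0.0, 100.0, n=400_001)
                assert got == pytest.approx(oracle, abs=0.05)
                checked += 1
        assert checked >= 20


class TestConfigValidation:
    def test_uncovered_input_universe_rejected(self):
        gap_var = FuzzyVariable(
            "x",
            (0.0, 10.0),
            (TrapezoidLabel("a", (0, 0, 2, 3)), TrapezoidLabel("b", (5, 6, 10, 10))),
        )
        out = FuzzyVariable("y", (0.0, 1.0), (TrapezoidLabel("o", (0, 0, 1, 1)),))
        with pytest.raises(ConfigurationError, match="not covered"):
            InferenceSystemConfig(
                inputs=(gap_var,),
                output=out,
                rules=(rule("x", "a", "o"),),
                resolution=101,
            )

    def test_dangling_consequent_rejected(self):
        with pytest.raises(ConfigurationError):
            toy_config((rule("x", "lo", "nonexistent"),))

    def test_resolution_floor(self):
        with pytest.raises(ConfigurationError):
            toy_config((rule("x", "lo", "small"),), resolution=51)

    def test_serialization_round_trip(self):
        cfg = toy_config((rule("x", "lo", "small"), rule("x", "hi", "large", "is_not")))
        again = InferenceSystemConfig.from_dict(cfg.to_dict())
        assert again == cfg
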