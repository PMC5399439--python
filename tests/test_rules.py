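import io

import numpy as np
import pandas as pd
import pytest

from mamsbayes import (
    ArmState,
    BetaPrior,
    ConfigurationError,
    DesignParams,
    InvalidParameterError,
    evaluate_look,
    prob_diff_exceeds_mc,
    sensitivity_grid,
    standard_prior_grid,
)

UNIFORM = BetaPrior(1.0, 1.0)


class TestDesignParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p0": 0.0},
            {"delta": 0.2, "delta_star": 0.1},
            {"gamma1": 1.0},
            {"gamma2": 0.0},
            {"min_enrollment": -1},
            {"gate_scope": "cohort"},
            {"n_max": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            DesignParams(**kwargs)

    def test_case_study_defaults(self):
        p = DesignParams()
        assert (p.p0, p.delta, p.delta_star) == (0.3, 0.0, 0.15)
        assert (p.gamma1, p.gamma2, p.gamma3) == (0.9, 0.1, 0.9)


class TestEvaluateLook:
    def test_flat_prior_case_study(self, uniform_states, case_params):
        report = evaluate_look(uniform_states, case_params)
        expected = {
            "A": (0.3810, 0.1384, None, None),
            "B": (0.3333, 0.3346, 0.3223, 0.0281),
            "C": (0.4048, 0.0789, 0.5894, 0.1161),
        }
        for arm, (mean, c1, c2, c3) in expected.items():
            dec = report[arm]
            assert dec.posterior_mean == pytest.approx(mean, abs=5e-5)
            assert dec.crit1 == pytest.approx(c1, abs=5e-5)
            if c2 is None:
                assert dec.crit2 is None and dec.crit3 is None
            else:
                assert dec.crit2 == pytest.approx(c2, abs=5e-5)
                assert dec.crit3 == pytest.approx(c3, abs=5e-5)
            assert not (dec.rule1 or dec.rule2 or dec.rule3)

    def test_jeffreys_prior_case_study(self, stage1_counts, case_params):
        j = BetaPrior(0.5, 0.5)
        states = [
            ArmState(arm, j, n=n, y=y, is_control=(arm == "A"))
            for arm, (y, n) in stage1_counts.items()
        ]
        report = evaluate_look(states, case_params)
        assert report["A"].crit1 == pytest.approx(0.1505, abs=5e-5)
        assert report["B"].crit1 == pytest.approx(0.3576, abs=5e-5)
        assert report["C"].crit1 == pytest.approx(0.0863, abs=5e-5)
        assert report["B"].crit3 == pytest.approx(0.0286, abs=5e-5)
        assert report["C"].crit3 == pytest.approx(0.1197, abs=5e-5)

    def test_flags_suppressed_below_minimum_enrollment(self):
        # 0 responses in 20 patients is far past the rule-1 boundary, but the
        # trial-level gate of 100 suppresses the flag
        states = [
            ArmState("A", UNIFORM, n=20, y=6, is_control=True),
            ArmState("B", UNIFORM, n=20, y=0),
        ]
        gated = evaluate_look(states, DesignParams(min_enrollment=100))
        assert gated["B"].crit1 > 0.9
        assert not gated["B"].rule1
        open_ = evaluate_look(states, DesignParams(min_enrollment=0))
        assert open_["B"].rule1

    def test_per_arm_gate_scope(self):
        states = [
            ArmState("A", UNIFORM, n=30, y=9, is_control=True),
            ArmState("B", UNIFORM, n=10, y=0),
        ]
        per_arm = evaluate_look(
            states, DesignParams(min_enrollment=15, gate_scope="arm")
        )
        assert not per_arm["B"].rule1  # own n below the per-arm minimum
        trial = evaluate_look(
            states, DesignParams(min_enrollment=15, gate_scope="trial")
        )
        assert trial["B"].rule1

    def test_trigger_comparisons_are_strict(self, uniform_states):
        report = evaluate_look(
            uniform_states,
            DesignParams(gamma2=0.3223, min_enrollment=0),
        )
        b = report["B"]
        # crit2 == 0.32226... < 0.3223 is a hair below the threshold: triggers
        assert b.rule2 == (b.crit2 < 0.3223)

    def test_combined_futility_flag(self, uniform_states):
        report = evaluate_look(
            uniform_states,
            DesignParams(gamma2=0.4, min_enrollment=0),
            combine_futility=True,
        )
        assert report["B"].futility == (report["B"].rule1 or report["B"].rule2)
        plain = evaluate_look(uniform_states, DesignParams(min_enrollment=0))
        assert plain["B"].futility is None

    @pytest.mark.parametrize("controls", [0, 2])
    def test_exactly_one_control_required(self, controls, case_params):
        states = [
            ArmState(f"x{i}", UNIFORM, n=20, y=5, is_control=(i < controls))
            for i in range(3)
        ]
        with pytest.raises(ConfigurationError):
            evaluate_look(states, case_params)

    def test_report_does_not_mutate_states(self, uniform_states, case_params):
        before = [(s.n, s.y) for s in uniform_states]
        evaluate_look(uniform_states, case_params)
        assert [(s.n, s.y) for s in uniform_states] == before

    def test_comparative_futility_dominates_efficacy_margin(self, case_params):
        # P(diff > delta) >= P(diff > delta_star) whenever delta < delta_star
        rng = np.random.default_rng(5)
        for _ in range(10):
            states = [
                ArmState("A", UNIFORM, n=20, y=int(rng.integers(0, 21)),
                         is_control=True),
                ArmState("B", UNIFORM, n=20, y=int(rng.integers(0, 21))),
            ]
            report = evaluate_look(states, case_params)
            assert report["B"].crit2 >= report["B"].crit3


class TestCriterionMonotonicity:
    """Exhaustive small-sample checks of direction-of-evidence ordering."""

    N = 10

    def test_futility_criterion_decreases_in_responses(self, case_params):
        for n in range(1, self.N + 1):
            ctrl = ArmState("A", UNIFORM, n=n, y=n // 2, is_control=True)
            c1 = [
                evaluate_look(
                    [ctrl, ArmState("B", UNIFORM, n=n, y=y)], case_params
                )["B"].crit1
                for y in range(n + 1)
            ]
            assert all(u >= v for u, v in zip(c1, c1[1:]))

    def test_comparative_criteria_monotone_in_both_counts(self, case_params):
        n = self.N
        ctrl = ArmState("A", UNIFORM, n=n, y=4, is_control=True)
        for crit in ("crit2", "crit3"):
            by_exp = [
                getattr(
                    evaluate_look(
                        [ctrl, ArmState("B", UNIFORM, n=n, y=y)], case_params
                    )["B"],
                    crit,
                )
                for y in range(n + 1)
            ]
            assert all(u <= v for u, v in zip(by_exp, by_exp[1:]))
        exp = ArmState("B", UNIFORM, n=n, y=6)
        by_ctrl = [
            evaluate_look(
                [ArmState("A", UNIFORM, n=n, y=y, is_control=True), exp],
                case_params,
            )["B"].crit2
            for y in range(n + 1)
        ]
        assert all(u >= v for u, v in zip(by_ctrl, by_ctrl[1:]))

    def test_spot_values_match_sampling_oracle(self, case_params):
        draws = 400_000
        for y_exp, y_ctrl in [(0, 5), (5, 5), (9, 2)]:
            exp = ArmState("B", UNIFORM, n=self.N, y=y_exp)
            ctrl = ArmState("A", UNIFORM, n=self.N, y=y_ctrl, is_control=True)
            report = evaluate_look([ctrl, exp], case_params)
            mc = prob_diff_exceeds_mc(exp, ctrl, 0.0, draws, seed=y_exp * 17 + y_ctrl)
            se = np.sqrt(max(mc * (1 - mc), 1e-12) / draws)
            assert report["B"].crit2 == pytest.approx(mc, abs=3 * se + 5 / draws)


class TestSensitivityGrid:
    def test_reference_and_posterior_means(self, stage1_counts, case_params):
        grid = standard_prior_grid("A", ["B", "C"])
        frame = sensitivity_grid(stage1_counts, "A", grid, case_params)

        mle = frame[frame["prior"] == "MLE"].set_index("arm")["posterior_mean"]
        assert mle["A"] == pytest.approx(0.3750)
        assert mle["B"] == pytest.approx(0.3250)
        assert mle["C"] == pytest.approx(0.4000)
        assert frame[frame["prior"] == "MLE"]["crit1"].isna().all()

        uni = frame[frame["prior"] == "uniform"].set_index("arm")
        assert uni.loc["A", "posterior_mean"] == pytest.approx(0.3810, abs=5e-5)
        assert uni.loc["B", "posterior_mean"] == pytest.approx(0.3333, abs=5e-5)
        assert uni.loc["C", "posterior_mean"] == pytest.approx(0.4048, abs=5e-5)

        sk = frame[frame["prior"] == "skeptical-ess1"].set_index("arm")
        assert sk.loc["A", "posterior_mean"] == pytest.approx(0.3600, abs=5e-5)
        assert sk.loc["B", "posterior_mean"] == pytest.approx(0.3244, abs=5e-5)
        assert sk.loc["C", "posterior_mean"] == pytest.approx(0.3976, abs=5e-5)
        assert sk.loc["A", "ess"] == pytest.approx(10.0)  # skeptical control

    def test_missing_control_rejected(self, stage1_counts, case_params):
        with pytest.raises(ConfigurationError):
            sensitivity_grid(stage1_counts, "Z", [], case_params)

    def test_four_decimal_csv_round_trip(self, stage1_counts, case_params):
        grid = standard_prior_grid("A", ["B", "C"])
        frame = sensitivity_grid(stage1_counts, "A", grid, case_params)
        buf = io.StringIO()
        frame.to_csv(buf, index=False, float_format="%.4f")
        buf.seek(0)
        back = pd.read_csv(buf)
        buf2 = io.StringIO()
        back.to_csv(buf2, index=False, float_format="%.4f")
        assert buf.getvalue() == buf2.getvalue()
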