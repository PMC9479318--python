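"""Tests of the agent-based opinion-dynamics model."""

import numpy as np
import pytest

from moralargs.exceptions import ValidationError
from moralargs.simulation import (
    FreqClass,
    OpinionDynamicsModel,
    SimConfig,
    calibrate_ingroup_bias,
    liberal_drift_oracle,
    run_simulation,
)


def small_config(**kw):
    base = dict(
        n_agents=400,
        horizon=50,
        n_replicates=60,
        seed=10,
        freq_classes=[FreqClass("slow", 0.01, 0.5), FreqClass("fast", 0.05, 0.5)],
    )
    base.update(kw)
    return SimConfig(**base)


class TestCalibration:
    def test_two_rate_algebra(self):
        assert calibrate_ingroup_bias([0.2, 1.0]) == {0.2: 0.0, 1.0: 0.8}

    def test_cross_contact_constant(self):
        rates = [0.05, 0.2, 0.7]
        b = calibrate_ingroup_bias(rates)
        contact = {f * (1 - b[f]) for f in rates}
        assert max(contact) - min(contact) < 1e-12

    def test_single_class_zero_bias(self):
        assert calibrate_ingroup_bias([0.3]) == {0.3: 0.0}

    def test_equal_rates_equal_bias(self):
        assert calibrate_ingroup_bias([0.4, 0.4]) == {0.4: 0.0}

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_ingroup_bias([0.0, 0.5])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"advantage": 1.5},
            {"persuade_prob": -0.1},
            {"prop_liberal": 2.0},
            {"freq_classes": [FreqClass("a", 0.5, 0.4), FreqClass("b", 0.1, 0.4)]},
            {"ingroup_bias": 1.4},
            {"init_prevalence": {"liberal": 1.2}},
        ],
    )
    def test_invalid_configs(self, kw):
        with pytest.raises(ValidationError):
            small_config(**kw)


class TestDynamics:
    def test_zero_persuasion_freezes_state(self):
        res = run_simulation(small_config(persuade_prob=0.0, horizon=20))
        first = res.prevalence[:, 0, :]
        assert np.array_equal(res.prevalence, np.repeat(first[:, None, :], 21, axis=1))

    def test_no_advantage_no_drift(self):
        """A=0 with symmetric 0.5 start leaves every cell at 0.5 in
        expectation."""
        res = run_simulation(
            small_config(
                advantage=0.0,
                init_prevalence={"liberal": 0.5, "conservative": 0.5},
                n_replicates=100,
            )
        )
        for k in range(len(res.cells)):
            term = res.prevalence[k, -1, :]
            se = term.std(ddof=1) / np.sqrt(len(term))
            assert abs(term.mean() - 0.5) <= 3 * se

    def test_prevalence_bounds_and_length(self):
        res = run_simulation(small_config())
        assert res.prevalence.shape[1] == 51
        assert np.nanmin(res.prevalence) >= 0.0
        assert np.nanmax(res.prevalence) <= 1.0

    def test_relabeling_symmetry(self):
        """A -> -A with opinion labels (initial prevalence) swapped gives
        mirrored dynamics."""
        a = run_simulation(
            small_config(advantage=0.3, init_prevalence={"liberal": 0.2,
                                                         "conservative": 0.2},
                         n_replicates=150, seed=21)
        )
        b = run_simulation(
            small_config(advantage=-0.3, init_prevalence={"liberal": 0.8,
                                                          "conservative": 0.8},
                         n_replicates=150, seed=22)
        )
        for ideo in ("liberal", "conservative"):
            pa = a.group_prevalence(ideo, 50)
            pb = 1.0 - b.group_prevalence(ideo, 50)
            se = np.sqrt(pa.var(ddof=1) / len(pa) + pb.var(ddof=1) / len(pb))
            assert abs(pa.mean() - pb.mean()) <= 3 * se

    def test_larger_advantage_drifts_faster(self):
        """Mean liberal prevalence under A=0.3 dominates A=0.1 at every
        recorded time (stochastic ordering of the replicate means)."""
        lo = run_simulation(small_config(advantage=0.1, horizon=80, seed=30))
        hi = run_simulation(small_config(advantage=0.3, horizon=80, seed=30))
        t_checks = [20, 40, 60, 80]
        for t in t_checks:
            assert hi.group_prevalence("liberal", t).mean() >= (
                lo.group_prevalence("liberal", t).mean()
            )

    def test_expected_advantaged_growth(self):
        """For A>0 the advantaged share rises in expectation after the
        start."""
        res = run_simulation(small_config(advantage=0.3, horizon=80, seed=31))
        lib = res.group_prevalence("liberal", 80).mean()
        lib0 = res.group_prevalence("liberal", 0).mean()
        assert lib > lib0


class TestDriftOracle:
    def test_boundaries_and_zero_advantage(self):
        assert liberal_drift_oracle(0.0, 0.3, 0.5, 0.1) == 0.0
        assert liberal_drift_oracle(1.0, 0.3, 0.5, 0.1) == 0.0
        assert liberal_drift_oracle(0.5, 0.0, 0.5, 0.1) == 0.0

    def test_one_step_increment_matches_closed_form(self):
        """Simulated one-step drift in an all-liberal population matches
        2*s*A*x(1-x)*f within Monte-Carlo error."""
        f, A, s, x0 = 0.02, 0.2, 0.5, 0.5
        cfg = SimConfig(
            n_agents=20000, prop_liberal=1.0, advantage=A, persuade_prob=s,
            freq_classes=[FreqClass("only", f, 1.0)], ingroup_bias=0.0,
            init_prevalence={"liberal": x0}, horizon=1, n_replicates=120,
            seed=40,
        )
        res = run_simulation(cfg)
        inc = res.group_prevalence("liberal", 1) - res.group_prevalence("liberal", 0)
        pred = liberal_drift_oracle(x0, A, s, f)
        se = inc.std(ddof=1) / np.sqrt(len(inc))
        assert abs(inc.mean() - pred) <= 3 * se


class TestSummaries:
    def test_df_effect_requires_two_classes(self):
        cfg = small_config(freq_classes=[FreqClass("only", 0.02, 1.0)])
        res = run_simulation(cfg)
        with pytest.raises(ValidationError):
            res.summarize_df_effect()

    def test_time_beyond_horizon_rejected(self):
        res = run_simulation(small_config(horizon=10))
        with pytest.raises(ValidationError, match="horizon"):
            res.summarize_df_effect(at_time=11)

    def test_trajectory_table_shape(self):
        res = run_simulation(small_config(horizon=5, n_replicates=3))
        df = res.trajectories()
        assert len(df) == len(res.cells) * 6 * 3
        assert set(df.columns) == {
            "replicate", "t", "ideology", "freq_class", "prevalence"
        }

    def test_df_gap_direction_matches_drift_oracle(self):
        """Liberal frequent-vs-infrequent gap has the sign the drift law
        implies (positive for A>0: faster contact, faster drift)."""
        res = run_simulation(small_config(advantage=0.3, horizon=80, seed=50,
                                          n_replicates=100))
        eff = res.summarize_df_effect(at_time=80)
        oracle_sign = np.sign(
            liberal_drift_oracle(0.1, 0.3, 0.5, 0.05)
            - liberal_drift_oracle(0.1, 0.3, 0.5, 0.01)
        )
        assert np.sign(eff["liberal"].gap) == oracle_sign
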