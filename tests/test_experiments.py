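"""Sweep engine, threshold finders and the model-comparison operation."""

import numpy as np
import pytest

import usospa as u


class TestSweepSpec:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            u.SweepSpec(preset="baseline_sec3", quantity="a",
                        grid=(1.0, 1.0, 2.0))

    def test_grid_must_be_nonempty(self):
        with pytest.raises(ValueError, match="non-empty"):
            u.SweepSpec(preset="baseline_sec3", quantity="a", grid=())

    def test_unknown_quantity(self):
        with pytest.raises(ValueError, match="initial_P"):
            u.SweepSpec(preset="baseline_sec3", quantity="bogus",
                        grid=(0.1, 0.2))


class TestRunSweep:
    def test_single_point_equals_direct_run(self, baseline):
        spec = u.SweepSpec(preset="baseline_sec3", quantity="alpha_p",
                           grid=(0.04,), t_end=50.0)
        result = u.run_sweep(spec)
        direct = u.integrate(baseline.params, baseline.initial, t_end=50.0)
        assert len(result.records) == 1
        assert np.array_equal(result.trajectories[0].states, direct.states)
        t_pk, v_pk = u.peak(direct, "P")
        assert result.records[0]["peak_value"] == v_pk
        assert result.records[0]["peak_t"] == t_pk

    def test_records_ordered_as_grid(self, uniform):
        spec = u.SweepSpec(preset="uniform_sec4", quantity="alpha_p",
                           grid=(0.04, 0.08, 0.16), t_end=50.0)
        result = u.run_sweep(spec)
        assert result.values("value") == [0.04, 0.08, 0.16]

    def test_initial_condition_sweep_rebalances_susceptibles(self):
        spec = u.SweepSpec(preset="baseline_sec3", quantity="initial_P",
                           grid=(0.1, 0.3), t_end=1.0)
        result = u.run_sweep(spec)
        for rec, traj in zip(result.records, result.trajectories):
            s0 = traj.states[0]
            assert s0.sum() == pytest.approx(1.0, abs=1e-12)
            assert s0[1] == 0.1 and s0[3] == 0.05  # O0, U0 kept at preset

    def test_infeasible_rebalance_lists_offenders(self):
        spec = u.SweepSpec(preset="baseline_sec3", quantity="initial_P",
                           grid=(0.5, 0.9), t_end=1.0)
        with pytest.raises(u.StateError, match=r"0\.9"):
            u.run_sweep(spec)

    def test_sweep_frame_long_format(self):
        spec = u.SweepSpec(preset="uniform_sec4", quantity="a",
                           grid=(0.0, 50.0), t_end=20.0)
        frame = u.run_sweep(spec).to_frame()
        assert list(frame["value"]) == [0.0, 50.0]
        assert {"peak_value", "equilibrium_time", "shape"} <= set(frame.columns)


class TestCriticalInitialP:
    def test_no_inflow_means_no_threshold(self, baseline):
        params = baseline.params.replace(alpha_p=0.0, beta_p=0.0, m_o=0.0)
        with pytest.raises(u.NoThresholdError):
            u.critical_initial_p(params, t_end=50.0)

    def test_bracket_certifies_shape_flip(self, baseline):
        est = u.critical_initial_p(baseline.params, resolution=0.02)
        lo, hi = est.bracket
        assert lo <= est.estimate <= hi
        assert hi - lo <= 0.02

        def shape_at(p0):
            initial = u.PopulationState(S=1 - p0 - 0.15, O=0.1, P=p0, U=0.05)
            traj = u.integrate(baseline.params, initial)
            return u.classify_shape(traj, "P").label

        assert shape_at(lo) is u.ShapeLabel.INCREASE_THEN_DECREASE
        assert shape_at(hi) is u.ShapeLabel.MONOTONE_DECREASE

    def test_rule_recorded(self, baseline):
        est = u.critical_initial_p(baseline.params, resolution=0.05)
        assert "bisection" in est.rule and "O0=0.1" in est.rule

    def test_invalid_arguments(self, baseline):
        with pytest.raises(ValueError):
            u.critical_initial_p(baseline.params, o0=0.9, u0=0.2)
        with pytest.raises(ValueError):
            u.critical_initial_p(baseline.params, resolution=0.0)


class TestRiskSaturation:
    def test_flat_response_is_inapplicable(self, baseline):
        # k=1 keeps the pessimist curve monotone-decreasing from a uniform
        # start, so the peak equals P(0) for every a: no rising slope.
        uniform = u.preset("uniform_sec4")
        with pytest.raises(u.RuleInapplicableError):
            u.risk_saturation_point(uniform.params, uniform.initial,
                                    a_grid=(0.0, 10.0), t_end=50.0)

    def test_grid_validation(self, uniform):
        with pytest.raises(ValueError, match="start at 0"):
            u.risk_saturation_point(uniform.params, uniform.initial,
                                    a_grid=(10.0, 20.0))
        with pytest.raises(ValueError, match="slope_fraction"):
            u.risk_saturation_point(uniform.params, uniform.initial,
                                    slope_fraction=1.5)

    def test_detects_flattening_in_rising_regime(self, uniform):
        # contact coefficient high enough that raising the risk coefficient
        # damps pessimist outflow and lifts the peak: the rule applies
        params = uniform.params.replace(k=4.0)
        est = u.risk_saturation_point(params, uniform.initial,
                                      a_grid=tuple(range(0, 101, 10)),
                                      t_end=100.0)
        assert est.quantity == "a"
        assert est.estimate in range(10, 101, 10)
        assert est.bracket[1] == est.estimate

    def test_magnitude_variant_handles_decreasing_response(self, uniform):
        # at k=5 the peak falls with the risk coefficient; the magnitude
        # rule still localises where the response flattens
        params = uniform.params.replace(k=5.0)
        with pytest.raises(u.RuleInapplicableError):
            u.risk_saturation_point(params, uniform.initial, t_end=100.0)
        est = u.risk_saturation_point(params, uniform.initial, t_end=100.0,
                                      magnitude=True)
        assert est.estimate in range(10, 101, 10)


class TestComparison:
    def test_reduced_keeps_stable_empty_and_totals_match(self, baseline):
        cmp = u.compare_with_without_u(baseline.params, baseline.initial,
                                       t_end=100.0)
        assert cmp.reduced["final"]["U"] == 0.0
        for side in (cmp.full, cmp.reduced):
            assert sum(side["final"].values()) == pytest.approx(1.0, abs=1e-8)

    def test_full_model_settles_later(self, baseline):
        """Absorption into the stable group drags out the transient, so the
        full model's settling time exceeds the reduction's."""
        cmp = u.compare_with_without_u(baseline.params, baseline.initial,
                                       t_end=1500.0)
        assert cmp.full["equilibrium_time"] is not None
        assert cmp.reduced["equilibrium_time"] is not None
        assert cmp.full["equilibrium_time"] > cmp.reduced["equilibrium_time"]


class TestFigureRecipes:
    def test_unknown_figure(self):
        with pytest.raises(KeyError, match="fig99"):
            u.reproduce_figure("fig99")

    def test_baseline_figure_is_single_trajectory(self):
        traj = u.reproduce_figure("fig4", t_end=20.0)
        assert isinstance(traj, u.Trajectory)
        assert traj.states[0] == pytest.approx((0.7, 0.1, 0.15, 0.05))

    def test_initial_p_figure_spans_published_range(self):
        result = u.reproduce_figure("fig7", t_end=10.0)
        grid = result.spec.grid
        assert grid[0] == 0.01 and grid[-1] == 0.8

    def test_risk_figure_spans_published_range(self):
        result = u.reproduce_figure("fig17", t_end=10.0)
        assert result.spec.grid == tuple(float(v) for v in range(0, 101, 10))

    def test_two_panel_recipe_returns_one_sweep_per_rate(self):
        results = u.reproduce_figure("fig9", t_end=10.0)
        assert [r.spec.quantity for r in results] == ["alpha_o", "alpha_p"]
        # geometric grid centred on the published rate
        assert results[1].spec.grid == (0.02, 0.04, 0.08)
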