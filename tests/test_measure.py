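"""Trace arc lengths, interval rates, deceleration fits, rate aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cablescale as cs


class TestPolylineLength:
    def test_three_four_five(self):
        assert cs.polyline_length([(0, 0), (3, 4)]) == pytest.approx(5.0)

    def test_unit_steps(self):
        assert cs.polyline_length([(0, 0), (1, 0), (1, 1), (2, 1)]) == pytest.approx(3.0)

    def test_duplicate_points_add_nothing(self):
        base = [(0, 0), (1, 0), (2, 0)]
        dup = [(0, 0), (1, 0), (1, 0), (2, 0)]
        assert cs.polyline_length(dup) == pytest.approx(cs.polyline_length(base))

    def test_3d_supported(self):
        assert cs.polyline_length([(0, 0, 0), (1, 2, 2)]) == pytest.approx(3.0)

    def test_single_point_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.polyline_length([(0, 0)])

    @settings(derandomize=True, max_examples=30)
    @given(
        angle=st.floats(0.0, 2 * np.pi),
        dx=st.floats(-10.0, 10.0),
        dy=st.floats(-10.0, 10.0),
    )
    def test_rigid_motion_invariance(self, angle, dx, dy):
        pts = np.array([[0.0, 0.0], [1.2, 0.3], [2.1, 1.7], [2.5, 3.0]])
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pts @ R.T + [dx, dy]
        assert cs.polyline_length(moved) == pytest.approx(
            cs.polyline_length(pts), abs=1e-9
        )


class TestIntervalRates:
    def test_first_interval_rate(self, wt_cell):
        traj = cs.Trajectory("c", [0.0, 3.0], [0.0, 1.08], wt_cell)
        rs = cs.interval_rates(traj)
        assert rs.mean_rate_um_per_s[0] == pytest.approx(0.36)
        assert rs.axis_values[0] == 0.0

    def test_constant_lengths_zero_rates(self, wt_cell):
        traj = cs.Trajectory("c", [0, 3, 6, 9], [2.0, 2.0, 2.0, 2.0], wt_cell)
        assert np.all(cs.interval_rates(traj).mean_rate_um_per_s == 0.0)

    def test_noise_free_rates_decrease_monotonically(self, wt_params, wt_cell, quiet_obs):
        traj = cs.simulate_observed_trajectory(wt_params, wt_cell, quiet_obs)
        rates = cs.interval_rates(traj).mean_rate_um_per_s
        assert np.all(np.diff(rates) < 0)

    def test_rates_bracketed_by_instantaneous_rate(self, wt_params, wt_cell, quiet_obs):
        """Interval rates sit between the instantaneous rates at the interval
        endpoints (the rate decays monotonically)."""
        traj = cs.simulate_observed_trajectory(wt_params, wt_cell, quiet_obs)
        rs = cs.interval_rates(traj)
        start = cs.closed_form_rate(wt_params, wt_cell, traj.times_s[:-1])
        end = cs.closed_form_rate(wt_params, wt_cell, traj.times_s[1:])
        assert np.all(rs.mean_rate_um_per_s <= start + 1e-12)
        assert np.all(rs.mean_rate_um_per_s >= end - 1e-12)

    def test_single_frame_rejected(self, wt_cell):
        with pytest.raises(cs.ValidationError):
            cs.interval_rates(cs.Trajectory("c", [0.0], [0.0], wt_cell))


class TestInitialDecelerationFit:
    def test_exact_line_recovered_without_residual(self):
        t = np.array([0.0, 3.0, 6.0, 9.0])
        series = cs.RateSeries(
            "time_s", t, 0.36 - 0.02 * t, np.zeros(4), np.ones(4, dtype=int)
        )
        est = cs.fit_initial_deceleration(series, window_s=10.0)
        assert est.d0_um_per_s2 == pytest.approx(-0.02, abs=1e-15)
        assert est.ci95_halfwidth == pytest.approx(0.0, abs=1e-12)
        assert est.n_points == 4

    def test_regression_attenuates_d0_toward_zero(
        self, wt_params, wt_cell, quiet_obs
    ):
        """The 10 s regression of 3 s interval rates underestimates |d0|
        (exponential curvature plus interval averaging): same sign, smaller
        magnitude, never less than ~half of it."""
        traj = cs.simulate_observed_trajectory(wt_params, wt_cell, quiet_obs)
        est = cs.fit_initial_deceleration(cs.interval_rates(traj), window_s=10.0)
        d0 = cs.initial_deceleration(wt_params, wt_cell)
        assert 0.5 < est.d0_um_per_s2 / d0 < 1.0

    def test_fine_sampling_short_window_recovers_d0(self, wt_params, wt_cell):
        """As the window and frame interval shrink, the regression slope
        converges to the analytic initial deceleration."""
        obs = cs.ObservationModel(
            frame_interval_s=0.1, rate_noise_cv=0.0, tip_noise_sd_um=0.0, duration_s=30.0
        )
        traj = cs.simulate_observed_trajectory(wt_params, wt_cell, obs)
        est = cs.fit_initial_deceleration(cs.interval_rates(traj), window_s=0.5)
        assert est.d0_um_per_s2 == pytest.approx(
            cs.initial_deceleration(wt_params, wt_cell), rel=0.04
        )

    def test_matches_analytic_least_squares_oracle(self, wt_params, wt_cell, quiet_obs):
        """The fitted slope equals a hand-rolled LSQ on the same rate points."""
        traj = cs.simulate_observed_trajectory(wt_params, wt_cell, quiet_obs)
        rs = cs.interval_rates(traj)
        mask = rs.axis_values <= 10.0
        t, r = rs.axis_values[mask], rs.mean_rate_um_per_s[mask]
        slope = np.polyfit(t, r, 1)[0]
        est = cs.fit_initial_deceleration(rs, window_s=10.0)
        assert est.d0_um_per_s2 == pytest.approx(slope, rel=1e-12)

    @pytest.mark.parametrize(
        "frame_s, window_s, tol",
        [
            # standard acquisition settings: attenuation compresses the ratio below the
            # exact inverse-length value 8.2/4.3 but keeps it well above 1
            (3.0, 10.0, None),
            # window -> 0 limit recovers the exact inverse-length ratio 1.9
            (0.1, 0.5, 0.05),
        ],
    )
    def test_deceleration_ratio_across_cell_lengths(self, frame_s, window_s, tol):
        """Same feedback in 4.3 vs 8.2 µm cells: fitted |d0| ratio tracks the
        inverse cell-length ratio, exactly so for short windows."""
        p = cs.FeedbackParams.linear(0.36, x_star=1.0)
        slopes = {}
        for L in (4.3, 8.2):
            cell = cs.CellGeometry(L, L * 0.8, L * 0.8)
            obs = cs.ObservationModel(
                frame_interval_s=frame_s, rate_noise_cv=0.0, tip_noise_sd_um=0.0
            )
            traj = cs.simulate_observed_trajectory(p, cell, obs)
            est = cs.fit_initial_deceleration(cs.interval_rates(traj), window_s=window_s)
            slopes[L] = est.d0_um_per_s2
        ratio = slopes[4.3] / slopes[8.2]
        exact = 8.2 / 4.3
        if tol is None:
            assert 1.3 < ratio < exact
        else:
            assert ratio == pytest.approx(exact, abs=tol)

    def test_too_few_points_in_window(self, wt_cell):
        traj = cs.Trajectory("c", [0.0, 30.0, 60.0], [0.0, 2.0, 3.0], wt_cell)
        with pytest.raises(cs.EstimationError):
            cs.fit_initial_deceleration(cs.interval_rates(traj), window_s=10.0)


def _scaled_cohorts(f0=0.36, lengths=(4.3, 8.2), base_dt=3.0, base_T=120.0, n=5):
    """Noise-free populations sampled on a shared dimensionless time grid:
    the frame interval scales with cell length, so every cable sees the
    same sequence of normalized lengths."""
    p = cs.FeedbackParams.linear(f0, x_star=1.0)
    pops = {}
    for L in lengths:
        cell = cs.CellGeometry(L, L * 0.8, L * 0.8)
        scale = L / lengths[0]
        obs = cs.ObservationModel(
            frame_interval_s=base_dt * scale,
            rate_noise_cv=0.0,
            tip_noise_sd_um=0.0,
            duration_s=base_T * scale,
        )
        pops[L] = cs.simulate_cohort(p, [cell] * n, obs, seed=0)
    return pops


class TestAggregateRates:
    def test_single_trajectory_time_axis_equals_interval_rates(
        self, wt_params, wt_cell, quiet_obs
    ):
        traj = cs.simulate_observed_trajectory(wt_params, wt_cell, quiet_obs)
        agg = cs.aggregate_rates([traj], axis="time_s")
        rs = cs.interval_rates(traj)
        np.testing.assert_allclose(agg.axis_values, rs.axis_values)
        np.testing.assert_allclose(agg.mean_rate_um_per_s, rs.mean_rate_um_per_s)
        assert np.all(agg.n_per_point == 1)

    def test_normalized_length_curves_collapse_exactly(self):
        """Rate-vs-x curves from short and long cells coincide when sampled
        on the shared dimensionless grid; rate-vs-length curves do not."""
        pops = _scaled_cohorts()
        curves = {
            L: cs.aggregate_rates(pop, axis="normalized_length", bin_width=0.1)
            for L, pop in pops.items()
        }
        a, b = curves[4.3], curves[8.2]
        np.testing.assert_allclose(a.axis_values, b.axis_values, atol=1e-12)
        assert np.max(np.abs(a.mean_rate_um_per_s - b.mean_rate_um_per_s)) < 1e-9
        by_len = {
            L: cs.aggregate_rates(pop, axis="length_um", bin_width=0.5)
            for L, pop in pops.items()
        }
        assert by_len[4.3].axis_values.size != by_len[8.2].axis_values.size

    def test_fixed_frame_interval_near_collapse(self, quiet_obs):
        """With a fixed 3 s frame interval the collapse holds to the
        discretization accuracy of interval-averaged rates."""
        p = cs.FeedbackParams.linear(0.36, x_star=1.0)
        curves = {}
        for L in (4.3, 8.2):
            cell = cs.CellGeometry(L, L * 0.8, L * 0.8)
            traj = cs.simulate_observed_trajectory(p, cell, quiet_obs)
            curves[L] = cs.aggregate_rates([traj], axis="normalized_length", bin_width=0.25)
        a, b = curves[4.3], curves[8.2]
        shared = np.intersect1d(a.axis_values, b.axis_values)
        ra = a.mean_rate_um_per_s[np.isin(a.axis_values, shared)]
        rb = b.mean_rate_um_per_s[np.isin(b.axis_values, shared)]
        assert np.max(np.abs(ra - rb)) < 0.05

    def test_boundary_population_flat_then_drops(self, wt_cell, quiet_obs):
        p = cs.FeedbackParams.boundary(0.36, 1.0)
        trajs = cs.simulate_cohort(p, [wt_cell] * 10, quiet_obs, seed=0)
        agg = cs.aggregate_rates(trajs, axis="time_s")
        rates = agg.mean_rate_um_per_s
        # flat at f0 until the tip reaches the rear (t = 12.5 s), then zero
        assert np.all(rates[agg.axis_values < 12.0 - 3.0] == pytest.approx(0.36))
        assert np.all(rates[agg.axis_values > 15.0] == pytest.approx(0.0, abs=1e-12))

    def test_bin_width_required_for_length_axes(self, wt_params, wt_cell, quiet_obs):
        traj = cs.simulate_observed_trajectory(wt_params, wt_cell, quiet_obs)
        with pytest.raises(cs.ValidationError):
            cs.aggregate_rates([traj], axis="length_um")


class TestLengthRatioStats:
    def test_cables_matching_cells(self):
        out = cs.length_ratio_stats([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
        np.testing.assert_allclose(out["ratios"], 1.0)
        assert out["mean"] == 1.0
        assert out["ci95_halfwidth"] == 0.0

    def test_saturated_snapshot_mean_ratio_unity(self, wt_params):
        cells = [cs.CellGeometry(L, L * 0.8, L * 0.8) for L in (4.0, 4.5, 5.0, 5.5)] * 25
        df = cs.simulate_fixed_snapshot(wt_params, cells, 1e6, seed=3)
        out = cs.length_ratio_stats(
            df["cable_length_um"], df["cell_length_um"]
        )
        assert out["mean"] == pytest.approx(1.0, abs=0.01)

    def test_scale_invariant_strains_have_identical_ratio_distributions(self):
        """Short and long strains with the same x* produce the same ratio
        distribution (paired observation times)."""
        p = cs.FeedbackParams.linear(0.36, x_star=1.0)
        samples = {}
        for L in (4.3, 8.2):
            cells = [cs.CellGeometry(L, L * 0.8, L * 0.8)] * 200
            tau = L / 0.36
            df = cs.simulate_fixed_snapshot(p, cells, 3 * tau, seed=12)
            samples[L] = (df["cable_length_um"] / df["cell_length_um"]).to_numpy()
        from scipy.stats import ks_2samp

        d = ks_2samp(samples[4.3], samples[8.2]).statistic
        assert d < 0.05

    def test_zero_cell_length_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.length_ratio_stats([1.0], [0.0])
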