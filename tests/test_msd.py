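"""MSD computation, anomalous-diffusion fitting, and population statistics."""

import numpy as np
import pytest

from erclust import msd as msd_mod
from erclust import synth
from erclust.msd import DiffusionFit, MSDCurve
from erclust.synth import TrackSimConfig
from erclust.tracking import Trajectory

from conftest import brute_force_msd


def power_law_curve(D, alpha, dt=0.5, n_lags=20):
    lags = np.arange(1, n_lags + 1) * dt
    return MSDCurve(lags, 4 * D * lags**alpha, np.full(n_lags, 100, dtype=int))


class TestComputeMSD:
    def test_stationary_track_has_zero_msd(self):
        t = Trajectory(0, np.arange(10), np.zeros(10), np.zeros(10), 0.5)
        c = msd_mod.compute_msd(t)
        assert np.all(c.values == 0)

    def test_pure_drift_ballistic_closed_form(self):
        # v = 1 µm/s, dt = 0.5 s -> MSD(k dt) = (0.5 k)^2 exactly
        n = 40
        frames = np.arange(n)
        t = Trajectory(0, frames, frames * 0.5, np.zeros(n), 0.5)
        c = msd_mod.compute_msd(t, 0.25)
        k = np.arange(1, len(c.values) + 1)
        np.testing.assert_allclose(c.values, (0.5 * k) ** 2, rtol=1e-12)
        np.testing.assert_array_equal(c.n_pairs, n - k)

    def test_equals_brute_force_double_loop(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 50))
            x, y = rng.normal(0, 1, (2, n))
            t = Trajectory(0, np.arange(n), x, y, 0.5)
            c = msd_mod.compute_msd(t, 0.5)
            lags, values, pairs = brute_force_msd(x, y, 0.5, len(c.values))
            np.testing.assert_allclose(c.values, values, atol=1e-10)
            np.testing.assert_array_equal(c.n_pairs, pairs)
            np.testing.assert_allclose(c.lags, lags)

    def test_too_short_track_raises(self):
        t = Trajectory(0, [0, 1], [0.0, 1.0], [0.0, 0.0], 0.5)
        with pytest.raises(ValueError, match="short"):
            msd_mod.compute_msd(t)

    def test_gapped_track_rejected(self):
        t = Trajectory(0, [0, 1, 3, 4], np.arange(4.0), np.zeros(4), 0.5)
        with pytest.raises(ValueError, match="consecutive"):
            msd_mod.compute_msd(t)


class TestFitAnomalous:
    def test_exact_on_reported_parameter_values(self):
        # noiseless curve built from the reported population values
        fit = msd_mod.fit_anomalous(power_law_curve(0.0045, 0.74), n_points=20)
        assert fit.D == pytest.approx(0.0045, abs=1e-12)
        assert fit.alpha == pytest.approx(0.74, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_brownian_curve_gives_alpha_one(self):
        fit = msd_mod.fit_anomalous(power_law_curve(0.01, 1.0))
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("D", [1e-4, 1e-3, 1e-2, 1e-1])
    @pytest.mark.parametrize("alpha", [0.3, 0.74, 1.0, 1.5, 2.0])
    def test_exact_recovery_on_grid(self, D, alpha):
        fit = msd_mod.fit_anomalous(power_law_curve(D, alpha))
        assert fit.D == pytest.approx(D, abs=1e-10, rel=1e-10)
        assert fit.alpha == pytest.approx(alpha, abs=1e-10)

    def test_nonpositive_msd_in_window_raises(self):
        curve = power_law_curve(0.01, 1.0)
        curve.values[5] = 0.0
        with pytest.raises(ValueError, match="log-fit undefined"):
            msd_mod.fit_anomalous(curve)

    def test_short_curve_raises(self):
        with pytest.raises(ValueError, match="fewer"):
            msd_mod.fit_anomalous(power_law_curve(0.01, 1.0, n_lags=10), n_points=20)

    def test_parameter_recovery_at_paper_scale(self, paper_scale_cfg):
        # 115 tracks x 300 frames, dt 0.5 s, truth D=0.0045, alpha=0.74
        tracks = synth.simulate_population(paper_scale_cfg, 115, seed=20)
        fits = [msd_mod.fit_anomalous(msd_mod.compute_msd(t)) for t in tracks]
        s = msd_mod.summarize_population(fits)
        assert abs(s.mean_alpha - 0.74) < 0.05
        assert abs(s.mean_D - 0.0045) / 0.0045 < 0.25

    def test_localization_noise_biases_alpha_down_monotonically(self):
        import dataclasses

        means = []
        for sd in (0.0, 0.02, 0.05):
            cfg = dataclasses.replace(
                TrackSimConfig(n_frames=150), loc_noise_sd=sd
            )
            tracks = synth.simulate_population(cfg, 80, seed=31)
            fits = [msd_mod.fit_anomalous(msd_mod.compute_msd(t)) for t in tracks]
            means.append(np.mean([f.alpha for f in fits]))
        assert means[0] > means[1] > means[2]

    def test_fitted_D_invariant_to_pixel_representation(self, tmp_path):
        from erclust import tracking

        cfg = TrackSimConfig(n_frames=100, seed=4)
        t = synth.simulate_track(cfg)
        fit_um = msd_mod.fit_anomalous(msd_mod.compute_msd(t))
        # re-express in pixels at 0.1 µm/px, reread with the conversion
        px = tmp_path / "px.csv"
        rows = ["track_id,frame,x,y"] + [
            f"0,{f},{x / 0.1:.9f},{y / 0.1:.9f}" for f, x, y in zip(t.frames, t.x, t.y)
        ]
        px.write_text("\n".join(rows) + "\n")
        (t2,) = tracking.read_track_table(px, pixel_size=0.1, frame_interval=0.5)
        fit_px = msd_mod.fit_anomalous(msd_mod.compute_msd(t2))
        assert fit_px.D == pytest.approx(fit_um.D, rel=1e-5)
        assert fit_px.alpha == pytest.approx(fit_um.alpha, abs=1e-5)

    def test_drift_flagged_superdiffusive(self):
        cfg = TrackSimConfig(D=0.0, drift_velocity=(0.2, 0.0), n_frames=100)
        t = synth.simulate_track(cfg)
        fit = msd_mod.fit_anomalous(msd_mod.compute_msd(t))
        assert fit.superdiffusive
        assert fit.alpha == pytest.approx(2.0, abs=1e-9)


class TestSummarizePopulation:
    def test_identical_fits_have_zero_sem(self):
        fits = [DiffusionFit(0.004, 0.7, 20, 0.99, track_id=i) for i in range(5)]
        s = msd_mod.summarize_population(fits)
        assert s.sem_D == 0.0 and s.sem_alpha == 0.0
        assert s.n_tracks == 5

    def test_two_point_formula(self):
        fits = [
            DiffusionFit(0.004, 0.7, 20, 1.0),
            DiffusionFit(0.004, 0.8, 20, 1.0),
        ]
        s = msd_mod.summarize_population(fits)
        assert s.mean_alpha == pytest.approx(0.75)
        assert s.sem_alpha == pytest.approx(0.05)

    def test_matches_independent_recomputation(self, rng):
        fits = [
            DiffusionFit(float(d), float(a), 20, 1.0)
            for d, a in zip(rng.lognormal(-5.4, 0.5, 115), rng.normal(0.74, 0.07, 115))
        ]
        s = msd_mod.summarize_population(fits)
        D = np.array([f.D for f in fits])
        a = np.array([f.alpha for f in fits])
        assert s.mean_D == pytest.approx(D.mean())
        assert s.sem_D == pytest.approx(D.std(ddof=1) / np.sqrt(115))
        assert s.mean_alpha == pytest.approx(a.mean())
        assert s.sem_alpha == pytest.approx(a.std(ddof=1) / np.sqrt(115))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            msd_mod.summarize_population([])


class TestSizeMobilityRelation:
    def test_perfect_inverse_relation(self):
        d = np.linspace(0.5, 2.0, 20)
        fits = [DiffusionFit(float(0.004 / x), 0.7 + 0.001 * i, 20, 1.0)
                for i, x in enumerate(d)]
        out = msd_mod.size_mobility_relation(fits, d)
        assert out["D"][0] == pytest.approx(-1.0)

    def test_constant_alpha_is_degenerate(self):
        d = np.linspace(0.5, 2.0, 10)
        fits = [DiffusionFit(float(0.004 / x), 0.7, 20, 1.0) for x in d]
        with pytest.raises(ValueError, match="degenerate"):
            msd_mod.size_mobility_relation(fits, d)

    def test_noisy_inverse_relation_detected(self, rng):
        n = 100
        d = rng.uniform(0.4, 2.0, n)
        D = 0.004 / d * rng.lognormal(0, 0.3, n)
        fits = [DiffusionFit(float(x), float(0.74 + e), 20, 1.0)
                for x, e in zip(D, rng.normal(0, 0.05, n))]
        out = msd_mod.size_mobility_relation(fits, d)
        rho, p = out["D"]
        assert rho < 0 and p < 0.05

    def test_length_mismatch_raises(self):
        fits = [DiffusionFit(0.004, 0.7, 20, 1.0)] * 4
        with pytest.raises(ValueError):
            msd_mod.size_mobility_relation(fits, [1.0, 2.0])


class TestCompareConditions:
    def _fits(self, D_values, alpha_values, condition):
        return [
            DiffusionFit(float(d), float(a), 20, 1.0, track_id=i, condition=condition)
            for i, (d, a) in enumerate(zip(D_values, alpha_values))
        ]

    def test_halved_D_flagged_alpha_not(self, rng):
        # group b has D halved, same alpha and sizes: the treated-arm pattern
        n = 50
        alpha_a, alpha_b = rng.normal(0.74, 0.07, (2, n))
        D_a = rng.lognormal(np.log(0.0045), 0.4, n)
        D_b = rng.lognormal(np.log(0.00225), 0.4, n)
        cmp = msd_mod.compare_conditions(
            self._fits(D_a, alpha_a, "untreated"), self._fits(D_b, alpha_b, "nocodazole")
        )
        assert cmp.tests["D"]["p_value"] < 0.01
        assert cmp.tests["alpha"]["p_value"] > 0.05
        assert 0.4 < cmp.tests["D"]["ratio_of_means"] < 0.6

    def test_identical_groups_ratios_one(self):
        vals_D = np.linspace(0.003, 0.006, 10)
        vals_a = np.linspace(0.6, 0.9, 10)
        a = self._fits(vals_D, vals_a, "a")
        b = self._fits(vals_D, vals_a, "b")
        cmp = msd_mod.compare_conditions(a, b, np.ones(10) * 1.2, np.ones(10) * 1.2)
        for name in ("D", "alpha", "diameter"):
            assert cmp.tests[name]["ratio_of_means"] == pytest.approx(1.0)
        assert cmp.tests["D"]["p_value"] == pytest.approx(1.0, abs=0.05)

    def test_type_i_error_rate_near_nominal(self):
        # identical sampled groups: p(D) < 0.05 should fire at ~5%
        n_reps, hits = 200, 0
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            D_a = rng.lognormal(-5.4, 0.5, 30)
            D_b = rng.lognormal(-5.4, 0.5, 30)
            a = self._fits(D_a, rng.normal(0.74, 0.05, 30), "a")
            b = self._fits(D_b, rng.normal(0.74, 0.05, 30), "b")
            cmp = msd_mod.compare_conditions(a, b)
            if cmp.tests["D"]["p_value"] < 0.05:
                hits += 1
        from scipy import stats

        lo, hi = stats.binom.interval(0.999, n_reps, 0.05)
        assert lo <= hits <= hi

    def test_group_of_two_raises(self):
        a = self._fits([0.004, 0.005], [0.7, 0.8], "a")
        b = self._fits([0.004, 0.005, 0.006], [0.7, 0.8, 0.9], "b")
        with pytest.raises(ValueError, match="at least 3"):
            msd_mod.compare_conditions(a, b)

    def test_welch_option(self, rng):
        a = self._fits(rng.normal(0.004, 0.0005, 20), rng.normal(0.7, 0.05, 20), "a")
        b = self._fits(rng.normal(0.002, 0.0005, 20), rng.normal(0.7, 0.05, 20), "b")
        cmp = msd_mod.compare_conditions(a, b, method="welch")
        assert cmp.tests["D"]["p_value"] < 0.01


def test_plot_msd_curves_writes_file(tmp_path, paper_scale_cfg):
    tracks = synth.simulate_population(paper_scale_cfg, 5, seed=2)
    curves = [msd_mod.compute_msd(t) for t in tracks]
    out = tmp_path / "msd.png"
    msd_mod.plot_msd_curves(curves, out)
    assert out.stat().st_size > 0
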