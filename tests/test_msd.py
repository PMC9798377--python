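"""MSD computation, the four model fits, and the nonsegmented analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trajmodes as tm
from trajmodes.msd import (
    fit_active_batch,
    fit_anomalous_batch,
    fit_confined_batch,
    fit_normal_batch,
)


class TestTimeAveragedMSD:
    def test_stationary_is_zero(self, stationary_trajectory):
        curve = tm.time_averaged_msd(stationary_trajectory)
        np.testing.assert_array_equal(curve.values, 0.0)

    def test_hand_summed_square_walk(self, square_walk):
        # displacements: lag1 -> 1,1,1; lag2 -> 2,2; lag3 -> 5
        curve = tm.time_averaged_msd(square_walk)
        np.testing.assert_allclose(curve.values, [1.0, 2.0, 5.0])
        np.testing.assert_array_equal(curve.counts, [3, 2, 1])

    def test_matches_brute_force_on_random_trajectories(self, msd_oracle):
        rng = np.random.default_rng(42)
        for i in range(20):
            n = int(rng.integers(4, 15))
            frames = np.sort(rng.choice(np.arange(2 * n), size=n, replace=False))
            traj = tm.Trajectory(
                f"r{i}", frames, rng.normal(size=n), rng.normal(size=n), 0.1
            )
            curve = tm.time_averaged_msd(traj)
            taus, values, counts = msd_oracle(traj)
            np.testing.assert_allclose(curve.taus, taus, rtol=1e-12)
            np.testing.assert_allclose(curve.values, values, rtol=1e-12)
            np.testing.assert_array_equal(curve.counts, counts)

    def test_brownian_msd_near_4Dtau(self, brownian_sims):
        curves = [tm.time_averaged_msd(s.trajectory) for s in brownian_sims]
        ens = tm.ensemble_msd(curves)
        sel = ens.lags <= 10
        np.testing.assert_allclose(
            ens.values[sel] / ens.taus[sel], 4 * 3.0, rtol=0.05
        )

    def test_invariant_under_rotation_and_translation(self):
        rng = np.random.default_rng(3)
        xy = rng.normal(size=(30, 2))
        theta = 0.73
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = xy @ R.T + np.array([5.0, -2.0])
        t1 = tm.Trajectory("a", np.arange(30), xy[:, 0], xy[:, 1], 0.1)
        t2 = tm.Trajectory("b", np.arange(30), moved[:, 0], moved[:, 1], 0.1)
        np.testing.assert_allclose(
            tm.time_averaged_msd(t1).values,
            tm.time_averaged_msd(t2).values,
            rtol=1e-9,
        )

    def test_max_lag_fraction_truncates(self, square_walk):
        curve = tm.time_averaged_msd(square_walk, max_lag_fraction=0.5)
        assert len(curve) == 1


class TestEnsembleMSD:
    def test_single_curve_identity(self, square_walk):
        c = tm.time_averaged_msd(square_walk)
        e = tm.ensemble_msd([c])
        np.testing.assert_allclose(e.values, c.values)

    def test_arithmetic_mean_of_two(self):
        a = tm.MSDCurve(np.array([1.0]), np.array([2.0]), np.array([1]), 1.0)
        b = tm.MSDCurve(np.array([1.0]), np.array([4.0]), np.array([1]), 1.0)
        assert tm.ensemble_msd([a, b]).values[0] == pytest.approx(3.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tm.ensemble_msd([])

    def test_equal_length_curves_match_pooled_average(self, brownian_sims):
        # with equal trajectory lengths the curve mean equals the pooled
        # average over all displacement pairs, exactly
        curves = [tm.time_averaged_msd(s.trajectory) for s in brownian_sims[:10]]
        ens = tm.ensemble_msd(curves)
        pooled = np.mean([c.values for c in curves], axis=0)
        np.testing.assert_allclose(ens.values, pooled, rtol=1e-12)


class TestFitMSD:
    def test_exact_linear_curve(self):
        c = tm.MSDCurve(np.array([1.0, 2, 3]), np.array([4.0, 8, 12]),
                        np.array([3, 2, 1]), 1.0)
        f = tm.fit_msd(c, "normal", (1, 3))
        assert f.D == pytest.approx(1.0, abs=1e-12)
        assert f.fit_error == pytest.approx(0.0, abs=1e-12)

    def test_exact_active_curve(self):
        tau = np.arange(1, 8) * 0.5
        c = tm.MSDCurve(tau, 4 * 1.0 * tau + (0.5 * tau) ** 2,
                        np.ones(7, int), 0.5)
        f = tm.fit_msd(c, "active", (1, 7))
        assert f.D == pytest.approx(1.0, rel=1e-8)
        assert f.v == pytest.approx(0.5, rel=1e-8)

    def test_exact_power_law_curve(self):
        tau = np.arange(1, 11) * 0.2
        c = tm.MSDCurve(tau, 4 * 0.5 * tau**0.6, np.ones(10, int), 0.2)
        f = tm.fit_msd(c, "anomalous", (1, 10))
        assert f.D == pytest.approx(0.5, rel=1e-8)
        assert f.alpha == pytest.approx(0.6, rel=1e-8)

    def test_exact_confined_curve(self):
        tau = np.arange(1, 21) * 0.1
        rc, A1, D = 0.5, 0.9, 0.05
        vals = rc**2 * (1 - A1 * np.exp(-4 * D * tau / rc**2))
        c = tm.MSDCurve(tau, vals, np.ones(20, int), 0.1)
        f = tm.fit_msd(c, "confined", (1, 20))
        assert f.r_c == pytest.approx(rc, rel=1e-4)
        assert f.A1 == pytest.approx(A1, rel=1e-3)

    def test_stationary_curve_degenerates_cleanly(self, stationary_trajectory):
        c = tm.time_averaged_msd(stationary_trajectory)
        for model in ("normal", "active", "anomalous", "confined"):
            f = tm.fit_msd(c, model, (1, 9))
            assert f.D == 0.0
            assert f.fit_error == 0.0

    def test_too_few_lags_rejected(self):
        c = tm.MSDCurve(np.array([1.0, 2]), np.array([4.0, 8]),
                        np.array([2, 1]), 1.0)
        with pytest.raises(ValueError, match="lags"):
            tm.fit_msd(c, "normal", (1, 2))

    def test_deterministic(self, brownian_sims):
        c = tm.time_averaged_msd(brownian_sims[0].trajectory)
        fits = [tm.fit_msd(c, "confined", (1, 30)) for _ in range(2)]
        assert fits[0] == fits[1]

    @pytest.mark.parametrize("model", ["normal", "active", "anomalous"])
    def test_batch_fitters_match_scalar_path(self, brownian_sims, model):
        batch_fn = {
            "normal": fit_normal_batch,
            "active": fit_active_batch,
            "anomalous": fit_anomalous_batch,
        }[model]
        curves = [tm.time_averaged_msd(s.trajectory) for s in brownian_sims[:5]]
        k = 20
        tau = curves[0].taus[:k]
        M = np.vstack([c.values[:k] for c in curves])
        out = batch_fn(tau, M)
        for i, c in enumerate(curves):
            f = tm.fit_msd(c, model, (1, k))
            assert out["D"][i] == pytest.approx(f.D, rel=1e-6, abs=1e-12)
            if model == "anomalous":
                assert out["alpha"][i] == pytest.approx(f.alpha, rel=1e-6)


class TestParameterRecovery:
    """Median parameter recovery per mode on 1000-step simulations.

    D and α are estimated over the first 10 lags where the diffusive signal
    dominates; v and r_c over the default quarter-range where the ballistic
    and plateau signatures live.
    """

    N_REPS = 100

    def test_normal_D_within_10pct(self):
        errs = []
        for seed in range(self.N_REPS):
            cfg = tm.SimulationConfig(
                mode="normal", D=3.0, n_steps=1000, dt=0.02, seed=500 + seed
            )
            c = tm.time_averaged_msd(tm.simulate_trajectory(cfg).trajectory)
            errs.append(abs(tm.fit_msd(c, "normal", (1, 10)).D - 3.0) / 3.0)
        assert np.median(errs) < 0.10

    def test_alpha_within_0p05_absolute(self):
        errs = []
        for seed in range(self.N_REPS):
            cfg = tm.SimulationConfig(
                mode="anomalous", D=0.5, alpha=0.6, n_steps=1000, dt=0.02,
                seed=600 + seed,
            )
            c = tm.time_averaged_msd(tm.simulate_trajectory(cfg).trajectory)
            errs.append(abs(tm.fit_msd(c, "anomalous", (1, 10)).alpha - 0.6))
        assert np.median(errs) < 0.05

    def test_active_v_within_10pct(self):
        errs = []
        for seed in range(self.N_REPS):
            cfg = tm.SimulationConfig(
                mode="active", D=0.001, v=0.1, n_steps=1000, dt=0.05,
                seed=700 + seed,
            )
            c = tm.time_averaged_msd(tm.simulate_trajectory(cfg).trajectory)
            f = tm.fit_msd(c, "active", tm.default_lag_range(1000))
            errs.append(abs(f.v - 0.1) / 0.1)
        assert np.median(errs) < 0.10

    def test_confined_rc_within_15pct(self):
        errs = []
        for seed in range(self.N_REPS):
            cfg = tm.SimulationConfig(
                mode="confined", D=0.1, r_c=0.5, n_steps=1000, dt=0.05,
                seed=800 + seed,
            )
            c = tm.time_averaged_msd(tm.simulate_trajectory(cfg).trajectory)
            f = tm.fit_msd(c, "confined", tm.default_lag_range(1000))
            errs.append(abs(f.r_c - 0.5) / 0.5)
        assert np.median(errs) < 0.15

    def test_localization_noise_depresses_alpha_monotonically(self):
        # static localization error inflates short-lag MSD, mimicking
        # subdiffusion; the fitted exponent must fall as noise grows
        def mean_alpha(sigma):
            out = []
            for seed in range(30):
                cfg = tm.SimulationConfig(
                    mode="normal", D=0.01, n_steps=500, dt=0.05,
                    sigma_loc=sigma, seed=900 + seed,
                )
                c = tm.time_averaged_msd(tm.simulate_trajectory(cfg).trajectory)
                out.append(tm.fit_msd(c, "anomalous", (1, 10)).alpha)
            return np.mean(out)

        alphas = [mean_alpha(s) for s in (0.0, 0.02, 0.05)]
        assert alphas[0] > alphas[1] > alphas[2]


class TestPerTrajectoryAnomaly:
    def test_superdiffusive_ensemble_mean_above_1p3(self):
        sims = [
            tm.simulate_trajectory(
                tm.SimulationConfig(
                    mode="active", D=0.001, v=0.1, n_steps=500, dt=0.05,
                    seed=40 + i,
                ),
                traj_id=f"a{i}",
            )
            for i in range(30)
        ]
        table = tm.per_trajectory_anomaly(tm.ensemble_from_ground_truth(sims))
        assert table["alpha"].mean() > 1.3

    def test_confined_ensemble_mean_below_0p7(self):
        sims = [
            tm.simulate_trajectory(
                tm.SimulationConfig(
                    mode="confined", D=0.1, r_c=0.2, n_steps=500, dt=0.05,
                    seed=60 + i,
                ),
                traj_id=f"c{i}",
            )
            for i in range(30)
        ]
        table = tm.per_trajectory_anomaly(tm.ensemble_from_ground_truth(sims))
        assert table["alpha"].mean() < 0.7


class TestRelativeDisplacement:
    def test_stationary_is_zero(self, stationary_trajectory):
        rd = tm.relative_displacement(stationary_trajectory)
        assert rd.scaled_dx == 0.0 and rd.scaled_dy == 0.0

    def test_linear_walk_scaling(self):
        # x spans 9 μm over 9 s -> 9/sqrt(9) = 3
        t = tm.Trajectory("w", np.arange(10), np.arange(10.0), np.zeros(10), 1.0)
        rd = tm.relative_displacement(t)
        assert rd.scaled_dx == pytest.approx(3.0)
        assert rd.scaled_dy == 0.0

    @given(dx=st.floats(-100, 100), dy=st.floats(-100, 100))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_translation_invariant(self, dx, dy):
        rng = np.random.default_rng(5)
        t = tm.Trajectory(
            "t", np.arange(20), rng.normal(size=20), rng.normal(size=20), 0.5
        )
        a = tm.relative_displacement(t)
        b = tm.relative_displacement(t.shifted(dx, dy))
        assert b.scaled_dx == pytest.approx(a.scaled_dx, rel=1e-9, abs=1e-9)
        assert b.scaled_dy == pytest.approx(a.scaled_dy, rel=1e-9, abs=1e-9)


class TestClassifyMobility:
    @staticmethod
    def _mixture_ensemble():
        fast = [
            tm.simulate_trajectory(
                tm.SimulationConfig(mode="normal", D=3.0, n_steps=200, dt=0.02,
                                    seed=i),
                traj_id=f"fast{i}",
            )
            for i in range(25)
        ]
        slow = [
            tm.simulate_trajectory(
                tm.SimulationConfig(mode="normal", D=0.001, n_steps=200, dt=0.02,
                                    seed=100 + i),
                traj_id=f"slow{i}",
            )
            for i in range(25)
        ]
        return tm.ensemble_from_ground_truth(fast + slow)

    def test_mixture_recovered_with_auto_threshold(self):
        split = tm.classify_mobility(self._mixture_ensemble())
        fast_ids = {t.id for t in split.fast}
        correct = sum(
            1
            for tid in fast_ids
            if tid.startswith("fast")
        ) + sum(
            1 for t in split.slow if t.id.startswith("slow")
        )
        assert correct >= 0.95 * 50

    def test_all_stationary_all_slow(self):
        trajs = [
            tm.Trajectory(f"s{i}", np.arange(5), np.zeros(5) + i, np.zeros(5), 1.0)
            for i in range(5)
        ]
        ens = tm.TrajectoryEnsemble(trajs, tm.AcquisitionMetadata(fps=1))
        split = tm.classify_mobility(ens, threshold=1.0)
        assert len(split.fast) == 0 and len(split.slow) == 5

    def test_infinite_threshold_all_slow(self):
        split = tm.classify_mobility(self._mixture_ensemble(), threshold=np.inf)
        assert len(split.fast) == 0

    def test_unimodal_auto_threshold_errors(self):
        sims = [
            tm.simulate_trajectory(
                tm.SimulationConfig(mode="normal", D=1.0, n_steps=200, dt=0.02,
                                    seed=i),
                traj_id=f"u{i}",
            )
            for i in range(40)
        ]
        with pytest.raises(ValueError, match="unimodal"):
            tm.classify_mobility(tm.ensemble_from_ground_truth(sims))


class TestDisplacementPDF:
    def test_brownian_sigma_and_kurtosis(self, brownian_ensemble):
        pdf = tm.displacement_pdf(brownian_ensemble, tau=0.02)
        assert pdf.gaussian_sigma**2 == pytest.approx(2 * 3.0 * 0.02, rel=0.10)
        assert abs(pdf.non_gaussianity) < 0.2
        # density integrates to ~1 over the binned support
        width = np.diff(pdf.bin_centers).mean()
        assert np.sum(pdf.density) * width == pytest.approx(1.0, abs=0.01)

    def test_mixture_is_heavy_tailed(self):
        sims = [
            tm.simulate_trajectory(
                tm.SimulationConfig(mode="normal", D=D, n_steps=300, dt=0.02,
                                    seed=i + int(D)),
                traj_id=f"m{D}{i}",
            )
            for D in (0.01, 3.0)
            for i in range(20)
        ]
        pdf = tm.displacement_pdf(tm.ensemble_from_ground_truth(sims), tau=0.02)
        assert pdf.non_gaussianity > 1.0

    def test_too_few_samples_reports_count(self):
        t = tm.Trajectory("t", np.arange(5), np.arange(5.0), np.zeros(5), 0.1)
        ens = tm.TrajectoryEnsemble([t], tm.AcquisitionMetadata(fps=10))
        with pytest.raises(ValueError, match="8"):
            tm.displacement_pdf(ens, tau=0.1)

    def test_degenerate_distribution_flagged(self, stationary_trajectory):
        ens = tm.TrajectoryEnsemble(
            [stationary_trajectory] + [
                tm.Trajectory(f"s{i}", np.arange(100), np.zeros(100),
                              np.zeros(100), 0.5)
                for i in range(20)
            ],
            tm.AcquisitionMetadata(fps=2),
        )
        with pytest.raises(ValueError, match="zero width"):
            tm.displacement_pdf(ens, tau=0.5)


class TestStokesEinstein:
    def test_fast_particle_viscosity_near_water(self):
        # 100 nm sphere diffusing at 3 μm²/s at room temperature sits in a
        # medium of ~1.4 mPa·s, close to water
        est = tm.stokes_einstein_viscosity(D=3.0, d=100.0, T=293.0)
        assert est.eta == pytest.approx(1.4, abs=0.05)

    def test_doubling_D_halves_eta(self):
        a = tm.stokes_einstein_viscosity(1.0, 100.0)
        b = tm.stokes_einstein_viscosity(2.0, 100.0)
        assert b.eta == pytest.approx(a.eta / 2, rel=1e-12)

    def test_eta_times_D_constant(self):
        prods = [
            tm.stokes_einstein_viscosity(D, 150.0, 300.0).eta * D
            for D in (0.01, 0.1, 1.0, 10.0)
        ]
        np.testing.assert_allclose(prods, prods[0], rtol=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            tm.stokes_einstein_viscosity(0.0, 100.0)
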