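"""Synthetic-data generator: input function, compartment solvers, forward
model, frame averaging, noise model, phantom, cohorts."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from refkin import synth
from refkin.tac import make_default_schedule


class TestFengAIF:
    def test_zero_before_delay(self):
        p = synth.AIFParams()
        t = np.linspace(0, p.tau * 0.999, 50)
        assert np.all(synth.feng_aif(t, p) == 0)

    def test_continuous_at_origin_without_delay(self):
        p = synth.AIFParams(tau=0.0)
        assert synth.feng_aif(np.array([0.0]), p)[0] == pytest.approx(0.0, abs=1e-12)

    def test_peak_shape_on_dense_grid(self):
        p = synth.AIFParams()
        t = np.arange(0, 90, 0.01)
        cp = synth.feng_aif(t, p)
        t_peak = t[np.argmax(cp)]
        assert p.tau < t_peak < 1.5  # sharp sub-1.5-min peak
        assert cp.max() > 10 * cp[-1]  # mostly cleared by scan end
        # continuity at the delay
        eps = 1e-6
        assert abs(synth.feng_aif(np.array([p.tau + eps]), p)[0]) < 1e-2


class TestCompartmentSolvers:
    def test_zero_input_zero_output(self, fine):
        t = fine["t"]
        c = synth.simulate_1t(np.zeros_like(t), synth.Tissue1TParams(0.9, 0.35), t)
        assert np.allclose(c, 0.0)

    def test_1t_steady_state(self):
        t = synth.fine_grid(600.0)  # long horizon to reach equilibrium
        cp = np.full_like(t, 10.0)
        c = synth.simulate_1t(cp, synth.Tissue1TParams(0.9, 0.35), t)
        assert c[-1] == pytest.approx(0.9 * 10.0 / 0.35, rel=1e-4)

    def test_1t_matches_ode_oracle(self, fine):
        t, cp = fine["t"], fine["cp"]
        p = synth.Tissue1TParams(0.9, 0.35)
        mine = synth.simulate_1t(cp, p, t)

        def rhs(tt, y):
            return [p.K1 * np.interp(tt, t, cp) - p.k2 * y[0]]

        sol = solve_ivp(rhs, (0, t[-1]), [0.0], t_eval=t, rtol=1e-8, atol=1e-10)
        assert np.max(np.abs(mine - sol.y[0])) / sol.y[0].max() < 1e-3

    def test_2t_reduces_to_1t_when_k3_zero(self, fine):
        t, cp = fine["t"], fine["cp"]
        c1 = synth.simulate_1t(cp, synth.Tissue1TParams(0.9, 0.35), t)
        c2 = synth.simulate_2t(cp, synth.Tissue2TParams(0.9, 0.35, 0.0, 0.02), t)
        np.testing.assert_allclose(c2, c1, atol=1e-10 * c1.max())

    def test_2t_steady_state(self):
        t = synth.fine_grid(3000.0)
        cp = np.full_like(t, 10.0)
        p = synth.Tissue2TParams(0.9, 0.35, 0.05, 0.02)
        c = synth.simulate_2t(cp, p, t)
        expect = (0.9 * 10.0 / 0.35) * (1.0 + 0.05 / 0.02)
        assert c[-1] == pytest.approx(expect, rel=1e-3)

    def test_2t_matches_ode_oracle(self, fine):
        t, cp = fine["t"], fine["cp"]
        p = synth.Tissue2TParams(0.9, 0.35, 0.07, 0.006)
        mine = synth.simulate_2t(cp, p, t)

        def rhs(tt, y):
            c = np.interp(tt, t, cp)
            return [
                p.K1 * c - (p.k2 + p.k3) * y[0] + p.k4 * y[1],
                p.k3 * y[0] - p.k4 * y[1],
            ]

        sol = solve_ivp(rhs, (0, t[-1]), [0, 0], t_eval=t, rtol=1e-8, atol=1e-10)
        tot = sol.y.sum(axis=0)
        assert np.max(np.abs(mine - tot)) / tot.max() < 1e-3


class TestSRTMForward:
    def test_identity_when_r1_one_bpnd_zero(self, fine):
        t, ref = fine["t"], fine["ref_curve"]
        truth = synth.SRTMTruth(r1=1.0, k2=0.4, bpnd=0.0)
        np.testing.assert_allclose(synth.srtm_forward(ref, truth, t), ref, atol=1e-9)

    def test_matches_dense_convolution_oracle(self, fine):
        # independent oracle: rectangle-rule convolution on a 0.01-min grid
        truth = synth.SRTMTruth(r1=1.0, k2=0.4, bpnd=1.5)
        dt = 0.01
        t = np.arange(0, 90 + dt, dt)
        cp = synth.feng_aif(t)
        ref = synth.simulate_1t(cp, synth.DEFAULT_REF_TISSUE, t)
        mine = synth.srtm_forward(ref, truth, t)
        kern = np.exp(-truth.k2a * t)
        conv = np.convolve(ref, kern)[: t.size] * dt
        oracle = truth.r1 * ref + (truth.k2 - truth.r1 * truth.k2a) * conv
        assert np.max(np.abs(mine - oracle)) / oracle.max() < 1e-3

    def test_linear_in_reference_scaling(self, fine, wt_truth):
        t, ref = fine["t"], fine["ref_curve"]
        a = synth.srtm_forward(ref, wt_truth, t)
        b = synth.srtm_forward(3.0 * ref, wt_truth, t)
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-12)


class TestFrameAverage:
    def test_constant_curve(self, schedule):
        t = synth.fine_grid(schedule.duration_min)
        tac = synth.frame_average(np.full_like(t, 4.2), t, schedule)
        assert np.allclose(tac.values, 4.2)

    def test_linear_curve_first_frame(self, schedule):
        t = synth.fine_grid(schedule.duration_min)
        tac = synth.frame_average(t * 60.0, t, schedule)  # curve = time in s
        assert tac.values[0] == pytest.approx(5.0)  # mean of [0,10) s

    def test_matches_quadrature_oracle(self, schedule):
        f = lambda tt: (tt + 5.0) ** 2 * np.exp(-tt / 20.0)
        t = synth.fine_grid(schedule.duration_min)
        tac = synth.frame_average(f(t), t, schedule)
        for j in [0, 5, 14, 20, 38]:
            lo, hi = schedule.start_s[j] / 60, schedule.end_s[j] / 60
            exact = quad(f, lo, hi)[0] / (hi - lo)
            assert tac.values[j] == pytest.approx(exact, rel=5e-4)

    def test_never_exceeds_frame_max(self, schedule):
        rng = np.random.default_rng(11)
        t = synth.fine_grid(schedule.duration_min)
        curve = np.interp(t, np.linspace(0, 90, 25), rng.uniform(0, 50, 25))
        tac = synth.frame_average(curve, t, schedule)
        for j in range(schedule.n_frames):
            seg = curve[(t >= schedule.start_s[j] / 60) & (t <= schedule.end_s[j] / 60)]
            assert tac.values[j] <= seg.max() + 1e-12

    def test_short_grid_rejected(self, schedule):
        t = synth.fine_grid(45.0)
        with pytest.raises(ValueError, match="grid"):
            synth.frame_average(np.zeros_like(t), t, schedule)


class TestNoiseModel:
    def test_alpha_zero_is_identity(self, noise_free_pair):
        tgt, _ = noise_free_pair
        out = synth.add_noise(tgt, synth.NoiseModel(alpha=0.0, seed=1))
        assert out is tgt

    def test_seed_determinism(self, noise_free_pair):
        tgt, _ = noise_free_pair
        a = synth.add_noise(tgt, synth.NoiseModel(alpha=0.3, seed=42))
        b = synth.add_noise(tgt, synth.NoiseModel(alpha=0.3, seed=42))
        np.testing.assert_array_equal(a.values, b.values)

    def test_empirical_sd_matches_formula(self, noise_free_pair):
        tgt, _ = noise_free_pair
        nm = synth.NoiseModel(alpha=0.5)
        sig = synth.noise_sigma(tgt, nm)
        frame = 20
        vals = [
            synth.add_noise(tgt, synth.NoiseModel(alpha=0.5, seed=i)).values[frame]
            for i in range(10_000)
        ]
        assert np.std(vals, ddof=1) == pytest.approx(sig[frame], rel=0.03)


class TestPhantom:
    def test_region_volumes_within_one_voxel(self, phantom):
        img, labels = phantom
        voxvol = img.voxel_volume_cm3
        vol_str = (labels.labels == 1).sum() * voxvol
        vol_cer = (labels.labels == 2).sum() * voxvol
        assert abs(vol_str - 0.0215) <= voxvol
        assert abs(vol_cer - 0.0507) <= voxvol

    def test_labels_disjoint_by_construction(self, phantom):
        _, labels = phantom
        assert set(np.unique(labels.labels)) == {0, 1, 2}

    def test_fill_then_extract_round_trip(self, filled_phantom, noise_free_pair):
        tgt, ref = noise_free_pair
        from refkin.tac import extract_regional_tac

        img, labels = filled_phantom
        np.testing.assert_allclose(
            extract_regional_tac(img, labels, "cerebellum").values, ref.values
        )

    def test_unattainable_volume_rejected(self, schedule):
        with pytest.raises(ValueError):
            synth.build_phantom((4, 4, 4), [0.776] * 3, {"striatum": 10.0}, schedule)


class TestCohort:
    def test_zero_sds_zero_noise_gives_identical_subjects(self):
        spec = synth.CohortSpec(
            groups={"WT": synth.GroupSpec(3, 11.54, 0.0, r1_sd=0.0)},
            sessions=2,
            retest_sd_frac=0.0,
            seed=5,
        )
        cohort = synth.simulate_cohort(spec, noise=synth.NoiseModel(alpha=0.0))
        base = cohort.scans[0].tacs["striatum"].values
        for scan in cohort.scans[1:]:
            np.testing.assert_array_equal(scan.tacs["striatum"].values, base)

    def test_sample_stats_match_spec_at_large_n(self):
        spec = synth.CohortSpec(
            groups={"WT": synth.GroupSpec(200, 11.54, 2.03)}, seed=2
        )
        cohort = synth.simulate_cohort(spec, noise=synth.NoiseModel(alpha=0.0))
        bp = cohort.truth["bpnd_true"].to_numpy()
        assert np.mean(bp) == pytest.approx(11.54, rel=0.05)
        assert np.std(bp, ddof=1) == pytest.approx(2.03, rel=0.05)

    def test_seed_reproducibility_and_subject_stability(self):
        spec = lambda n: synth.CohortSpec(
            groups={"WT": synth.GroupSpec(n, 11.54, 2.03)}, seed=3
        )
        small = synth.simulate_cohort(spec(3), noise=synth.NoiseModel(alpha=0.1))
        again = synth.simulate_cohort(spec(3), noise=synth.NoiseModel(alpha=0.1))
        big = synth.simulate_cohort(spec(5), noise=synth.NoiseModel(alpha=0.1))
        for a, b in zip(small.scans, again.scans):
            np.testing.assert_array_equal(
                a.tacs["striatum"].values, b.tacs["striatum"].values
            )
        # enlarging the cohort must not reshuffle existing subjects
        for a, b in zip(small.scans, big.scans[:3]):
            np.testing.assert_array_equal(
                a.tacs["striatum"].values, b.tacs["striatum"].values
            )

    def test_noise_free_curves_nonnegative(self):
        spec = synth.CohortSpec(
            groups={"HET": synth.GroupSpec(2, 7.09, 0.65)}, seed=1
        )
        cohort = synth.simulate_cohort(spec, noise=synth.NoiseModel(alpha=0.0))
        for scan in cohort.scans:
            for tac in scan.tacs.values():
                assert np.all(np.isfinite(tac.values))
                assert np.all(tac.values >= 0)
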