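"""Kinetic model fitters: identities, generator-fitter round trips,
cross-model equivalence, standard-error calibration, AIC, SUVR."""

import math

import numpy as np
import pytest

from refkin import models, synth


def _noisy_pair(pair, alpha, seed):
    tgt, ref = pair
    return (
        synth.add_noise(tgt, synth.NoiseModel(alpha=alpha, seed=seed)),
        synth.add_noise(ref, synth.NoiseModel(alpha=alpha, seed=seed + 100_000)),
    )


class TestSRTM:
    def test_identity_curves(self, noise_free_pair):
        _, ref = noise_free_pair
        f = models.fit_srtm(ref, ref)
        assert f.r1 == pytest.approx(1.0, abs=1e-6)
        assert f.bpnd == pytest.approx(0.0, abs=1e-4)

    def test_round_trip_recovery_low_bp(self, low_bp_pair):
        tgt, ref, truth = low_bp_pair
        f = models.fit_srtm(tgt, ref)
        assert f.r1 == pytest.approx(truth.r1, rel=5e-3)
        assert f.k2 == pytest.approx(truth.k2, rel=5e-3)
        assert f.bpnd == pytest.approx(truth.bpnd, rel=5e-3)

    def test_round_trip_recovery_high_bp(self, noise_free_pair, wt_truth):
        tgt, ref = noise_free_pair
        f = models.fit_srtm(tgt, ref)
        assert f.bpnd == pytest.approx(wt_truth.bpnd, rel=5e-3)
        assert f.r1 == pytest.approx(wt_truth.r1, rel=5e-3)

    def test_genotype_percent_difference_of_recovered_bpnd(self, schedule, fine):
        # WT-like vs HET-like truths; arithmetic on the recovered values
        t, ref_curve = fine["t"], fine["ref_curve"]
        ref = synth.frame_average(ref_curve, t, schedule)
        bps = {}
        for name, bp in [("wt", 11.54), ("het", 7.09)]:
            truth = synth.SRTMTruth(r1=1.0, k2=0.35, bpnd=bp)
            tgt = synth.frame_average(
                synth.srtm_forward(ref_curve, truth, t), t, schedule
            )
            bps[name] = models.fit_srtm(tgt, ref).bpnd
        diff = 100.0 * (bps["wt"] - bps["het"]) / bps["wt"]
        assert round(diff, 1) == 38.6

    def test_scale_invariance_of_bpnd(self, noise_free_pair):
        tgt, ref = noise_free_pair
        a = models.fit_srtm(tgt, ref)
        b = models.fit_srtm(tgt.scaled(7.3), ref.scaled(7.3))
        assert b.bpnd == pytest.approx(a.bpnd, rel=1e-9)

    def test_k2a_consistent_with_k2_and_bpnd(self, noise_free_pair):
        tgt, ref = noise_free_pair
        f = models.fit_srtm(tgt, ref)
        assert f.k2a == pytest.approx(f.k2 / (1.0 + f.bpnd), abs=1e-9)

    def test_zero_reference_rejected(self, noise_free_pair):
        tgt, ref = noise_free_pair
        with pytest.raises(ValueError, match="zero"):
            models.fit_srtm(tgt, ref.with_values(np.zeros_like(ref.values)))


class TestSRTM2:
    def test_identity_curves_with_true_k2_prime(self, noise_free_pair):
        _, ref = noise_free_pair
        f = models.fit_srtm2(ref, ref, k2_prime=0.35)
        assert f.r1 == pytest.approx(1.0, abs=1e-6)
        assert f.bpnd == pytest.approx(0.0, abs=1e-3)

    def test_round_trip_with_true_k2_prime(self, noise_free_pair, wt_truth):
        tgt, ref = noise_free_pair
        f = models.fit_srtm2(tgt, ref, k2_prime=wt_truth.k2 / wt_truth.r1)
        assert f.bpnd == pytest.approx(wt_truth.bpnd, rel=5e-3)

    def test_wrong_k2_prime_biases_bpnd(self, noise_free_pair, wt_truth):
        tgt, ref = noise_free_pair
        true_kp = wt_truth.k2 / wt_truth.r1
        good = models.fit_srtm2(tgt, ref, k2_prime=true_kp)
        bad = models.fit_srtm2(tgt, ref, k2_prime=1.2 * true_kp)
        # 20%-high k2' visibly biases BPND and degrades the fit
        assert abs(bad.bpnd - wt_truth.bpnd) > abs(good.bpnd - wt_truth.bpnd)
        assert bad.rss > 10 * max(good.rss, 1e-12)


class TestMRTM:
    def test_identity_curves_degenerate_flagged(self, noise_free_pair):
        _, ref = noise_free_pair
        f = models.fit_mrtm(ref, ref)
        assert f.bpnd == 0.0
        assert "degenerate-identical-tacs" in f.flags

    def test_agrees_with_srtm_on_consistent_data(self, noise_free_pair):
        tgt, ref = noise_free_pair
        s = models.fit_srtm(tgt, ref)
        m = models.fit_mrtm(tgt, ref)
        assert m.bpnd == pytest.approx(s.bpnd, rel=0.01)
        assert m.r1 == pytest.approx(s.r1, rel=0.01)

    def test_recovers_truth(self, noise_free_pair, wt_truth):
        tgt, ref = noise_free_pair
        m = models.fit_mrtm(tgt, ref)
        assert m.bpnd == pytest.approx(wt_truth.bpnd, rel=5e-3)
        assert m.k2 == pytest.approx(wt_truth.k2, rel=5e-3)
        assert m.k2_prime == pytest.approx(0.35, rel=5e-3)

    def test_k2_prime_se_calibrated_against_monte_carlo(self, noise_free_pair):
        k2ps, ses = [], []
        for i in range(50):
            tn, rn = _noisy_pair(noise_free_pair, alpha=0.05, seed=10_000 + i)
            f = models.fit_mrtm(tn, rn)
            k2ps.append(f.k2_prime)
            ses.append(f.se_pct["k2_prime"])
        empirical = 100.0 * np.std(k2ps, ddof=1) / np.mean(k2ps)
        assert np.mean(ses) == pytest.approx(empirical, rel=0.30)

    def test_k2_prime_se_decreases_with_noise(self, noise_free_pair):
        mean_se = []
        for alpha in (0.1, 0.05, 0.02):
            ses = [
                models.fit_mrtm(*_noisy_pair(noise_free_pair, alpha, 500 + i)).se_pct[
                    "k2_prime"
                ]
                for i in range(50)
            ]
            mean_se.append(np.mean(ses))
        assert mean_se[0] > mean_se[1] > mean_se[2]


class TestMRTM2:
    def test_identity_curves(self, noise_free_pair):
        _, ref = noise_free_pair
        f = models.fit_mrtm2(ref, ref, k2_prime=0.35)
        assert f.bpnd == pytest.approx(0.0, abs=1e-6)

    def test_matches_mrtm_with_its_own_k2_prime(self, noise_free_pair):
        tgt, ref = noise_free_pair
        m = models.fit_mrtm(tgt, ref)
        m2 = models.fit_mrtm2(tgt, ref, k2_prime=m.k2_prime)
        assert m2.bpnd == pytest.approx(m.bpnd, rel=0.01)

    def test_all_zero_target_rejected(self, noise_free_pair):
        tgt, ref = noise_free_pair
        with pytest.raises(ValueError):
            models.fit_mrtm2(tgt.with_values(np.zeros_like(tgt.values)), ref, 0.35)


class TestLogan:
    def test_identity_curves_unit_slope(self, noise_free_pair):
        _, ref = noise_free_pair
        f = models.fit_logan_ref(ref, ref, k2_prime=0.35)
        assert f.dvr == pytest.approx(1.0, rel=1e-6)
        assert f.bpnd == pytest.approx(0.0, abs=1e-6)

    def test_default_t_star_is_15_min(self, noise_free_pair):
        tgt, ref = noise_free_pair
        f = models.fit_logan_ref(tgt, ref, k2_prime=0.35)
        assert f.t_star == 15.0
        # frames with midpoint >= 15 min on the 39-frame schedule
        assert f.n_points_used == 15

    def test_round_trip_within_graphical_tolerance(self, low_bp_pair):
        tgt, ref, truth = low_bp_pair
        kp = models.fit_mrtm(tgt, ref).k2_prime
        f = models.fit_logan_ref(tgt, ref, k2_prime=kp)
        assert f.bpnd == pytest.approx(truth.bpnd, rel=0.02)
        assert f.bpnd == f.dvr - 1.0

    def test_nonpositive_frames_dropped_with_flag(self, noise_free_pair):
        tgt, ref = noise_free_pair
        v = tgt.values.copy()
        v[30] = -1.0
        f = models.fit_logan_ref(tgt.with_values(v), ref, k2_prime=0.35)
        assert any("nonpositive" in fl for fl in f.flags)
        assert f.n_points_used == 14


class TestAIC:
    def test_reference_value(self):
        assert models.aic(rss=39.0, n=39, k=3) == pytest.approx(6.0)

    def test_monotone_in_rss(self):
        a = [models.aic(r, 39, 3) for r in (8.0, 4.0, 2.0, 1.0)]
        assert all(x > y for x, y in zip(a, a[1:]))

    def test_zero_rss_sentinel(self):
        assert models.aic(0.0, 39, 3) == -math.inf

    def test_n_not_greater_than_k_rejected(self):
        with pytest.raises(ValueError):
            models.aic(1.0, 3, 3)

    def test_srtm_beats_misspecified_model_on_noisy_replicates(self, noise_free_pair):
        tgt, ref = noise_free_pair
        wins = 0
        for i in range(100):
            tn = synth.add_noise(tgt, synth.NoiseModel(alpha=0.02, seed=i))
            f = models.fit_srtm(tn, ref)
            # mis-specified 1-parameter alternative: scaled reference
            y, r = tn.values, ref.values
            th = float(y @ r) / float(r @ r)
            rss1 = float(((y - th * r) ** 2).sum())
            wins += f.aic < models.aic(rss1, y.size, 1)
        assert wins >= 95


class TestCrossModelConsistency:
    def test_all_models_agree_on_noise_free_data(self, low_bp_pair):
        tgt, ref, truth = low_bp_pair
        kp_true = truth.k2 / truth.r1
        estimates = {
            "srtm": models.fit_srtm(tgt, ref).bpnd,
            "srtm2": models.fit_srtm2(tgt, ref, kp_true).bpnd,
            "mrtm": models.fit_mrtm(tgt, ref).bpnd,
            "mrtm2": models.fit_mrtm2(tgt, ref, kp_true).bpnd,
            "logan": models.fit_logan_ref(tgt, ref, kp_true).bpnd,
        }
        for name, bp in estimates.items():
            assert bp == pytest.approx(truth.bpnd, rel=0.02), name
        values = list(estimates.values())
        assert max(values) - min(values) < 0.02 * truth.bpnd

    def test_dispatcher_sources_k2_prime_from_mrtm(self, noise_free_pair):
        tgt, ref = noise_free_pair
        kp = models.fit_mrtm(tgt, ref).k2_prime
        via_dispatch = models.fit_model("logan", tgt, ref)
        explicit = models.fit_logan_ref(tgt, ref, k2_prime=kp)
        assert via_dispatch.dvr == pytest.approx(explicit.dvr, rel=1e-12)


class TestSUVR:
    def test_identical_tacs_give_zero(self, noise_free_pair):
        _, ref = noise_free_pair
        assert models.suvr_minus_1(ref, ref, (40, 60)).suvr_minus_1 == 0.0

    def test_double_target_gives_one(self, noise_free_pair):
        _, ref = noise_free_pair
        res = models.suvr_minus_1(ref.scaled(2.0), ref, (70, 90))
        assert res.suvr_minus_1 == pytest.approx(1.0)

    @pytest.mark.parametrize("window", [(40, 60), (70, 90)])
    def test_standard_windows_computable(self, noise_free_pair, window):
        tgt, ref = noise_free_pair
        res = models.suvr_minus_1(tgt, ref, window)
        assert np.isfinite(res.suvr_minus_1)
        assert res.suvr_minus_1 > 0  # receptor-rich target exceeds reference

    def test_window_outside_scan_rejected(self, noise_free_pair):
        tgt, ref = noise_free_pair
        with pytest.raises(ValueError):
            models.suvr_minus_1(tgt, ref, (80, 100))
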