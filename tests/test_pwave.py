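"""P-wave pipeline: filtering, epoching, templating, delineation, features."""

import numpy as np
import pytest

from atrialep import pwave, synth
from atrialep.pwave import (EcgRecording, PwaveConfig, build_template,
                            delineate, detect_r_peaks, epoch_features,
                            extract_candidate_pwaves, global_features,
                            local_features, preprocess, sample_entropy,
                            segment_epochs)


def _rec(samples, fs=1000.0, leads=None):
    samples = np.atleast_2d(samples)
    leads = leads or [f"L{k}" for k in range(samples.shape[0])]
    return EcgRecording(samples=samples, fs=fs, lead_names=leads)


class TestPreprocess:
    def test_mains_interference_suppressed(self):
        t = np.arange(15000) / 1000.0
        x = np.sin(2 * np.pi * 50.0 * t)
        out = preprocess(_rec(x), PwaveConfig(notch_hz=50.0))
        core = out.samples[0, 1000:-1000]
        assert np.sqrt(np.mean(core ** 2)) < 0.03 * np.sqrt(0.5)

    def test_passband_sinusoid_preserved_within_1db(self):
        t = np.arange(15000) / 1000.0
        x = np.sin(2 * np.pi * 10.0 * t)
        out = preprocess(_rec(x))
        core = out.samples[0, 1000:-1000]
        gain = np.sqrt(np.mean(core ** 2)) / np.sqrt(0.5)
        assert 10 ** (-1 / 20) < gain < 10 ** (1 / 20)

    def test_zeros_in_zeros_out(self):
        out = preprocess(_rec(np.zeros(2000)))
        assert np.allclose(out.samples, 0.0)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess(_rec(np.zeros(2000), fs=150.0),
                       PwaveConfig(lp_cutoff_hz=100.0, notch_hz=None))


class TestEpoching:
    @pytest.mark.parametrize("dur_s,n_expected", [(30, 2), (44, 2), (300, 20)])
    def test_epoch_counts(self, dur_s, n_expected):
        rec = _rec(np.zeros(int(dur_s * 1000)))
        assert len(segment_epochs(rec)) == n_expected

    def test_short_recording_names_minimum(self):
        with pytest.raises(ValueError, match="15"):
            segment_epochs(_rec(np.zeros(10000)))


class TestRPeaks:
    def test_clean_ecg_peak_count_and_accuracy(self, clean_ecg):
        rec, truth = clean_ecg
        epoch = segment_epochs(preprocess(rec))[0]
        r = detect_r_peaks(epoch)
        true_in_epoch = truth.r_times_ms[truth.r_times_ms < 15000]
        assert len(r) == len(true_in_epoch) == 15
        assert np.max(np.abs(r - true_in_epoch)) <= 10.0

    def test_powerline_noise_does_not_change_count(self):
        spec = synth.EcgSynthSpec(duration_s=15.0, powerline_hz=50.0,
                                  powerline_amp_mv=0.3, noise_sd_mv=0.02,
                                  seed=2)
        rec, truth = synth.gen_ecg(spec)
        epoch = segment_epochs(preprocess(rec))[0]
        assert len(detect_r_peaks(epoch)) == len(truth.r_times_ms)

    def test_flat_line_returns_empty(self):
        assert len(detect_r_peaks(_rec(np.zeros(15000)))) == 0


class TestWindows:
    def test_window_placement_and_length(self):
        epoch = _rec(np.arange(15000.0))
        wins, kept = extract_candidate_pwaves(epoch, np.array([400.0]))
        assert wins.shape == (1, 1, 300)
        # window spans [R-350, R-50) ms -> samples 50..349
        assert wins[0, 0, 0] == 50.0 and wins[0, 0, -1] == 349.0

    def test_early_beat_dropped(self):
        epoch = _rec(np.zeros(15000))
        wins, kept = extract_candidate_pwaves(
            epoch, np.array([200.0, 400.0, 800.0]))
        assert len(kept) == 2 and 0 not in kept

    def test_full_epoch_yields_all_windows(self, clean_ecg):
        rec, truth = clean_ecg
        epoch = segment_epochs(rec)[0]
        r = truth.r_times_ms[truth.r_times_ms < 15000]
        wins, kept = extract_candidate_pwaves(epoch, r)
        assert wins.shape == (15, 12, 300)


class TestTemplate:
    def test_identical_windows_recovered_exactly(self, rng):
        w = rng.normal(size=(1, 300))
        wins = np.repeat(w[None, :, :], 10, axis=0)
        tpl = build_template(wins)
        assert np.allclose(tpl.data[0], w[0])
        assert tpl.n_beats_discarded[0] == 0

    def test_inverted_beat_discarded(self, rng):
        w = rng.normal(size=300)
        wins = np.stack([w.copy() for _ in range(9)] + [-w])[:, None, :]
        tpl = build_template(wins)
        assert tpl.n_beats_used[0] == 9
        assert tpl.n_beats_discarded[0] == 1

    def test_alignment_uses_best_lag(self, rng):
        base = np.exp(-0.5 * ((np.arange(300) - 150) / 12.0) ** 2)
        wins = []
        for shift in (0, 0, 5, -5, 10):
            wins.append(np.roll(base, shift))
        tpl = build_template(np.asarray(wins)[:, None, :],
                             PwaveConfig(corr_threshold=0.9))
        assert tpl.n_beats_used[0] == 5
        # aligned averaging must not smear the pulse: the template keeps the
        # full unit amplitude (unaligned averaging of these shifts loses >5%)
        assert np.nanmax(tpl.data[0]) == pytest.approx(1.0, abs=0.01)
        naive = np.mean(np.asarray(wins), axis=0)
        assert naive.max() < 0.95

    def test_averaging_reduces_noise_like_sqrt_n(self, rng):
        """Residual template noise shrinks ~1/sqrt(N) (Monte-Carlo)."""
        base = np.exp(-0.5 * ((np.arange(300) - 150) / 15.0) ** 2)
        sigma, n_rep, n_beats = 0.05, 60, 20
        resid_sd = []
        for _ in range(n_rep):
            wins = base + rng.normal(0, sigma, size=(n_beats, 300))
            tpl = build_template(wins[:, None, :],
                                 PwaveConfig(corr_threshold=0.5))
            resid_sd.append(np.std(tpl.data[0] - base))
        got = np.mean(resid_sd)
        assert got == pytest.approx(sigma / np.sqrt(n_beats), rel=0.3)

    def test_all_beats_unusable_raises(self):
        wins = np.zeros((3, 1, 300))
        with pytest.raises(Exception):
            build_template(wins)


class TestDelineation:
    def test_gaussian_duration_recovered(self):
        """5%-crossing delineation matches the generator's definition."""
        d = 120.0
        sigma = d / (2 * np.sqrt(2 * np.log(20)))
        t = np.arange(300.0)
        x = 0.1 * np.exp(-0.5 * ((t - 150) / sigma) ** 2)
        tpl = pwave.PwaveTemplate(data=x[None, :], fs=1000.0,
                                  lead_names=["II"])
        delin = delineate(tpl)
        got = delin.global_offset_ms - delin.global_onset_ms
        assert got == pytest.approx(d, rel=0.10)

    def test_identical_leads_share_global_extremes(self):
        x = np.zeros(300)
        x[100:200] = np.hanning(100)
        tpl = pwave.PwaveTemplate(data=np.tile(x, (3, 1)), fs=1000.0,
                                  lead_names=["I", "II", "III"])
        delin = delineate(tpl)
        assert delin.global_onset_ms == delin.onset_ms[0]
        assert delin.global_offset_ms == delin.offset_ms[0]

    def test_flat_lead_excluded_from_global(self):
        x = np.zeros(300)
        x[100:200] = np.hanning(100)
        tpl = pwave.PwaveTemplate(data=np.stack([x, np.zeros(300)]),
                                  fs=1000.0, lead_names=["II", "V9"])
        delin = delineate(tpl)
        assert np.isnan(delin.onset_ms[1])
        assert np.isfinite(delin.global_onset_ms)

    def test_flat_template_raises(self):
        tpl = pwave.PwaveTemplate(data=np.zeros((2, 300)), fs=1000.0,
                                  lead_names=["I", "II"])
        with pytest.raises(ValueError, match="flat"):
            delineate(tpl)


def _triangle(n_base, peak=0.1, start=100, n=300):
    x = np.zeros(n)
    half = n_base // 2
    up = np.linspace(0, peak, half, endpoint=False)
    down = np.linspace(peak, 0, n_base - half)
    x[start:start + n_base] = np.concatenate([up, down])
    return x


class TestGlobalFeatures:
    def test_monophasic_positive_v1_has_zero_ptfv1(self):
        x = _triangle(100)
        tpl = pwave.PwaveTemplate(data=x[None, :], fs=1000.0,
                                  lead_names=["V1"])
        g = global_features(tpl, delineate(tpl))
        assert g["ptfv1"] == 0.0

    def test_biphasic_v1_ptfv1_negative(self):
        t = np.arange(300.0)
        x = 0.08 * np.exp(-0.5 * ((t - 130) / 12) ** 2) \
            - 0.06 * np.exp(-0.5 * ((t - 180) / 12) ** 2)
        tpl = pwave.PwaveTemplate(data=x[None, :], fs=1000.0,
                                  lead_names=["V1"])
        g = global_features(tpl, delineate(tpl))
        assert g["ptfv1"] < 0

    def test_missing_v1_reports_absent(self):
        x = _triangle(100)
        tpl = pwave.PwaveTemplate(data=x[None, :], fs=1000.0,
                                  lead_names=["II"])
        g = global_features(tpl, delineate(tpl))
        assert g["ptfv1"] is None

    def test_triangular_fwhm_is_half_base(self):
        x = _triangle(120)
        tpl = pwave.PwaveTemplate(data=x[None, :], fs=1000.0,
                                  lead_names=["II"])
        g = global_features(tpl, delineate(tpl))
        assert g["fwhm"] == pytest.approx(60.0, abs=2.0)

    def test_equal_areas_give_45_degree_axis(self):
        x = _triangle(100)
        tpl = pwave.PwaveTemplate(data=np.stack([x, x]), fs=1000.0,
                                  lead_names=["I", "aVF"])
        g = global_features(tpl, delineate(tpl))
        assert g["p_axis"] == pytest.approx(45.0, abs=0.5)

    def test_pr_interval_uses_window_end_as_qrs_proxy(self):
        x = _triangle(100, start=100)
        tpl = pwave.PwaveTemplate(data=x[None, :], fs=1000.0,
                                  lead_names=["II"])
        delin = delineate(tpl)
        g = global_features(tpl, delin)
        assert g["pr_interval"] == pytest.approx(300.0 - delin.global_onset_ms)


def _sampen_bruteforce(x, m, r):
    """Direct pairwise-count sample entropy (independent oracle)."""
    n = len(x)

    def count(mm):
        c = 0
        for i in range(n - mm + 1):
            for j in range(i + 1, n - mm + 1):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    B, A = count(m), count(m + 1)
    return -np.log(A / B)


class TestLocalFeatures:
    def test_constant_segment(self):
        x = np.full(300, 0.2)
        f = local_features(x, 50.0, 250.0, 0.0)
        assert f["entropy"] == 0.0
        assert f["n_peaks"] == 0

    def test_unit_gaussian(self):
        t = np.arange(300.0)
        x = np.exp(-0.5 * ((t - 150) / 20) ** 2)
        f = local_features(x, 50.0, 250.0, 0.0)
        assert f["n_peaks"] == 1
        assert f["max_amplitude"] == pytest.approx(1.0, abs=1e-6)

    def test_sample_entropy_matches_bruteforce(self, rng):
        x = rng.normal(size=120)
        r = 0.2 * np.std(x)
        got = sample_entropy(x, m=2, r=r)
        want = _sampen_bruteforce(x, 2, r)
        assert got == pytest.approx(want, abs=1e-12)

    def test_entropy_invariant_to_positive_scaling(self, rng):
        x = rng.normal(size=300)
        f1 = local_features(x, 0.0, 299.0, 0.0)
        f2 = local_features(7.3 * x, 0.0, 299.0, 0.0)
        assert f1["entropy"] == pytest.approx(f2["entropy"], abs=1e-12)

    def test_degenerate_delineation_flagged(self):
        f = local_features(np.zeros(300), 100.0, 100.0, 0.0)
        assert all(np.isnan(v) for v in f.values())


class TestAggregation:
    def _features_with_duration(self, d):
        x = _triangle(100)
        tpl = pwave.PwaveTemplate(data=np.tile(x, (12, 1)), fs=1000.0,
                                  lead_names=pwave.STANDARD_LEADS)
        f = epoch_features(tpl)
        f.p_duration = d
        return f

    def test_single_epoch_identity(self):
        f = self._features_with_duration(120.0)
        avg, counts = pwave.average_over_epochs([f])
        assert avg["p_duration"] == 120.0

    def test_two_epoch_mean(self):
        fs = [self._features_with_duration(d) for d in (120.0, 130.0)]
        avg, _ = pwave.average_over_epochs(fs)
        assert avg["p_duration"] == 125.0

    def test_nan_feature_skipped_with_count(self):
        f1 = self._features_with_duration(120.0)
        f2 = self._features_with_duration(np.nan)
        avg, counts = pwave.average_over_epochs([f1, f2])
        assert avg["p_duration"] == 120.0
        assert counts["p_duration"] == 1

    def test_zero_epochs_raises(self):
        with pytest.raises(ValueError):
            pwave.average_over_epochs([])

    def test_feature_vector_has_65_entries(self):
        f = self._features_with_duration(110.0)
        assert len(f.to_series()) == 65


class TestEndToEnd:
    def test_clean_patient_recovers_duration_and_pr(self):
        spec = synth.EcgSynthSpec(duration_s=30.0, p_duration_ms=120.0,
                                  pr_interval_ms=170.0, noise_sd_mv=0.0,
                                  powerline_hz=None, seed=11)
        rec, truth = synth.gen_ecg(spec)
        feats, qc = pwave.process_recording(rec)
        assert qc["n_epochs_valid"] == 2
        assert feats["p_duration"] == pytest.approx(120.0, abs=12.0)
        assert feats["pr_interval"] == pytest.approx(170.0, abs=10.0)
        assert len(feats) == 65
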