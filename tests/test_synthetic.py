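import hashlib
import pickle

import numpy as np
import pytest
from scipy import signal as sig

import amsanet as a
from amsanet.synthetic import _median_pp_per_second


class TestGenerateVf:
    def test_energy_concentrated_below_18hz(self):
        for seed in (1, 2, 3):
            seg = a.highpass(a.generate_vf(rng_seed=seed))
            freqs = np.fft.rfftfreq(seg.n, 1 / seg.fs)
            power = np.abs(np.fft.rfft(seg.samples)) ** 2
            frac = power[freqs <= 18.0].sum() / power.sum()
            assert frac >= 0.90

    def test_pinned_amplitude_range(self):
        params = a.VfGenParams(amplitude_pp_range=(0.5, 0.5))
        seg = a.generate_vf(params, rng_seed=4)
        assert 0.4 <= _median_pp_per_second(seg.samples, seg.fs) <= 0.6

    def test_seed_determinism_and_seed_decorrelation(self):
        s1 = a.generate_vf(rng_seed=9)
        s2 = a.generate_vf(rng_seed=9)
        s3 = a.generate_vf(rng_seed=10)
        np.testing.assert_array_equal(s1.samples, s2.samples)
        corr = np.corrcoef(s1.samples, s3.samples)[0, 1]
        assert abs(corr) < 0.5

    def test_passes_vf_rhythm_rule(self):
        for seed in range(5):
            assert a.is_vf(a.generate_vf(rng_seed=seed))

    def test_invalid_params_rejected(self):
        with pytest.raises(a.ConfigurationError):
            a.generate_vf(a.VfGenParams(dominant_freq_range=(1.0, 7.0)))
        with pytest.raises(a.ConfigurationError):
            a.generate_vf(duration=2.0)


class TestGenerateCcArtifact:
    def test_fixed_rate_spectral_peaks_at_harmonics(self):
        params = a.CcGenParams(rate_range=(100.0, 100.0), cycle_jitter_cv=0.0,
                               magnitude_mod_sigma=0.0)
        seg, _ = a.generate_cc_artifact(params, rng_seed=1)
        freqs = np.fft.rfftfreq(seg.n, 1 / seg.fs)
        amp = np.abs(np.fft.rfft(seg.samples))
        f0 = 100.0 / 60.0
        for k in (1, 2, 3):
            region = np.abs(freqs - k * f0) <= 0.25 + 1e-9  # +/- 1 bin
            peak_bin = freqs[np.argmax(amp)]
            assert amp[region].max() > 5 * np.median(amp)
        assert abs(peak_bin - f0) <= 0.25 + 1e-9

    def test_cycle_count_at_120_per_min(self):
        params = a.CcGenParams(rate_range=(120.0, 120.0), cycle_jitter_cv=0.0)
        _, ref = a.generate_cc_artifact(params, duration=4.0, rng_seed=2)
        complete = np.sum(ref.onset_times[1:] <= 4.0 + 1e-9)
        assert complete == 8

    def test_single_harmonic_is_pure_tone_per_cycle(self):
        params = a.CcGenParams(rate_range=(110.0, 110.0), cycle_jitter_cv=0.0,
                               magnitude_mod_sigma=0.0, n_harmonics=1)
        seg, ref = a.generate_cc_artifact(params, rng_seed=3)
        # oracle: per-cycle least-squares single-sinusoid fit; residual = THD
        t = np.arange(seg.n) / seg.fs
        resid_power, total_power = 0.0, 0.0
        for t_on, t_off in zip(ref.onset_times[:-1], ref.onset_times[1:]):
            sel = (t >= t_on) & (t < min(t_off, seg.duration))
            if not sel.any():
                continue
            tau = (t[sel] - t_on) / (t_off - t_on)
            basis = np.stack([np.cos(2 * np.pi * tau), np.sin(2 * np.pi * tau)], 1)
            coef, *_ = np.linalg.lstsq(basis, seg.samples[sel], rcond=None)
            resid = seg.samples[sel] - basis @ coef
            resid_power += np.sum(resid ** 2)
            total_power += np.sum(seg.samples[sel] ** 2)
        assert np.sqrt(resid_power / total_power) < 0.01

    def test_rate_outside_range_rejected(self):
        with pytest.raises(a.ConfigurationError):
            a.generate_cc_artifact(a.CcGenParams(rate_range=(40.0, 100.0)))


class TestMixAtSnr:
    @pytest.mark.parametrize("snr_db", a.STUDY_SNR_LEVELS_DB)
    def test_requested_snr_achieved_exactly(self, vf_segment, cc_artifact, snr_db):
        art, _ = cc_artifact
        mixed = a.mix_at_snr(vf_segment, art, snr_db)
        scaled = mixed.with_samples(mixed.samples - vf_segment.samples)
        assert a.measured_snr_db(vf_segment, scaled) == pytest.approx(snr_db, abs=1e-9)

    def test_zero_db_equalises_powers(self, vf_segment, cc_artifact):
        art, _ = cc_artifact
        mixed = a.mix_at_snr(vf_segment, art, 0.0)
        scaled = mixed.samples - vf_segment.samples
        ratio = np.mean(vf_segment.samples ** 2) / np.mean(scaled ** 2)
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_gain_for_unit_power_inputs(self):
        t = np.arange(1000) / 250.0
        clean = a.EcgSegment(samples=np.sqrt(2) * np.sin(2 * np.pi * 5 * t))
        art = a.EcgSegment(samples=np.sqrt(2) * np.sin(2 * np.pi * 2 * t))
        mixed = a.mix_at_snr(clean, art, 3.0)
        big = np.abs(art.samples) > 0.5
        g = np.median((mixed.samples - clean.samples)[big] / art.samples[big])
        assert g == pytest.approx(10 ** (-3 / 20), rel=1e-6)

    def test_zero_artifact_rejected(self, vf_segment):
        silent = a.EcgSegment(samples=np.zeros(vf_segment.n))
        with pytest.raises(a.InvalidInputError):
            a.mix_at_snr(vf_segment, silent, 0.0)


class TestRhythmRules:
    def test_zero_segment_is_asystole_not_vf(self):
        seg = a.EcgSegment(samples=np.zeros(1000))
        assert a.is_asystole(seg) and not a.is_vf(seg)

    @pytest.mark.parametrize("pp,expected", [(0.099, True), (0.101, False)])
    def test_asystole_boundary(self, sinusoid_segment, pp, expected):
        seg = sinusoid_segment(freq_hz=5.0, amp_mv=pp / 2)
        assert a.is_asystole(seg) is expected

    def test_organized_rhythm_fails_vf_rule(self, sinusoid_segment):
        # a large pure 2 Hz tone is periodic at lag 0.5 s: organized
        seg = sinusoid_segment(freq_hz=2.0, amp_mv=1.0)
        assert not a.is_vf(seg)


class TestShockOutcomes:
    def test_flat_model_matches_base_rate(self):
        # beta1 -> 0 limit handled by direct probability check
        model = a.OutcomeModel(beta0=-1.0, beta1=1e-9)
        amsa = np.random.default_rng(0).uniform(2, 25, size=4000)
        labels = a.simulate_shock_outcomes(amsa, model, rng_seed=1)
        from scipy.special import expit
        p = expit(-1.0)
        se = np.sqrt(p * (1 - p) / labels.size)
        assert abs(labels.mean() - p) < 4 * se

    def test_steep_model_separates_perfectly(self):
        model = a.OutcomeModel(beta0=-25.0, beta1=10.0)
        amsa = np.random.default_rng(1).uniform(2, 25, size=2000)
        labels = a.simulate_shock_outcomes(amsa, model, rng_seed=2)
        roc = a.roc_auc(amsa, labels)
        assert roc.auc > 0.97

    def test_auc_matches_integration_oracle(self):
        model = a.OutcomeModel(beta0=-3.0, beta1=1.5)
        rng = np.random.default_rng(3)
        amsa = np.sort(rng.lognormal(np.log(10), 0.5, size=5000))
        labels = a.simulate_shock_outcomes(amsa, model, rng_seed=7)
        emp = a.roc_auc(amsa, labels).auc
        # oracle: expected AUC over label draws given the scores =
        # P(a_i > a_j | y_i=1, y_j=0), via prefix sums on sorted scores
        p = model.success_probability(amsa)
        above = np.sum(p) - np.cumsum(p)  # sum of p_i over scores above a_j
        num = np.sum((1 - p) * above)  # sorted, distinct scores
        den = np.sum(p) * np.sum(1 - p) - np.sum(p * (1 - p))
        oracle = num / den
        assert emp == pytest.approx(oracle, abs=0.03)

    def test_non_positive_amsa_rejected(self):
        with pytest.raises(a.InvalidInputError):
            a.simulate_shock_outcomes(np.array([1.0, 0.0]), a.OutcomeModel(), 0)


class TestBuildDataset:
    def test_subjects_disjoint_across_splits(self, tiny_dataset):
        seen = {}
        for split, pairs in tiny_dataset.items():
            for p in pairs:
                assert seen.setdefault(p.subject_id, split) == split

    def test_snr_levels_balanced(self, tiny_dataset):
        counts = {}
        for pairs in tiny_dataset.values():
            for p in pairs:
                counts[p.snr_db] = counts.get(p.snr_db, 0) + 1
        assert set(counts) == set(a.STUDY_SNR_LEVELS_DB)
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_labels_match_clean_member_amsa(self, tiny_dataset):
        for pairs in tiny_dataset.values():
            for p in pairs[:3]:
                assert p.amsa_true == pytest.approx(a.amsa_fft(p.uncorrupted))

    def test_deterministic_under_fixed_seed(self):
        cfg = a.DatasetConfig(seed=5, n_subjects=4, pairs_per_subject=2)
        h = []
        for _ in range(2):
            splits = a.build_dataset(cfg)
            blob = pickle.dumps([(s, p.subject_id, p.snr_db,
                                  p.corrupted.samples.tobytes(),
                                  p.uncorrupted.samples.tobytes())
                                 for s in sorted(splits) for p in splits[s]])
            h.append(hashlib.sha256(blob).hexdigest())
        assert h[0] == h[1]

    def test_concat_mode_uses_adjacent_window(self):
        cfg = a.DatasetConfig(seed=6, n_subjects=4, pairs_per_subject=2,
                              mode="concat")
        splits = a.build_dataset(cfg)
        pair = next(p for pairs in splits.values() for p in pairs)
        assert pair.corrupted.role == a.SegmentRole.CVF
        assert pair.uncorrupted.role == a.SegmentRole.UVF

    def test_bad_split_fractions_rejected(self):
        cfg = a.DatasetConfig(split_fractions={"train": 0.5, "test": 0.4})
        with pytest.raises(a.ConfigurationError):
            a.build_dataset(cfg)
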