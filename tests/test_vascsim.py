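"""Synthetic carotid-sound generator: contracts and signal properties."""

import os

import numpy as np
import pytest
from scipy import signal as sps

import carotidprint as cp
from carotidprint.hs_segmentation import S1, SYSTOLE, S2, DIASTOLE


class TestProfiles:
    def test_bands_inside_murmur_range(self, profiles):
        assert len(profiles) == 7
        for p in profiles:
            lo, hi, gain = p.murmur_band
            assert 4.0 <= lo < hi <= 100.0
            assert gain >= 0

    def test_deterministic_given_seed(self):
        a = cp.make_profiles(5, seed=42)
        b = cp.make_profiles(5, seed=42)
        for pa, pb in zip(a, b):
            assert pa == pb
        c = cp.make_profiles(5, seed=43)
        assert any(pa != pc for pa, pc in zip(a, c))

    def test_degenerate_separation_still_valid(self):
        for p in cp.make_profiles(2, seed=1, separation=0.0):
            assert 4.0 <= p.murmur_band[0] < p.murmur_band[1] <= 100.0

    def test_too_few_users_rejected(self):
        with pytest.raises(ValueError):
            cp.make_profiles(1, seed=0)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError):
            cp.UserProfile("X", hr_mean=30.0, hr_sd=1.0,
                           s1_freqs=[(40.0, 1.0)], s2_freqs=[(50.0, 0.5)],
                           murmur_band=(5.0, 9.0, 0.1),
                           s1_dur=0.1, s2_dur=0.08)


class TestSimulateRecording:
    def test_length_and_normalization(self, clean_rec):
        assert len(clean_rec.samples) == 11 * 16000
        assert np.max(np.abs(clean_rec.samples)) == pytest.approx(1.0)
        assert clean_rec.samples.min() >= -1.0

    def test_truth_states_cycle_in_order(self, clean_rec):
        assert clean_rec.truth_states.is_cyclic()
        states = {s for _, _, s in clean_rec.truth_states.runs()}
        assert states == {S1, SYSTOLE, S2, DIASTOLE}

    def test_s1_count_matches_heart_rate(self, rec_60bpm):
        n_s1 = sum(1 for _, _, s in rec_60bpm.truth_states.runs() if s == S1)
        assert 9 <= n_s1 <= 13   # 11 s at 60 bpm -> 11 +- 2 bursts

    def test_invalid_arguments(self, profile):
        with pytest.raises(ValueError):
            cp.simulate_recording(profile, duration=-1.0)
        with pytest.raises(ValueError):
            cp.simulate_recording(profile, duration=11.0, fs=0)

    def test_low_quality_attenuates_s2(self, profile):
        clean = cp.simulate_recording(profile, seed=9)
        low = cp.simulate_recording(profile, seed=9, low_quality=True)
        # S2 energy relative to S1 collapses in the degraded recording
        def band_energy(rec, state):
            lab = rec.truth_states.labels
            return float(np.mean(rec.samples[lab == state] ** 2))
        ratio_clean = band_energy(clean, S2) / band_energy(clean, S1)
        ratio_low = band_energy(low, S2) / band_energy(low, S1)
        # the murmur noise floor persists in the S2 span, so the energy
        # ratio drops toward the floor rather than to zero
        assert ratio_low < 0.5 * ratio_clean

    def test_murmur_peak_inside_profile_band(self, profiles):
        # within the 4-100 Hz signature region the averaged periodogram
        # must peak inside the user's own murmur band
        for p in profiles:
            rec = cp.simulate_recording(p, seed=11)
            f, pxx = sps.welch(rec.samples, fs=rec.fs, nperseg=1 << 15)
            keep = (f >= cp.vascsim.MURMUR_RANGE[0]) \
                & (f <= cp.vascsim.MURMUR_RANGE[1])
            df = f[1] - f[0]
            lo, hi, _ = p.murmur_band
            fpeak = f[keep][np.argmax(pxx[keep])]
            assert lo - df <= fpeak <= hi + df


class TestSimulateDataset:
    def test_counts_files_and_determinism(self, tmp_path):
        profiles = cp.make_profiles(2, seed=4)
        man = cp.simulate_dataset(profiles, 4, str(tmp_path / "a"), seed=7,
                                  duration=3.0)
        assert len(man) == 8
        for path in man.paths():
            assert os.path.exists(path)
        assert set(man.frame["user"]) == {"U1", "U2"}
        assert set(man.frame["device"]) <= set(cp.vascsim.DEVICES)
        man2 = cp.simulate_dataset(profiles, 4, str(tmp_path / "b"), seed=7,
                                   duration=3.0)
        a = (tmp_path / "a" / "manifest.csv").read_bytes()
        b = (tmp_path / "b" / "manifest.csv").read_bytes()
        assert a == b

    def test_low_quality_flag_rate(self, tmp_path):
        profiles = cp.make_profiles(2, seed=4)
        man = cp.simulate_dataset(profiles, 50, str(tmp_path / "c"), seed=7,
                                  duration=3.0, low_quality_fraction=0.1)
        n_low = int((man.frame["quality"] == "low").sum())
        assert 2 <= n_low <= 25      # Binomial(100, 0.1)

    def test_truth_roundtrip(self, tmp_path):
        profiles = cp.make_profiles(2, seed=4)
        man = cp.simulate_dataset(profiles, 1, str(tmp_path / "d"), seed=7,
                                  duration=3.0)
        truth = cp.vascsim.truth_for(man, 0)
        assert truth.is_cyclic()
        assert len(truth) == 3 * 16000

    def test_bad_counts_rejected(self, tmp_path):
        profiles = cp.make_profiles(2, seed=4)
        with pytest.raises(ValueError):
            cp.simulate_dataset(profiles, 0, str(tmp_path / "e"))


def test_separation_one_users_linearly_separable():
    """Full murmur-band separation allows a perfect threshold rule."""
    profiles = cp.make_profiles(2, seed=2, separation=1.0)
    centers, labels = [], []
    for li, p in enumerate(profiles):
        for s in range(5):
            rec = cp.simulate_recording(p, seed=s)
            f, pxx = sps.welch(rec.samples, fs=rec.fs, nperseg=1 << 15)
            keep = (f >= 4.0) & (f <= 100.0)
            centers.append(float(f[keep][np.argmax(pxx[keep])]))
            labels.append(li)
    centers, labels = np.array(centers), np.array(labels)
    # brute-force threshold sweep
    best = 0.0
    for thr in np.sort(centers):
        acc = max(np.mean((centers <= thr) == labels),
                  np.mean((centers > thr) == labels))
        best = max(best, acc)
    assert best == 1.0
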