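"""HSMM segmentation: features, heart rate, decoding, cycle extraction."""

import numpy as np
import pytest

import carotidprint as cp
from carotidprint.hs_segmentation import (
    S1, SYSTOLE, S2, DIASTOLE, N_STATES, NEXT_STATE, SegmentationError,
    StateSequence, extract_features, estimate_heart_rate, fit_hsmm,
    viterbi_segment, extract_cycles, path_log_score)


def brute_force_decode(logE, durs):
    """Exhaustive search over all cyclic labellings (oracle)."""
    T = logE.shape[0]
    best, best_lab = -np.inf, None

    def recurse(labels):
        nonlocal best, best_lab
        if len(labels) == T:
            s = path_log_score(labels, logE, durs)
            if s > best:
                best, best_lab = s, list(labels)
            return
        if labels:
            for nxt in (labels[-1], NEXT_STATE[labels[-1]]):
                recurse(labels + [nxt])
        else:
            for j in range(N_STATES):
                recurse([j])

    recurse([])
    return best, best_lab


def random_toy(rng, T):
    logE = np.log(rng.uniform(0.05, 1.0, (T, N_STATES)))
    durs = []
    for _ in range(N_STATES):
        dmax = int(rng.integers(2, 6))
        pmf = rng.uniform(0.1, 1.0, dmax)
        pmf /= pmf.sum()
        tail = np.cumsum(pmf[::-1])[::-1]
        durs.append((1, dmax, np.log(pmf), np.log(tail)))
    return logE, durs


class _ToyModel:
    frame_rate = 50.0

    def __init__(self, logE, durs):
        self.logE, self.durs = logE, durs

    def emission_log_probs(self, features):
        return self.logE

    def durations_for_heart_rate(self, heart_rate):
        return self.durs


class _ToyFrames:
    rate = 50.0

    def __init__(self, T):
        self.values = np.zeros((T, 4))

    def __len__(self):
        return len(self.values)


def decode_toy(logE, durs):
    return viterbi_segment(_ToyFrames(logE.shape[0]), _ToyModel(logE, durs),
                           70.0)


class TestFeatures:
    def test_frame_count_and_range(self, clean_rec):
        feats = extract_features(clean_rec)
        assert abs(len(feats) - 550) <= 1
        assert feats.values.shape[1] == 4
        assert feats.values.min() >= 0.0 and feats.values.max() <= 1.0

    def test_constant_input_rejected(self):
        rec = cp.AudioRecording(np.zeros(5 * 16000), 16000)
        with pytest.raises(SegmentationError):
            extract_features(rec)

    def test_short_input_rejected(self, clean_rec):
        rec = cp.AudioRecording(clean_rec.samples[:16000], 16000)
        with pytest.raises(SegmentationError):
            extract_features(rec)

    def test_homomorphic_peak_falls_on_s1(self, clean_rec):
        feats = extract_features(clean_rec)
        truth = clean_rec.truth_states.to_rate(feats.rate, len(feats))
        peak_frame = int(np.argmax(feats.values[:, 0]))
        assert truth.labels[peak_frame] == S1


class TestHeartRate:
    def test_60_bpm_recovered(self, rec_60bpm):
        hr = estimate_heart_rate(extract_features(rec_60bpm))
        assert hr == pytest.approx(60.0, abs=3.0)

    def test_100_bpm_recovered(self):
        prof = cp.UserProfile(
            user_id="HR100", hr_mean=100.0, hr_sd=1.5,
            s1_freqs=[(115.0, 1.0)], s2_freqs=[(140.0, 0.7)],
            murmur_band=(10.0, 18.0, 0.08), s1_dur=0.10, s2_dur=0.07)
        rec = cp.simulate_recording(prof, seed=6)
        hr = estimate_heart_rate(extract_features(rec))
        assert hr == pytest.approx(100.0, abs=5.0)

    def test_noise_falls_back_with_warning(self):
        rng = np.random.default_rng(0)
        rec = cp.AudioRecording(rng.standard_normal(11 * 16000), 16000)
        feats = extract_features(rec)
        with pytest.warns(UserWarning):
            assert estimate_heart_rate(feats) == pytest.approx(70.0)

    def test_too_short_rejected(self, clean_rec):
        feats = extract_features(clean_rec)
        from carotidprint.hs_segmentation import FeatureFrames
        with pytest.raises(SegmentationError):
            estimate_heart_rate(FeatureFrames(feats.values[:100], feats.rate))


class TestFit:
    def test_deterministic(self, profiles):
        training = []
        for p in profiles[:3]:
            rec = cp.simulate_recording(p, seed=100)
            feats = extract_features(rec)
            training.append(
                (feats, rec.truth_states.to_rate(feats.rate, len(feats))))
        m1 = fit_hsmm(training)
        m2 = fit_hsmm(training)
        assert np.array_equal(m1.weights, m2.weights)
        assert np.array_equal(m1.dur_mean, m2.dur_mean)

    def test_missing_state_named_in_error(self, clean_rec):
        feats = extract_features(clean_rec)
        labels = np.where(
            clean_rec.truth_states.to_rate(feats.rate, len(feats)).labels == S2,
            SYSTOLE, clean_rec.truth_states.to_rate(feats.rate,
                                                    len(feats)).labels)
        broken = StateSequence(labels, feats.rate)
        with pytest.raises(SegmentationError, match="S2"):
            fit_hsmm([(feats, broken)])

    def test_model_json_roundtrip(self, hsmm_model, tmp_path):
        path = tmp_path / "hsmm.json"
        hsmm_model.to_json(path)
        back = cp.HsmmModel.from_json(path)
        assert np.allclose(back.weights, hsmm_model.weights)
        assert np.allclose(back.dur_sd, hsmm_model.dur_sd)


class TestViterbi:
    def test_matches_brute_force_on_toys(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            logE, durs = random_toy(rng, int(rng.integers(3, 13)))
            got = decode_toy(logE, durs)
            vs = path_log_score(got.labels, logE, durs)
            bs, _ = brute_force_decode(logE, durs)
            assert vs == pytest.approx(bs, rel=1e-12)

    def test_sharp_durations_dominate_uniform_emissions(self):
        # durations concentrated on the true run lengths, emissions flat
        # except a nudge on the first frame: the truth is the unique
        # optimum and decoding must reproduce it exactly
        truth = [DIASTOLE] * 3 + [S1] * 2 + [SYSTOLE] * 3 + [S2] * 2 \
            + [DIASTOLE] * 3
        T = len(truth)
        logE = np.zeros((T, N_STATES))
        logE[0, DIASTOLE] = 0.1             # break rotation ties
        lengths = {S1: 2, SYSTOLE: 3, S2: 2, DIASTOLE: 3}
        durs = []
        for j in range(N_STATES):
            dmax = 5
            pmf = np.full(dmax, 1e-9)
            pmf[lengths[j] - 1] = 1.0
            pmf /= pmf.sum()
            tail = np.cumsum(pmf[::-1])[::-1]
            durs.append((1, dmax, np.log(pmf), np.log(tail)))
        got = decode_toy(logE, durs)
        assert list(got.labels) == truth
        # with fully uniform emissions every rotation ties; the decoder
        # must still pick a path whose interior runs sit on the pmf peaks
        logE[0, DIASTOLE] = 0.0
        got = decode_toy(logE, durs)
        for a, b, s in StateSequence(got.labels, 50.0).runs()[1:-1]:
            assert b - a == lengths[s]

    def test_amplitude_invariant_segmentation(self, hsmm_model, clean_rec):
        feats1 = extract_features(clean_rec)
        half = cp.AudioRecording(0.5 * clean_rec.samples, clean_rec.fs)
        feats2 = extract_features(half)
        hr = estimate_heart_rate(feats1)
        s1 = viterbi_segment(feats1, hsmm_model, hr)
        s2 = viterbi_segment(feats2, hsmm_model, hr)
        assert np.array_equal(s1.labels, s2.labels)

    def test_heldout_frame_accuracy(self, hsmm_model, profiles):
        accs = []
        for p in profiles[:4]:
            rec = cp.simulate_recording(p, seed=301)   # unseen in training
            feats = extract_features(rec)
            states = viterbi_segment(feats, hsmm_model,
                                     estimate_heart_rate(feats))
            truth = rec.truth_states.to_rate(feats.rate, len(feats))
            accs.append(np.mean(states.labels == truth.labels[:len(states)]))
        assert np.mean(accs) >= 0.90


class TestExtractCycles:
    def label_seq(self, names):
        ids = {"D": DIASTOLE, "S1": S1, "Sys": SYSTOLE, "S2": S2}
        return StateSequence(np.array([ids[n] for n in names]), 1.0)

    def test_two_complete_cycles(self):
        seq = self.label_seq(["D", "S1", "Sys", "S2", "D", "S1", "Sys", "S2"])
        cycles = extract_cycles(seq)
        assert cycles.spans == [(0, 4), (4, 8)]

    def test_leading_fragment_discarded(self):
        seq = self.label_seq(["S1", "Sys", "S2", "D"])
        assert extract_cycles(seq).spans == []

    def test_synthetic_cycle_count(self, hsmm_model, rec_60bpm):
        feats = extract_features(rec_60bpm)
        states = viterbi_segment(feats, hsmm_model,
                                 estimate_heart_rate(feats))
        cycles = extract_cycles(states)
        assert 8 <= len(cycles) <= 11      # 11 s at 60 bpm, edges trimmed

    def test_cycle_count_bounded_by_s2_runs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            labels, state = [], int(rng.integers(0, 4))
            for _ in range(int(rng.integers(1, 12))):
                labels.extend([state] * int(rng.integers(1, 4)))
                state = NEXT_STATE[state]
            seq = StateSequence(np.array(labels), 1.0)
            n_s2 = sum(1 for _, _, s in seq.runs() if s == S2)
            assert len(extract_cycles(seq)) <= n_s2
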