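"""Shared fixtures: simulated cohort, recordings, and a fitted HSMM.

Everything is generated at test time from fixed seeds; session scope
keeps the expensive pieces (wavelet transforms, model fits) shared.
"""

import numpy as np
import pytest

import carotidprint as cp
from carotidprint.hs_segmentation import extract_features


@pytest.fixture(scope="session")
def profiles():
    return cp.make_profiles(7, seed=1, separation=0.8)


@pytest.fixture(scope="session")
def profile(profiles):
    return profiles[0]


@pytest.fixture(scope="session")
def clean_rec(profile):
    return cp.simulate_recording(profile, duration=11.0, fs=16000, seed=3)


@pytest.fixture(scope="session")
def low_quality_rec(profile):
    return cp.simulate_recording(profile, duration=11.0, fs=16000, seed=3,
                                 low_quality=True)


@pytest.fixture(scope="session")
def profile_60bpm():
    return cp.UserProfile(
        user_id="HR60", hr_mean=60.0, hr_sd=1.0,
        s1_freqs=[(110.0, 1.0), (135.0, 0.7)], s2_freqs=[(125.0, 0.8)],
        murmur_band=(8.0, 14.0, 0.08), s1_dur=0.11, s2_dur=0.08)


@pytest.fixture(scope="session")
def rec_60bpm(profile_60bpm):
    return cp.simulate_recording(profile_60bpm, duration=11.0, fs=16000,
                                 seed=5)


@pytest.fixture(scope="session")
def hsmm_model(profiles):
    """HSMM fitted on 14 labelled clean recordings (2 per user)."""
    training = []
    for p in profiles:
        for s in range(2):
            rec = cp.simulate_recording(p, duration=11.0, fs=16000,
                                        seed=100 + s)
            feats = extract_features(rec)
            training.append(
                (feats, rec.truth_states.to_rate(feats.rate, len(feats))))
    return cp.fit_hsmm(training)


@pytest.fixture(scope="session")
def fingerprint_corpus(profiles):
    """Per-user/side fingerprints from ground-truth cycle boundaries.

    Three users, two recordings per side, cycles cut with the generator's
    exact state labels (segmentation quality is tested elsewhere).
    """
    from carotidprint.fingerprint import (segment_spectrum, resize_cycle,
                                          average_spectra)
    from carotidprint.hs_segmentation import extract_cycles

    out = {}   # (user_id, side, rec_index) -> Fingerprint
    for p in profiles[:3]:
        for side in ("L", "R"):
            for ri in range(2):
                rec = cp.simulate_recording(p, duration=11.0, fs=16000,
                                            seed=40 + ri, side=side)
                spec = cp.compute_cwt(rec, single_precision=True)
                cycles = extract_cycles(rec.truth_states)
                cycs = [resize_cycle(m, spec.freqs,
                                     meta={"user": p.user_id, "side": side})
                        for m in segment_spectrum(spec, cycles)]
                out[(p.user_id, side, ri)] = average_spectra(cycs)
    return out
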