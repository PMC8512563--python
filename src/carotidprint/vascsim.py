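"""Synthetic carotid-sound generator with ground-truth cardiac states.

Emulates short (nominally 11 s, 16 kHz) carotid auscultation recordings
from a small cohort of users: each cardiac cycle carries an S1 and an S2
transient (Gaussian-enveloped multi-tone bursts), superimposed on a
continuous user-specific "murmur" flow sound (band-pass-filtered noise
with a systolic gain boost) whose band lies in the 4-100 Hz range where
carotid spectra differ between individuals.  Recordings carry exact
per-sample state labels, which downstream quality screening, HSMM
training and cycle extraction are tested against.

Device clones are modelled as a small gain/low-pass perturbation, and
the left/right side as a mild multiplicative asymmetry.  All randomness
derives from one explicit seed through splittable ``SeedSequence``s.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .hs_segmentation import (S1, SYSTOLE, S2, DIASTOLE, StateSequence)

#: band (Hz) inside which every user's murmur signature is placed
MURMUR_RANGE = (4.0, 100.0)
#: fraction of recordings degraded by default: 9 of 890 in the emulated protocol
DEFAULT_LOW_QUALITY_FRACTION = 9.0 / 890.0

DEVICES = ("D1", "D2", "D3", "D4")
SIDES = ("L", "R")
# per-device clone perturbations: gain (dB) and first-order low-pass (Hz)
_DEVICE_GAIN_DB = {"D1": 0.0, "D2": 2.0, "D3": -2.0, "D4": 1.0}
_DEVICE_LOWPASS_HZ = {"D1": 7000.0, "D2": 6000.0, "D3": 6500.0, "D4": 7500.0}


@dataclass
class UserProfile:
    """Spectral and timing signature of one simulated user."""

    user_id: str
    hr_mean: float                 # beats/min
    hr_sd: float                   # beats/min
    s1_freqs: list                 # [(Hz, amplitude), ...]
    s2_freqs: list
    murmur_band: tuple             # (low Hz, high Hz, gain)
    s1_dur: float                  # s
    s2_dur: float                  # s
    side_asymmetry: float = 1.0    # multiplicative gain, L vs R

    def __post_init__(self):
        if not 40.0 <= self.hr_mean <= 140.0:
            raise ValueError("hr_mean outside [40, 140] bpm")
        for f, a in list(self.s1_freqs) + list(self.s2_freqs):
            if not 0.0 < f < 8000.0:
                raise ValueError("component frequency outside (0, 8000) Hz")
            if a < 0:
                raise ValueError("negative component amplitude")
        if not (0.0 < self.murmur_band[0] < self.murmur_band[1] < 8000.0):
            raise ValueError("invalid murmur band")
        for d in (self.s1_dur, self.s2_dur):
            if not 0.02 < d < 0.25:
                raise ValueError("sound duration outside (0.02, 0.25) s")

    @property
    def murmur_center(self) -> float:
        """Geometric centre (Hz) of the murmur band."""
        return float(np.sqrt(self.murmur_band[0] * self.murmur_band[1]))


@dataclass
class AudioRecording:
    """A mono recording plus provenance labels and optional ground truth."""

    samples: np.ndarray
    fs: int = 16000
    user_id: str | None = None
    device_id: str | None = None
    side: str | None = None
    truth_states: StateSequence | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class DatasetManifest:
    """Rows of (path, user, device, side, quality) for a simulated dataset."""

    frame: pd.DataFrame
    root: str = "."

    def __len__(self):
        return len(self.frame)

    def paths(self):
        return [os.path.join(self.root, p) for p in self.frame["path"]]

    def save(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path), os.path.dirname(os.path.abspath(path)))


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def make_profiles(n_users: int, seed: int, separation: float = 0.8
                  ) -> list[UserProfile]:
    """Deterministically draw ``n_users`` user signatures.

    ``separation`` (0-1) sets the target spacing of murmur-band centres
    in octaves; the spacing is reduced when the requested cohort cannot
    fit inside the 4-100 Hz murmur range, so all bands always stay within
    that range.  Centres are assigned to users in a seed-dependent order.
    """
    if n_users < 2:
        raise ValueError("need at least two users")
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))

    half_bw = 0.3   # octaves, half-width of the murmur band
    lo_c = MURMUR_RANGE[0] * 2.0 ** half_bw
    hi_c = MURMUR_RANGE[1] / 2.0 ** half_bw
    span = np.log2(hi_c / lo_c)
    step = min(separation, span / (n_users - 1))
    start = np.log2(lo_c) + 0.5 * (span - step * (n_users - 1))
    centers = 2.0 ** (start + step * np.arange(n_users))
    centers = centers[rng.permutation(n_users)]

    profiles = []
    for i in range(n_users):
        c = centers[i]
        hw = 2.0 ** rng.uniform(0.15, 0.25)
        n1 = rng.integers(2, 4)
        n2 = rng.integers(2, 4)
        profiles.append(UserProfile(
            user_id=f"U{i + 1}",
            hr_mean=float(rng.uniform(55.0, 85.0)),
            hr_sd=float(rng.uniform(1.0, 3.0)),
            s1_freqs=[(float(f), float(a)) for f, a in zip(
                rng.uniform(100.0, 150.0, n1), rng.uniform(0.6, 1.0, n1))],
            s2_freqs=[(float(f), float(a)) for f, a in zip(
                rng.uniform(110.0, 170.0, n2), rng.uniform(0.5, 0.9, n2))],
            murmur_band=(float(c / hw), float(c * hw),
                         float(rng.uniform(0.08, 0.13))),
            s1_dur=float(rng.uniform(0.09, 0.13)),
            s2_dur=float(rng.uniform(0.07, 0.10)),
            side_asymmetry=float(rng.uniform(0.92, 0.99)),
        ))
    return profiles


# ---------------------------------------------------------------------------
# Single recording
# ---------------------------------------------------------------------------

def _gauss_burst(t_local: np.ndarray, dur: float, comps, rng,
                 amplitude: float = 1.0) -> np.ndarray:
    """Gaussian-windowed multi-tone burst over a state span.

    The burst peak is normalized to ``amplitude`` so random component
    phases cannot cancel a heart sound away.
    """
    tc = dur / 2.0
    sigma = dur / 6.0
    window = np.exp(-0.5 * ((t_local - tc) / sigma) ** 2)
    burst = np.zeros_like(t_local)
    for f, a in comps:
        burst += a * np.cos(2.0 * np.pi * f * (t_local - tc)
                            + rng.uniform(0.0, 2.0 * np.pi))
    burst *= window
    peak = np.max(np.abs(burst))
    return burst * (amplitude / peak) if peak > 0 else burst


def simulate_recording(profile: UserProfile, duration: float = 11.0,
                       fs: int = 16000, seed: int = 0,
                       low_quality: bool = False, side: str = "L",
                       device_id: str | None = None) -> AudioRecording:
    """Simulate one recording with exact per-sample state labels.

    Cycle timing: RR intervals ~ Normal(60/hr_mean, proportional sd)
    truncated positive; systole tracks the RR interval weakly, diastole
    absorbs the rest.  A ``low_quality`` recording has its S2 bursts
    attenuated below the murmur noise floor, mimicking recordings whose
    S2 events cannot be recognized.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if duration <= 2.0 * 60.0 / profile.hr_mean:
        raise ValueError("duration too short for two cardiac cycles")
    rng = np.random.default_rng(np.random.SeedSequence(
        [zlib.crc32(profile.user_id.encode()), int(seed)]))
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    labels = np.full(n, DIASTOLE, dtype=np.int64)

    rr_mean = 60.0 / profile.hr_mean
    rr_sd = rr_mean * profile.hr_sd / profile.hr_mean

    s2_scale = 0.04 if low_quality else 0.55
    side_gain = profile.side_asymmetry if side == "R" else 1.0

    # lay out runs: leading diastole fragment, then S1/systole/S2/diastole
    events = []  # (state, start_s, end_s)
    pos = rng.uniform(0.05, 0.4)
    events.append((DIASTOLE, 0.0, pos))
    while True:
        rr = rng.normal(rr_mean, rr_sd)
        while rr <= 0.5 * rr_mean:
            rr = rng.normal(rr_mean, rr_sd)
        sys_dur = np.clip(0.30 + 0.10 * (rr - 1.0), 0.18, 0.45)
        dia_dur = max(0.10, rr - profile.s1_dur - sys_dur - profile.s2_dur)
        for state, d in ((S1, profile.s1_dur), (SYSTOLE, sys_dur),
                         (S2, profile.s2_dur), (DIASTOLE, dia_dur)):
            events.append((state, pos, pos + d))
            pos += d
        if pos >= duration:
            break

    sys_indicator = np.zeros(n)
    for state, a_s, b_s in events:
        a, b = int(round(a_s * fs)), min(int(round(b_s * fs)), n)
        if a >= n or b <= a:
            continue
        labels[a:b] = state
        tl = t[a:b] - a_s
        if state == S1:
            # per-burst frequency jitter: real heart sounds are not pure
            # tones, and it spreads burst energy off any single PSD line
            comps = [(f * rng.uniform(0.88, 1.12), amp)
                     for f, amp in profile.s1_freqs]
            x[a:b] += _gauss_burst(tl, profile.s1_dur, comps, rng,
                                   amplitude=rng.uniform(0.9, 1.1))
        elif state == S2:
            comps = [(f * rng.uniform(0.88, 1.12), amp)
                     for f, amp in profile.s2_freqs]
            x[a:b] += _gauss_burst(tl, profile.s2_dur, comps, rng,
                                   amplitude=s2_scale * rng.uniform(0.9, 1.1))
        elif state == SYSTOLE:
            sys_indicator[a:b] = 1.0

    # murmur: band-limited noise, continuous, boosted during systole
    lo, hi, gain = profile.murmur_band
    sos = sps.butter(2, (lo, hi), btype="bandpass", fs=fs, output="sos")
    murmur = sps.sosfiltfilt(sos, rng.standard_normal(n))
    murmur /= max(np.sqrt(np.mean(murmur ** 2)), 1e-12)
    smooth_n = int(0.03 * fs)
    boost = 1.0 + 0.4 * np.convolve(sys_indicator,
                                    np.ones(smooth_n) / smooth_n, mode="same")
    x += gain * side_gain * murmur * boost

    x += 0.02 * rng.standard_normal(n)          # sensor noise floor

    if device_id is not None:
        x *= 10.0 ** (_DEVICE_GAIN_DB[device_id] / 20.0)
        b, a = sps.butter(1, _DEVICE_LOWPASS_HZ[device_id], btype="low", fs=fs)
        x = sps.lfilter(b, a, x)

    x /= np.max(np.abs(x))
    return AudioRecording(x, fs, profile.user_id, device_id, side,
                          StateSequence(labels, fs))


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

def simulate_dataset(profiles: list[UserProfile], per_user_counts,
                     out_dir: str, seed: int = 0,
                     devices=DEVICES, sides=SIDES,
                     low_quality_fraction: float = DEFAULT_LOW_QUALITY_FRACTION,
                     duration: float = 11.0, fs: int = 16000
                     ) -> DatasetManifest:
    """Write a WAV dataset plus manifest and per-recording truth CSVs.

    ``per_user_counts`` is an int (same count for every user) or a mapping
    ``user_id -> count``.  Devices and sides are cycled round-robin per
    user; each recording's quality flag is an independent Bernoulli draw.
    Deterministic given the seed: rerunning yields byte-identical files.
    """
    if isinstance(per_user_counts, int):
        per_user_counts = {p.user_id: per_user_counts for p in profiles}
    if any(c <= 0 for c in per_user_counts.values()):
        raise ValueError("per-user counts must be positive")
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory not writable: {out_dir}")

    rows = []
    flag_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1A6]))
    for profile in profiles:
        count = per_user_counts[profile.user_id]
        for i in range(count):
            device = devices[i % len(devices)]
            side = sides[i % len(sides)]
            low = bool(flag_rng.random() < low_quality_fraction)
            rec = simulate_recording(
                profile, duration=duration, fs=fs,
                seed=int(np.random.SeedSequence(
                    [int(seed), zlib.crc32(profile.user_id.encode()), i]
                ).generate_state(1)[0] % (2 ** 31)),
                low_quality=low, side=side, device_id=device)
            stem = f"{profile.user_id}_{side}_{device}_{i:04d}"
            wav_rel = f"{stem}.wav"
            write_wav(os.path.join(out_dir, wav_rel), rec)
            rec.truth_states.to_csv(os.path.join(out_dir, f"{stem}_states.csv"))
            rows.append({"path": wav_rel, "user": profile.user_id,
                         "device": device, "side": side,
                         "quality": "low" if low else "good"})
    manifest = DatasetManifest(pd.DataFrame(rows), out_dir)
    manifest.save(os.path.join(out_dir, "manifest.csv"))
    return manifest


def write_wav(path, rec: AudioRecording) -> None:
    """Write a mono 16-bit PCM RIFF WAV file."""
    q = np.clip(np.round(rec.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(rec.fs), q)


def truth_for(manifest: DatasetManifest, row_index: int, fs: int = 16000
              ) -> StateSequence:
    """Load the ground-truth state sequence matching a manifest row."""
    rel = manifest.frame.iloc[row_index]["path"]
    return StateSequence.from_csv(
        os.path.join(manifest.root, rel.replace(".wav", "_states.csv")), fs)
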