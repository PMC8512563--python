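"""Recording ingest and automated low-signal-quality rejection.

A recording is usable when its S1 and S2 heart-sound events are
recognizable.  This module automates that screen: an amplitude envelope
is smoothed and peak-picked; within each beat the larger peak is taken
as the S1 candidate and the following smaller peak as the S2 candidate;
a recording passes when at least a configured fraction (default 0.7) of
the expected cycles show both events.  Identification downstream does
not depend on this screen — the pipeline offers a bypass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .vascsim import AudioRecording
from .hs_segmentation import _autocorr_beat_period


class FormatError(ValueError):
    """Unsupported audio file layout (e.g. multi-channel)."""


class DegenerateInputError(ValueError):
    """All-zero or otherwise unusable signal content."""


@dataclass
class QualityConfig:
    band: tuple = (25.0, 400.0)    # Hz, heart-sound band for the envelope
    smooth_ms: float = 50.0        # envelope smoothing window
    min_distance_s: float = 0.15   # minimum inter-peak distance; must stay
                                   # below the shortest real S1-S2 spacing
    height_frac: float = 0.15      # peak height threshold vs envelope max
    prominence_frac: float = 0.05  # peak prominence threshold vs envelope max
    accept_frac: float = 0.7       # required detected/expected event ratio
    s1_window_frac: float = 0.55   # beat-period fraction an S1 must dominate
    s2_min_rel: float = 0.15       # S2 prominence floor relative to its S1's
    s2_window: tuple = (0.1, 0.7)  # S2 search window after S1, period fractions
    s2_phase_tol: float = 0.06     # admissible S1->S2 offset spread, period frac
    beat_lag_range: tuple = (0.43, 1.5)   # s (40-140 bpm)
    beat_peak_prominence: float = 0.05
    fallback_period_s: float = 60.0 / 70.0


@dataclass
class QualityReport:
    """Counts behind the accept/reject decision for one recording."""

    n_expected_cycles: int
    n_s1_detected: int
    n_s2_detected: int
    passed: bool


def load_recording(path, user_id=None, device_id=None, side=None
                   ) -> AudioRecording:
    """Read a mono WAV file and normalize so max |sample| = 1."""
    try:
        fs, data = wavfile.read(path)
    except FormatError:
        raise
    except Exception as exc:  # unreadable / malformed container
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise FormatError("expected a mono recording, got multi-channel")
    x = data.astype(np.float64)
    if np.issubdtype(data.dtype, np.integer):
        x /= float(np.iinfo(data.dtype).max) + 1.0
    peak = np.max(np.abs(x))
    if peak == 0:
        raise DegenerateInputError("all-zero signal")
    return AudioRecording(x / peak, int(fs), user_id, device_id, side)


def _smooth_envelope(rec: AudioRecording, cfg: QualityConfig) -> np.ndarray:
    # heart sounds live in the band; most murmur energy sits below it
    sos = sps.butter(4, cfg.band, btype="bandpass", fs=rec.fs, output="sos")
    env = np.abs(sps.hilbert(sps.sosfiltfilt(sos, rec.samples)))
    w = max(1, int(round(cfg.smooth_ms / 1000.0 * rec.fs)))
    return np.convolve(env, np.ones(w) / w, mode="same")


def _beat_period(env: np.ndarray, fs: int, cfg: QualityConfig) -> float:
    # decimated envelope autocorrelation; falls back to the 70 bpm prior
    step = max(1, fs // 50)
    period = _autocorr_beat_period(env[::step], fs / step,
                                   cfg.beat_lag_range,
                                   cfg.beat_peak_prominence)
    return cfg.fallback_period_s if period is None else period


def detect_event_candidates(rec: AudioRecording,
                            config: QualityConfig | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Candidate S1 and S2 event positions (sample indices).

    Envelope peaks at least ``min_distance_s`` apart and above the
    height/prominence floors are grouped by beat: a peak that dominates
    its beat-period neighbourhood is an S1 candidate.  S2 candidates are
    sufficiently prominent non-S1 peaks in the post-S1 window whose
    S1-to-S2 offset agrees with the recording's median offset — a real
    S2 recurs at a nearly constant phase, murmur transients do not.
    """
    cfg = config or QualityConfig()
    if rec.duration < 2.0:
        raise ValueError("recording shorter than 2 s")
    if np.max(np.abs(rec.samples)) == 0:
        raise DegenerateInputError("all-zero signal")
    env = _smooth_envelope(rec, cfg)
    period = _beat_period(env, rec.fs, cfg)
    tp = int(round(period * rec.fs))
    emax = float(env.max())
    peaks, props = sps.find_peaks(
        env, distance=max(1, int(cfg.min_distance_s * rec.fs)),
        height=cfg.height_frac * emax, prominence=cfg.prominence_frac * emax)
    if len(peaks) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    heights = env[peaks]
    proms = props["prominences"]
    s1_mask = np.zeros(len(peaks), dtype=bool)
    for i, p in enumerate(peaks):
        near = np.abs(peaks - p) <= cfg.s1_window_frac * tp
        s1_mask[i] = heights[i] >= heights[near].max()
    s1 = peaks[s1_mask]
    # plausible S2 candidates per beat (prominence above a fraction of
    # that beat's S1 prominence)
    cand_per_beat = []
    for i, p in enumerate(peaks):
        if not s1_mask[i]:
            continue
        window = ((peaks > p + cfg.s2_window[0] * tp)
                  & (peaks <= p + cfg.s2_window[1] * tp) & ~s1_mask
                  & (proms >= cfg.s2_min_rel * proms[i]))
        cand_per_beat.append((int(p), peaks[window]))
    all_offsets = np.concatenate(
        [c - p for p, c in cand_per_beat]) if cand_per_beat else np.array([])
    if all_offsets.size == 0:
        return s1.astype(int), np.array([], dtype=int)
    # a real S2 sits at a consistent offset after its S1 in nearly every
    # beat; noise transients scatter across the systolic window
    median_off = float(np.median(all_offsets))
    s2 = []
    for p, cand in cand_per_beat:
        if cand.size == 0:
            continue
        dev = np.abs(cand - p - median_off)
        j = int(np.argmin(dev))
        if dev[j] <= cfg.s2_phase_tol * tp:
            s2.append(int(cand[j]))
    return s1.astype(int), np.asarray(s2, dtype=int)


def assess_quality(rec: AudioRecording,
                   config: QualityConfig | None = None) -> QualityReport:
    """Accept/reject decision from detected vs expected event counts.

    ``passed`` is true when both S1 and S2 detections reach
    ``accept_frac`` of the number of cycles expected from the estimated
    beat period.  Deterministic for a fixed recording and configuration.
    """
    cfg = config or QualityConfig()
    try:
        s1, s2 = detect_event_candidates(rec, cfg)
    except DegenerateInputError:
        s1 = s2 = np.array([], dtype=int)
    env = None
    if np.max(np.abs(rec.samples)) == 0:
        n_expected = int(rec.duration / cfg.fallback_period_s)
    else:
        env = _smooth_envelope(rec, cfg)
        n_expected = int(rec.duration / _beat_period(env, rec.fs, cfg))
    need = cfg.accept_frac * n_expected
    passed = (len(s1) >= need) and (len(s2) >= need)
    return QualityReport(n_expected, len(s1), len(s2), bool(passed))


def screen_manifest(manifest, config: QualityConfig | None = None):
    """Quality-screen every manifest row; returns a DataFrame
    ``path,n_expected,n_s1,n_s2,pass``."""
    import pandas as pd

    rows = []
    for rel, full in zip(manifest.frame["path"], manifest.paths()):
        rep = assess_quality(load_recording(full), config)
        rows.append({"path": rel, "n_expected": rep.n_expected_cycles,
                     "n_s1": rep.n_s1_detected, "n_s2": rep.n_s2_detected,
                     "pass": rep.passed})
    return pd.DataFrame(rows)
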