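"""Cardiac-cycle segmentation of carotid sound recordings.

Assigns each frame of a recording to one of the four cardiac states
S1 -> systole -> S2 -> diastole (cyclic, no skips) with a
duration-dependent logistic-regression hidden Markov model (HSMM):
per-state one-vs-rest logistic emissions over four envelope features,
deterministic cyclic transitions, and explicit Gaussian state-duration
densities whose systole/diastole means scale with the estimated heart
rate.  Decoding is an extended Viterbi over run lengths.

Path score semantics (shared by :func:`viterbi_segment` and any
exhaustive-enumeration oracle): a labelling is a sequence of runs whose
states follow the cyclic order; its log score is

    sum_t log E[t, state_t]
    + sum over interior runs of log pmf_state(run length)
    + for the first and the last run, log of the duration survival
      function (tail mass at the observed, possibly truncated, length).

A single-run path is charged one tail term.  The initial state is free
(uniform).  Ties are broken toward the earlier state in cycle order and
the shorter final run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from sklearn.linear_model import LogisticRegression

# Cardiac states, in cycle order.
S1, SYSTOLE, S2, DIASTOLE = 0, 1, 2, 3
STATE_NAMES = ("S1", "systole", "S2", "diastole")
N_STATES = 4
#: successor state in the cardiac cycle
NEXT_STATE = (SYSTOLE, S2, DIASTOLE, S1)
#: predecessor state in the cardiac cycle
PREV_STATE = (DIASTOLE, S1, SYSTOLE, S2)


class SegmentationError(ValueError):
    """Raised for invalid inputs or an unfittable segmentation model."""


@dataclass
class SegConfig:
    """Tunable segmentation parameters (defaults follow common PCG practice)."""

    frame_rate: float = 50.0          # Hz of the feature/label frames
    band: tuple = (25.0, 400.0)       # Hz, analysis band-pass
    work_fs: int = 1000               # Hz, intermediate envelope rate
    homomorphic_lpf_hz: float = 8.0
    psd_band: tuple = (90.0, 200.0)   # Hz, band of the spectral feature
    wavelet_scale_hz: float = 130.0   # pseudo-frequency of the wavelet envelope
    hr_lag_range: tuple = (0.43, 1.5)  # s, admissible beat periods (40-140 bpm)
    hr_fallback_bpm: float = 70.0
    hr_peak_prominence: float = 0.35   # periodic envelopes score ~0.5+,
                                       # noise-only autocorrelations < 0.25
    duration_max_factor: float = 2.0  # duration search capped at 2x mean
    min_duration_sd_frames: float = 0.5


# ---------------------------------------------------------------------------
# State sequences
# ---------------------------------------------------------------------------

@dataclass
class StateSequence:
    """Per-frame cardiac-state labels at a given frame rate.

    ``labels`` holds integers in {S1, SYSTOLE, S2, DIASTOLE}; ``rate`` is
    frames per second (equal to the audio sampling rate for per-sample
    ground truth).
    """

    labels: np.ndarray
    rate: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise SegmentationError("labels must be a 1-D array")

    def __len__(self):
        return len(self.labels)

    def runs(self) -> list[tuple[int, int, int]]:
        """Maximal constant runs as ``(start, end, state)``, half-open."""
        lab = self.labels
        if len(lab) == 0:
            return []
        edges = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [len(lab)]))
        return [(int(a), int(b), int(lab[a])) for a, b in zip(starts, ends)]

    def is_cyclic(self) -> bool:
        """True if consecutive runs follow S1->systole->S2->diastole->S1."""
        r = self.runs()
        return all(NEXT_STATE[r[i][2]] == r[i + 1][2] for i in range(len(r) - 1))

    def to_rate(self, new_rate: float, n_out: int | None = None) -> "StateSequence":
        """Nearest-neighbour resampling of the labels to another rate."""
        if n_out is None:
            n_out = int(round(len(self.labels) * new_rate / self.rate))
        # midpoint of each target frame, mapped into source frames
        src = ((np.arange(n_out) + 0.5) * self.rate / new_rate).astype(np.int64)
        src = np.clip(src, 0, len(self.labels) - 1)
        return StateSequence(self.labels[src], new_rate)

    @classmethod
    def from_runs(cls, runs, rate: float, n: int | None = None) -> "StateSequence":
        if n is None:
            n = max(e for _, e, _ in runs)
        lab = np.empty(n, dtype=np.int64)
        for a, b, s in runs:
            lab[a:b] = s
        return cls(lab, rate)

    def to_csv(self, path) -> None:
        """Write runs as ``start_sample,end_sample,state`` rows."""
        with open(path, "w") as fh:
            fh.write("start_sample,end_sample,state\n")
            for a, b, s in self.runs():
                fh.write(f"{a},{b},{STATE_NAMES[s]}\n")

    @classmethod
    def from_csv(cls, path, rate: float) -> "StateSequence":
        name_to_id = {n: i for i, n in enumerate(STATE_NAMES)}
        runs = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                a, b, s = line.strip().split(",")
                runs.append((int(a), int(b), name_to_id[s]))
        return cls.from_runs(runs, rate)


@dataclass
class FeatureFrames:
    """Envelope features, ``values`` shaped [n_frames, 4], min-max in [0, 1].

    Columns: homomorphic envelope, Hilbert envelope, wavelet envelope,
    power-spectral-density band feature.
    """

    values: np.ndarray
    rate: float = 50.0

    def __len__(self):
        return len(self.values)


@dataclass
class CycleBoundaries:
    """Non-overlapping ``(start, end)`` index pairs, one per cardiac cycle,
    each spanning a diastole-run start through the following S2-run end."""

    spans: list[tuple[int, int]]

    def __len__(self):
        return len(self.spans)

    def __iter__(self):
        return iter(self.spans)

    def scaled(self, factor: float) -> "CycleBoundaries":
        """Boundaries converted to another sampling resolution."""
        return CycleBoundaries(
            [(int(round(a * factor)), int(round(b * factor))) for a, b in self.spans]
        )


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise SegmentationError("degenerate (constant) feature channel")
    return (x - lo) / (hi - lo)


def extract_features(rec, config: SegConfig | None = None) -> FeatureFrames:
    """Compute the four envelope features of a recording at 50 Hz.

    The signal is band-passed to ``config.band``, decimated to an
    intermediate 1 kHz rate, converted to homomorphic / Hilbert / wavelet
    envelopes and a PSD band feature, decimated to the frame rate, and
    min-max scaled per recording.
    """
    cfg = config or SegConfig()
    x = np.asarray(rec.samples, dtype=np.float64)
    fs = int(rec.fs)
    if len(x) < 2 * fs:
        raise SegmentationError("recording shorter than 2 s")
    if np.ptp(x) == 0:
        raise SegmentationError("degenerate constant input")

    sos = sps.butter(4, cfg.band, btype="bandpass", fs=fs, output="sos")
    xb = sps.sosfiltfilt(sos, x)
    if np.ptp(xb) == 0:
        raise SegmentationError("degenerate input after band-pass")

    # work at an intermediate rate: envelopes carry only low-frequency content
    x1k = sps.resample_poly(xb, cfg.work_fs, fs)
    wfs = cfg.work_fs
    analytic = sps.hilbert(x1k)
    hilbert_env = np.abs(analytic)

    b, a = sps.butter(1, cfg.homomorphic_lpf_hz, btype="low", fs=wfs)
    homomorphic_env = np.exp(sps.filtfilt(b, a, np.log(hilbert_env + 1e-12)))

    scale = pywt.scale2frequency("morl", 1) * wfs / cfg.wavelet_scale_hz
    coef, _ = pywt.cwt(x1k, [scale], "morl")
    wavelet_env = np.abs(coef[0])

    n_frames = int(round(len(x) / fs * cfg.frame_rate))
    step = int(round(wfs / cfg.frame_rate))

    def to_frames(env):
        e = sps.resample_poly(env, 1, step)
        if len(e) < n_frames:
            e = np.pad(e, (0, n_frames - len(e)), mode="edge")
        return e[:n_frames]

    f, t, Sxx = sps.spectrogram(x1k, fs=wfs, nperseg=100, noverlap=80)
    band = (f >= cfg.psd_band[0]) & (f <= cfg.psd_band[1])
    psd = Sxx[band].mean(axis=0)
    frame_t = (np.arange(n_frames) + 0.5) / cfg.frame_rate
    psd_frames = np.interp(frame_t, t, psd)

    cols = [to_frames(homomorphic_env), to_frames(hilbert_env),
            to_frames(wavelet_env), psd_frames]
    values = np.stack([_minmax(c) for c in cols], axis=1)
    return FeatureFrames(values, cfg.frame_rate)


def _autocorr_beat_period(env: np.ndarray, rate: float, lag_range,
                          prominence: float) -> float | None:
    """Beat period (s) from the envelope autocorrelation, or None."""
    e = env - env.mean()
    denom = float(np.dot(e, e))
    if denom <= 0:
        return None
    ac = np.correlate(e, e, mode="full")[len(e) - 1:] / denom
    lo = max(1, int(round(lag_range[0] * rate)))
    hi = min(len(ac) - 1, int(round(lag_range[1] * rate)))
    if hi <= lo:
        return None
    peaks, _ = sps.find_peaks(ac[: hi + 1], prominence=prominence)
    peaks = peaks[peaks >= lo]
    if len(peaks) == 0:
        return None
    best = peaks[np.argmax(ac[peaks])]
    return best / rate


def estimate_heart_rate(features: FeatureFrames,
                        config: SegConfig | None = None) -> float:
    """Heart rate (beats/min) from the homomorphic-envelope autocorrelation.

    The peak lag is searched in ``config.hr_lag_range`` (40-140 bpm); when
    no sufficiently prominent peak exists (e.g. noise-only input) the
    configured prior is returned with a warning.
    """
    cfg = config or SegConfig()
    if len(features) < 5 * features.rate:
        raise SegmentationError("need at least 5 s of frames")
    period = _autocorr_beat_period(features.values[:, 0], features.rate,
                                   cfg.hr_lag_range, cfg.hr_peak_prominence)
    if period is None:
        warnings.warn("no beat-period peak found; falling back to prior heart rate")
        return cfg.hr_fallback_bpm
    return 60.0 / period


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class HsmmModel:
    """Fitted emission and duration model.

    ``weights``/``intercepts`` are the one-vs-rest logistic-regression
    parameters per state; ``dur_mean``/``dur_sd`` are duration moments in
    frames estimated from labelled run lengths.  At decode time the
    systole and diastole means are rescaled so one model generalises over
    heart rate.
    """

    weights: np.ndarray          # [4, n_features]
    intercepts: np.ndarray       # [4]
    dur_mean: np.ndarray         # [4] frames
    dur_sd: np.ndarray           # [4] frames
    frame_rate: float = 50.0
    duration_max_factor: float = 2.0

    def emission_log_probs(self, features: FeatureFrames) -> np.ndarray:
        """Normalized per-frame state log-probabilities, shape [T, 4]."""
        z = features.values @ self.weights.T + self.intercepts
        p = 1.0 / (1.0 + np.exp(-z))
        p = np.clip(p, 1e-12, None)
        p /= p.sum(axis=1, keepdims=True)
        return np.log(p)

    def durations_for_heart_rate(self, heart_rate: float):
        """Per-state ``(dmin, dmax, log_pmf, log_tail)`` at a heart rate.

        S1 and S2 keep their trained means; systole and diastole means are
        scaled by the ratio of the target inter-sound interval to the
        trained one, since those phases absorb RR-interval variation.
        """
        cycle = 60.0 / heart_rate * self.frame_rate
        fixed = self.dur_mean[S1] + self.dur_mean[S2]
        trained_flex = self.dur_mean[SYSTOLE] + self.dur_mean[DIASTOLE]
        ratio = max(cycle - fixed, 2.0) / max(trained_flex, 1e-9)
        means = self.dur_mean.copy()
        means[SYSTOLE] *= ratio
        means[DIASTOLE] *= ratio
        out = []
        for j in range(N_STATES):
            m, sd = float(means[j]), float(self.dur_sd[j])
            dmax = max(2, int(round(self.duration_max_factor * m)))
            d = np.arange(1, dmax + 1, dtype=np.float64)
            logw = -0.5 * ((d - m) / sd) ** 2
            logw -= np.log(np.exp(logw - logw.max()).sum()) + logw.max()
            pmf = np.exp(logw)
            tail = np.cumsum(pmf[::-1])[::-1]
            out.append((1, dmax, logw, np.log(np.clip(tail, 1e-300, None))))
        return out

    def to_json(self, path) -> None:
        obj = {
            "weights": self.weights.tolist(),
            "intercepts": self.intercepts.tolist(),
            "dur_mean": self.dur_mean.tolist(),
            "dur_sd": self.dur_sd.tolist(),
            "frame_rate": self.frame_rate,
            "duration_max_factor": self.duration_max_factor,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "HsmmModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(np.array(obj["weights"]), np.array(obj["intercepts"]),
                   np.array(obj["dur_mean"]), np.array(obj["dur_sd"]),
                   obj["frame_rate"], obj["duration_max_factor"])


def fit_hsmm(training: list[tuple[FeatureFrames, StateSequence]],
             config: SegConfig | None = None) -> HsmmModel:
    """Fit emission and duration models from labelled recordings.

    ``training`` pairs each recording's features with its ground-truth
    state sequence (resampled here to the frame rate if needed).  The fit
    is deterministic.  A state absent from the labels raises, naming it.
    """
    cfg = config or SegConfig()
    feats, labs, run_lengths = [], [], {j: [] for j in range(N_STATES)}
    for features, truth in training:
        frames = truth if truth.rate == features.rate else truth.to_rate(
            features.rate, len(features))
        lab = frames.labels[: len(features)]
        feats.append(features.values[: len(lab)])
        labs.append(lab)
        runs = StateSequence(lab, features.rate).runs()
        # boundary runs are truncated; keep interior durations only
        for a, b, s in runs[1:-1]:
            run_lengths[s].append(b - a)
    X = np.concatenate(feats)
    y = np.concatenate(labs)
    for j in range(N_STATES):
        if not np.any(y == j):
            raise SegmentationError(
                f"state {STATE_NAMES[j]} absent from training labels")

    weights = np.zeros((N_STATES, X.shape[1]))
    intercepts = np.zeros(N_STATES)
    for j in range(N_STATES):
        clf = LogisticRegression(C=100.0, max_iter=2000, tol=1e-8)
        clf.fit(X, (y == j).astype(int))
        weights[j] = clf.coef_[0]
        intercepts[j] = clf.intercept_[0]

    dur_mean = np.empty(N_STATES)
    dur_sd = np.empty(N_STATES)
    for j in range(N_STATES):
        lens = run_lengths[j] or [int(np.sum(y == j) / max(1, len(training)))]
        dur_mean[j] = max(1.0, float(np.mean(lens)))
        dur_sd[j] = max(cfg.min_duration_sd_frames, float(np.std(lens)))
    return HsmmModel(weights, intercepts, dur_mean, dur_sd,
                     cfg.frame_rate, cfg.duration_max_factor)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def viterbi_segment(features: FeatureFrames, model: HsmmModel,
                    heart_rate: float,
                    emission_log_probs: np.ndarray | None = None) -> StateSequence:
    """Maximum a-posteriori state path under the duration-dependent model.

    Implements the extended (run-length) Viterbi recursion for the path
    score defined in the module docstring.  ``emission_log_probs`` may be
    supplied directly (shape [T, 4]) to bypass the logistic emissions,
    which the toy-problem tests use.
    """
    logE = (model.emission_log_probs(features)
            if emission_log_probs is None else np.asarray(emission_log_probs))
    T = logE.shape[0]
    durs = model.durations_for_heart_rate(heart_rate)
    if T < 1:
        raise SegmentationError("empty feature sequence")
    # boundary runs may be truncated, so a path shorter than one full
    # cycle is legal; we only need room for a single state run
    if T < min(d[0] for d in durs):
        raise SegmentationError("too few frames for even one state run")

    cumE = np.concatenate([np.zeros((1, N_STATES)), np.cumsum(logE, axis=0)])
    NEG = -np.inf
    delta = np.full((T, N_STATES), NEG)
    back = np.full((T, N_STATES), -1, dtype=np.int64)   # run length used

    for t in range(T):
        for j in range(N_STATES):
            _, dmax, log_pmf, log_tail = durs[j]
            prev = PREV_STATE[j]
            dmx = min(dmax, t + 1)
            d = np.arange(1, dmx + 1)
            seg = cumE[t + 1, j] - cumE[t + 1 - d, j]
            scores = np.full(dmx, NEG)
            inner = d < t + 1
            if np.any(inner):
                scores[inner] = delta[t - d[inner], prev] + log_pmf[d[inner] - 1] \
                    + seg[inner]
            if dmx == t + 1:
                scores[-1] = log_tail[t] + seg[-1]
            best = int(np.argmax(scores))
            delta[t, j] = scores[best]
            back[t, j] = best + 1

    # final run scored with the duration tail instead of the pmf
    best_score, best_j, best_d = NEG, -1, -1
    for j in range(N_STATES):
        _, dmax, _, log_tail = durs[j]
        prev = PREV_STATE[j]
        for dd in range(1, min(dmax, T) + 1):
            seg = cumE[T, j] - cumE[T - dd, j]
            if dd == T:
                s = log_tail[T - 1] + seg
            else:
                s = delta[T - 1 - dd, prev] + log_tail[dd - 1] + seg
            if s > best_score:
                best_score, best_j, best_d = s, j, dd

    labels = np.empty(T, dtype=np.int64)
    t, j, dd = T - 1, best_j, best_d
    labels[t - dd + 1: t + 1] = j
    t -= dd
    while t >= 0:
        j = PREV_STATE[j]
        dd = int(back[t, j])
        labels[t - dd + 1: t + 1] = j
        t -= dd
    return StateSequence(labels, features.rate if features is not None else
                         model.frame_rate)


def path_log_score(labels, logE: np.ndarray, durs) -> float:
    """Score one explicit labelling under the model semantics.

    Independent of the Viterbi recursion: walks the runs of ``labels``
    and accumulates emission, interior-pmf and boundary-tail terms.
    Returns ``-inf`` for labellings that break the cyclic state order or
    exceed a state's maximum duration.
    """
    labels = np.asarray(labels)
    T = len(labels)
    seq = StateSequence(labels, 1.0)
    runs = seq.runs()
    if not seq.is_cyclic():
        return -np.inf
    score = float(np.sum(logE[np.arange(T), labels]))
    for idx, (a, b, s) in enumerate(runs):
        dmin, dmax, log_pmf, log_tail = durs[s]
        length = b - a
        if length > dmax:
            return -np.inf
        if idx == 0 or idx == len(runs) - 1:
            score += float(log_tail[length - 1])
        else:
            score += float(log_pmf[length - 1])
    return score


# ---------------------------------------------------------------------------
# Cycle extraction
# ---------------------------------------------------------------------------

def extract_cycles(states: StateSequence) -> CycleBoundaries:
    """Cardiac cycles: each diastole-run start through the next S2-run end.

    A cycle requires the full run pattern diastole, S1, systole, S2;
    incomplete leading or trailing fragments are discarded.  An input with
    no complete cycle yields an empty list.
    """
    runs = states.runs()
    spans = []
    for i in range(len(runs) - 3):
        pattern = tuple(runs[i + k][2] for k in range(4))
        if pattern == (DIASTOLE, S1, SYSTOLE, S2):
            spans.append((runs[i][0], runs[i + 3][1]))
    return CycleBoundaries(spans)
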