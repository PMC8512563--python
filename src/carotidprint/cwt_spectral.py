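"""Continuous wavelet transform with generalized Morse wavelets.

The analysis wavelet is the generalized Morse family, frequency-domain
form  Psi(w) ∝ w^beta exp(-w^gamma) for w > 0, with gamma = 3 (the
perfectly symmetric member) and beta chosen so the time-bandwidth
product gamma*beta equals 60 (beta = 20).  The transform is computed as
an FFT filter bank: the padded signal's spectrum is multiplied by each
scale's sampled wavelet (peak-normalized to 2, so a unit-amplitude tone
produces a unit-magnitude ridge) and inverse-transformed; magnitudes are
stored on a geometric (log-spaced) pseudo-frequency grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft


@dataclass
class MorseParams:
    """Generalized Morse wavelet parameters.

    gamma controls symmetry (3 = perfectly symmetric member), beta the
    decay; their product is the time-bandwidth product.
    """

    gamma: float = 3.0
    beta: float = 20.0

    def __post_init__(self):
        if self.gamma <= 0 or self.beta <= (self.gamma - 1) / 2.0:
            raise ValueError("require gamma > 0 and beta > (gamma - 1)/2")

    @property
    def time_bandwidth(self) -> float:
        return self.gamma * self.beta

    @classmethod
    def from_time_bandwidth(cls, time_bandwidth: float = 60.0,
                            gamma: float = 3.0) -> "MorseParams":
        return cls(gamma=gamma, beta=time_bandwidth / gamma)


def morse_peak_frequency(p: MorseParams) -> float:
    """Radian frequency of the wavelet's spectral peak, (beta/gamma)^(1/gamma)."""
    return float((p.beta / p.gamma) ** (1.0 / p.gamma))


@dataclass
class CWTSpectrum:
    """Time x pseudo-frequency magnitude matrix.

    ``magnitude`` has shape [n_freqs, n_samples]; ``freqs`` (Hz) are
    strictly decreasing and log-spaced, all within (0, fs/2].
    """

    magnitude: np.ndarray
    freqs: np.ndarray
    fs: float
    params: MorseParams | None = None

    @property
    def n_samples(self) -> int:
        return self.magnitude.shape[1]

    def save(self, stem) -> None:
        """Persist as ``<stem>.npy`` plus a ``<stem>.json`` sidecar."""
        np.save(f"{stem}.npy", self.magnitude)
        meta = {"freqs": self.freqs.tolist(), "fs": self.fs}
        if self.params is not None:
            meta["morse"] = {"gamma": self.params.gamma, "beta": self.params.beta}
        with open(f"{stem}.json", "w") as fh:
            json.dump(meta, fh, sort_keys=True)

    @classmethod
    def load(cls, stem) -> "CWTSpectrum":
        mag = np.load(f"{stem}.npy")
        with open(f"{stem}.json") as fh:
            meta = json.load(fh)
        params = None
        if "morse" in meta:
            params = MorseParams(**meta["morse"])
        return cls(mag, np.asarray(meta["freqs"]), meta["fs"], params)


def _morse_filter(w: np.ndarray, f_hz: float, p: MorseParams) -> np.ndarray:
    """Sampled Morse wavelet at pseudo-frequency ``f_hz``, peak value 2."""
    wp = morse_peak_frequency(p)
    H = np.zeros_like(w)
    pos = w > 0
    # evaluate in log space: log H = log 2 + beta log(r/wp) - r^gamma + wp^gamma
    r = w[pos] * (wp / (2.0 * np.pi * f_hz))
    logH = (np.log(2.0) + p.beta * (np.log(r) - np.log(wp))
            - r ** p.gamma + wp ** p.gamma)
    H[pos] = np.exp(logH)
    return H


def frequency_grid(f_min: float, f_max: float,
                   voices_per_octave: int) -> np.ndarray:
    """Geometric pseudo-frequency grid, strictly decreasing from f_max."""
    n = int(np.floor(np.log2(f_max / f_min) * voices_per_octave)) + 1
    return f_max * 2.0 ** (-np.arange(n) / voices_per_octave)


def compute_cwt(rec, p: MorseParams | None = None,
                voices_per_octave: int = 10,
                f_min: float = 1.0, f_max: float = 200.0,
                single_precision: bool = False) -> CWTSpectrum:
    """Morse-wavelet CWT magnitude of a recording (or 1-D array with .fs).

    The default analysis band [1, 200] Hz covers the carotid-sound
    structure of interest; pass ``f_max=fs/2`` for the full band.  The
    signal is symmetrically padded by half the longest wavelet support to
    suppress edge energy, and the pad is cropped from the output.
    ``single_precision`` halves memory and runtime at ~1e-7 relative
    accuracy (the batch pipeline uses it; the default is double).
    """
    p = p or MorseParams()
    dtype = np.float32 if single_precision else np.float64
    x = np.asarray(rec.samples, dtype=dtype)
    fs = float(rec.fs)
    if x.size == 0:
        raise ValueError("empty signal")
    if f_min >= f_max:
        raise ValueError("f_min must be below f_max")
    if f_min <= 0 or f_max > fs / 2.0:
        raise ValueError("frequency band outside (0, fs/2]")

    freqs = frequency_grid(f_min, f_max, voices_per_octave)

    # half-support of the slowest wavelet: a few time-domain sigmas
    support_s = 3.0 * np.sqrt(p.beta * p.gamma) / (2.0 * np.pi * freqs[-1])
    pad = int(min(len(x), np.ceil(support_s * fs)))
    xp = np.pad(x, pad, mode="symmetric") if pad > 0 else x
    N = sfft.next_fast_len(len(xp))
    extra = N - len(xp)
    xp = np.pad(xp, (0, extra))
    X = sfft.fft(xp)
    w = 2.0 * np.pi * sfft.fftfreq(N, d=1.0 / fs)

    mag = np.empty((len(freqs), len(x)), dtype=dtype)
    for i, f in enumerate(freqs):
        H = _morse_filter(w, f, p).astype(dtype)
        coef = sfft.ifft(X * H, overwrite_x=True)
        mag[i] = np.abs(coef[pad: pad + len(x)])
    return CWTSpectrum(mag, freqs, fs, p)
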