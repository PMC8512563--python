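"""Per-cycle spectral slices, user fingerprints, and classifier images.

The CWT spectrum of a recording is cut at the cardiac-cycle boundaries,
each slice is resized in time to a fixed 1 s grid (16,000 columns,
nearest-neighbour), and the slices of one user/side are averaged pixel
by pixel into a spectral "fingerprint".  For classification each cycle
slice is log-compressed, min-max normalized, colormapped through a fixed
256-entry RGB lookup table and nearest-neighbour-resized to a
134 x 134 x 3 image with values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cwt_spectral import CWTSpectrum

#: fixed time grid (columns) of a resized cycle: 1 s at 16 kHz
CYCLE_TIME_LEN = 16000
#: square side of a classifier input image
IMAGE_SIZE = 134


@dataclass
class CycleSpectrum:
    """One cardiac cycle's CWT magnitude on a fixed time grid.

    The pipeline resizes every cycle to ``CYCLE_TIME_LEN`` (16,000)
    columns; a different grid may be requested through
    :func:`resize_cycle` for small-scale work.
    """

    magnitude: np.ndarray
    freqs: np.ndarray
    meta: dict = field(default_factory=dict)   # user/device/side/recording/cycle

    def __post_init__(self):
        if self.magnitude.ndim != 2 or self.magnitude.shape[1] == 0:
            raise ValueError("cycle spectrum must be 2-D with time columns")


@dataclass
class Fingerprint:
    """Pixel-wise mean cycle spectrum of one (user, side)."""

    magnitude: np.ndarray
    freqs: np.ndarray
    n_cycles: int
    user_id: str | None = None
    side: str | None = None


@dataclass
class CycleImage:
    """A 134 x 134 x 3 image in [0, 1] plus its class label."""

    pixels: np.ndarray
    label: str


def segment_spectrum(spec: CWTSpectrum, cycles) -> list[np.ndarray]:
    """Column-slice the spectrum at cycle boundaries (sample units)."""
    out = []
    for a, b in cycles:
        if not (0 <= a < b <= spec.n_samples):
            raise ValueError(f"cycle boundary ({a}, {b}) out of range")
        out.append(spec.magnitude[:, a:b].copy())
    return out


def _nn_index_map(n_in: int, n_out: int) -> np.ndarray:
    """Nearest-neighbour source index for each target position:
    ``floor((j + 0.5) * n_in / n_out)``."""
    idx = np.floor((np.arange(n_out) + 0.5) * n_in / n_out).astype(np.int64)
    return np.clip(idx, 0, n_in - 1)


def resize_cycle(mat: np.ndarray, freqs=None, target_len: int = CYCLE_TIME_LEN,
                 meta: dict | None = None) -> CycleSpectrum:
    """Resize a raw cycle matrix in time to ``target_len`` columns.

    Nearest-neighbour: output column j copies input column
    floor((j + 0.5) * w_in / target_len); the frequency axis is untouched.
    """
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise ValueError("cycle matrix must be 2-D with at least one column")
    out = mat[:, _nn_index_map(mat.shape[1], target_len)]
    if freqs is None:
        freqs = np.arange(mat.shape[0])
    return CycleSpectrum(out, np.asarray(freqs), meta or {})


def average_spectra(cycles: list[CycleSpectrum]) -> Fingerprint:
    """Pixel-wise arithmetic mean of same-shape cycle spectra."""
    if len(cycles) == 0:
        raise ValueError("need at least one cycle")
    shape = cycles[0].magnitude.shape
    if any(c.magnitude.shape != shape for c in cycles):
        raise ValueError("cycle spectra differ in shape")
    mean = np.mean([c.magnitude for c in cycles], axis=0)
    meta = cycles[0].meta
    return Fingerprint(mean, cycles[0].freqs, len(cycles),
                       meta.get("user"), meta.get("side"))


def default_colormap_lut(n: int = 256) -> np.ndarray:
    """Fixed heat-style RGB lookup table (black-red-yellow-white), [n, 3].

    Generated analytically so rendered images are bit-stable across
    installations regardless of any plotting library's palette tables.
    """
    t = np.linspace(0.0, 1.0, n)
    r = np.clip(3.0 * t, 0.0, 1.0)
    g = np.clip(3.0 * t - 1.0, 0.0, 1.0)
    b = np.clip(3.0 * t - 2.0, 0.0, 1.0)
    return np.stack([r, g, b], axis=1)


def render_cycle_image(cyc: CycleSpectrum, colormap_lut: np.ndarray | None = None,
                       out_size: int = IMAGE_SIZE,
                       log_eps_rel: float = 1e-3) -> CycleImage:
    """Render a cycle spectrum as a [0, 1] RGB image for the classifier.

    Magnitude is log-compressed as log(1 + m/eps) with eps proportional
    to the cycle's own maximum (making the image amplitude-invariant),
    min-max normalized per image, mapped through the LUT and
    nearest-neighbour resized to ``out_size`` square.  An all-zero cycle
    renders as the colormap's zero colour.
    """
    lut = default_colormap_lut() if colormap_lut is None else np.asarray(colormap_lut)
    m = cyc.magnitude
    mx = float(m.max())
    if mx <= 0:
        v = np.zeros_like(m)
    else:
        v = np.log1p(m / (log_eps_rel * mx))
        lo, hi = float(v.min()), float(v.max())
        v = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    idx = np.minimum((v * len(lut)).astype(np.int64), len(lut) - 1)
    rgb = lut[idx]
    rows = _nn_index_map(rgb.shape[0], out_size)
    cols = _nn_index_map(rgb.shape[1], out_size)
    pixels = rgb[np.ix_(rows, cols)].astype(np.float32)
    return CycleImage(pixels, cyc.meta.get("user", ""))


def save_fingerprint_png(fp: Fingerprint, path,
                         colormap_lut: np.ndarray | None = None) -> None:
    """Export a fingerprint as a PNG for visual inspection."""
    import matplotlib.image

    cyc = CycleSpectrum(fp.magnitude, fp.freqs,
                        {"user": fp.user_id, "side": fp.side})
    img = render_cycle_image(cyc, colormap_lut)
    matplotlib.image.imsave(path, img.pixels)
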