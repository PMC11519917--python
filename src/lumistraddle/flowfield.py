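"""Two-pass FFT cross-correlation PIV with the standard preprocessing chain.

Minimal particle image velocimetry for combined O2/flow (sensPIV) scenes:

1. :func:`piv_preprocess` -- contrast-limited adaptive histogram
   equalization (32 px tiles), a 5 px high-pass (image minus boxcar) and a
   3 px Wiener-style adaptive low-pass, in that order.  This flattens the
   O2-dependent phosphorescence brightness so the correlation sees particle
   texture rather than luminescence gradients.  The O2 pipeline always
   works on the *unpreprocessed* frames; the two chains split after loading.
2. :func:`piv_displacement` -- pass 1 on 64 px interrogation windows at 50%
   overlap gives an integer displacement predictor; pass 2 on 32 px windows
   offsets the search window by the predictor (discrete window deformation)
   and refines with a 3-point Gaussian subpixel fit per axis.
3. :func:`validate_field` -- range-based outlier masking with optional
   local-median replacement.

Displacements are in px per frame interval; convert to velocity with
:func:`displacement_to_velocity` using the pixel pitch and the time between
the correlated frames (pulse separation within a pair, or 1/frame-rate
between pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage import exposure

from .exceptions import InputError, ParameterError

__all__ = [
    "PIVConfig",
    "VelocityField",
    "piv_preprocess",
    "piv_displacement",
    "validate_field",
    "displacement_to_velocity",
]


@dataclass(frozen=True)
class PIVConfig:
    """Interrogation parameters of the two-pass correlator."""

    window_pass1: int = 64
    window_pass2: int = 32
    overlap: float = 0.5
    clahe_tile: int = 32
    highpass_size: int = 5
    wiener_size: int = 3

    def __post_init__(self) -> None:
        for w in (self.window_pass1, self.window_pass2):
            if w < 4 or (w & (w - 1)) != 0:
                raise ParameterError("interrogation windows must be powers of two")
        if self.window_pass2 > self.window_pass1:
            raise ParameterError("pass-2 window must not exceed pass-1 window")
        if not (0 <= self.overlap < 1):
            raise ParameterError("overlap must be in [0, 1)")


@dataclass
class VelocityField:
    """Vector grid from one image pair.

    ``x``/``y`` are window-center coordinates (px); ``u``/``v`` are
    displacements along columns/rows (px per frame interval); ``peak`` is
    the primary correlation peak height and ``peak_ratio`` its ratio to the
    second-highest peak (a detectability measure).  ``valid`` flags vectors
    kept by validation; masked vectors are excluded from statistics.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    peak: np.ndarray
    peak_ratio: np.ndarray
    valid: np.ndarray

    def to_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                "x_px": xx.ravel(),
                "y_px": yy.ravel(),
                "u_px": self.u.ravel(),
                "v_px": self.v.ravel(),
                "peak": self.peak.ravel(),
                "peak_ratio": self.peak_ratio.ravel(),
                "valid": self.valid.ravel().astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def piv_preprocess(image: np.ndarray, config: PIVConfig = PIVConfig()) -> np.ndarray:
    """CLAHE, 5 px high-pass, 3 px adaptive (Wiener) low-pass, in that order."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InputError("image must be 2-D")
    if min(img.shape) < config.clahe_tile:
        raise InputError(
            f"image smaller than the {config.clahe_tile} px CLAHE tile"
        )
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img)  # constant image: no texture to enhance
    img = (img - lo) / (hi - lo)
    img = exposure.equalize_adapthist(img, kernel_size=config.clahe_tile)
    img = img - ndimage.uniform_filter(img, size=config.highpass_size)
    with np.errstate(divide="ignore", invalid="ignore"):
        img = signal.wiener(img, mysize=config.wiener_size)
    return np.nan_to_num(img, nan=0.0)


def _correlate(wa: np.ndarray, wb: np.ndarray):
    """Circular cross-correlation peak of two equal windows.

    Returns (dy, dx) integer displacement of ``wb`` relative to ``wa``, the
    correlation plane, and the peak index.
    """
    a = wa - wa.mean()
    b = wb - wb.mean()
    corr = np.fft.irfft2(
        np.conj(np.fft.rfft2(a)) * np.fft.rfft2(b), s=a.shape
    )
    idx = np.unravel_index(int(np.argmax(corr)), corr.shape)
    n = a.shape[0]
    dy = idx[0] if idx[0] <= n // 2 else idx[0] - n
    dx = idx[1] if idx[1] <= n // 2 else idx[1] - n
    return dy, dx, corr, idx


def _gauss_subpixel(corr: np.ndarray, idx: tuple[int, int]) -> tuple[float, float]:
    """3-point Gaussian peak interpolation along each axis (wrapped)."""
    n0, n1 = corr.shape
    out = []
    for axis, n in ((0, n0), (1, n1)):
        i = idx[axis]
        take = lambda k: corr[(k % n0, idx[1]) if axis == 0 else (idx[0], k % n1)]
        c0, cm, cp = take(i), take(i - 1), take(i + 1)
        if cm <= 0 or cp <= 0 or c0 <= 0 or c0 < cm or c0 < cp:
            out.append(0.0)
            continue
        denom = 2 * np.log(cm) - 4 * np.log(c0) + 2 * np.log(cp)
        out.append(0.0 if denom == 0 else float(
            (np.log(cm) - np.log(cp)) / denom))
    return out[0], out[1]


def _second_peak(corr: np.ndarray, idx: tuple[int, int], excl: int = 2) -> float:
    masked = corr.copy()
    n0, n1 = corr.shape
    ys = [(idx[0] + d) % n0 for d in range(-excl, excl + 1)]
    xs = [(idx[1] + d) % n1 for d in range(-excl, excl + 1)]
    masked[np.ix_(ys, xs)] = -np.inf
    return float(masked.max())


def _grid_positions(extent: int, window: int, step: int) -> np.ndarray:
    """Top-left corners of interrogation windows fully inside the image."""
    return np.arange(0, extent - window + 1, step, dtype=int)


def piv_displacement(
    image_a: np.ndarray,
    image_b: np.ndarray,
    config: PIVConfig = PIVConfig(),
) -> VelocityField:
    """Two-pass FFT cross-correlation displacement field (B relative to A)."""
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("images must share a shape")
    if a.ndim != 2:
        raise InputError("images must be 2-D")
    if min(a.shape) < config.window_pass1:
        raise InputError("interrogation window larger than the image")

    # pass 1: integer predictor on coarse windows
    w1 = config.window_pass1
    step1 = max(1, int(round(w1 * (1 - config.overlap))))
    rows1 = _grid_positions(a.shape[0], w1, step1)
    cols1 = _grid_positions(a.shape[1], w1, step1)
    pred_v = np.zeros((rows1.size, cols1.size))
    pred_u = np.zeros_like(pred_v)
    for i, r in enumerate(rows1):
        for j, c in enumerate(cols1):
            dy, dx, _, _ = _correlate(
                a[r : r + w1, c : c + w1], b[r : r + w1, c : c + w1]
            )
            pred_v[i, j], pred_u[i, j] = dy, dx
    if pred_v.size >= 9:
        pred_v = ndimage.median_filter(pred_v, size=3, mode="nearest")
        pred_u = ndimage.median_filter(pred_u, size=3, mode="nearest")

    # pass 2: refined windows, search window offset by the predictor
    w2 = config.window_pass2
    step2 = max(1, int(round(w2 * (1 - config.overlap))))
    rows2 = _grid_positions(a.shape[0], w2, step2)
    cols2 = _grid_positions(a.shape[1], w2, step2)
    centers1_r = rows1 + w1 / 2
    centers1_c = cols1 + w1 / 2

    def nearest_pred(r, c):
        i = int(np.argmin(np.abs(centers1_r - (r + w2 / 2))))
        j = int(np.argmin(np.abs(centers1_c - (c + w2 / 2))))
        return int(round(pred_v[i, j])), int(round(pred_u[i, j]))

    u = np.zeros((rows2.size, cols2.size))
    v = np.zeros_like(u)
    peak = np.zeros_like(u)
    ratio = np.zeros_like(u)
    for i, r in enumerate(rows2):
        for j, c in enumerate(cols2):
            pv, pu = nearest_pred(r, c)
            rb = min(max(r + pv, 0), a.shape[0] - w2)
            cb = min(max(c + pu, 0), a.shape[1] - w2)
            dy, dx, corr, idx = _correlate(
                a[r : r + w2, c : c + w2], b[rb : rb + w2, cb : cb + w2]
            )
            sy, sx = _gauss_subpixel(corr, idx)
            v[i, j] = (rb - r) + dy + sy
            u[i, j] = (cb - c) + dx + sx
            peak[i, j] = float(corr.max())
            second = _second_peak(corr, idx)
            ratio[i, j] = peak[i, j] / second if second > 0 else np.inf

    return VelocityField(
        x=cols2 + w2 / 2,
        y=rows2 + w2 / 2,
        u=u,
        v=v,
        peak=peak,
        peak_ratio=ratio,
        valid=np.ones_like(u, dtype=bool),
    )


def validate_field(
    field: VelocityField,
    velocity_range: tuple[float, float],
    replace_with_median: bool = True,
) -> VelocityField:
    """Mask vectors whose magnitude falls outside the velocity range.

    ``velocity_range`` is (min, max) speed in px per frame interval.
    Masked vectors are optionally replaced by the median of the valid
    vectors in their 3x3 neighborhood (left unchanged when no valid
    neighbor exists).
    """
    lo, hi = velocity_range
    if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
        raise InputError("velocity range must be finite with max >= min")
    speed = np.hypot(field.u, field.v)
    valid = field.valid & (speed >= lo) & (speed <= hi)
    u, v = field.u.copy(), field.v.copy()
    if replace_with_median:
        for i, j in zip(*np.nonzero(~valid)):
            i0, i1 = max(0, i - 1), min(u.shape[0], i + 2)
            j0, j1 = max(0, j - 1), min(u.shape[1], j + 2)
            sel = valid[i0:i1, j0:j1]
            if sel.any():
                u[i, j] = np.median(field.u[i0:i1, j0:j1][sel])
                v[i, j] = np.median(field.v[i0:i1, j0:j1][sel])
    return VelocityField(
        x=field.x, y=field.y, u=u, v=v,
        peak=field.peak, peak_ratio=field.peak_ratio, valid=valid,
    )


def displacement_to_velocity(
    displacement_px, pixel_pitch_mm: float, dt_us: float
):
    """Convert px displacement to mm/s given pixel pitch and frame interval."""
    if pixel_pitch_mm <= 0 or dt_us <= 0:
        raise ParameterError("pixel pitch and dt must be > 0")
    return np.asarray(displacement_px) * pixel_pitch_mm / (dt_us * 1e-6)
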