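"""Image-pair processing: P and P_N images, calibration, O2 inversion.

The pipeline mirrors the acquisition model pixel by pixel.  From a
dim/bright frame pair the integrated luminescence decay image is
P = I1 - I0 (background cancels) and the normalized image is
P_N = (I1 - I0)/(I1 + I0), which is invariant to multiplicative
illumination and dye-density variation.  A Stern-Volmer calibration
P_N0/P_N = 1 + K_SV*[O2] fitted from known O2 levels then inverts any P_N
image to an O2 map.

Because the apparent K_SV depends on the acquisition timing (pulse length,
interframe time), a :class:`CalibrationCurve` stores a timing fingerprint
and by default refuses to invert images taken with different timing.

Invalid pixels carry reason codes (bit flags) rather than being silently
zeroed: saturation, division guard, negative-P clipping, out-of-range P_N,
non-decaying RLD ratios.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .acquisition import TimingConfig
from .exceptions import (
    CalibrationError,
    InputError,
    ParameterError,
    TimingMismatchError,
)

__all__ = [
    "MASK_SATURATED",
    "MASK_GUARD",
    "MASK_OUT_OF_RANGE",
    "MASK_CLIPPED",
    "MASK_NONPOSITIVE",
    "MASK_NONDECAYING",
    "FramePair",
    "MaskedImage",
    "CalibrationCurve",
    "O2Map",
    "RLDConfig",
    "integrated_decay_image",
    "normalized_decay_image",
    "fit_calibration",
    "o2_from_pn",
    "temporal_moving_average",
    "spatial_median",
    "smooth_series",
    "rld_lifetime",
]

# reason codes for invalid pixels (bit flags, OR-able)
MASK_SATURATED = np.uint8(1)
MASK_GUARD = np.uint8(2)
MASK_OUT_OF_RANGE = np.uint8(4)
MASK_CLIPPED = np.uint8(8)
MASK_NONPOSITIVE = np.uint8(16)
MASK_NONDECAYING = np.uint8(32)


@dataclass
class FramePair:
    """One co-registered dim/bright image pair with its acquisition timing.

    Images are row-major float arrays in camera counts (decoded from the
    integer container); ``full_scale`` is the sensor saturation level used
    for the saturation mask and the default division guard.
    """

    dim: np.ndarray
    bright: np.ndarray
    timing: TimingConfig
    full_scale: float = 65535.0
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dim = np.asarray(self.dim, dtype=float)
        self.bright = np.asarray(self.bright, dtype=float)
        if self.dim.shape != self.bright.shape:
            raise InputError(
                f"frame shapes differ: {self.dim.shape} vs {self.bright.shape}"
            )
        if self.dim.ndim != 2:
            raise InputError("frames must be 2-D")
        if self.saturated is None:
            self.saturated = (self.dim >= self.full_scale) | (
                self.bright >= self.full_scale
            )
        else:
            self.saturated = np.asarray(self.saturated, dtype=bool)
            if self.saturated.shape != self.dim.shape:
                raise InputError("saturation mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dim.shape


@dataclass
class MaskedImage:
    """A float image plus per-pixel invalidity reason codes."""

    values: np.ndarray
    reasons: np.ndarray  # uint8 bit flags; 0 = valid

    @property
    def valid(self) -> np.ndarray:
        return self.reasons == 0


def integrated_decay_image(pair: FramePair) -> MaskedImage:
    """Pixel-wise integrated luminescence decay P = I1 - I0.

    Negative differences (noise) are clipped to zero and flagged; saturated
    pixels are propagated into the mask.
    """
    p = pair.bright - pair.dim
    reasons = np.zeros(pair.shape, dtype=np.uint8)
    clipped = p < 0
    reasons[clipped] |= MASK_CLIPPED
    reasons[pair.saturated] |= MASK_SATURATED
    return MaskedImage(values=np.where(clipped, 0.0, p), reasons=reasons)


def normalized_decay_image(
    pair: FramePair, guard_eps: float | None = None
) -> MaskedImage:
    """Pixel-wise normalized decay P_N = (I1 - I0)/(I1 + I0).

    Pixels whose denominator falls below ``guard_eps`` are masked instead of
    diverging.  The default guard is 1% of the sensor full scale (the images
    are already time-integrated counts).  Scaling both frames by any k > 0
    leaves P_N unchanged up to the guard.
    """
    if guard_eps is None:
        if math.isfinite(pair.full_scale):
            guard_eps = 0.01 * pair.full_scale
        else:
            # noiseless model-unit images: guard only against true zeros
            guard_eps = np.finfo(float).tiny
    if not (guard_eps > 0):
        raise ParameterError("guard_eps must be > 0")
    p_img = integrated_decay_image(pair)
    denom = pair.bright + pair.dim
    guarded = denom < guard_eps
    reasons = p_img.reasons.copy()
    reasons[guarded] |= MASK_GUARD
    with np.errstate(divide="ignore", invalid="ignore"):
        p_n = np.where(guarded, 0.0, p_img.values / np.where(guarded, 1.0, denom))
    return MaskedImage(values=p_n, reasons=reasons)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted Stern-Volmer calibration P_N0/P_N = 1 + K_SV*[O2].

    ``timing_fingerprint`` records (pulse_length, interframe, exposure) of
    the calibration acquisition; :func:`o2_from_pn` refuses to invert
    measurements taken with different timing unless forced.
    """

    pn0: float
    ksv: float
    r_squared: float = float("nan")
    method: str = "least-squares"
    timing_fingerprint: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.pn0 > 0):
            raise CalibrationError("P_N at zero O2 must be > 0")
        if self.ksv < 0:
            raise CalibrationError("K_SV must be >= 0")

    def o2(self, p_n):
        """Invert the curve for P_N values in (0, pn0]."""
        p_n = np.asarray(p_n, dtype=float)
        out = (self.pn0 / p_n - 1.0) / self.ksv
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "pn0": self.pn0,
            "ksv": self.ksv,
            "r_squared": self.r_squared,
            "method": self.method,
            "timing_fingerprint": list(self.timing_fingerprint)
            if self.timing_fingerprint
            else None,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        fp = d.get("timing_fingerprint")
        return cls(
            pn0=d["pn0"],
            ksv=d["ksv"],
            r_squared=d.get("r_squared", float("nan")),
            method=d.get("method", "least-squares"),
            timing_fingerprint=tuple(fp) if fp else None,
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


_ZERO_LEVEL_TOL = 1.0  # % air sat: how close the lowest level must be to 0


def fit_calibration(
    mean_pn,
    o2_levels,
    method: str = "least-squares",
    timing: TimingConfig | None = None,
    monotone_tol: float = 0.0,
) -> CalibrationCurve:
    """Fit a Stern-Volmer calibration from mean P_N values at known O2 levels.

    ``two-point`` solves the curve exactly from the near-zero level and the
    highest level; ``least-squares`` fixes the intercept of P_N0/P_N at 1
    (P_N0 taken from the near-zero level) and fits K_SV by OLS over all
    levels.  A non-monotone P_N-vs-O2 relation beyond ``monotone_tol``
    triggers a warning but still fits.
    """
    pn = np.asarray(mean_pn, dtype=float)
    o2 = np.asarray(o2_levels, dtype=float)
    if pn.shape != o2.shape or pn.ndim != 1:
        raise CalibrationError("mean_pn and o2_levels must be 1-D and aligned")
    if np.unique(o2).size < 2:
        raise CalibrationError("need >= 2 distinct O2 levels")
    if np.any(o2 < 0):
        raise CalibrationError("O2 levels must be non-negative")
    order = np.argsort(o2)
    o2, pn = o2[order], pn[order]
    if o2[0] > _ZERO_LEVEL_TOL:
        raise CalibrationError(
            f"lowest O2 level ({o2[0]}% air sat) is not near zero; a zero "
            "(anoxic) level anchors P_N0"
        )
    if np.any(pn <= 0):
        raise CalibrationError("P_N values must be positive")
    if np.any(np.diff(pn) > monotone_tol):
        warnings.warn(
            "P_N is not monotonically decreasing with O2 beyond the stated "
            "tolerance; fitting anyway",
            stacklevel=2,
        )

    fingerprint = timing.fingerprint if timing is not None else None
    if method == "two-point":
        lo, hi = 0, len(o2) - 1
        # solve pn0 = pn_lo*(1 + K*o2_lo) and pn0 = pn_hi*(1 + K*o2_hi)
        k = (pn[lo] - pn[hi]) / (pn[hi] * o2[hi] - pn[lo] * o2[lo])
        pn0 = pn[lo] * (1.0 + k * o2[lo])
        return CalibrationCurve(
            pn0=float(pn0), ksv=float(k), r_squared=1.0,
            method="two-point", timing_fingerprint=fingerprint,
        )
    if method == "least-squares":
        pn0 = float(pn[0])
        y = pn0 / pn - 1.0
        sxx = float(np.sum(o2 * o2))
        k = float(np.sum(o2 * y) / sxx)
        resid = y - k * o2
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot <= 1e-300 else 1.0 - float(np.sum(resid**2)) / ss_tot
        return CalibrationCurve(
            pn0=pn0, ksv=k, r_squared=r2,
            method="least-squares", timing_fingerprint=fingerprint,
        )
    raise CalibrationError(f"unknown calibration method {method!r}")


@dataclass
class O2Map:
    """A 2-D O2 field (% air saturation) plus validity reason codes."""

    o2: np.ndarray
    reasons: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.reasons == 0


def o2_from_pn(
    p_n: MaskedImage | np.ndarray,
    cal: CalibrationCurve,
    timing: TimingConfig | None = None,
    force: bool = False,
) -> O2Map:
    """Invert a P_N image to O2 through a fitted calibration curve.

    Pixels with P_N above P_N0 (apparently less quenched than the anoxic
    calibration) are reported as 0 with the out-of-range bit set; masked
    input pixels stay masked.  If both the curve and the measurement carry
    timing information they must match unless ``force`` is set.
    """
    if (
        not force
        and timing is not None
        and cal.timing_fingerprint is not None
        and tuple(cal.timing_fingerprint) != timing.fingerprint
    ):
        raise TimingMismatchError(
            f"calibration timing {cal.timing_fingerprint} does not match "
            f"measurement timing {timing.fingerprint}; pass force=True to "
            "override"
        )
    if cal.ksv <= 0:
        raise CalibrationError("K_SV must be > 0 to invert P_N to O2")
    if isinstance(p_n, MaskedImage):
        values, reasons = p_n.values, p_n.reasons.copy()
    else:
        values = np.asarray(p_n, dtype=float)
        reasons = np.zeros(values.shape, dtype=np.uint8)

    nonpos = values <= 0
    reasons[nonpos] |= MASK_NONPOSITIVE
    over = (values > cal.pn0) & ~nonpos
    reasons[over] |= MASK_OUT_OF_RANGE

    safe = np.where(nonpos, 1.0, values)
    o2 = (cal.pn0 / safe - 1.0) / cal.ksv
    o2 = np.where(nonpos | over, 0.0, o2)
    return O2Map(o2=o2, reasons=reasons)


def temporal_moving_average(stack: np.ndarray) -> np.ndarray:
    """Centered pixel-wise 3-point moving average along axis 0.

    The first and last frames average over the neighbors that exist
    (2 points instead of 3).
    """
    stack = np.asarray(stack, dtype=float)
    out = np.empty_like(stack)
    n = stack.shape[0]
    for t in range(n):
        lo, hi = max(0, t - 1), min(n, t + 2)
        out[t] = stack[lo:hi].mean(axis=0)
    return out


def spatial_median(stack: np.ndarray) -> np.ndarray:
    """Per-frame 3x3 median filter with edge replication."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return ndimage.median_filter(stack, size=3, mode="nearest")
    return ndimage.median_filter(stack, size=(1, 3, 3), mode="nearest")


def smooth_series(
    stack: np.ndarray, invalid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Temporal 3-point mean, then per-frame 3x3 spatial median.

    ``stack`` is (T, H, W) -- O2 maps or P_N images.  ``invalid`` is an
    optional boolean stack of the same shape; it propagates by majority at
    each stage: a temporally averaged pixel is invalid when most of its
    temporal samples were, and a median-filtered pixel is invalid when most
    of its 3x3 neighborhood is (an isolated bad pixel is repaired by the
    median, a bad patch is not).  For stacks shorter than 3 frames the
    temporal step is skipped with a warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise InputError("stack must be 3-D (time, rows, cols)")
    short = stack.shape[0] < 3
    if short:
        warnings.warn(
            "stack shorter than 3 frames: temporal smoothing skipped",
            stacklevel=2,
        )
        smoothed = spatial_median(stack)
    else:
        smoothed = spatial_median(temporal_moving_average(stack))
    if invalid is None:
        return smoothed, None
    frac = np.asarray(invalid, dtype=float)
    if not short:
        frac = (temporal_moving_average(frac) > 0.5).astype(float)
    frac = ndimage.uniform_filter(frac, size=(1, 3, 3), mode="nearest")
    return smoothed, frac > 0.5


@dataclass(frozen=True)
class RLDConfig:
    """Two-gate rapid-lifetime-determination timing.

    ``gate1_delay`` (t1) and ``gate2_delay`` (t2) are the delays of the two
    gated exposures after the end of the excitation pulse, in microseconds.
    The gate separation t1 - t2 must be non-zero.
    """

    gate1_delay: float
    gate2_delay: float

    def __post_init__(self) -> None:
        if self.gate1_delay == self.gate2_delay:
            raise ParameterError("gate separation must be non-zero")

    @property
    def separation(self) -> float:
        return self.gate1_delay - self.gate2_delay


def rld_lifetime(
    gate1: np.ndarray, gate2: np.ndarray, config: RLDConfig
) -> MaskedImage:
    """Two-gate lifetime image tau = (t1 - t2)/ln(F2/F1).

    Assumes a monoexponential decay sampled by two gated images F1 (delay
    t1) and F2 (delay t2).  Pixels with non-positive intensities, equal
    gate values (infinite lifetime) or a non-decaying ratio are masked.
    """
    f1 = np.asarray(gate1, dtype=float)
    f2 = np.asarray(gate2, dtype=float)
    if f1.shape != f2.shape:
        raise InputError("gate images must share a shape")
    reasons = np.zeros(f1.shape, dtype=np.uint8)
    nonpos = (f1 <= 0) | (f2 <= 0)
    reasons[nonpos] |= MASK_NONPOSITIVE
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(nonpos, 1.0, f2 / f1)
        logr = np.log(ratio)
        tau = np.where(logr != 0, (config.gate1_delay - config.gate2_delay)
                       / np.where(logr != 0, logr, 1.0), np.nan)
    flat = ~nonpos & (logr == 0)
    reasons[flat] |= MASK_NONDECAYING
    nondecay = ~nonpos & ~flat & (tau <= 0)
    reasons[nondecay] |= MASK_NONDECAYING
    tau = np.where(reasons == 0, tau, np.nan)
    return MaskedImage(values=tau, reasons=reasons)
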