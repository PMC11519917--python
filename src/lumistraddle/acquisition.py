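"""Closed-form frame-straddling integrals and timing design.

Frame straddling fires one excitation pulse at the very end of camera frame
1 and the next pulse at the very start of frame 2.  Frame 1 therefore
records only the excitation rise (the decay is cut off when its exposure
ends), while frame 2 records the rise of its own pulse *plus* the full
luminescence decay in the remaining exposure -- and, if the interframe gap
is short relative to the lifetime, a carry-over tail of the first pulse's
decay.  With the rise/decay kinetics of :mod:`lumistraddle.kinetics` every
window integral has a closed form:

    I0 = F0*[tau_L - tau_p*(1 - exp(-tau_L/tau_p))]           (dim frame)
    F1 = Fm*tau_d*(1 - exp(-W/tau_d))                         (decay, W = tau_E - tau_L)
    C  = Fm*tau_d*exp(-tau_c/tau_d)*(1 - exp(-tau_E/tau_d))   (carry-over)
    I1 = I0 + F1 + C                                          (bright frame)

The integrated luminescence decay P = I1 - I0 = F1 + C is proportional to
the lifetime and cancels any background common to both frames.  The
normalized integrated luminescence decay

    P_N = (I1 - I0) / (I1 + I0)

is additionally invariant to multiplicative illumination and dye-density
variations, which is what makes pixel-wise calibration possible under
inhomogeneous excitation.  The same normalization is used for model
predictions, calibration and measurement (it is an internal constant of the
module, not a user option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate

from .camera import NoiseModel
from .exceptions import CalibrationError, NumericsError, ParameterError, TimingError
from .kinetics import KineticsParams, emission_timecourse, lifetime_from_o2

__all__ = [
    "TimingConfig",
    "DecayIntegrals",
    "PredictedCalibration",
    "TimingScanResult",
    "frame_integrals",
    "frame_integrals_numeric",
    "predicted_calibration",
    "timing_scan",
    "recommend_pulse_window",
    "SNR_CAP",
]

#: sentinel reported when the Monte-Carlo P_N spread is exactly zero
SNR_CAP = 1e6


@dataclass(frozen=True)
class TimingConfig:
    """Acquisition timing: pulse length, exposure and interframe time (us).

    ``exposure`` may be ``math.inf`` for idealized complete decay capture.
    ``frame1_decay_overlap`` models trigger skew where frame 1 keeps
    exposing for a short duration after its pulse ends (default 0: the dim
    frame records no decay, matching the nominal trigger scheme).
    """

    pulse_length: float
    exposure: float = math.inf
    interframe: float = 6.0
    frame1_decay_overlap: float = 0.0
    carry_over_enabled: bool = False

    def __post_init__(self) -> None:
        if not (self.pulse_length > 0):
            raise TimingError("pulse_length must be > 0")
        if self.pulse_length > self.exposure:
            raise TimingError(
                f"pulse_length {self.pulse_length} exceeds exposure {self.exposure}"
            )
        if not (self.interframe > 0):
            raise TimingError("interframe must be > 0")
        if self.frame1_decay_overlap < 0:
            raise TimingError("frame1_decay_overlap must be >= 0")

    @property
    def decay_capture_window(self) -> float:
        """Duration of frame-2 exposure remaining after its pulse (us)."""
        return self.exposure - self.pulse_length

    @property
    def pulse_separation(self) -> float:
        """Time between the starts of the two straddled pulses (us)."""
        return self.pulse_length + self.frame1_decay_overlap + self.interframe

    @property
    def fingerprint(self) -> tuple[float, float, float]:
        """(pulse_length, interframe, exposure) identifying the acquisition."""
        return (self.pulse_length, self.interframe, self.exposure)


@dataclass(frozen=True)
class DecayIntegrals:
    """Window integrals of one frame pair (intensity*us; p_n dimensionless)."""

    i0: float
    i1: float
    decay: float  # F1, frame-2 decay integral
    carry_over: float
    p: float
    p_n: float


def _integral_arrays(tau_d, tau_p, f0, background, timing: TimingConfig):
    """Vectorized closed-form frame integrals.

    All kinetic arguments broadcast; returns (i0, i1, f1, c) arrays.  The
    per-pulse background dose background*exposure is added to both frames
    (it cancels exactly in P).
    """
    tau_d = np.asarray(tau_d, dtype=float)
    tau_p = np.asarray(tau_p, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    background = np.asarray(background, dtype=float)
    if np.any(tau_d <= 0) or np.any(tau_p <= 0):
        raise ParameterError("lifetimes must be > 0")
    tl = timing.pulse_length
    w = timing.decay_capture_window
    if w < 0:
        raise TimingError("negative decay capture window")
    if np.any(background > 0) and not math.isfinite(timing.exposure):
        raise TimingError(
            "ambient background requires a finite exposure (background dose "
            "background*exposure would be infinite)"
        )

    fm = f0 * -np.expm1(-tl / tau_p)  # peak emission rate
    rise = f0 * tl - tau_p * fm  # integral of the rise over the pulse
    overlap = timing.frame1_decay_overlap
    # decay recorded by frame 1 when its exposure outlasts the pulse
    ov = fm * tau_d * -np.expm1(-overlap / tau_d)

    f1 = fm * tau_d * -np.expm1(-w / tau_d) if w > 0 else np.zeros_like(fm)
    if timing.carry_over_enabled:
        # tail of the *previous* pulse entering frame 2, delayed by the
        # interframe gap (plus any frame-1 overlap already recorded)
        delay = timing.interframe + overlap
        span = -np.expm1(-timing.exposure / tau_d) if math.isfinite(
            timing.exposure
        ) else 1.0
        c = fm * tau_d * np.exp(-delay / tau_d) * span
    else:
        c = np.zeros_like(fm)

    bg = background * (timing.exposure if math.isfinite(timing.exposure) else 0.0)
    i0 = rise + ov + bg
    # P is formed algebraically so the common background and rise cancel
    # exactly (bitwise), and I1 = I0 + P stays self-consistent
    p = f1 + c - ov
    i1 = i0 + p
    return i0, i1, f1, c, p


def _normalize(p, denom):
    """The P_N normalization shared by model, calibration and measurement."""
    return p / denom


def _pack(i0, i1, f1, c, p) -> DecayIntegrals:
    denom = i0 + i1
    p_n = _normalize(p, denom) if denom > 0 else 0.0
    return DecayIntegrals(
        i0=float(i0), i1=float(i1), decay=float(f1), carry_over=float(c),
        p=float(p), p_n=float(p_n),
    )


def frame_integrals(kinetics: KineticsParams, timing: TimingConfig) -> DecayIntegrals:
    """Closed-form dim/bright frame integrals for one pulse pair.

    The pulse duration is taken from ``timing`` (the synchronizer defines
    the excitation window); ``kinetics`` supplies F0, tau_p, tau_d and the
    background rate.
    """
    i0, i1, f1, c, p = _integral_arrays(
        kinetics.decay_lifetime,
        kinetics.rise_time,
        kinetics.f0,
        kinetics.background,
        timing,
    )
    return _pack(i0, i1, f1, c, p)


def frame_integrals_numeric(
    kinetics: KineticsParams, timing: TimingConfig, rtol: float = 1e-10
) -> DecayIntegrals:
    """Same quantities by adaptive quadrature of the emission timecourse.

    Independent oracle for :func:`frame_integrals`; requires a finite
    exposure.  Intended for tests and verification, not production use.
    """
    if not math.isfinite(timing.exposure):
        raise NumericsError("numeric integrals require a finite exposure")
    tl = timing.pulse_length
    d = timing.frame1_decay_overlap
    te = timing.exposure
    params = replace(
        kinetics, excitation_start=0.0, excitation_stop=tl
    )

    def emit(t):
        return float(emission_timecourse(params, np.atleast_1d(t))[0])

    def _quad(a, b, pts=()):
        val, err = integrate.quad(
            emit, a, b, points=[p for p in pts if a < p < b] or None,
            limit=400, epsrel=rtol,
        )
        if not math.isfinite(val):
            raise NumericsError("quadrature failed to converge")
        return val

    # frame 1 spans [tl + d - te, tl + d]; the timecourse returns the pure
    # background before t=0, so one quadrature over the window is correct
    i0 = _quad(tl + d - te, tl + d, pts=(0.0, tl))

    # frame 2: its own pulse starts at the frame start; integrate the same
    # pulse shape over [0, te] = rise + captured decay
    i1_own = _quad(0.0, te, pts=(tl,))
    # decay part of frame 2's own pulse, net of the background dose
    f1 = _quad(tl, te) - kinetics.background * (te - tl)

    c = 0.0
    if timing.carry_over_enabled:
        fm = params.peak_emission
        delay = timing.interframe + d

        def tail(t):
            return fm * math.exp(-(delay + t) / kinetics.decay_lifetime)

        c, _ = integrate.quad(tail, 0.0, te, limit=400, epsrel=rtol)

    i1 = i1_own + c
    return _pack(i0, i1, f1, c, i1 - i0)


@dataclass(frozen=True)
class PredictedCalibration:
    """Model-predicted calibration curve over an O2 grid."""

    o2: np.ndarray
    i0: np.ndarray
    i1: np.ndarray
    p: np.ndarray
    p_n: np.ndarray
    pn0: float
    ksv_apparent: float
    r_squared: float


def _fit_ratio_slope(o2: np.ndarray, ratio: np.ndarray) -> tuple[float, float]:
    """OLS fit of ratio = 1 + K*o2 with the intercept fixed at 1.

    Returns (K, R^2); R^2 is computed on the ratio residuals and defined as
    1.0 for a perfectly flat (unquenched) response.
    """
    y = ratio - 1.0
    sxx = float(np.sum(o2 * o2))
    if sxx == 0:
        raise CalibrationError("degenerate O2 grid (all zeros)")
    k = float(np.sum(o2 * y) / sxx)
    resid = y - k * o2
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot <= 1e-300 else 1.0 - ss_res / ss_tot
    return k, r2


def predicted_calibration(
    sensor,
    timing: TimingConfig,
    o2_grid,
    *,
    f0: float = 1.0,
    background: float = 0.0,
    rise_equals_decay: bool = True,
    rise_time: float | None = None,
) -> PredictedCalibration:
    """Evaluate the frame-straddling model across an O2 grid.

    For each grid point the sensor law converts O2 to a lifetime, the frame
    integrals are evaluated, and the apparent Stern-Volmer constant is
    fitted from P_N0/P_N = 1 + K_app*O2 (ordinary least squares, intercept
    fixed at 1).  P_N0 is always evaluated at O2 = 0 from the law itself.

    By default the rise time tracks the decay lifetime at every O2 level
    (single-population kinetics); pass ``rise_equals_decay=False`` with an
    explicit ``rise_time`` to decouple them.
    """
    o2 = np.asarray(o2_grid, dtype=float)
    if o2.size < 2 or np.unique(o2).size < 2:
        raise CalibrationError("o2_grid must contain at least 2 distinct levels")
    if np.any(o2 < 0):
        raise CalibrationError("o2_grid must be non-negative")

    tau = np.asarray(lifetime_from_o2(sensor, o2), dtype=float)
    tau_p = tau if rise_equals_decay else float(rise_time)
    i0, i1, f1, c, p = _integral_arrays(tau, tau_p, f0, background, timing)
    p_n = _normalize(p, i0 + i1)

    tau0 = float(lifetime_from_o2(sensor, 0.0))
    tp0 = tau0 if rise_equals_decay else float(rise_time)
    i0z, i1z, _, _, pz = _integral_arrays(tau0, tp0, f0, background, timing)
    pn0 = float(_normalize(pz, i0z + i1z))

    if np.any(p_n <= 0):
        raise CalibrationError("P_N is non-positive on the grid; cannot fit")
    k, r2 = _fit_ratio_slope(o2, pn0 / p_n)
    return PredictedCalibration(
        o2=o2, i0=i0, i1=i1, p=p, p_n=p_n, pn0=pn0,
        ksv_apparent=k, r_squared=r2,
    )


@dataclass(frozen=True)
class TimingScanResult:
    """Apparent K_SV and SNR as a function of pulse length."""

    pulse_lengths: np.ndarray
    ksv_apparent: np.ndarray
    snr: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pulse_length_us": self.pulse_lengths,
                "ksv_apparent": self.ksv_apparent,
                "snr": self.snr,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def timing_scan(
    sensor,
    timing: TimingConfig,
    pulse_grid,
    noise: NoiseModel,
    *,
    photon_budget: float | None = None,
    replicates: int = 8,
    seed: int = 0,
    o2: float = 0.0,
    region_shape: tuple[int, int] = (64, 64),
    calibration_o2=(0.0, 25.0, 50.0, 75.0, 100.0),
    snr_cap: float = SNR_CAP,
) -> TimingScanResult:
    """Scan pulse lengths: apparent K_SV (noiseless) and Monte-Carlo SNR.

    For each pulse length the apparent Stern-Volmer constant is computed
    from the noiseless model calibration, and the SNR of P_N is estimated
    as mean/sd over ``replicates`` noisy renders of a homogeneous
    ``region_shape`` region held at the fixed ``o2`` level (default 0:
    the anoxic, brightest-P_N condition).  ``photon_budget`` overrides the
    noise model's photon scale (expected counts per unit of noiseless
    integrated signal).  Deterministic for a given seed.
    """
    if replicates < 2:
        raise ParameterError("replicates must be >= 2")
    scale = noise.photon_scale if photon_budget is None else photon_budget
    if scale <= 0:
        raise ParameterError("photon budget must be > 0")
    nm = replace(noise, photon_scale=scale)
    pulses = np.asarray(pulse_grid, dtype=float)
    if pulses.size == 0:
        raise ParameterError("pulse grid is empty")
    if np.any(pulses <= 0) or np.any(pulses > timing.exposure):
        raise TimingError("pulse grid must lie within (0, exposure]")

    rng = np.random.default_rng(seed)
    tau = float(lifetime_from_o2(sensor, o2))
    npix = replicates * int(np.prod(region_shape))
    ksv = np.empty_like(pulses)
    snr = np.empty_like(pulses)
    for i, pl in enumerate(pulses):
        t_i = replace(timing, pulse_length=float(pl))
        ksv[i] = predicted_calibration(sensor, t_i, calibration_o2).ksv_apparent
        ints = frame_integrals(KineticsParams(decay_lifetime=tau), t_i)
        dim = nm.apply(np.full(npix, ints.i0), rng)
        bright = nm.apply(np.full(npix, ints.i1), rng)
        # clipped pixels carry no usable signal: exclude them, and report an
        # unusable pulse length (SNR 0) when saturation dominates
        ok = (dim < nm.full_scale) & (bright < nm.full_scale) & (dim + bright > 0)
        if ok.sum() < max(2, npix // 100):
            snr[i] = 0.0
            continue
        p_n = (bright[ok] - dim[ok]) / (dim[ok] + bright[ok])
        sd = float(p_n.std())
        snr[i] = min(abs(float(p_n.mean())) / sd, snr_cap) if sd > 0 else snr_cap
    return TimingScanResult(pulse_lengths=pulses, ksv_apparent=ksv, snr=snr)


def recommend_pulse_window(
    scan: TimingScanResult,
    snr_threshold: float = 20.0,
    ksv_stability: float = 0.15,
) -> tuple[float, float] | None:
    """Largest contiguous pulse interval with SNR >= threshold and stable K_SV.

    Stability means the apparent K_SV lies within ``ksv_stability``
    (relative) of its plateau value, taken as the value at the longest
    pulse (where incomplete excitation no longer biases it).  Returns
    (min_pulse, max_pulse) or ``None`` when no pulse qualifies.
    """
    order = np.argsort(scan.pulse_lengths)
    pulses = scan.pulse_lengths[order]
    snr = scan.snr[order]
    ksv = scan.ksv_apparent[order]
    plateau = ksv[-1]
    if plateau == 0:
        ok_k = ksv == 0
    else:
        ok_k = np.abs(ksv - plateau) <= ksv_stability * abs(plateau)
    ok = (snr >= snr_threshold) & ok_k
    if not ok.any():
        return None
    best = (0, -1)  # (length, start)
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best[0]:
                best = (i - start, start)
            start = None
    length, start = best
    return float(pulses[start]), float(pulses[start + length - 1])
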