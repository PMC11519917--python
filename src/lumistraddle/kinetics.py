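"""Luminophore excitation/decay kinetics and lifetime-vs-O2 laws.

The emission model is a single excited-state population driven by a
rectangular excitation pulse.  While the pulse is on, the population (and
hence the emitted intensity) relaxes toward its equilibrium value F0 with a
characteristic rise time tau_p::

    F(t) = B + F0 * (1 - exp(-(t - t0)/tau_p)),    t0 <= t <= t1

which solves dN/dt = (F0 - N)/tau_p.  When the pulse switches off at t1 the
signal decays monoexponentially with the luminescence lifetime tau_d from
the peak it reached::

    F(t) = B + Fm * exp(-(t - t1)/tau_d),          t > t1
    Fm   = F0 * (1 - exp(-(t1 - t0)/tau_p))

B is a constant ambient background rate (non-decaying fluorescence plus any
stray light); it is additive at all times, so the timecourse is continuous
at t1 and a pair of equal-length camera exposures collects identical
background doses that cancel in the frame difference.

For an O2-quenched phosphor the lifetime follows the Stern-Volmer relation
tau_d0 / tau_d = 1 + K_SV * [O2], with [O2] in % air saturation.  All times
are in microseconds throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InputError, ParameterError

__all__ = [
    "KineticsParams",
    "SternVolmerLaw",
    "EmpiricalLifetimeLaw",
    "emission_timecourse",
    "lifetime_from_o2",
    "o2_from_lifetime",
]


@dataclass(frozen=True)
class KineticsParams:
    """Parameters of the rectangular-pulse excitation/decay model.

    Parameters
    ----------
    f0 : equilibrium emission rate (intensity per microsecond, arbitrary
        scale; this is the plateau reached under long excitation).
    decay_lifetime : luminescence lifetime tau_d in microseconds.
    rise_time : excitation equilibration time tau_p in microseconds.
        Defaults to ``decay_lifetime`` -- for a single excited-state
        population the approach to equilibrium and the decay share the same
        kinetics -- but remains independently settable.
    excitation_start, excitation_stop : pulse window [t0, t1] in us.
    background : constant ambient emission rate B (intensity per us).
    """

    f0: float = 1.0
    decay_lifetime: float = 62.0
    rise_time: float | None = None
    excitation_start: float = 0.0
    excitation_stop: float = 80.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.rise_time is None:
            object.__setattr__(self, "rise_time", self.decay_lifetime)
        if not (self.rise_time > 0):
            raise ParameterError(f"rise_time must be > 0, got {self.rise_time}")
        if not (self.decay_lifetime > 0):
            raise ParameterError(
                f"decay_lifetime must be > 0, got {self.decay_lifetime}"
            )
        if not (self.excitation_stop > self.excitation_start):
            raise ParameterError(
                "excitation_stop must exceed excitation_start "
                f"({self.excitation_stop} <= {self.excitation_start})"
            )
        if self.f0 < 0:
            raise ParameterError(f"f0 must be >= 0, got {self.f0}")
        if self.background < 0:
            raise ParameterError(f"background must be >= 0, got {self.background}")

    @property
    def pulse_duration(self) -> float:
        return self.excitation_stop - self.excitation_start

    @property
    def peak_emission(self) -> float:
        """Emission rate Fm reached at the end of the pulse (0 <= Fm <= F0)."""
        return self.f0 * -math.expm1(-self.pulse_duration / self.rise_time)


def emission_timecourse(params: KineticsParams, times) -> np.ndarray:
    """Evaluate the pulse-driven emission rate at the given time points.

    ``times`` must be sorted ascending (microseconds).  Returns the emitted
    intensity per unit time at each point; continuous at the pulse edge t1.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise InputError("times must be a 1-D sequence")
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise InputError("times must be sorted ascending")
    t0, t1 = params.excitation_start, params.excitation_stop
    out = np.full(t.shape, params.background, dtype=float)
    rising = (t >= t0) & (t <= t1)
    out[rising] += params.f0 * -np.expm1(-(t[rising] - t0) / params.rise_time)
    decaying = t > t1
    out[decaying] += params.peak_emission * np.exp(
        -(t[decaying] - t1) / params.decay_lifetime
    )
    return out


@dataclass(frozen=True)
class SternVolmerLaw:
    """Collisional-quenching lifetime law tau(O2) = tau_d0 / (1 + K_SV*O2).

    ``unquenched_lifetime`` is tau_d0 in microseconds; ``quenching_constant``
    K_SV is per % air saturation.  ``from_endpoints`` builds the law from
    the two lifetimes a sensor datasheet usually quotes (at 0% and at some
    reference saturation, normally 100%).
    """

    unquenched_lifetime: float = 62.0
    quenching_constant: float = 0.018182

    def __post_init__(self) -> None:
        if not (self.unquenched_lifetime > 0):
            raise ParameterError("unquenched_lifetime must be > 0")
        if self.quenching_constant < 0:
            raise ParameterError("quenching_constant must be >= 0")

    @classmethod
    def from_endpoints(
        cls, tau_zero: float, tau_ref: float, o2_ref: float = 100.0
    ) -> "SternVolmerLaw":
        if not (0 < tau_ref <= tau_zero):
            raise ParameterError("need 0 < tau_ref <= tau_zero")
        return cls(tau_zero, (tau_zero / tau_ref - 1.0) / o2_ref)

    def lifetime(self, o2):
        o2 = np.asarray(o2, dtype=float)
        if np.any(o2 < 0):
            raise InputError("O2 must be >= 0 % air saturation")
        out = self.unquenched_lifetime / (1.0 + self.quenching_constant * o2)
        return float(out) if out.ndim == 0 else out

    def o2(self, tau):
        """Invert the law; defined for 0 < tau <= tau_d0 and K_SV > 0."""
        if self.quenching_constant == 0:
            raise ParameterError("K_SV = 0: O2 is undefined from lifetime")
        tau = np.asarray(tau, dtype=float)
        if np.any(tau <= 0):
            raise InputError("lifetime must be > 0")
        if np.any(tau > self.unquenched_lifetime * (1 + 1e-12)):
            raise InputError(
                "lifetime exceeds the unquenched lifetime (super-unquenched signal)"
            )
        out = (self.unquenched_lifetime / tau - 1.0) / self.quenching_constant
        out = np.maximum(out, 0.0)
        return float(out) if out.ndim == 0 else out


#: unit interpretations for :class:`EmpiricalLifetimeLaw`
RATE_PER_MS = "rate_per_ms"
INVERSE_LIFETIME_US = "inverse_lifetime_us"


@dataclass(frozen=True)
class EmpiricalLifetimeLaw:
    """Literal evaluation of the fitted planar-optode lifetime expression.

    The published fit reads ``tau_d = 1/(a*exp(-[O2]/b) + c)`` with
    a = 35.77, b = 56.3 % air sat, c = 22.63.  The units of the
    parenthesised expression were not stated, and evaluated literally the
    expression *increases* with O2 -- inconsistent with the 62 -> 22 us
    quenching of the same dye.  It is therefore evaluated exactly as printed
    behind a unit-interpretation flag rather than silently corrected:

    - ``rate_per_ms`` (default): the denominator is a decay rate per
      millisecond; the lifetime is returned in microseconds
      (``1000 / denominator``).
    - ``inverse_lifetime_us``: the denominator is an inverse lifetime in
      1/us (``1 / denominator``).
    """

    amplitude: float = 35.77
    scale: float = 56.3
    offset: float = 22.63
    interpretation: str = RATE_PER_MS

    def __post_init__(self) -> None:
        if self.interpretation not in (RATE_PER_MS, INVERSE_LIFETIME_US):
            raise ParameterError(
                f"unknown unit interpretation {self.interpretation!r}"
            )
        if self.scale <= 0:
            raise ParameterError("scale must be > 0")

    def lifetime(self, o2):
        o2 = np.asarray(o2, dtype=float)
        if np.any(o2 < 0):
            raise InputError("O2 must be >= 0 % air saturation")
        denom = self.amplitude * np.exp(-o2 / self.scale) + self.offset
        factor = 1000.0 if self.interpretation == RATE_PER_MS else 1.0
        out = factor / denom
        return float(out) if out.ndim == 0 else out


def lifetime_from_o2(law, o2):
    """Lifetime (us) at the given O2 level (% air saturation).

    ``law`` is a :class:`SternVolmerLaw` or :class:`EmpiricalLifetimeLaw`
    (anything exposing ``lifetime``).
    """
    return law.lifetime(o2)


def o2_from_lifetime(law: SternVolmerLaw, tau):
    """O2 (% air saturation) from a lifetime; exact inverse of the SV law."""
    return law.o2(tau)
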