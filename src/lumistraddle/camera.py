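"""Camera noise model and named presets.

The forward model produces noiseless integrated signals in intensity*us.
:class:`NoiseModel` converts them to camera counts: Poisson shot noise on
the expected counts (``photon_scale`` counts per unit of noiseless signal),
additive Gaussian read noise, rounding to integer counts and clipping at
full scale.  ``photon_scale`` is the single interpretable photon-budget
knob: doubling it doubles the expected counts everywhere.

The default model is a generic 16-bit scientific camera whose photon scale
keeps a 61-500 us pulse scan inside the ADC range while placing the anoxic
80 us condition in the SNR ~ 20 regime; both numbers are synthetic
conventions (no instrument noise figures exist for this method) and are
documented as such.  The presets emulate the two camera classes used for
frame straddling in practice -- an 8-bit double-frame PIV camera with a
62 us interframe time and a 12-bit high-speed camera with a 10 us
interframe time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

__all__ = ["NoiseModel", "CameraPreset", "CAMERA_PRESETS"]

_ALLOWED_DEPTHS = (8, 12, 16)


@dataclass(frozen=True)
class NoiseModel:
    """Photon (shot), read and quantization noise of a monochrome camera.

    Parameters
    ----------
    photon_scale : expected counts per unit of noiseless integrated signal.
    read_noise : Gaussian read noise sigma in counts.
    bit_depth : ADC depth; full scale defaults to ``2**bit_depth - 1``.
    full_scale : saturation level in counts (overrides the bit-depth default).
    """

    photon_scale: float = 40.0
    read_noise: float = 4.0
    bit_depth: int = 16
    full_scale: int | None = None

    def __post_init__(self) -> None:
        if not (self.photon_scale > 0):
            raise ParameterError("photon_scale must be > 0")
        if self.read_noise < 0:
            raise ParameterError("read_noise must be >= 0")
        if self.bit_depth not in _ALLOWED_DEPTHS:
            raise ParameterError(f"bit_depth must be one of {_ALLOWED_DEPTHS}")
        if self.full_scale is None:
            object.__setattr__(self, "full_scale", 2**self.bit_depth - 1)

    def apply(self, signal, rng: np.random.Generator) -> np.ndarray:
        """Sample camera counts for a noiseless signal array."""
        lam = np.clip(np.asarray(signal, dtype=float), 0.0, None) * self.photon_scale
        counts = rng.poisson(lam).astype(float)
        if self.read_noise > 0:
            counts += rng.normal(0.0, self.read_noise, size=counts.shape)
        counts = np.rint(counts)
        return np.clip(counts, 0.0, float(self.full_scale))

    def expected_counts(self, signal) -> np.ndarray:
        """Noise-free expected counts (before clipping) for a signal array."""
        return np.clip(np.asarray(signal, dtype=float), 0.0, None) * self.photon_scale


@dataclass(frozen=True)
class CameraPreset:
    noise: NoiseModel
    interframe: float  # us


CAMERA_PRESETS: dict[str, CameraPreset] = {
    # 8-bit double-frame PIV camera
    "piv8": CameraPreset(
        NoiseModel(photon_scale=2.0, read_noise=2.0, bit_depth=8), interframe=62.0
    ),
    # 12-bit high-speed camera
    "highspeed12": CameraPreset(
        NoiseModel(photon_scale=20.0, read_noise=4.0, bit_depth=12), interframe=10.0
    ),
}
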