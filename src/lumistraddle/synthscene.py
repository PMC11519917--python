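"""Synthetic scenes and the forward renderer.

Every stage of the pipeline is testable without instrument data: a
:class:`Scene` holds per-pixel O2, excitation illumination, dye density and
background-fluorescence fields (plus optional particle tracers), and
:func:`render_pair` pushes it through the closed-form acquisition model and
a camera noise model to produce the dim/bright frame pair a frame-straddled
camera would record.

Scene kinds
-----------
``uniform``           constant fields (calibration cuvette at one O2 level)
``cuvette_gradient``  exponential attenuation of the excitation light along
                      the optical path (a dense sensor-particle suspension
                      absorbing the light sheet)
``optode_patch``      planar optode with circular patches at different O2
``granule_wake``      O2-scavenging granules with depleted cores and
                      Gaussian-cross-section wakes in ambient water

Tracer particles are rendered as Gaussian spots (sigma ~ 1 px) added to the
dye-density field, so one rendered sequence serves both the O2 pipeline and
PIV, as in combined sensor-particle/velocimetry (sensPIV) measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import TimingConfig, _integral_arrays
from .camera import NoiseModel
from .exceptions import InputError, ParameterError
from .kinetics import lifetime_from_o2
from .processing import FramePair

__all__ = [
    "Particles",
    "Scene",
    "GranuleScenario",
    "SequenceResult",
    "build_scene",
    "render_pair",
    "render_sequence",
]


@dataclass
class Particles:
    """Gaussian tracer spots: (row, col) positions, spot sigma, brightness."""

    positions: np.ndarray  # (N, 2) float, row/col in px
    sigma: float = 1.0
    brightness: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 2:
            raise InputError("particle positions must be (N, 2)")
        if self.sigma <= 0 or self.brightness < 0:
            raise ParameterError("sigma must be > 0 and brightness >= 0")


@dataclass
class Scene:
    """Per-pixel fields of a synthetic measurement scene.

    ``o2`` in % air saturation, ``illumination`` and ``dye_density`` as
    relative (non-negative) factors multiplying the emission amplitude, and
    ``background`` as an ambient emission rate (intensity per us).
    """

    o2: np.ndarray
    illumination: np.ndarray
    dye_density: np.ndarray
    background: np.ndarray
    particles: Particles | None = None

    def __post_init__(self) -> None:
        arrs = {}
        for name in ("o2", "illumination", "dye_density", "background"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 2:
                raise InputError(f"{name} field must be 2-D")
            if np.any(a < 0):
                raise InputError(f"{name} field must be non-negative")
            arrs[name] = a
        shapes = {a.shape for a in arrs.values()}
        if len(shapes) != 1:
            raise InputError(f"scene fields have mismatched shapes: {shapes}")
        for name, a in arrs.items():
            setattr(self, name, a)

    @property
    def shape(self) -> tuple[int, int]:
        return self.o2.shape

    def effective_dye(self) -> np.ndarray:
        """Dye density with particle spots stamped on top."""
        if self.particles is None:
            return self.dye_density
        return self.dye_density + _stamp_gaussians(
            self.shape,
            self.particles.positions,
            self.particles.sigma,
            self.particles.brightness,
        )


def _stamp_gaussians(shape, positions, sigma, brightness) -> np.ndarray:
    """Add Gaussian spots to a zero field (vectorized small stamps)."""
    out = np.zeros(shape, dtype=float)
    h, w = shape
    r = max(2, int(math.ceil(4 * sigma)))
    for row, col in positions:
        r0, r1 = int(math.floor(row)) - r, int(math.floor(row)) + r + 1
        c0, c1 = int(math.floor(col)) - r, int(math.floor(col)) + r + 1
        rr0, rr1 = max(r0, 0), min(r1, h)
        cc0, cc1 = max(c0, 0), min(c1, w)
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        ys = np.arange(rr0, rr1)[:, None] - row
        xs = np.arange(cc0, cc1)[None, :] - col
        out[rr0:rr1, cc0:cc1] += brightness * np.exp(
            -(ys**2 + xs**2) / (2 * sigma**2)
        )
    return out


def build_scene(kind: str, shape: tuple[int, int] = (64, 64), **params) -> Scene:
    """Construct a deterministic scene of the given kind.

    Parameters vary by kind; common ones are ``o2`` / ``ambient_o2``
    (% air sat), ``illumination``, ``dye_density``, ``background``.

    - ``uniform``: constant fields.
    - ``cuvette_gradient``: illumination decays as exp(-depth/L) along axis
      0 with ``attenuation_length`` L in px (depth spans 0..H over the
      frame, so L = H/ln(5) gives an exact 5x top-to-bottom ratio).
    - ``optode_patch``: ``patches`` is a list of (row, col, radius, o2)
      circular regions overriding the ambient O2.
    - ``granule_wake``: ``granules`` is a list of (row, col); each carries a
      depleted core at ``core_o2`` with Gaussian cross-section
      ``wake_sigma`` px, and a wake extending ``wake_length`` px upward
      (opposite the sinking direction) with exponential recovery.
    """
    h, w = shape
    o2 = float(params.pop("o2", params.pop("ambient_o2", 100.0)))
    illum = float(params.pop("illumination", 1.0))
    dye = float(params.pop("dye_density", 1.0))
    bg = float(params.pop("background", 0.0))
    fields = dict(
        o2=np.full(shape, o2),
        illumination=np.full(shape, illum),
        dye_density=np.full(shape, dye),
        background=np.full(shape, bg),
    )

    if kind == "uniform":
        pass
    elif kind == "cuvette_gradient":
        length = float(params.pop("attenuation_length", h / math.log(5.0)))
        if length <= 0:
            raise ParameterError("attenuation_length must be > 0")
        depth = np.linspace(0.0, float(h), h)
        fields["illumination"] = illum * np.exp(-depth / length)[:, None] * np.ones(
            (1, w)
        )
    elif kind == "optode_patch":
        patches = params.pop("patches", [])
        yy, xx = np.mgrid[0:h, 0:w]
        for row, col, radius, patch_o2 in patches:
            inside = (yy - row) ** 2 + (xx - col) ** 2 <= radius**2
            fields["o2"][inside] = patch_o2
    elif kind == "granule_wake":
        granules = np.atleast_2d(
            np.asarray(params.pop("granules", [(h / 2, w / 2)]), dtype=float)
        )
        core = float(params.pop("core_o2", 40.0))
        sigma = float(params.pop("wake_sigma", 3.0))
        length = float(params.pop("wake_length", h / 2))
        yy, xx = np.mgrid[0:h, 0:w]
        depletion = np.zeros(shape)
        for row, col in granules:
            radial = np.exp(-((xx - col) ** 2 + (yy - row) ** 2) / (2 * sigma**2))
            above = yy < row  # wake trails upward behind a sinking granule
            wake = (
                np.exp(-((xx - col) ** 2) / (2 * sigma**2))
                * np.exp(-(row - yy) / length)
                * above
            )
            depletion = np.maximum(depletion, np.maximum(radial, wake))
        fields["o2"] = fields["o2"] - (o2 - core) * depletion
    else:
        raise InputError(f"unknown scene kind {kind!r}")

    particles = params.pop("particles", None)
    if params:
        raise InputError(f"unknown scene parameters: {sorted(params)}")
    return Scene(particles=particles, **fields)


def render_pair(
    scene: Scene,
    sensor,
    timing: TimingConfig,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    f0: float = 1.0,
    rng: np.random.Generator | None = None,
) -> FramePair:
    """Render one dim/bright frame pair from a scene.

    Per pixel: the sensor law converts O2 to a lifetime; the closed-form
    frame integrals are scaled by illumination x dye density (particle
    spots included); the ambient background adds its exposure dose to both
    frames.  With ``noise=None`` the returned images are the exact
    noiseless integrals (floats); otherwise Poisson shot noise, Gaussian
    read noise, quantization and clipping are applied, bit-identically for
    a fixed seed.
    """
    tau = np.asarray(lifetime_from_o2(sensor, scene.o2), dtype=float)
    amp = f0 * scene.illumination * scene.effective_dye()
    i0, i1, _, _, _ = _integral_arrays(tau, tau, amp, scene.background, timing)
    if noise is None:
        return FramePair(dim=i0, bright=i1, timing=timing,
                         full_scale=float(np.inf))
    if rng is None:
        rng = np.random.default_rng(seed)
    dim = noise.apply(i0, rng)
    bright = noise.apply(i1, rng)
    return FramePair(
        dim=dim, bright=bright, timing=timing, full_scale=float(noise.full_scale)
    )


@dataclass(frozen=True)
class GranuleScenario:
    """Sinking O2-scavenger granules in an aerated cuvette.

    Units: positions in px, sinking speed in mm/s, O2 in % air saturation,
    wake geometry in px, frame rate in pairs/s, pixel pitch in mm/px.
    The flow is modeled as a uniform downward field at the sinking speed
    (a parametric stand-in for the entrained flow, not a hydrodynamic
    simulation); tracers and granules advect with it.
    """

    granules: tuple[tuple[float, float], ...] = ((16.0, 32.0),)
    sinking_speed: float = 10.0
    core_o2: float = 40.0
    ambient_o2: float = 100.0
    wake_sigma: float = 3.0
    wake_length: float = 32.0
    frame_rate: float = 100.0
    pixel_pitch: float = 0.05
    n_tracers: int = 200
    tracer_brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.sinking_speed < 0:
            raise ParameterError("sinking speed must be >= 0")
        if self.frame_rate <= 0 or self.pixel_pitch <= 0:
            raise ParameterError("frame rate and pixel pitch must be > 0")


@dataclass
class SequenceResult:
    """Rendered pair sequence plus ground truth for pipeline validation."""

    pairs: list[FramePair]
    o2_truth: np.ndarray  # (n_pairs, H, W)
    intra_pair_displacement_px: float  # along +rows (sinking direction)
    inter_pair_displacement_px: float
    granule_positions: np.ndarray  # (n_pairs, n_granules, 2)


def render_sequence(
    scenario: GranuleScenario,
    sensor,
    timing: TimingConfig,
    noise: NoiseModel | None,
    n_pairs: int,
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
) -> SequenceResult:
    """Render a frame-straddled pair sequence of sinking granules.

    Granules and tracers advect downward by ``speed/frame_rate`` between
    pairs and by ``speed * pulse_separation`` within a pair (the two frames
    of a pair are exposed one pulse separation apart).  Returns the ground
    truth O2 stack and displacements for validating the O2 and PIV stages.
    """
    if n_pairs < 1:
        raise InputError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = shape
    tracers = rng.uniform(0.0, [h, w], size=(scenario.n_tracers, 2))
    granules = np.asarray(scenario.granules, dtype=float).copy()

    px_per_s = scenario.sinking_speed / scenario.pixel_pitch
    inter = px_per_s / scenario.frame_rate
    intra = px_per_s * timing.pulse_separation * 1e-6
    if inter > h / 2:
        warnings.warn(
            "inter-pair displacement exceeds half the image; PIV between "
            "pairs will be unreliable",
            stacklevel=2,
        )

    pairs: list[FramePair] = []
    o2_truth = np.empty((n_pairs, h, w))
    gpos = np.empty((n_pairs, len(granules), 2))

    def scene_at(granule_pos, tracer_pos) -> Scene:
        sc = build_scene(
            "granule_wake",
            shape,
            ambient_o2=scenario.ambient_o2,
            core_o2=scenario.core_o2,
            wake_sigma=scenario.wake_sigma,
            wake_length=scenario.wake_length,
            granules=[tuple(g) for g in granule_pos],
        )
        sc.particles = Particles(
            positions=tracer_pos, sigma=1.0, brightness=scenario.tracer_brightness
        )
        return sc

    shift = np.array([intra, 0.0])
    for k in range(n_pairs):
        scene_a = scene_at(granules, tracers)
        scene_b = scene_at(granules + shift, tracers + shift)
        # frame 1 sees the scene at pulse 1, frame 2 at pulse 2
        pa = render_pair(scene_a, sensor, timing, noise=noise, rng=rng)
        pb = render_pair(scene_b, sensor, timing, noise=noise, rng=rng)
        pairs.append(
            FramePair(
                dim=pa.dim, bright=pb.bright, timing=timing,
                full_scale=pa.full_scale,
            )
        )
        o2_truth[k] = scene_a.o2
        gpos[k] = granules
        granules = granules + np.array([inter, 0.0])
        tracers = tracers + np.array([inter, 0.0])
        tracers[:, 0] %= h  # recycle tracers leaving the frame

    return SequenceResult(
        pairs=pairs,
        o2_truth=o2_truth,
        intra_pair_displacement_px=float(intra),
        inter_pair_displacement_px=float(inter),
        granule_positions=gpos,
    )
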