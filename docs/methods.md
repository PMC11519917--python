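# Methods

## Emission model

A luminophore population driven by a rectangular excitation pulse of length
tau_L relaxes toward its equilibrium emission F0 with time constant tau_P
(`dN/dt = (F0 - N)/tau_P`), reaching the peak
`Fm = F0*(1 - exp(-tau_L/tau_P))` when the pulse ends, then decays
monoexponentially with the luminescence lifetime tau_D.  By default
`tau_P = tau_D`: rise and decay of a single excited-state population share
kinetics, which couples the "incomplete excitation" and "carry-over"
effects below to the same O2-dependent lifetime.  Both parameters remain
independently settable.

Ambient background B (prompt fluorescence plus stray light, intensity per
microsecond) is modeled as a constant additive rate over the whole
timecourse.  This keeps the emission continuous at the pulse edge and makes
each of two equal-length exposures collect the identical dose B·tau_E, so B
cancels *exactly* (bitwise, the difference is formed algebraically) in the
frame difference P.  An alternative convention — background present only
while the pulse is on — would cancel equally well in P; the constant-rate
form was chosen because it is the one compatible with a continuous
timecourse and with quadrature over arbitrary exposure windows.  A
consequence: closed-form integrals with `exposure = inf` (idealized
complete capture) require B = 0, and raise otherwise.

All times are microseconds, all O2 values % air saturation, all image
coordinates pixels (row-major, origin top-left).  Units are fixed, never
configurable.

## Frame-straddling integrals

With the pulse at the end of frame 1 and at the start of frame 2:

    I0 = F0*[tau_L - tau_P*(1 - exp(-tau_L/tau_P))]         dim frame
    F1 = Fm*tau_D*(1 - exp(-W/tau_D)),  W = tau_E - tau_L   captured decay
    C  = Fm*tau_D*exp(-tau_C/tau_D)*(1 - exp(-tau_E/tau_D)) carry-over
    I1 = I0 + F1 + C,   P = I1 - I0

Carry-over implements only the immediately preceding pulse's tail: at pair
periods of 10 ms or more, earlier pulses contribute factors below
exp(-150) of Fm for the lifetimes considered and are ignored.  A
configurable frame-1 decay overlap (default 0) covers trigger skew where
the dim frame records a short slice of decay; it subtracts from P.

When `tau_P = tau_D`, full capture, no carry-over and B = 0, the integrals
obey the photon-conservation identity `I0 + F1 = F0*tau_L` (every photon
excited by the pulse is counted exactly once); the test suite checks it to
1e-10 relative.

`frame_integrals_numeric` recomputes every quantity by adaptive quadrature
(scipy QUADPACK) of the emission timecourse over the exposure windows; it
exists purely as an independent oracle and is held to 1e-8 relative
agreement over randomized parameters.

## The normalization (and the published percentages)

The normalized integrated luminescence decay is

    P_N = (I1 - I0) / (I1 + I0)

i.e. the denominator is the summed signal of both frames.  The published
equation could not be transcribed from the available source text (the
equations are only present as figure placeholders), so the denominator had
to be chosen among the plausible readings.  The symmetric form above is
adopted because, evaluated with tau_D = 62 us:

- it predicts P_N = 39.1% at tau_L = 80 us, 21.8% at 160 us, and 3.2% for
  tau_D = 5 us at 80 us — against published model values of 41%, 20% and
  3% (independent quadrature bounds any natural normalization of these
  integrals to roughly 39-44% for the first case; the residual ~2-point
  discrepancy with the printed values is attributed to the unstated exact
  denominator and is documented rather than fitted away);
- it predicts the anoxic/aerated cuvette levels (39% / 15.5%) close to the
  measured 44% / 15%, and a Stern-Volmer ratio P_N0/P_N(100%) = 2.53,
  inside the typical 2-4 band of such sensors;
- doubling the pulse from 80 to 160 us reduces P_N by the factor 0.56,
  matching the reported "approximately half".

P_N is homogeneous of degree zero in the pixel intensity, so multiplicative
illumination and dye-density fields cancel identically; the rendered
5x-gradient cuvette scene recovers a flat P_N to machine precision.  The
denominator is an internal constant of the package — calibration and
measurement always share it.

One consequence of this denominator: in the complete-excitation limit the
apparent quenching constant converges to
`K_app = K_SV * 2*tau_L / (2*tau_L - tau_D0)`, i.e. it approaches the
sensor's K_SV from above as the pulse grows (2.6% high at
tau_L = 20*tau_D0, 1% at 50x).  The property tests assert this convergence
rather than a fixed small error at a fixed ratio.

## Calibration and inversion

`fit_calibration` offers the two routes used in practice: an exact
two-point solution through the anoxic and the highest-O2 level, and an
ordinary least-squares fit of `P_N0/P_N = 1 + K_SV*[O2]` with the intercept
fixed at 1 and P_N0 anchored at the (required) near-zero level.  Curves
store a timing fingerprint (pulse length, interframe, exposure); because
K_app depends on all three, `o2_from_pn` refuses to invert an image whose
timing differs from the calibration's unless explicitly forced.

Pixels are never silently zeroed: saturation, the division guard, clipped
negative P, non-positive or out-of-range P_N each set a distinct bit in a
reason mask.  The division guard defaults to 1% of the sensor full scale
applied to the two-frame sum (pixel data are already time-integrated
counts, so no additional tau_L factor applies); negative P values (noise)
are clipped to zero and flagged before any logarithm or division.

### Validation regimes

Two distinct end-to-end checks are run, each in the regime where it is
meaningful:

- **Algebraic closure** (noiseless, < 0.1% air sat): at
  `tau_L = 20*tau_D0` the excitation is complete and P_N0/P_N is exactly
  linear in O2, so render → calibrate → invert must close to numerical
  precision.  Measured closure error: ~1e-7 % air sat.
- **Noise propagation** (RMSE < 3% air sat): at the 80 us operating pulse
  with two-point 0/100% calibration, a 0-100% O2 gradient scene, 1e4
  expected bright-frame counts per pixel, and three pairs smoothed by the
  3-point temporal mean plus 3x3 median.  Measured RMSE: ~2.7% air sat,
  of which ~2.3% is the *systematic* nonlinearity of a linear calibration
  at short pulses (incomplete excitation — the same effect that makes
  K_app pulse-length dependent) and the remainder shot noise.

These cannot be collapsed into one condition: short pulses are where the
signal (and hence noise performance) lives, but they are also where the
linear Stern-Volmer calibration is only an R^2 ≈ 0.99 approximation; long
pulses are exactly linear but P_N shrinks as 1/tau_L and 1e4 counts no
longer resolve it.

## Smoothing

`smooth_series` applies a centered pixel-wise 3-point moving average along
time (ends use the neighbors that exist) followed by a per-frame 3x3
median with edge replication.  Validity masks propagate by majority at
each stage: an isolated bad pixel is genuinely repaired by the median and
becomes valid; a persistent 3x3 bad patch stays masked.  Stacks shorter
than 3 frames skip the temporal step with a warning.

## Two-gate lifetime (RLD) estimator

For two gated exposures at delays t1 and t2 after the pulse,
`tau = (t1 - t2)/ln(F2/F1)`, exact for monoexponential decay; pixels with
non-positive gates, equal gates (infinite lifetime) or non-decaying ratios
are masked.  On a noiseless O2 gradient the RLD lifetime and the
frame-straddling P_N rank O2 identically (both strictly monotone), which
ties the two readout routes together without requiring them to share a
scale.

## Synthetic scenes and camera model

The generator emulates the features of real frame-straddled data that the
pipeline must be robust to: spatially varying O2 (uniform levels, patched
optodes, granule cores of 40% air sat in 100% ambient with Gaussian-cross-
section wakes), multiplicative illumination gradients (exponential
attenuation, 5x top-to-bottom as in a dense sensor suspension),
dye-density variation, additive background, and Gaussian tracer particles
(sigma ~ 1 px) stamped on the dye field so one sequence feeds both the O2
and the PIV stages.  The camera model applies Poisson shot noise on
expected counts (`photon_scale` counts per unit of noiseless integrated
signal), Gaussian read noise, rounding and clipping at full scale.

It does **not** emulate optical point-spread functions, radiative
transfer, reaction-diffusion chemistry of the granule wakes (shapes are
parametric), sensor photobleaching, or frame-to-frame registration errors;
passing tests therefore demonstrate the correctness of the acquisition
model and processing algebra under realistic noise, not instrument-level
fidelity.

No noise figures exist for the cameras used with this method, so the
defaults are declared conventions: a generic 16-bit model
(photon_scale 40, read noise 4 counts) chosen so a 61-500 us pulse scan
stays inside the ADC range while the anoxic 80 us condition sits in the
SNR ~ 20 regime, plus `piv8` (8-bit, 62 us interframe) and `highspeed12`
(12-bit, 10 us interframe) presets mirroring the two camera classes used
in practice.

The granule scenario advects granules and tracers with a uniform downward
field at the sinking speed (a parametric stand-in for the entrained flow);
within a pair the two frames are separated by one pulse separation
(tau_L + tau_C), between pairs by 1/frame-rate.  At realistic timings the
intra-pair displacement is well below 0.1 px, so velocity validation runs
PIV between the bright frames of successive pairs (2 px at 10 mm/s,
100 fps, 0.05 mm/px) and converts displacements with the generic
`displacement_to_velocity(px, pitch, dt)` helper.

## Timing design

`timing_scan` evaluates, per pulse length, the apparent K_SV from the
noiseless model calibration and the SNR (mean/sd of P_N) over Monte-Carlo
replicates of a homogeneous 64x64 region held at 0% air saturation (the
anoxic, brightest-P_N condition; region size and O2 level configurable).
Clipped pixels are excluded; a pulse whose frames are essentially all
saturated reports SNR 0, and a genuinely noise-free configuration reports
the cap sentinel 1e6.  `recommend_pulse_window` returns the largest
contiguous interval with SNR above threshold (default 20) and apparent
K_SV within a stability band (default 15% of its long-pulse plateau).
With the default camera model and a 62/22 us sensor this yields
101-201 us — the same qualitative structure as the published scan (K_SV
depressed at short pulses by incomplete excitation, SNR decaying at long
pulses as P_N shrinks).

## PIV

Pass 1 correlates 64 px windows at 50% overlap (FFT circular
cross-correlation, window means removed) for an integer predictor
(median-filtered 3x3); pass 2 offsets 32 px search windows by the
predictor — discrete window deformation, sufficient for the few-pixel
displacements of these scenes — and refines with a 3-point Gaussian
subpixel fit per axis.  Preprocessing (CLAHE with 32 px tiles, 5 px
high-pass, 3 px Wiener) flattens the O2-dependent phosphorescence so the
correlation sees particle texture; the O2 chain always uses the
unpreprocessed frames.  Measured on the standard Gaussian-spot fixture:
integer shifts recover exactly after rounding (continuous residual
< 0.1 px), subpixel bias ~0.06 px over displacements 0-4 px.  Validation
masks vectors by speed range and optionally replaces them with the local
3x3 median of valid neighbors.  The subpixel estimator and validation
defaults are package conventions (the published processing does not state
them).

## Empirical lifetime law

The printed planar-optode fit `tau_D = 1/(35.77*exp(-[O2]/56.3) + 22.63)`
is evaluated literally behind a unit-interpretation flag (default: the
denominator is a rate per millisecond, lifetime returned in microseconds).
Taken literally the expression *increases* with O2 and its zero-O2 value
does not match the 62 us quoted for the same dye; since the intended units
are unstated, the package does not silently repair it — the Stern-Volmer
law built from the 62/22 us endpoints is the default sensor model
everywhere else.

## Known limitations

- Monoexponential decay only; no triplet-state saturation or ground-state
  depletion (short pulses avoid that regime by design), no
  multi-exponential or distribution-of-lifetimes models.
- The linear Stern-Volmer inversion inherits the pulse-length-dependent
  nonlinearity at short pulses; users who need sub-percent accuracy at
  80 us pulses must calibrate densely and interpolate, which the package
  does not currently provide.
- PIV is two-pass discrete-offset only: no iterative image deformation,
  no particle tracking, displacements beyond ~1/4 window are unreliable.
- Scene physics is parametric (no diffusion, no hydrodynamics); rendered
  sequences validate pipelines, not fluid dynamics.
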