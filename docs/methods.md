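# Methods

This note documents the models behind `bptsim`, the choices made where the
physics or the processing chain admitted more than one reasonable
implementation, and what the synthetic experiments do and do not show.

## Bore electromagnetics (`em_bore`)

The scanner bore is modeled as an air-filled circular waveguide of radius
0.35 m and length 1.35 m with perfectly conducting walls. Mode cutoffs use
the closed form `f_c = p · c / (2π a)` with `p` the appropriate Bessel
root (`J'_n` for TE, `J_n` for TM; scipy's `jnp_zeros`/`jn_zeros`) and
CODATA `c = 299 792 458 m/s`; the dominant TE11 mode of the 70 cm bore
cuts off at 251.0 MHz. Above cutoff the axial wavenumber is
`β = √(k² − k_c²)`; below it the field decays at
`α = (2π/c)√(f_c² − f²)` Np/m (≈ 4.53 Np/m for TE11 at 127.8 MHz).

A full-wave solver would resolve the antenna and bore furniture; here the
field is a **truncated modal expansion**. A point magnetic dipole excites
each mode in proportion to the mode field at the source location projected
on the dipole orientation, with the coupling vector normalized to unit
norm. Azimuthally degenerate modes are represented by the polarization
maximally coupled to the source azimuth. Each mode propagates both ways
from the source plane and reflects at the two end planes with a complex
coefficient Γ (default |Γ| = 1, which guarantees standing waves above
cutoff); the infinite reflection series is summed in closed form,
`R0 = (1 + Γa)/(1 − Γ²ab)` with `a, b` the round-trip phases to each end.
A lossless cavity has true resonances; if a configuration lands exactly on
one the denominator is floored at 1e-12 rather than allowed to blow up.

The default mode set takes all modes with cutoff below 1.5× the operating
frequency, capped at 50 — but never fewer than 6 modes, because below the
TE11 cutoff the literal rule would return an empty catalog and a zero
field where the physics calls for an evanescent one.

Coil flux is a tensor-product Gauss–Legendre quadrature over the
rectangular coil surface (default 10 × 14 cm²), starting at 8×8 points and
doubling until successive estimates agree to 1e-6 **relative to the flux
scale of the series being computed**, hard cap 128×128. The scale-relative
criterion matters: interference nulls, and TM modes whose flux through a
symmetrically placed coil vanishes identically, would otherwise hold a
pointwise-relative criterion hostage to roundoff. Translation sweeps
exploit the geometry — every z-offset of a coil shares the same transverse
quadrature grid, so Bessel evaluations are done once per mode and only the
axial phase factors (an outer product when the whole coil stays on one
side of the source plane) vary per offset.

Sub-cutoff tones therefore show a monotone envelope over a 10 cm coil
translation while the 2400/2527.8 MHz pair crosses standing-wave nulls
(guide wavelength ≈ 12.6 cm for TE11); only this qualitative ordering —
peak count and modulation depth non-decreasing with frequency — is
asserted, since absolute modulation values depend on the geometry details
a modal model deliberately omits (cradle, cables, antenna pattern, body).

## Nonlinear reception (`receiver_chain`)

The preamplifier is a memoryless polynomial `y = a1 x + a2 x²` with an
optional cubic term for waveform studies. Tone powers are dBm into 50 Ω.
The IMD convention is **output-referred**: `P_IMD = P1,out + P2,out − IP2`,
equivalent to `a2 = 10^{(10 + 2·gain_dB − IP2)/20}` under the 50 Ω
amplitude convention; both sweep curves in an intercept-point measurement
are taken at the device output, which is what fixes this choice.
`fit_intercept_point` constrains the fundamental and IMD lines to slopes
1 and 2 and warns when the unconstrained slopes deviate by more than 0.3
(gain compression). Phase of the received beat follows the conjugate
product convention `conj(Φ1)·Φ2`, the assignment under which the
second-order trigonometric identity holds exactly; magnitude-based
processing downstream does not depend on it, so phase claims are
model-defined rather than validated against hardware.

## k-space embedding and extraction (`kspace`)

Raw acquisitions are `[lines × coils × samples]` complex arrays with
250 kHz readout bandwidth and 4.4 ms line spacing by default; the MR
content is a static 1-D band-limited pseudo-object (smooth random spectrum
inside the declared image band) — no 2-D encoding, since image
reconstruction is out of scope. Tones are generated on a single continuous
clock, `exp(2πj f t)` with `t` the absolute sample time, mirroring
transmitters locked to the scanner's 10 MHz reference, so line-to-line
phase is deterministic and demodulated using the line start times.

Extraction is an **exact single-frequency correlation** (matched filter)
per line rather than nearest-FFT-bin picking, which removes scalloping
loss for offsets that do not land on the per-line FFT grid; a
`nearest_bin` mode is kept for comparison. The notch filter projects out
the tone's complex exponentials after orthogonalizing them against the
image-band FFT subspace, so the image band is untouched by construction.
For a tone on the per-line FFT grid the removal is exact; an off-grid
tone leaks slightly into the image band, and that leakage — preserved to
protect the band — is the residual the notch leaves behind. The scenario
generators therefore place tone offsets on the line FFT grid by default.

## Signal transforms (`sigproc`)

Percent modulation is `(x/mean(x) − 1)·100` per channel; channels whose
|mean| falls below 0.1× the median |mean| are excluded (their percent
modulation is artificially large) and returned as NaN. Filtering uses
5th-order Butterworth designs applied forward–backward (`sosfiltfilt`,
zero group delay) — the filter family and order are this package's
defaults, chosen as the unremarkable standard for physiological traces;
per-experiment cutoffs (2, 5, 14, 15, 25 Hz …) are caller-supplied.

`accel_to_displacement` high-passes (default 2.5 Hz for coil vibration,
4 Hz conventional for ballistocardiography), then integrates twice by
cumulative trapezoid. Each integration pass is **linearly detrended**:
plain de-meaning leaves the residual integration constant as a ramp that
dominates the displacement after the second pass, while removing mean and
ramp bounds the drift and keeps the in-band amplitude error of a 10 Hz
test tone under 2%.

`phase_extract` computes, per coil, the complex least-squares scale onto a
reference coil over a sliding window and returns the unwrapped argument;
the reference is identically zero and common phase cancels. With
`reference_coil=None` the highest-energy coil is chosen. This windowed
least-squares reading is an interpretation of a loosely specified
multi-reference pseudo-inverse procedure and is flagged as such.

Repeat alignment is integer-lag cross-correlation to the first repeat
(no sub-sample interpolation), cropping to the common support before the
pointwise mean and SD. Artifact correction is OLS of each coil trace onto
the supplied regressors plus intercept, returning the residual and the
per-coil coefficients; rank-deficient designs fall back to the
pseudo-inverse with a warning.

## Motion analytics (`motion_analysis`)

PCA is mean-centered with a deterministic sign convention (largest-|loading|
entry positive) and operates on frame-averaged **magnitudes** — the
processing chain is magnitude-based throughout. Multicoil regression is
pure OLS on de-meaned signals (optional ridge for ill-conditioned channel
sets), reporting the Pearson correlation between fit and target. The
separating plane is a reproducible surrogate for a by-eye separator: a
linear-programming feasibility check decides separability; if separable, a
hard-margin linear SVM (C = 1e9) supplies the plane and margin, otherwise
a least-squares discriminant with margin 0; leave-one-out accuracy is the
separability score. The LP gate exists because a hard-margin SVM on
inseparable data does not converge in reasonable time. MIMO stacking
concatenates per-antenna channel blocks with antenna bookkeeping; since
single-antenna models are nested in the stacked one, the in-sample
correlation with both antennas can never be lower — the out-of-sample
analogue is checked empirically on the synthetic MIMO scenario.

## Synthetic scenarios (`scenarios`)

All generators are deterministic given the config seed and stamp a config
hash into every output. Defaults are the study conditions:

* **Translation sweep** — 3 posterior coils (10 × 14 cm², bottom of the
  bore, radial normals, 15 cm apart), 10 cm of z-travel in 41 steps, 5
  back-and-forth periods, tone set {127.8 MHz, 2400/2527.8 MHz}; envelopes
  are normalized per tone by their mean magnitude before embedding.
* **Vibration** — cradle ramps at 100 mm/s over 1 cm, then a 5 s rest; the
  stop triggers a damped ring-down (f0 = 22 Hz, ζ = 0.03, amplitude
  0.5 mm), and the return ramp a more damped one (ζ = 0.08). The ring term
  is `A e^{−ζω0 t} sin(ω0 √(1−ζ²) t)`, zero for ζ ≥ 1, so the overdamped
  limit is a pure step. The accelerometer trace is the numerical second
  derivative plus 0.1% noise; coil envelopes are linear in displacement
  (25 /m, i.e. ~25% modulation per cm).
* **Physiology** — 30 s at the 4.4 ms line rate; respiration is a
  quasi-sinusoid (chest 0.25 Hz / stomach 0.20 Hz / rapid 0.55 Hz regimes)
  with slow amplitude wander; bulk motion is smooth sigmoid steps; the
  cardiac envelope at 62 bpm blends a single smooth blood-volume bump per
  beat with a sharp three-lobe (I/J/K-like) dBCG wave train of fixed
  relative latencies. The blend weight is a sigmoid in transmit frequency
  centered at 1.2 GHz (soft switch, not hard), and a `stiffness` parameter
  scales the dBCG contribution — stiffness 0 reverts the high-frequency
  channels to the one-peak blood-volume shape, emulating a floppy vs rigid
  receive array.
* **MIMO head** — 22 coils × 2 antennas; calibration rasters the ±3 mm /
  ±4° rigid-motion box with a smooth space-filling (Lissajous) trajectory
  over 115 frames; inference nods (pitch) then shakes (yaw) over 50
  frames. Channel envelopes are seeded random quadratic response surfaces
  of the six box-normalized rigid parameters (the rigid head coil's true
  response is unknown; smooth-and-seeded is the minimal assumption that
  makes calibration/inference meaningful), embedded as one tone per
  antenna and frame-averaged back out of the raw data.

What the generators emulate: the mechanism — frequency-dependent
standing-wave sampling, nonlinear mixing, navigator extraction, and the
downstream analytics. What they do not: body electromagnetics, coil
loading and detuning, scanner vibration spectra, gradient-artifact
structure (a surrogate regressor is provided for the linear-correction
path), receiver gain drift. Passing tests therefore validate the
implementation and the mechanism's internal consistency, not quantitative
agreement with any in-vivo measurement; in-vivo headline statistics are
out of reach at desk scale by construction.

## Numerical choices

* Flux quadrature tolerance 1e-6 (series-scale relative), cap 128×128.
* Cavity resonance denominator floored at 1e-12.
* Tone offsets snapped to the per-line FFT grid in the default scenarios
  (`AcquisitionParams.on_grid_offset`); extraction itself is exact for any
  offset.
* Savitzky–Golay defaults window 11, order 4 (frame-rate denoising).
* `percent_modulation` low-mean threshold 0.1 of the median |mean|.
* PCA uses the full SVD solver for determinism; seeds derived from the
  scenario seed by small fixed offsets, all far below 2³¹.

## Known limitations

* The modal bore model is qualitative above cutoff: mode truncation and
  the point-dipole coupling change peak positions and depths relative to
  a full-wave solve, so only orderings and mechanism-level properties are
  asserted.
* Phase of the beat product is convention-defined (AM-PM conversion and
  hardware phase references are not modeled).
* The image-band notch guarantee is exact only for on-grid tones.
* Heart- and respiratory-rate estimators are peak/spectrum based and
  assume reasonably clean synthetic traces; they are utilities for the
  scenarios, not general physiological detectors.
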