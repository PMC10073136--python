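# Methods

This note records the physical models, parameter choices and numerical
decisions behind `nqrauth`, and what the synthetic-data tests do and do
not demonstrate about real measurements.

## Coil model

The planar spiral detector is approximated as `n_turns` concentric
circular loops at the mid-trace radii, outermost at
`outer_side/2 − trace_width/2`, stepping inward by one pitch
(`trace_width + trace_gap`). The reference geometry (7 cm outline, 11
turns, 0.9 mm trace, 0.2 mm gap) gives loop radii from 34.55 mm down to
23.55 mm. The printed outline is square while the winding is described as
circular; we model circular loops, which is the standard approximation
for tightly wound planar coils and is verified in the tests against a
dense Biot–Savart line integral of each discretized loop (agreement
≤ 0.1 % at all tested depths). Only the on-axis field is computed;
lateral non-uniformity is out of scope. The series resistance Rₛ is not
published for the reference coil; the default 0.5 Ω is typical of a PCB
spiral of this size and only scales the detection efficiency
η = (B₁/I₁)/√Rₛ.

Over depths of roughly half to twice the mean winding radius the on-axis
sensitivity follows an approximate power law 1/z^p with p ≈ 3/2; the
default fit window 15–50 mm reflects that range (the crossover between
the near-field plateau and the far-field 1/z³ dipole regime). The fitted
exponent for the reference coil is ≈ 1.47.

## Excitation and the depth integral

Flip angle: θ(z) = γ B₁(z) tₚ with γ/2π = 3.0777 MHz/T for ¹⁴N. The
spin-1 powder flip-angle response is

    r(θ) = (sin θ − θ cos θ)/θ²,

which equals θ^(−1/2) J₃/₂(θ) up to a constant; its first maximum is at
θ_opt = 2.0816 rad = 119.27° ≈ 119.5°. A bare J₃/₂(θ) peaks near 141°,
inconsistent with the canonical 119.5° optimum, so the normalized powder
form is the default integrand; the bare small-angle form γB₁tₚ is kept as
`mode="literal"` for the simplest linear model.

The initial amplitude is the quadrature

    A ∝ ∫_{z_min}^{z_max} |B₁(z)/I₁| · r(θ(z)) dz,

computed adaptively (scipy `quad`, relative tolerance 1e-9) with a dense
10⁴-point trapezoid fallback, and cross-checked in tests against a
trapezoid oracle to ≤ 0.1 %. Default drive current (10 A) and pulse
length (50 µs) put the surface flip angle at 2.33 rad, above θ_opt, so
the "sensitive slice" where θ(z) = θ_opt exists at z ≈ 7.9 mm and the
amplitude-vs-thickness curve shows the expected thin-linear /
thick-saturating shape.

Conductive packaging is reduced to one scalar: the attenuation multiplies
the transmit field inside θ(z) and the receive sensitivity term once
each, so the amplitude carries attenuation² exactly in literal mode
(transmit/receive reciprocity) and the physically consistent
generalization in powder mode. Quantitative eddy-current electromagnetics
is deliberately out of scope.

Mass → slab thickness uses a loose-powder bulk density of 0.6 g/cm³
spread over the coil outline area (both configurable; neither is
published), giving ≈ 4.1 mm for 12 g on the reference coil.

### Package presets

Wall standoffs are implementation defaults chosen to order the six
package types plausibly by wall thickness: plastic 0.1 mm, thin paper
0.2 mm, thick paper 0.5 mm, electrostatic mailer 1 mm (with a 0.85 field
attenuation for its metallized layer), cardboard 3 mm, bubble wrap 4 mm.
They reproduce the qualitative ordering that thin paper/plastic yield the
largest amplitudes and cardboard/bubble wrap the smallest; the numeric
values are not measurements.

## Echo-train simulator

An SLSE train of NE echoes at multiples of the echo period t_E. Echo k
carries the complex envelope

    A₀ · exp(−k·t_E/T₂,eff) · s(t) · exp(i 2π Δν t),

with s(t) = exp(−π Δf |t|) (Lorentzian line of FWHM Δf; Gaussian
optional — the true line shape of these compounds is not established
here) and Δν the resonance offset from the excitation frequency. T₂,eff
follows the saturating-linear model

    T₂,eff = base_t2 · min(1 + κ·B̄₁/B_ref, cap),    B̄₁ = B₁ · (tₚ/t_E),

with κ = 2, B_ref = 0.1 mT, cap = 4× — only the monotone increase of
T₂,eff with B̄₁ and the zero-field anchor are physical constraints; the
shape is a modelling choice. t_R (repetition period) is metadata only; T₁
recovery is not modelled.

The tuned matching network is modelled as a Lorentzian amplitude response
of FWHM equal to the matching bandwidth (default 20 kHz), applied on both
transmit and receive; outside the bandwidth the signal term is zeroed and
the train flagged. A perfectly flat in-band response would make several
adjacent sweep points statistically identical, leaving sweep localization
to chance; the tuned-circuit rolloff is the physically standard
alternative.

Noise is complex circular Gaussian, constant across echoes, per-scan
per-quadrature sd `noise_sigma`. The returned train is the N-scan
average, generated directly at sd `noise_sigma/√N` — statistically
identical to averaging N independent scans and an order of magnitude
cheaper. All randomness flows through one explicit integer seed recorded
in the train's provenance.

Sequence defaults: tₚ = 50 µs, t_E = 2 ms, NE = 64, N = 16 scans,
100 kHz complex sampling over a 1.8 ms acquisition window. The reference
instrument's optimized values are not public. t_E = 2 ms (rather than a
more typical 1 ms) buys an acquisition window long enough that a 2 kHz
Lorentzian envelope decays to < 0.5 % at the window edge — with a shorter
window, truncation convolves the line with a sinc comparable to its own
width and biases the FWHM estimate by ~10 %.

## Feature extraction

* Echo peaks: maximum envelope magnitude per echo (exact for centred
  noiseless echoes).
* (A, T₂,eff): nonlinear least squares of A·exp(−t/T₂,eff), initialized
  from the log-linear fit; A is the t = 0 extrapolation (noise-robust,
  unlike the first-echo peak; first-echo mode available). Peak magnitudes
  of a decaying train flatten onto a max-statistics noise plateau once
  the signal is below the noise; fitting a bare exponential through that
  plateau overestimates T₂,eff, so when the train's noise level is known
  the fit uses the magnitude-domain model √((A e^{−t/T₂})² + b²) with the
  plateau b as a nuisance parameter.
* Spectrum: FFT of the coherently echo-summed envelope, ×4 zero-padded;
  linewidth by linear interpolation of the half-maximum crossings (ties
  at the maximum break toward the lowest frequency); peak frequency
  refined by a three-point parabola through the peak bin — without the
  sub-bin refinement the estimator quantizes to the padded bin (139 Hz)
  and repeated measurements collapse to zero spread, which would make
  Gaussian signature statistics degenerate.
* Sweep detection: each grid point is summarized by the mean spectral
  magnitude within the receiver bandwidth of the excitation frequency; a
  detection requires the largest point to exceed the median plus
  z·1.4826·MAD of the off-peak points (default z = 5). The in-band
  *mean* is used rather than the raw spectral *peak* because the peak
  over many noise bins is an extreme-value (Gumbel-tailed) statistic: a
  Gaussian-calibrated 5σ threshold on it false-alarms at the several-
  percent level no matter the SNR, while the band average has a
  near-Gaussian null and the resonance line still dominates it. The
  detected frequency is the grid point of the maximum; no sub-grid
  refinement is claimed.

## Quantification and authentication

q = (A − c)/m with the six published per-package (m, c) pairs; default
validity range 6–18 g (the studied span; the linear regime ends near
18 g). Calibration fitting regresses A on q (matching the forward model)
and inverts. Amplitudes are in the calibrating instrument's arbitrary
units: the built-in constants are tied to the original instrument's
scale, so only relative/synthetic reproduction is possible here, and
cross-detector comparisons must go through amplitude normalization
(scaling by the ratio of reference amplitudes). T₂,eff offsets between
detectors are a B̄₁ effect and are handled by per-detector signatures,
not normalization.

Authentication gates each feature at k·σ (default k = 3) against a
Gaussian signature built from ≥ 3 reference measurements; a diagonal
Mahalanobis variant is available. Zero-spread signatures are rejected as
degenerate. The signature store is a local JSON database, one document
per (API, package, detector); no cloud layer is modelled.

## What the synthetic tests do and do not show

The generator reproduces the mechanisms the analysis relies on —
depth-weighted excitation, mono-exponential T₂,eff decay, finite
linewidth, √N averaging, Gaussian feature marginals — so the tests
demonstrate internal consistency and estimator correctness at realistic
SNR (Monte-Carlo studies use 100–500 seeds at peak amplitude SNR 20–50;
sweeps use the 10 kHz protocol grid, 2.3–2.5 MHz for localization and
the full 1–5 MHz discovery protocol for false-alarm control). They do
not capture radio-frequency interference, temperature drift of the
resonance (only a linear-coefficient hook is stored), probe ring-down,
pulse-shape effects, multi-exponential decay, or the absolute amplitude
scale of any real spectrometer. A real deployment would re-measure
signatures and calibrations on its own instrument.

## Known limitations

* On-axis field only; samples wider than the coil are treated as slabs.
* The T₂,eff(B̄₁) law and the package standoffs are plausible defaults,
  not measured values.
* Conductive packaging is one scalar; blister-pack geometry (discrete
  pills) is not modelled.
* The frequency-sweep simulator assumes per-point retuning with the same
  matched bandwidth at every grid point.
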