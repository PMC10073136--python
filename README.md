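# nqrauth

Non-invasive authentication and quantification of drug products inside mail
packaging, based on nuclear quadrupole resonance (NQR) — a desk-scale
simulator and analysis toolkit.

## The problem

¹⁴N NQR is a radiofrequency spectroscopy of spin-1 nuclei that needs no
magnet: each crystalline active pharmaceutical ingredient (API) has
characteristic resonance frequencies (benzocaine 2.408 MHz, nicotinamide
2.307 MHz at room temperature), and the echo signal carries a compact
signature — initial amplitude *A* (∝ API amount in the sensitive volume),
effective decay constant *T₂,eff*, and spectral linewidth *Δf* (physical
form). Because RF penetrates paper, cardboard and plastic, an open planar
detector coil can interrogate a sealed envelope or parcel and compare the
measured signature against a stored reference: a match authenticates the
contents, a mismatch flags a discrepancy, and a per-package linear
calibration converts amplitude to API mass.

This package models that whole chain for people studying or prototyping
such screening systems: detector physics, pulse-sequence simulation,
feature extraction, calibration and decision logic.

## What is modelled

* **Coil** (`coil_field`) — a planar PCB spiral (reference: 7 cm outline,
  11 turns, 0.9 mm trace / 0.2 mm gap) as concentric circular loops.
  On-axis sensitivity B₁/I₁, detection efficiency η = (B₁/I₁)/√Rₛ, and the
  empirical ~1/z³ᐟ² depth decay.
* **Excitation** (`signal_model`) — flip angle θ(z) = γB₁(z)tₚ; the spin-1
  powder response r(θ) = (sin θ − θ cos θ)/θ², peaking at the optimum flip
  angle θ_opt ≈ 119.5°; the depth-integrated initial amplitude
  A ∝ ∫ |B₁(z)/I₁| · r(θ(z)) dz over the sample slab, which saturates with
  thickness but is linear for thin samples. Package walls set the standoff
  z_min and, if conductive, attenuate B₁.
* **Echo trains** (`slse_sim`) — spin-locked spin-echo (SLSE) sequences
  with mono-exponential T₂,eff decay that grows with the mean RF field
  B̄₁ = B₁·(tₚ/t_E), Lorentzian line shape, scan averaging (power SNR ∝ η²N)
  and seeded complex Gaussian noise.
* **Features** (`features`) — echo-peak decay fits for (A, T₂,eff), FFT
  linewidth and peak frequency, and frequency-sweep resonance discovery
  with a robust MAD noise floor.
* **Quantification** (`quantify`) — the inverse calibration q = (A − c)/m
  with the six published per-package (m, c) constants for benzocaine,
  valid over 6–18 g.
* **Authentication** (`authenticate`) — Gaussian signature records,
  cross-detector amplitude normalization, and k·σ discrepancy decisions.

## Worked example

```python
import nqrauth as nq

coil, pulse, params = nq.CoilSpec(), nq.PulseSpec(), nq.SLSEParams()
package = nq.package_presets()["thin_paper"]

# simulate a 12 g benzocaine sample in a paper envelope, 16 averaged scans
train = nq.simulate_echo_train(nq.BENZOCAINE, package, coil, pulse, params,
                               noise_sigma=0.02, seed=7)
fv = nq.extract_features(train)
print(fv.initial_amplitude, fv.t2_effective, fv.linewidth, fv.peak_frequency)
```

prints (seed 7):

```
A         = 0.4178 a.u.
T2,eff    = 10.938 ms
linewidth = 2026.8 Hz
peak f    = 2.408022 MHz
```

i.e. the extracted signature recovers the simulated ground truth (line at
2.408 MHz, 2 kHz wide, T₂,eff ≈ 11 ms for this coil's B̄₁) to a few
percent at this noise level. Quantification inverts the published
cardboard calibration exactly:

```bash
$ nqrauth quantify --amplitude 0.04892 --package cardboard
12.0 g (ok)
```

Authenticating the same measurement against a 10-measurement reference
signature of the genuine configuration:

```
verdict: authentic (k = 3)
  initial_amplitude: z = -0.38
  t2_effective: z = +0.08
  linewidth: z = +0.59
  peak_frequency: z = +1.63
```

A package with, say, half the declared API mass fails on the amplitude
feature instead.

The `nqrauth` CLI exposes the same pipeline as subcommands: `simulate`,
`sweep`, `extract`, `calibrate`, `quantify`, `authenticate`, `fixtures`.

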