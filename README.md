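# polim2d — 2D polarization imaging for homo-FRET mapping

`polim2d` implements 2D polarization imaging (2D POLIM) analysis for
wide-field fluorescence microscopy: a way to image energy transfer between
chemically identical fluorophores (homo-FRET), and with it the local packing
density of fluorescently labeled proteins — e.g. aggregates of GFP-tagged
α-synuclein — without pulsed lasers or time-resolved detection.

In a 2D POLIM acquisition, a fluorescence image is recorded for many
combinations of the linear excitation polarization angle φ_ex and the emission
analyzer angle φ_em (by default the 24 pairs {0°,30°,…,150°} × {0°,45°,90°,135°}).
Each pixel then carries a **polarization portrait** I(φ_ex, φ_em), a
second-order trigonometric surface summarized by nine Fourier coefficients.
From the portrait the package computes:

- **Modulation depths/phases** M_ex, θ_ex, M_em, θ_em — the amplitude and
  orientation of the cosine dependence of intensity on each polarizer angle
  (0 = isotropic dipoles, 1 = uniaxial alignment).
- **Fluorescence anisotropy** r = (I_∥ − I_⊥)/(I_∥ + 2 I_⊥) at any chosen
  excitation orientation (fundamental value r₀ = 0.4 for parallel
  absorption/emission dipoles without rotation or transfer).
- **Energy funneling efficiency ε** from the *single funnel approximation*
  (SFA): the portrait is fitted by

  I = (1 − ε)·I_noET + ε·(1 + M_ex cos 2(φ_ex − θ_ex))·(1 + M_f cos 2(φ_em − θ_f)),

  where I_noET is a no-transfer model pinned to the measured (M_ex, θ_ex) and
  the second, separable term is emission routed through an effective common
  emitter ("funnel") with free polarization (M_f, θ_f).  ε runs from 0 (no
  homo-FRET) to 1 (complete energy funneling) and, unlike r, is insensitive
  to the local degree of dipole alignment.

The package also contains a Förster-theory lattice simulator that relates ε
and r to the distance between fluorophores: randomly oriented dipoles on a
cubic lattice, pairwise rates k = (3/2)κ²(R₀/r)⁶ (R₀ = 4.7 nm for GFP–GFP),
hop-expansion solution of the energy migration, and ensemble polarization
portraits — the calibration that turns ε into a nanoscale packing ruler.
A synthetic-stack generator provides ground-truth images (with Poisson/EMCCD
noise) for end-to-end validation, and a thin CLI (`polim analyze | simulate |
synth | validate`) wraps the library pipelines.

## Worked example

A synthetic image with equal brightness everywhere but different packing —
ε = 0.2 on the left (monomer-like), 0.65 on the right (fibril-like), Poisson
noise at 10⁴ counts (`examples/synthetic_image_roundtrip.py`):

```text
intensity left/right: 10002 / 9996 counts (indistinguishable)
eps left  = 0.202 +/- 0.005  (truth 0.20)
eps right = 0.651 +/- 0.005  (truth 0.65)
```

The intensity image cannot tell the regions apart; the ε map can.  The
distance calibration from the lattice simulator
(`examples/distance_curve.py`, GFP R₀ = 4.7 nm):

```text
  d_nm  r_mean  r_sd  eps_mean  eps_sd   n
 3.500   0.016 0.001     0.952   0.002 200
 5.000   0.084 0.002     0.757   0.006 200
 6.500   0.215 0.003     0.418   0.007 200
 9.000   0.352 0.001     0.103   0.003 200
13.000   0.395 0.000     0.010   0.000 200
```

r decreases and ε increases as dipoles get closer: ε ≈ 1 below ~4 nm, ε ≈ 0
beyond ~12 nm where r recovers its fundamental 0.4.  The other examples show
portrait contrasts (`portrait_and_contrasts.py`) and the SFA fit on a known
mixture (`fit_funneling_efficiency.py`).

Command-line equivalents:

```sh
polim synth --preset two-region --counts 10000 --seed 1 --out phantom.tif
polim analyze --stack phantom.tif --angles phantom.angles.yaml --out out/
polim simulate --spacing 3.5 --spacing 6.5 --spacing 13 --seed 1 --out curves.csv
```

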