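# Methods

## The polarization portrait

For fixed dipoles observed through ideal linear polarizers, the fluorescence
intensity of a pixel as a function of the excitation polarization angle φ_ex
and the emission analyzer angle φ_em contains only the constant and the
cos 2φ/sin 2φ harmonics in each angle (photoselection and analyzer projection
are both cos² laws, and dipoles have 180° symmetry).  The portrait is therefore
represented exactly by nine coefficients over
{1, cos 2φ_ex, sin 2φ_ex} ⊗ {1, cos 2φ_em, sin 2φ_em}, fitted to the frame
stack by linear least squares.  On the default 24-pair grid
({0,30,…,150}° × {0,45,90,135}°) the design matrix has full rank 9, so
noiseless second-order data are recovered to machine precision; everything
beyond second order (polarizer imperfections, nonlinearity, drift) lands in
the per-pixel RMS residual, which is reported and used as a model-violation
diagnostic.  Real polarizer leakage would alias into this residual rather
than being modeled.

Angles are degrees in the sample plane, counterclockwise from the laboratory
horizontal, reduced mod 180°.  Background may be subtracted as a constant or
per-frame value before fitting; negative pixels are clipped at zero (counted
and logged) so camera offset cannot bias modulation depths.  Pixels with mean
intensity below a threshold (default 3× a robust MAD-based noise estimate of
the stack; the appropriate value is setup-dependent) are masked, because every
downstream contrast is meaningless at zero signal.  A scalar G-factor
(detection transmission ratio between analyzer orientations, default 1) can
be divided out; no high-NA depolarization correction is applied, which is
adequate for NA ≤ 0.6 objectives.

## Contrasts

The φ_em-average of the portrait is A(φ_ex) = c00 + c20 cos 2φ_ex + s20 sin 2φ_ex;
its modulation depth M_ex = √(c20² + s20²)/c00 and phase
θ_ex = ½ atan2(s20, c20) describe the net alignment of the absorbing dipoles
(M_em, θ_em analogously for emission).  The phase of a flat curve is reported
as NaN.  Fluorescence anisotropy is evaluated from the fitted model,
r(φ₀) = (I(φ₀,φ₀) − I(φ₀,φ₀+90°)) / (I(φ₀,φ₀) + 2 I(φ₀,φ₀+90°)), which allows
orientations (e.g. φ₀ = 45°) that are not excitation grid points; for
noiseless second-order data this equals the raw two-frame ratio.  The
diagnostic |r(0°) − r(45°)| quantifies how strongly the anisotropy readout
depends on the chosen excitation orientation — zero for rotationally
symmetric portraits, large under local alignment, which is precisely when r
stops being a trustworthy transfer contrast.

## Single funnel approximation

The portrait, normalized to c00 = 1, is fitted on the acquisition grid by

(1 − ε)·I_noET(M_ex, θ_ex) + ε·(1 + M_ex cos 2(φ_ex − θ_ex))·(1 + M_f cos 2(φ_em − θ_f)).

Both components inherit the *measured* excitation polarization — the funnel is
fed by the same absorbers — so only ε, M_f and θ_f are free.  Bounds are
ε, M_f ∈ [0,1]; θ_f is unconstrained and wrapped to [0°,180°), with four fit
starts spaced 45° in θ_f to avoid the 90°-shifted local minimum.  Ties are
broken toward the smaller ε, which also resolves genuinely degenerate
portraits (a fully aligned pixel, M_ex = 1, satisfies both components
simultaneously).  Weighting is uniform over the grid points since measurement
error is per-frame.  An RMS residual above 5% of the mean intensity (the
default `residual_threshold`) flags the pixel as violating the single-funnel
model instead of forcing an ε.  Exactly flat portraits are masked in ε maps:
with no polarization information, an unpolarized source and complete transfer
to an isotropic emitter are indistinguishable.

Two no-transfer families are provided.  The default `aligned_iso` family
mixes a perfectly aligned population at θ_ex with a 3D-isotropic population,
I_noET = M_ex (1 + cos 2(φ_ex−θ_ex))(1 + cos 2(φ_em−θ_ex)) + (1−M_ex)(1 + ½ cos 2(φ_ex−φ_em)),
chosen because it matches any measured M_ex and reduces at M_ex = 0 to the
portrait whose anisotropy is the fundamental r₀ = 0.4 — so isotropic
no-transfer ensembles fit with ε = 0, as they must.  The alternative
`two_delta` family (two in-plane populations at θ_ex ± β with cos 2β = M_ex)
is the classic ansatz of the single-funnel literature; on 3D-isotropic
ensembles it is a poor no-transfer reference (its crossed-dipole geometry
yields ε ≈ 0.5 even without transfer), which is why it is not the default.
The exact functional family used in prior work is not uniquely determined
from published material; ε values from different defensible families can
differ by up to ~0.1 at intermediate transfer, and this family bias is the
dominant systematic of the method.

ε is invariant under global sample rotation (θ_f shifts accordingly) and
under intensity rescaling; both invariances are enforced by tests.

## Förster lattice simulation

One realization places randomly oriented unit dipoles on an n³ cubic lattice
(default n = 7, 343 sites) with spacing d; the central dipole is the one
initially excited.  Pairwise transfer rates follow classical Förster theory,
k_ij = (3/2) κ²_ij (R₀/r_ij)⁶ in units of the radiative rate (τ = 1), with
κ = μ̂_i·μ̂_j − 3(μ̂_i·R̂)(μ̂_j·R̂) and R₀ quoted at the isotropic mean κ² = 2/3
(R₀ = 4.7 nm for GFP–GFP, 5.6 nm for ATTO-550).  Rates beyond 3 R₀ are zeroed
for speed (relative error < 10⁻³; configurable off).  The excitation performs
a random walk: at each visit to dipole i it emits with probability
1/(1 + Σ_l k_il) and hops to j with probability k_ij/(1 + Σ_l k_il); occupancy
is propagated until the residual excited fraction is below 10⁻⁹.  The
resulting per-dipole emission probabilities sum to one (no nonradiative
channel — a uniform quantum yield would cancel after normalization) and agree
with a direct linear solve of the master equation, which the tests use as an
independent oracle on small systems.

Detection is the ideal low-NA projection: excitation field and analyzer lie
in the sample plane, each dipole couples through its in-plane component, so
one realization contributes
p_abs(φ_ex) · Σ_m e_m |μ_m,xy|² cos²(φ_m − φ_em) with
p_abs = |μ_c,xy|² cos²(φ_c − φ_ex).  This reproduces r₀ = 0.4 exactly in the
no-transfer limit.  Summing many independent realizations (default 1000)
emulates a macroscopic isotropic ensemble; the ensemble portrait then goes
through the same contrast and SFA analysis as experimental data.

Because the ensemble is statistically isotropic, `ensemble_portrait` by
default averages each realization's contribution analytically over a uniform
in-plane rotation of the whole dipole system (an exact symmetry average with
identical expectation).  This removes the azimuthal component of the Monte
Carlo noise, which otherwise dominates the anisotropy error bars (SD ≈ 0.017
at 1000 realizations for the far lattice, vs ≈ 0.0002 with the average); the
remaining variance reflects radial and orientation-correlation fluctuations.
`realization_portrait` keeps the plain single-realization formula available.

Dimers are modeled by replacing a Bernoulli-selected fraction of sites with
two dipoles 3.5 nm apart: random pair axis through the site center, each
partner orientation independent and random.  Real GFP dimers tend to be more
collinear than random, which would weaken the funneling signature, so the
simulated dimer curve is an upper bound on the dimer contribution to ε.

Seeding: one master seed; per-realization generators derive from spawned
`SeedSequence` children, so every curve is reproducible.

### What the simulation predicts

With the defaults, r(d) falls from 0.395 at 13 nm (the fundamental 0.4 minus
the residual coupling at 13 nm < 3R₀) to ≈ 0.01 at 3.5 nm, and ε(d) rises
from ≈ 0.01 to ≈ 0.96 over the same range, approximately linearly between
9 and 5 nm.  At intermediate spacing the fitted ε sits slightly below the raw
absorption-weighted transferred fraction (e.g. 0.43 vs 0.49 at 6.5 nm, and
0.34 vs 0.39 for the pure-dimer lattice at 13 nm): transfer is biased toward
acceptors whose orientation correlates with the donor (κ² weighting), the
transferred emission therefore retains some donor polarization, and the SFA
attributes that correlated part to the no-transfer component.  How much of
this orientation memory is absorbed into ε depends on the no-transfer family
(see above); it is the main source of disagreement between ε scales of
different implementations at intermediate distances.

## Synthetic data generator

Truth maps (ε, M_ex, θ_ex, M_f, θ_f, intensity per pixel) are rendered through
the same portrait model the fitter assumes, sampled at the grid angles, with
optional noise: Poisson shot noise, an EMCCD excess-noise factor (√2 doubles
the variance at constant mean, emulating the electron-multiplying register),
and additive Gaussian read noise.  By default truth portraits use the
`aligned_iso` family so round trips test the estimators rather than family
mismatch; rendering with `two_delta` quantifies the model bias.  The generator
emulates an ideal instrument — no PSF, drift, flat-field error, polarizer
leakage or focus variation — so passing round trips demonstrate estimator
correctness and noise behavior, not robustness to optical artifacts.
Phantoms: a two-region image (ε = 0.2 / 0.65 at equal intensity, the
monomer-vs-fibril contrast), an anti-correlation image (bright/low-ε
background with a dim/high-ε disk), and the two calibration samples — a
dipolar "artificial molecule" (M_ex = M_em = 1) and an unpolarized sample
(flat portrait) — used by `polim validate` to check for polarization and
transmission artifacts.

## Problem sizes and numerical defaults

Test-suite and acceptance runs use 1000 realizations of the 7³ lattice per
condition (the package's standard ensemble size; the pure-dimer condition is
the most expensive at roughly two minutes on one CPU).  Hop-expansion
tolerance 10⁻⁹; rate cutoff 3R₀; SFA optimizer is SciPy's bounded
trust-region least squares with 4 θ_f starts; portrait fits are direct
least-squares solves.  Degenerate inputs are handled explicitly: non-positive
mean intensity masks a pixel, flat portraits are masked in ε maps, θ is NaN
where M = 0, and θ_f is NaN when ε·M_f ≈ 0.

## Known limitations

- No modeling of excited-state annihilation, photobleaching, rotational
  diffusion during the excited-state lifetime, spectral heterogeneity or
  concentration quenching; ε reflects energy migration among static dipoles.
- The no-transfer family is a modeling choice with an ε scale uncertainty of
  order 0.1 at intermediate transfer (exact at the ε = 0 and ε = 1 ends).
- The detection model ignores high-NA z-dipole leakage; quantitative use at
  NA > ~0.6 would need an aperture correction.
- Finite lattice and rate cutoff slightly depress r below 0.4 at 13 nm
  (≈ 0.005), a real coupling effect at that spacing rather than an artifact.
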