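# Methods

## Model

The survival model is the microdosimetric-kinetic (MK/IMK) linear-quadratic
form for a single cell-cycle phase ★:

    −ln S★(D) = (α₀★ + z₁D*·β★)·D + β★·D²,

with α₀★ (Gy⁻¹) and β★ (Gy⁻²) cell-cycle-specific coefficients and z₁D*
(Gy) the dose-mean specific energy per event in a sub-nuclear domain. The
radiation field enters only through z₁D*: the model assumes that a change of
radiation quality re-weights the linear term while leaving β★ untouched.
Overkill at very high LET is handled entirely by the saturation correction
inside y* (below); no additional high-LET term is applied.

An asynchronous population is modelled as a static mixture
S(D) = Σ★ f★·S★(D); the phase fractions are treated as fixed during the
exposure (no redistribution or repair kinetics — a deliberate limitation,
see below). The default fractions are 54.9% G₁/S and 45.1% S/G₂/M, and the
default phase parameters are (α₀, β) = (0.319, 0.055) for G₁/S and
(0.083, 0.067) for S/G₂/M at the 150 kVp X-ray quality z₁D* = 0.698 Gy.

### Microdosimetric quantities

Given a per-event lineal-energy density f(y) (keV/μm), the
saturation-corrected dose-mean lineal energy is

    y* = y₀² ∫ [1 − exp(−y²/y₀²)] f(y) dy / ∫ y f(y) dy,

with the saturation parameter y₀ = 250 keV/μm by default. The
term-wise bound 1 − e⁻ˣ ≤ x gives y* ≤ ȳD for every spectrum, with
equality as y₀ → ∞.

The keV/μm → Gy conversion uses

    z₁D* = K · y* / (ρ π r_d²),   K = 0.160218,

derived from 1 keV = 1.60218·10⁻¹⁶ J and the 10⁻¹⁵ kg mass of 1 μm³ at
1 g/cm³; at the default geometry (r_d = 0.5 μm, ρ = 1 g/cm³) this is
z₁D* ≈ 0.2039·y*. The constant is verified in the tests by a round trip
through the 0.698 Gy X-ray quality.

All spectrum integrals use the trapezoidal rule on the supplied grid. A
refinement diagnostic (`refinement_error`) reports the relative change in y*
when the grid step is halved by linear interpolation; spectra should be
supplied on grids where this is below ~10⁻⁴ (the shipped generators use
800-point log grids, diagnostic ≈ 10⁻⁴ or better).

Mixed fields are specified by **dose** fractions d_i, because boron loading
is naturally described by the dose share of the α/⁷Li component. Per-event
densities combine with frequency weights w_i ∝ d_i/ȳF,i (the dose per event
is proportional to ȳF), linearly interpolated onto the union grid with zero
density outside each component's support, then renormalized.

### Mean inactivation dose and RBE

Effectiveness is compared on the mean-inactivation-dose scale
D̄ = ∫₀^∞ S(D) dD, RBE = D̄_ref/D̄. For pure LQ curves the closed form
√(π/4β)·exp(α²/4β)·erfc(α/2√β) is used (computed via erfcx to avoid
overflow at small β; β = 0 reduces to 1/α). Generic survival functions
(e.g. the asynchronous mixture) are integrated adaptively: the truncation
dose is found by doubling until S < 10⁻¹² S(0) (configurable `tail_tol`),
then scipy's adaptive quadrature covers [0, D_c] and [D_c, ∞). The two
routes agree to better than 10⁻⁸ relative over α ∈ [0.05, 1.5],
β ∈ [0.005, 0.2], which the test suite checks on a 20×20 grid. The
reference radiation is a configuration entry — either a γ/X-ray-like
spectrum file or a direct z₁D* value — since the reference quality is an
input, not something the package can derive.

## Bayesian fit

The likelihood treats each observed point as Gaussian on −ln S with scale σ
(default 0.05, matching the generator). σ is fixed by default; an optional
mode samples it as a third parameter under a uniform prior on [10⁻⁴, 1]
(which mode is appropriate depends on whether replicate scatter is known —
both are provided). Priors on (α₀, β) are uniform boxes, default
[0, 2] Gy⁻¹ × [0, 0.5] Gy⁻², generous around all fitted values seen in
practice. The sampler is plain Metropolis: symmetric Gaussian proposals,
acceptance min(1, posterior ratio), candidates outside the box rejected.

Numerical choices: proposal scales default to 5% of each prior width;
because the posterior under the default conditions is much narrower than
the prior, an optional pre-burn-in adaptation multiplies the scales by
exp(rate − 0.3) every burn-in/20 iterations and freezes them at the end of
burn-in, so the post-burn-in kernel is exactly the plain Metropolis kernel.
Burn-in defaults to 20% of the chain and thinning to 5. Chains are exactly
reproducible from the seed. Default problem sizes — 20 000 iterations on a
24-point dataset, 50 replications for the coverage check — keep a full run
in the tens of seconds while giving ~1500 retained samples per chain.

## Etch-pit boron quantification

Per cell: net density = pit_count/area − background_density. The background
is the recoil-proton pit density measured outside the cells; one value per
field (per-plate backgrounds can be handled by splitting fields). Negative
net densities are floored at zero and flagged per cell — concentrations are
physical non-negatives and the flags preserve auditability; group
statistics use the floored values. The net density is divided by the α/⁷Li
detection efficiency and compared with `expected_density_100`, the
*physical* track density that 100% uptake of the administered concentration
would produce (an input computed upstream by radiation transport, or
supplied by the generator): uptake (%) = corrected/expected × 100 and
concentration = administered ppm × uptake/100.

Detection efficiency is a **required** input with two named presets per
etchant recipe — `pew0_ion` 92.9%, `pew15_ion` 62.9% (and proton analogues
57.8% / 12.2%). No silent default is applied because the applicable value
depends on the etching protocol of the plates being analysed.

Group statistics are mean ± s.e.m. *across cells* (the cell is the unit of
analysis). Phase comparisons use Welch's two-sample t-test on per-cell
densities, tiered at p < 0.10 (†), < 0.05 (*), < 0.01 (**). The
S/G₂/M-to-G₁/S uptake ratio carries a first-order propagated uncertainty
ratio·√((σ_a/a)² + (σ_b/b)²) treating the two s.e.m.s as independent.

## Synthetic generators

The generators produce data with exactly the statistical structure the
analysis assumes, which is what makes the recovery tests meaningful — and
bounds what they show about real data (below).

**Pit fields.** Each cell draws a phase (default 54.9/45.1), a lognormal
cross-section area (median 150 μm², geometric SD 1.4 — invented, chosen as
a plausible adherent-cell footprint), and a Poisson pit count with mean
area·(ε_ion·Φ₁₀₀·u★/100 + ε_p·Φ_p), where Φ₁₀₀ is the physical ion fluence
at full uptake (default 0.5 tracks/μm², giving ≈11 detected ion pits for a
median cell at the default uptake — countable numbers), u★ the phase uptake
truth (defaults 24.4% G₁/S, 46.0% S/G₂/M at 20 ppm administered), and the
proton term the background (Φ_p = 0.18 tracks/μm² at ε_p = 12.2%, sized so
detected background ≈ 20% of detected signal). The field's background
density is stored exactly (as if measured over a large outside area), so
background-subtraction bias and variance can be separated in tests.

**Survival data.** −ln S_obs = α★D + β★D² + N(0, σ²), truncated below at
zero with a flag; defaults 8 doses of 1–8 Gy × 3 replicates, σ = 0.05,
G₁/S truth at the X-ray quality. This is the same observation model the
likelihood assumes, so MCMC recovery tests are well-specified by
construction.

**Spectra.** Lognormal bumps on an 800-point log grid over
0.01–2000 keV/μm: photon-like (median ≈1.7 keV/μm, GSD 2) and α/⁷Li-like
(median 150 keV/μm, GSD 1.3). `tune_photon_median_to_z1d` root-finds the
photon median so the spectrum reproduces a target z₁D* (default 0.698 Gy)
to ~10⁻⁹ Gy. BNCT mixtures give the ion component a dose share
f = f_max·(1 − exp(−k·ppm)) (defaults f_max = 0.95, k = 0.005/ppm):
linear with slope f_max·k at low concentration — mirroring a linear
boron-to-dose relation — and saturating smoothly, so y* and hence RBE are
*strictly* increasing in ppm at any concentration. The coefficient is a
synthetic stand-in for a transport calculation and sets the absolute scale
of the resulting RBE values; only their ordering and monotonicity are
meaningful.

### What the generators do not emulate

Real CR-39 data have spatially correlated backgrounds, pit-overlap
undercounting at high fluence, segmentation errors in the cell outlines,
and phase-misclassification noise; real survival assays have dose-dependent
heteroscedasticity and plating-efficiency drift; real lineal-energy spectra
have multi-component structure beyond two lognormal bumps. Passing recovery
tests therefore demonstrates correctness of the estimators *under the
stated model*, not robustness to these effects.

## Degenerate inputs and tie-breaks

All-zero spectra, non-increasing grids and negative densities are rejected
at construction; moment operations require a unit integral (10⁻⁶
tolerance) and direct users to `normalize()`. Zero-variance t-test groups
with equal means return t = 0, p = 1; unequal means with zero variance are
an error. A chain with no accepted post-burn-in moves raises rather than
returning a degenerate posterior. β = 0 survival falls back to the pure
exponential closed form.

## Known limitations

- No time–dose structure: repair during protracted irradiation and phase
  redistribution over the exposure are outside the model.
- The ppm → dose-fraction map is synthetic; absolute RBE values for mixed
  fields are only as good as that map.
- Uptake uncertainty and parameter-posterior uncertainty are propagated
  independently when both are used; any correlation between them is ignored.
- One background density per field; spatial background structure is not
  modelled.
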