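# bnctmk

Microdosimetric-kinetic survival modelling and CR-39 etch-pit boron
quantification for boron neutron capture therapy (BNCT).

In BNCT, thermal neutrons captured by ¹⁰B release short-range α and ⁷Li
ions that kill the cells that took the boron carrier up. Two questions
drive the analysis this package supports: *how much boron did each cell
actually take up* (it varies with cell-cycle phase), and *what does that
uptake do to cell killing* once translated into radiation quality. The
package covers the whole computational chain for cultured cells:

- **Microdosimetry** — lineal-energy spectra f(y), the saturation-corrected
  dose-mean lineal energy
  y\* = y₀² ∫[1 − exp(−y²/y₀²)] f(y) dy / ∫ y f(y) dy (y₀ = 250 keV/μm),
  and its conversion to the per-event specific energy
  z₁D\* = y\*/(ρπr_d²) in a domain of radius r_d = 0.5 μm.
- **Survival model** — phase-specific linear-quadratic survival
  −ln S★(D) = (α₀★ + z₁D\*·β★)D + β★D², the asynchronous mixture
  S(D) = Σ★ f★ S★(D), the mean inactivation dose D̄ = ∫₀^∞ S(D) dD and
  RBE = D̄_ref/D̄.
- **MCMC fit** — Metropolis sampling of (α₀★, β★) under uniform priors with
  a Gaussian likelihood on −ln S.
- **Boron quantification** — per-cell etch-pit counts → background
  subtraction → detection-efficiency correction → intracellular ¹⁰B
  concentration and uptake fraction, with Welch t-tests between cell-cycle
  phases.
- **Synthetic data** — seeded generators for pit fields (Poisson counts with
  phase-dependent uptake and a recoil-proton background), noisy survival
  curves, and two-component lineal-energy spectra, so the full pipeline runs
  and is testable with no external data.

## Worked example

The `demo` subcommand simulates a full experiment and runs every stage:

```bash
bnctmk demo --seed 2 --out demo_out
```

The boron-quantification step prints the per-phase uptake report
(100 simulated cells, 20 ppm administered):

```
 group  concentration_ppm  concentration_sem  uptake_percent  uptake_sem  n_cells  n_floored
  G1/S           4.664366           0.218238       23.321831    1.091190       54          0
S/G2/M           9.422066           0.380062       47.110330    1.900309       46          0
```

i.e. the G₁/S cells hold ≈4.7 ppm of the administered 20 ppm (≈23% uptake)
while S/G₂/M cells hold about twice that — the cell-cycle heterogeneity the
generator was asked to produce (truths 24.4% and 46.0%). The RBE step then
prints, for a photon reference and a 20-ppm BNCT mixed field:

```
      quality_label        phase  dbar_Gy      rbe
    spectrum_photon         G1/S 1.899155 1.000000
    spectrum_photon       S/G2/M 2.635816 1.000000
    spectrum_photon asynchronous 2.231389 1.000000
spectrum_bnct_20ppm         G1/S 1.580042 1.201965
spectrum_bnct_20ppm       S/G2/M 2.019331 1.305292
spectrum_bnct_20ppm asynchronous 1.778161 1.254886
```

The reference quality reproduces RBE = 1 identically; adding the α/⁷Li dose
share of a 20-ppm boron loading raises the effectiveness of every phase,
most for the β-heavy S/G₂/M phase. (The absolute RBE values depend on the
synthetic ppm→dose-fraction map; see `docs/methods.md`.)

The same stages are available as `simulate`, `fit-survival`,
`quantify-boron` and `compute-rbe` subcommands on CSV/YAML files, and as
plain library calls:

```python
from bnctmk import (RadiationQuality, SurvivalSimSpec, generate_survival_data,
                    metropolis_sample, posterior_summary)

data, truth = generate_survival_data(SurvivalSimSpec(seed=7))
quality = RadiationQuality.from_z1d(0.698)  # 150 kVp X-ray quality
post = metropolis_sample(data, quality, adapt=True, seed=7)
print(posterior_summary(post)["alpha0"])   # mean ≈ truth["alpha0"] = 0.319
```

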