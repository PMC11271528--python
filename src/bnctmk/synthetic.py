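"""Synthetic generators for every input the pipeline consumes.

Three generators, all deterministic under a fixed seed:

* :func:`generate_pit_field` — a CR-39 field of cells with phase-dependent
  boron uptake.  Per cell the pit count is Poisson with mean
  ``area · (ε_ion·ion_fluence_100·uptake_phase/100 + ε_p·proton_fluence)``;
  the recoil-proton term is also what is measured outside the cells and
  supplied as the background density.
* :func:`generate_survival_data` — clonogenic dose–response points with
  Gaussian noise on −ln S, the same observation model the MCMC fit assumes.
* :func:`generate_spectrum` — lineal-energy spectra: a photon-like
  low-y lognormal bump, an α/⁷Li-like high-y bump, or a boron-concentration
  dependent dose-fraction mixture of the two on a log-spaced grid.

Defaults follow the measured study conditions where those exist (phase
fractions 54.9%/45.1%, phase uptakes 24.4%/46.0% at 20 ppm, LQ truth
(0.319, 0.055) at z1D* = 0.698 Gy, etch efficiencies 62.9%/12.2%); purely
synthetic knobs (cell-area distribution, fluence scales, ppm→dose-fraction
coefficient) are documented as such in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .boron import CellPitRecord, PitField
from .mcmc import SurvivalDataset
from .microdosimetry import (
    DomainGeometry,
    LinealEnergySpectrum,
    mix_spectra,
    y_star,
    z1d_from_ystar,
)

__all__ = [
    "FieldSpec",
    "SurvivalSimSpec",
    "generate_pit_field",
    "generate_survival_data",
    "generate_spectrum",
    "photon_like_spectrum",
    "ion_like_spectrum",
    "bnct_mix_spectrum",
    "boron_dose_fraction",
    "tune_photon_median_to_z1d",
]


@dataclass(frozen=True)
class FieldSpec:
    """Study conditions for one synthetic CR-39 pit field.

    Uptake truths default to the 20-ppm phase measurements (G₁/S 24.4%,
    S/G₂/M 46.0%); phase fractions to the asynchronous-population split
    54.9%/45.1%; efficiencies to the PEW-15 etch (ion 62.9%, proton 12.2%).
    ``ion_fluence_100`` is the physical α/⁷Li track density at full uptake;
    the proton background default makes the detected background ≈20% of the
    detected ion signal.
    """

    n_cells: int = 100
    phase_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"G1/S": 0.549, "S/G2/M": 0.451}
    )
    area_median: float = 150.0  # μm²
    area_gsd: float = 1.4  # geometric standard deviation
    uptake_truth: Mapping[str, float] = field(
        default_factory=lambda: {"G1/S": 24.4, "S/G2/M": 46.0}
    )
    administered_ppm: float = 20.0
    ion_fluence_100: float = 0.5  # tracks/μm² at 100% uptake
    proton_background_fluence: float = 0.18  # tracks/μm²
    efficiency_ion: float = 0.629
    efficiency_proton: float = 0.122
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        fr = np.array(list(self.phase_fractions.values()), dtype=float)
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("phase fractions must be non-negative and sum to 1")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        for name in ("ion_fluence_100", "proton_background_fluence", "administered_ppm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("efficiency_ion", "efficiency_proton"):
            e = getattr(self, name)
            if not (0.0 < e <= 1.0):
                raise ValueError(f"{name} must lie in (0,1], got {e}")
        if any(u < 0 for u in self.uptake_truth.values()):
            raise ValueError("uptake truths must be non-negative")


def generate_pit_field(spec: FieldSpec) -> tuple:
    """Draw a PitField and return it with the hidden generating truth.

    Cells get a phase by multinomial draw, a lognormal cross-section area,
    and a Poisson pit count with the phase's detected ion density plus the
    detected proton background.  The field's ``background_density`` is the
    exact detected proton density (as if measured over a large outside
    area) and ``expected_density_100`` the physical ion fluence at full
    uptake, so the quantifier's efficiency correction round-trips.
    """
    rng = np.random.default_rng(spec.seed)
    phases = list(spec.phase_fractions)
    labels = rng.choice(
        phases, size=spec.n_cells, p=[spec.phase_fractions[p] for p in phases]
    )
    areas = spec.area_median * np.exp(
        rng.normal(0.0, np.log(spec.area_gsd), size=spec.n_cells)
    )
    background = spec.efficiency_proton * spec.proton_background_fluence
    records = []
    for i, (phase, area) in enumerate(zip(labels, areas)):
        ion_detected = (
            spec.efficiency_ion
            * spec.ion_fluence_100
            * spec.uptake_truth.get(phase, 0.0)
            / 100.0
        )
        count = rng.poisson(area * (ion_detected + background))
        records.append(
            CellPitRecord(
                cell_id=f"cell{i:04d}", phase_label=str(phase), area=float(area),
                pit_count=int(count),
            )
        )
    fld = PitField(
        records=tuple(records),
        background_density=background,
        administered_ppm=spec.administered_ppm,
        expected_density_100=spec.ion_fluence_100,
        efficiency_ion=spec.efficiency_ion,
        efficiency_note="synthetic field; generator efficiencies applied",
    )
    g1s = spec.uptake_truth.get("G1/S", 0.0)
    truth = {
        "uptake_truth": dict(spec.uptake_truth),
        "concentration_truth_ppm": {
            p: spec.administered_ppm * u / 100.0 for p, u in spec.uptake_truth.items()
        },
        "phase_ratio_truth": (spec.uptake_truth.get("S/G2/M", 0.0) / g1s if g1s > 0 else None),
        "seed": spec.seed,
    }
    return fld, truth


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Conditions for a synthetic clonogenic survival dataset.

    Defaults are the G₁/S LQ truth (α0 = 0.319 Gy⁻¹, β = 0.055 Gy⁻²) at the
    150 kVp X-ray quality z1D* = 0.698 Gy, 8 doses of 1–8 Gy × 3 replicates
    and σ = 0.05 on −ln S.
    """

    alpha0: float = 0.319
    beta: float = 0.055
    z1d_star: float = 0.698
    doses: tuple = tuple(float(d) for d in range(1, 9))
    sigma: float = 0.05
    replicates: int = 3
    average_replicates: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def generate_survival_data(spec: SurvivalSimSpec) -> tuple:
    """Draw a SurvivalDataset and its generating truth.

    −ln S_obs = (α0 + z1D*·β)·D + β·D² + N(0, σ²), truncated below at zero
    (a flag in the truth records how many points were clipped).  Replicates
    are emitted as separate rows unless ``average_replicates``.
    """
    rng = np.random.default_rng(spec.seed)
    d = np.repeat(np.asarray(spec.doses, dtype=float), spec.replicates)
    alpha = spec.alpha0 + spec.z1d_star * spec.beta
    clean = alpha * d + spec.beta * d * d
    noisy = clean + rng.normal(0.0, spec.sigma, size=d.size)
    n_clipped = int(np.sum(noisy < 0))
    noisy = np.maximum(noisy, 0.0)
    if spec.average_replicates:
        doses = np.asarray(spec.doses, dtype=float)
        noisy = noisy.reshape(len(spec.doses), spec.replicates).mean(axis=1)
    else:
        doses = d
    truth = {
        "alpha0": spec.alpha0,
        "beta": spec.beta,
        "z1d_star": spec.z1d_star,
        "sigma": spec.sigma,
        "n_clipped": n_clipped,
        "seed": spec.seed,
    }
    return SurvivalDataset(doses=doses, neg_log_sf=noisy), truth


def _lognormal_spectrum(
    median: float, gsd: float, y_min: float, y_max: float, n_points: int
) -> LinealEnergySpectrum:
    grid = np.logspace(np.log10(y_min), np.log10(y_max), n_points)
    s = np.log(gsd)
    dens = np.exp(-0.5 * ((np.log(grid) - np.log(median)) / s) ** 2) / (
        grid * s * np.sqrt(2.0 * np.pi)
    )
    return LinealEnergySpectrum(grid, dens).normalize()


def photon_like_spectrum(
    median: float = 1.7, gsd: float = 2.0, y_min: float = 1e-2, y_max: float = 2e3,
    n_points: int = 800,
) -> LinealEnergySpectrum:
    """Low-y lognormal bump emulating a sparsely ionizing photon field."""
    return _lognormal_spectrum(median, gsd, y_min, y_max, n_points)


def ion_like_spectrum(
    median: float = 150.0, gsd: float = 1.3, y_min: float = 1e-2, y_max: float = 2e3,
    n_points: int = 800,
) -> LinealEnergySpectrum:
    """High-y lognormal bump emulating the short-range α/⁷Li component."""
    return _lognormal_spectrum(median, gsd, y_min, y_max, n_points)


def boron_dose_fraction(
    ppm: float, coefficient: float = 0.005, f_max: float = 0.95
) -> float:
    """Dose share of the α/⁷Li component vs administered ¹⁰B concentration.

    Saturating map f = f_max·(1 − exp(−k·ppm)): linear with slope f_max·k
    at low concentration, strictly increasing everywhere, approaching f_max
    as uptake saturates.  A synthetic stand-in for the transport-computed
    boron dose share; ``coefficient`` (per ppm) sets the scale.
    """
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    if not (0.0 < f_max < 1.0) or coefficient <= 0:
        raise ValueError("need 0 < f_max < 1 and coefficient > 0")
    return float(f_max * -np.expm1(-coefficient * ppm))


def bnct_mix_spectrum(
    ppm: float,
    base: Optional[LinealEnergySpectrum] = None,
    ion: Optional[LinealEnergySpectrum] = None,
    coefficient: float = 0.005,
    f_max: float = 0.95,
) -> LinealEnergySpectrum:
    """Mixed field: photon/neutron base plus a ppm-dependent α/⁷Li dose share."""
    base = base if base is not None else photon_like_spectrum()
    ion = ion if ion is not None else ion_like_spectrum()
    f_ion = boron_dose_fraction(ppm, coefficient, f_max)
    if f_ion == 0.0:
        return base.normalize()
    return mix_spectra([(base, 1.0 - f_ion), (ion, f_ion)])


def generate_spectrum(kind: str, **params) -> LinealEnergySpectrum:
    """Dispatch by kind: ``photon_like``, ``ion_like`` or ``bnct_mix``."""
    kinds = {
        "photon_like": photon_like_spectrum,
        "ion_like": ion_like_spectrum,
        "bnct_mix": bnct_mix_spectrum,
    }
    if kind not in kinds:
        raise ValueError(f"unknown spectrum kind {kind!r}; choose from {sorted(kinds)}")
    return kinds[kind](**params)


def tune_photon_median_to_z1d(
    target_z1d: float = 0.698,
    geometry: DomainGeometry = DomainGeometry(),
    y0: float = 250.0,
    gsd: float = 2.0,
    bracket: tuple = (0.05, 50.0),
) -> LinealEnergySpectrum:
    """Photon-like spectrum whose z1D* matches a target, by root-finding.

    The lognormal median is solved with Brent's method so that the
    spectrum's saturation-corrected y*, converted through the domain
    geometry, reproduces ``target_z1d`` (default: the 150 kVp X-ray value
    0.698 Gy at r_d = 0.5 μm, ρ = 1).
    """

    def gap(log_median: float) -> float:
        spec = photon_like_spectrum(median=float(np.exp(log_median)), gsd=gsd)
        return z1d_from_ystar(y_star(spec, y0), geometry) - target_z1d

    lo, hi = np.log(bracket[0]), np.log(bracket[1])
    root = brentq(gap, lo, hi, xtol=1e-14, rtol=1e-15)
    return photon_like_spectrum(median=float(np.exp(root)), gsd=gsd)
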