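import numpy as np
import pytest

from bnctmk import (
    LinealEnergySpectrum,
    PhaseMixture,
    PhaseParams,
    RadiationQuality,
)

# LQ parameters of the two cell-cycle phases at the 150 kVp X-ray quality
# (z1D* = 0.698 Gy): the fixture values every stage of the pipeline reuses.
G1S_PARAMS = PhaseParams(alpha0=0.319, beta=0.055, phase_label="G1/S")
SG2M_PARAMS = PhaseParams(alpha0=0.083, beta=0.067, phase_label="S/G2/M")
XRAY_Z1D = 0.698


@pytest.fixture(scope="session")
def xray_quality() -> RadiationQuality:
    return RadiationQuality.from_z1d(XRAY_Z1D, label="150kVp-X")


@pytest.fixture(scope="session")
def phase_params() -> dict:
    return {"G1/S": G1S_PARAMS, "S/G2/M": SG2M_PARAMS}


@pytest.fixture(scope="session")
def async_mixture() -> PhaseMixture:
    return PhaseMixture(fractions={"G1/S": 0.549, "S/G2/M": 0.451})


def near_delta(y1: float, rel_width: float = 1e-5, n: int = 21) -> LinealEnergySpectrum:
    """Narrow triangular spectrum approximating a point mass at y1."""
    w = rel_width * y1
    grid = np.linspace(y1 - w, y1 + w, n)
    dens = np.maximum(0.0, 1.0 - np.abs(grid - y1) / w)
    return LinealEnergySpectrum(grid, dens).normalize()


def random_spectrum(rng: np.random.Generator, n_points: int = 300) -> LinealEnergySpectrum:
    """Random smooth positive spectrum on a log grid spanning 0.1–1000 keV/μm."""
    lo = rng.uniform(-1.0, 0.5)
    hi = rng.uniform(1.5, 3.0)
    grid = np.logspace(lo, hi, n_points)
    # mixture of a few lognormal bumps
    dens = np.zeros_like(grid)
    for _ in range(rng.integers(1, 4)):
        mu = rng.uniform(np.log(grid[0] * 3), np.log(grid[-1] / 3))
        s = rng.uniform(0.2, 1.0)
        dens += rng.uniform(0.2, 1.0) * np.exp(-0.5 * ((np.log(grid) - mu) / s) ** 2)
    return LinealEnergySpectrum(grid, dens).normalize()
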