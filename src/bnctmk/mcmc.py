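"""Metropolis MCMC estimation of the LQ parameters (α0★, β★) from survival data.

The observation model treats each measured point as Gaussian noise on
−ln S: with model prediction −ln S_cal(D_i) = α★·D_i + β★·D_i² the
log-likelihood is

    ln P(d|θ) = Σ_i [ −½ ln(2πσ²) − (−ln S_exp,i + ln S_cal,i)² / (2σ²) ].

Priors on α0★ and β★ are uniform boxes; the sampler is plain Metropolis
with a symmetric Gaussian proposal, acceptance probability
min(1, posterior ratio), and rejection of candidates outside the prior box.
σ may be fixed (default) or sampled as a third parameter under a uniform
prior on a positive interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .microdosimetry import RadiationQuality
from .survival import PhaseParams, alpha_effective

__all__ = [
    "SurvivalDataset",
    "Posterior",
    "log_likelihood",
    "metropolis_sample",
    "posterior_summary",
]

DEFAULT_PRIOR_BOUNDS = ((0.0, 2.0), (0.0, 0.5))  # α0 [Gy⁻¹], β [Gy⁻²]


@dataclass(frozen=True)
class SurvivalDataset:
    """Observed dose–response points as (dose in Gy, −ln S)."""

    doses: np.ndarray
    neg_log_sf: np.ndarray
    sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        nls = np.asarray(self.neg_log_sf, dtype=float)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "neg_log_sf", nls)
        if d.ndim != 1 or nls.shape != d.shape:
            raise ValueError("doses and neg_log_sf must be 1-D arrays of equal length")
        if d.size < 3:
            raise ValueError("need at least 3 survival points to fit two parameters")
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        if np.any(nls < 0):
            # small negatives happen when assay noise pushes S slightly above 1
            warnings.warn(
                "negative −ln S values present (surviving fraction > 1); "
                "keeping them as-is",
                stacklevel=2,
            )
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            object.__setattr__(self, "sd", sd)
            if sd.shape != d.shape or np.any(sd <= 0):
                raise ValueError("per-point sd must be positive and match doses in length")

    @property
    def n(self) -> int:
        return int(self.doses.size)


@dataclass(frozen=True)
class Posterior:
    """Post-burn-in, thinned Metropolis samples with bookkeeping."""

    samples: np.ndarray  # shape (n_samples, n_params)
    param_names: tuple
    acceptance_rate: float
    seed: Optional[int]
    prior_bounds: tuple
    sigma: Optional[float] = None  # fixed σ, or None when σ was sampled
    n_iter: int = 0
    burn_in: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 2 or s.shape[1] != len(self.param_names):
            raise ValueError("samples must be (n, n_params)")
        if not (0.0 < self.acceptance_rate < 1.0):
            raise ValueError(
                f"acceptance rate must lie strictly in (0,1), got {self.acceptance_rate}"
            )
        for j, (lo, hi) in enumerate(self.prior_bounds):
            if np.any(s[:, j] < lo) or np.any(s[:, j] > hi):
                raise ValueError(f"samples for {self.param_names[j]} escape the prior box")

    def phase_params(self, phase_label: str = "other") -> PhaseParams:
        """Posterior-mean point estimate as PhaseParams."""
        m = self.samples.mean(axis=0)
        return PhaseParams(alpha0=float(m[0]), beta=float(m[1]), phase_label=phase_label)


def log_likelihood(
    theta: Sequence[float],
    data: SurvivalDataset,
    quality: RadiationQuality,
    sigma: float,
) -> float:
    """Gaussian log-likelihood of (α0, β) for −ln S observations."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    alpha0, beta = float(theta[0]), float(theta[1])
    a = alpha0 + quality.z1d_star * beta
    model = a * data.doses + beta * data.doses**2
    resid = data.neg_log_sf - model
    n = data.n
    return float(
        -0.5 * n * np.log(2.0 * np.pi * sigma * sigma)
        - float(resid @ resid) / (2.0 * sigma * sigma)
    )


def _in_box(theta: np.ndarray, bounds: tuple) -> bool:
    return all(lo <= t <= hi for t, (lo, hi) in zip(theta, bounds))


def metropolis_sample(
    data: SurvivalDataset,
    quality: RadiationQuality,
    prior_bounds: tuple = DEFAULT_PRIOR_BOUNDS,
    n_iter: int = 20000,
    burn_in: Optional[int] = None,
    thin: int = 5,
    proposal_scales: Optional[Sequence[float]] = None,
    sigma: float = 0.05,
    estimate_sigma: bool = False,
    sigma_bounds: tuple = (1e-4, 1.0),
    adapt: bool = False,
    seed: Optional[int] = None,
) -> Posterior:
    """Metropolis chain over (α0★, β★) [, σ] with uniform box priors.

    Parameters
    ----------
    prior_bounds : ((lo, hi), (lo, hi))
        Uniform prior box for α0 (Gy⁻¹) and β (Gy⁻²).
    burn_in : int, optional
        Iterations discarded; defaults to 20% of ``n_iter``.
    proposal_scales : optional
        Std of the symmetric Gaussian proposal per parameter; defaults to
        5% of each prior width.
    sigma, estimate_sigma
        Fixed noise scale of −ln S (default), or sample σ as a third
        parameter uniform on ``sigma_bounds``.
    adapt : bool
        If True, proposal scales are tuned toward ~30% acceptance during
        burn-in only and frozen afterwards, keeping the post-burn-in kernel
        a plain Metropolis kernel.

    The chain is fully reproducible from ``seed``.
    """
    if burn_in is None:
        burn_in = n_iter // 5
    if not (0 <= burn_in < n_iter):
        raise ValueError("need 0 <= burn_in < n_iter")
    if thin < 1:
        raise ValueError("thin must be >= 1")

    bounds = tuple(tuple(map(float, b)) for b in prior_bounds)
    names = ["alpha0", "beta"]
    if estimate_sigma:
        bounds = bounds + (tuple(map(float, sigma_bounds)),)
        names.append("sigma")
    for lo, hi in bounds:
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"prior bounds must be finite with lo < hi, got ({lo}, {hi})")

    if proposal_scales is None:
        scales = np.array([0.05 * (hi - lo) for lo, hi in bounds])
    else:
        scales = np.asarray(proposal_scales, dtype=float)
        if scales.shape != (len(bounds),) or np.any(scales <= 0):
            raise ValueError("proposal_scales must be positive, one per sampled parameter")

    rng = np.random.default_rng(seed)
    theta = np.array([0.5 * (lo + hi) for lo, hi in bounds])

    def logpost(t: np.ndarray) -> float:
        s = t[2] if estimate_sigma else sigma
        return log_likelihood(t[:2], data, quality, s)

    lp = logpost(theta)
    kept = []
    accepted_post = 0
    proposed_post = 0
    accepted_window = 0
    adapt_interval = max(50, burn_in // 20) if adapt else None

    for it in range(n_iter):
        candidate = theta + rng.normal(size=len(bounds)) * scales
        log_u = np.log(rng.uniform())
        if _in_box(candidate, bounds):
            lp_cand = logpost(candidate)
            if log_u < lp_cand - lp:  # min(1, posterior ratio), uniform prior cancels
                theta, lp = candidate, lp_cand
                if it >= burn_in:
                    accepted_post += 1
                else:
                    accepted_window += 1
        if it >= burn_in:
            proposed_post += 1
            if (it - burn_in) % thin == 0:
                kept.append(theta.copy())
        elif adapt and adapt_interval and (it + 1) % adapt_interval == 0:
            rate = accepted_window / adapt_interval
            scales = scales * np.exp(rate - 0.3)  # nudge toward ~30% acceptance
            accepted_window = 0

    if accepted_post == 0:
        raise RuntimeError(
            "no accepted moves after burn-in; check proposal scales, σ, or prior bounds"
        )
    return Posterior(
        samples=np.array(kept),
        param_names=tuple(names),
        acceptance_rate=accepted_post / proposed_post,
        seed=seed,
        prior_bounds=bounds,
        sigma=None if estimate_sigma else sigma,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
    )


def posterior_summary(posterior: Posterior, ci: float = 0.95) -> dict:
    """Mean ± sd and central credible interval per parameter.

    Returns ``{name: {"mean", "sd", "ci_low", "ci_high"}}``; requires at
    least 100 post-burn-in samples for the interval to be meaningful.
    """
    s = posterior.samples
    if s.shape[0] < 100:
        raise ValueError(f"need at least 100 posterior samples, have {s.shape[0]}")
    lo_q, hi_q = 50.0 * (1.0 - ci), 50.0 * (1.0 + ci)
    out = {}
    for j, name in enumerate(posterior.param_names):
        col = s[:, j]
        lo, hi = np.percentile(col, [lo_q, hi_q])
        out[name] = {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)),
            "ci_low": float(lo),
            "ci_high": float(hi),
        }
    return out
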