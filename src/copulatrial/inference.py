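"""Likelihood, priors and the posterior sampler for the joint outcome models.

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme run on
unconstrained scales (log for the slopes, logit-type maps for the association
parameter) with the appropriate Jacobian corrections; the compiled inner loop
lives in :mod:`copulatrial._kernels`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm as norm_dist

from . import _kernels
from .model_core import (
    CopulaSpec,
    DoseGrid,
    MarginalParams,
    MarginalPair,
    braun_true_marginals,
    joint_table,
    marginal_curves,
)

__all__ = [
    "TrialData",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "PARAM_NAMES",
    "log_likelihood",
    "log_prior",
    "sample_posterior",
    "posterior_dose_summaries",
]

PARAM_NAMES = ("beta0_T", "beta1_T", "beta0_E", "beta1_E", "beta2_E", "psi")

_FAMILY_CODES = {"braun": _kernels.BRAUN, "gumbel": _kernels.GUMBEL, "independence": _kernels.INDEPENDENCE}


@dataclass(frozen=True)
class TrialData:
    """Accrued per-subject (dose, toxicity, efficacy) outcome triples."""

    z: np.ndarray
    y_T: np.ndarray
    y_E: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=np.int64)
        y_t = np.asarray(self.y_T, dtype=np.int64)
        y_e = np.asarray(self.y_E, dtype=np.int64)
        if not (z.shape == y_t.shape == y_e.shape) or z.ndim != 1:
            raise ValueError("z, y_T, y_E must be 1-D arrays of equal length")
        if z.size and z.min() < 1:
            raise ValueError("dose indices must be >= 1")
        for name, y in (("y_T", y_t), ("y_E", y_e)):
            if y.size and not np.isin(y, (0, 1)).all():
                raise ValueError(f"{name} must be binary")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "y_T", y_t)
        object.__setattr__(self, "y_E", y_e)

    def __len__(self) -> int:
        return int(self.z.size)

    @staticmethod
    def empty() -> "TrialData":
        return TrialData(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))

    def extend(self, z: Sequence[int], y_T: Sequence[int], y_E: Sequence[int]) -> "TrialData":
        return TrialData(
            np.concatenate([self.z, np.asarray(z, dtype=np.int64)]),
            np.concatenate([self.y_T, np.asarray(y_T, dtype=np.int64)]),
            np.concatenate([self.y_E, np.asarray(y_E, dtype=np.int64)]),
        )

    def counts(self, grid: DoseGrid) -> np.ndarray:
        """(K, 4) contingency table; cell order (1,1), (1,0), (0,1), (0,0).

        The likelihood depends on the data only through this table.
        """
        if len(self) and self.z.max() > grid.levels[-1]:
            raise ValueError("data contain doses outside the grid")
        out = np.zeros((grid.k, 4), dtype=np.int64)
        cell = 2 * (1 - self.y_T) + (1 - self.y_E)  # 0:(1,1) 1:(1,0) 2:(0,1) 3:(0,0)
        for k, z in enumerate(grid.levels):
            mask = self.z == z
            if mask.any():
                out[k] = np.bincount(cell[mask], minlength=4)
        return out


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    Normal priors on the intercepts and the efficacy quadratic coefficient,
    Gamma(shape, rate) priors on the two slopes, and uniform priors over the
    family's interval for the association parameter.
    """

    b0T_mean: float = -3.0
    b0T_sd: float = 3.0
    b0E_mean: float = -1.0
    b0E_sd: float = 3.0
    b2E_mean: float = 0.0
    b2E_sd: float = 0.25
    slope_shape_T: float = 0.25
    slope_rate_T: float = 0.25
    slope_shape_E: float = 0.25
    slope_rate_E: float = 0.25
    name: str = "PS1"

    def __post_init__(self) -> None:
        for attr in ("b0T_sd", "b0E_sd", "b2E_sd", "slope_shape_T", "slope_rate_T", "slope_shape_E", "slope_rate_E"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")

    @classmethod
    def preset(cls, name: str) -> "PriorSpec":
        """The four named prior sets (intercept sd 3 or 5, slope Gamma(1/4,1/4) or Gamma(1/25,1/25))."""
        name = name.upper()
        table = {
            "PS1": dict(b0T_sd=3.0, b0E_sd=3.0, shape=0.25),
            "PS2": dict(b0T_sd=5.0, b0E_sd=5.0, shape=0.25),
            "PS3": dict(b0T_sd=3.0, b0E_sd=3.0, shape=0.04),
            "PS4": dict(b0T_sd=5.0, b0E_sd=5.0, shape=0.04),
        }
        if name not in table:
            raise ValueError(f"unknown prior preset {name!r}; expected one of {sorted(table)}")
        t = table[name]
        return cls(
            b0T_sd=t["b0T_sd"],
            b0E_sd=t["b0E_sd"],
            slope_shape_T=t["shape"],
            slope_rate_T=t["shape"],
            slope_shape_E=t["shape"],
            slope_rate_E=t["shape"],
            name=name,
        )

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.b0T_mean,
                self.b0T_sd,
                self.b0E_mean,
                self.b0E_sd,
                self.b2E_mean,
                self.b2E_sd,
                self.slope_shape_T,
                self.slope_rate_T,
                self.slope_shape_E,
                self.slope_rate_E,
            ]
        )


@dataclass(frozen=True)
class MCMCConfig:
    burn_in: int = 5000
    retained: int = 1000
    thin: int = 1
    adapt_interval: int = 100
    target_acceptance: float = 0.35

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.retained < 1 or self.thin < 1:
            raise ValueError("invalid chain-length configuration")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained posterior draws plus sampler metadata.

    ``draws`` has one row per retained iteration and columns in the order of
    :data:`PARAM_NAMES`; slopes are on the natural (positive) scale and
    ``psi`` is NaN for the independence model.
    """

    draws: np.ndarray
    family: str
    burn_in: int
    retained: int
    seed: int
    acceptance_rates: Tuple[float, ...]
    param_names: Tuple[str, ...] = PARAM_NAMES

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    def ess(self, name: str) -> float:
        """Effective sample size via the initial-positive-sequence estimator."""
        x = self.column(name)
        x = x - x.mean()
        n = x.size
        var = float(np.dot(x, x)) / n
        if var == 0.0:
            return float(n)
        acf_sum = 0.0
        for lag in range(1, n):
            rho = float(np.dot(x[:-lag], x[lag:])) / (n * var)
            if rho <= 0.0:
                break
            acf_sum += rho
        return n / (1.0 + 2.0 * acf_sum)

    def to_frame(self):
        import pandas as pd

        cols = list(self.param_names if self.family != "independence" else self.param_names[:-1])
        return pd.DataFrame(self.draws[:, : len(cols)], columns=cols)


def log_likelihood(
    params: MarginalParams,
    copula: CopulaSpec,
    data: TrialData,
    grid: DoseGrid = DoseGrid(),
) -> float:
    """Log likelihood of accrued trial data under one joint model.

    Probabilities are clamped away from zero by 1e-12 inside the log only;
    a genuinely zero cell with a positive count yields ``-inf``.
    """
    if len(data) == 0:
        raise ValueError("data must be non-empty")
    counts = data.counts(grid)
    pairs = marginal_curves(params, grid)
    total = 0.0
    for k in range(grid.k):
        cells = joint_table(pairs[k], copula).as_array()
        c = counts[k]
        if np.any((cells <= 0.0) & (c > 0)):
            return float("-inf")
        total += float(np.dot(c, np.log(np.maximum(cells, 1e-12))))
    return total


def log_prior(params: MarginalParams, copula: CopulaSpec, prior: PriorSpec) -> float:
    """Log prior density at the natural parameter values."""
    lp = norm_dist.logpdf(params.beta0_T, prior.b0T_mean, prior.b0T_sd)
    lp += norm_dist.logpdf(params.beta0_E, prior.b0E_mean, prior.b0E_sd)
    lp += norm_dist.logpdf(params.beta2_E, prior.b2E_mean, prior.b2E_sd)
    lp += gamma_dist.logpdf(params.beta1_T, prior.slope_shape_T, scale=1.0 / prior.slope_rate_T)
    lp += gamma_dist.logpdf(params.beta1_E, prior.slope_shape_E, scale=1.0 / prior.slope_rate_E)
    if copula.family == "braun":
        lp += 0.0 if 0.0 < copula.psi < 1.0 else float("-inf")
    elif copula.family == "gumbel":
        lp += np.log(0.5) if -1.0 < copula.psi < 1.0 else float("-inf")
    return float(lp)


def _initial_state(prior: PriorSpec) -> np.ndarray:
    # prior means for intercepts/quadratic, slope 1.0, association at independence
    return np.array([prior.b0T_mean, 0.0, prior.b0E_mean, 0.0, prior.b2E_mean, 0.0])


def sample_posterior(
    data: TrialData,
    copula_family: str,
    prior: PriorSpec,
    mcmc: MCMCConfig = MCMCConfig(),
    seed: int = 0,
    grid: DoseGrid = DoseGrid(),
    init: Optional[np.ndarray] = None,
    update_mask: Optional[np.ndarray] = None,
    use_likelihood: bool = True,
) -> PosteriorDraws:
    """Draw from the posterior of the joint model's parameters.

    Parameters
    ----------
    data:
        Accrued outcomes; must be non-empty when ``use_likelihood`` is set.
    copula_family:
        ``"braun"``, ``"gumbel"`` or ``"independence"``.
    init:
        Optional 6-vector of *unconstrained* starting values (slopes on the
        log scale); defaults to prior means / independence.
    update_mask:
        Optional boolean 6-vector; parameters with ``False`` stay fixed at
        their initial value (used for reduced-problem validation).
    use_likelihood:
        When ``False`` the sampler targets the prior alone.
    """
    if copula_family not in _FAMILY_CODES:
        raise ValueError(f"unknown family {copula_family!r}")
    if use_likelihood and len(data) == 0:
        raise ValueError("data must be non-empty")
    counts = data.counts(grid) if len(data) else np.zeros((grid.k, 4), dtype=np.int64)
    if use_likelihood and (counts.sum(axis=1) == 0).any():
        warnings.warn("some dose arms have no observations", stacklevel=2)
    x0 = np.asarray(init, dtype=float).copy() if init is not None else _initial_state(prior)
    mask = (
        np.asarray(update_mask, dtype=np.bool_)
        if update_mask is not None
        else np.ones(6, dtype=np.bool_)
    )
    init_scales = np.array([0.5, 0.5, 0.8])
    draws_u, rates, _ = _kernels.run_chain(
        counts.astype(np.float64),
        _FAMILY_CODES[copula_family],
        prior.as_vector(),
        x0,
        mask,
        mcmc.burn_in,
        mcmc.retained,
        mcmc.thin,
        mcmc.adapt_interval,
        mcmc.target_acceptance,
        init_scales,
        int(seed) % (2**32),
        use_likelihood,
    )
    draws = draws_u.copy()
    draws[:, 1] = np.exp(draws_u[:, 1])
    draws[:, 3] = np.exp(draws_u[:, 3])
    if copula_family == "braun":
        draws[:, 5] = expit(draws_u[:, 5])
    elif copula_family == "gumbel":
        draws[:, 5] = 2.0 * expit(draws_u[:, 5]) - 1.0
    else:
        draws[:, 5] = np.nan
    n_blocks = 3 if copula_family != "independence" else 2
    return PosteriorDraws(
        draws=draws,
        family=copula_family,
        burn_in=mcmc.burn_in,
        retained=mcmc.retained,
        seed=int(seed),
        acceptance_rates=tuple(float(r) for r in rates[:n_blocks]),
    )


def posterior_dose_summaries(
    draws: PosteriorDraws,
    grid: DoseGrid = DoseGrid(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-draw, per-dose marginal outcome probabilities.

    Returns arrays ``(pi_T, pi_E)`` of shape (n_draws, K).  For the Braun
    family these are the corrected marginals (the model parameters are not
    the outcome marginals away from psi = 0.5); for the other families they
    are the logistic curves directly.
    """
    d = np.arange(grid.k, dtype=float)[None, :]
    b0t = draws.column("beta0_T")[:, None]
    b1t = draws.column("beta1_T")[:, None]
    b0e = draws.column("beta0_E")[:, None]
    b1e = draws.column("beta1_E")[:, None]
    b2e = draws.column("beta2_E")[:, None]
    pi_t = expit(b0t + b1t * d)
    pi_e = expit(b0e + b1e * d + b2e * d * d)
    if draws.family == "braun":
        psi = draws.column("psi")[:, None]
        k = 1.0 / ((1.0 - psi) * (1.0 - pi_t * pi_e) + psi * pi_t * pi_e)
        m_t = k * pi_t * ((1.0 - pi_e) * (1.0 - psi) + pi_e * psi)
        m_e = k * pi_e * ((1.0 - pi_t) * (1.0 - psi) + pi_t * psi)
        return m_t, m_e
    return pi_t, pi_e
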