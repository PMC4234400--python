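"""Trade-off design logic: acceptability, desirability and dose selection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .model_core import DoseGrid, MarginalPair

__all__ = [
    "DesignCriteria",
    "DoseDecision",
    "desirability",
    "desirability_values",
    "solve_q",
    "acceptable_doses",
    "next_dose",
]


@dataclass(frozen=True)
class DesignCriteria:
    """Trade-off constants driving acceptability and desirability.

    ``pibar_T`` is the maximum acceptable toxicity probability assuming
    100% efficacy; ``piunder_E`` the minimum acceptable efficacy
    probability assuming no toxicity; ``pistar`` an optional equally
    desirable pair used to calibrate ``q``; ``p_threshold`` the posterior
    probability cutoff for a dose to be acceptable.
    """

    pibar_T: float = 0.5
    piunder_E: float = 0.55
    q: float = 2.0
    pistar: Optional[Tuple[float, float]] = (0.25, 0.60)
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.pibar_T < 1.0 or not 0.0 < self.piunder_E < 1.0:
            raise ValueError("acceptability bounds must lie in (0, 1)")
        if self.q <= 0:
            raise ValueError("q must be positive")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class DoseDecision:
    """Outcome of one interim (or final) dosing decision."""

    acceptable_set: Tuple[int, ...]
    desirability: Dict[int, float]
    action: str  # "treat", "stop_futility" or "select"
    dose: Optional[int] = None

    def __post_init__(self) -> None:
        if self.action not in ("treat", "stop_futility", "select"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "stop_futility":
            if self.acceptable_set:
                raise ValueError("futility requires an empty acceptable set")
        elif self.dose is None:
            raise ValueError(f"action {self.action!r} requires a dose")


def desirability_values(pi_T, pi_E, criteria: DesignCriteria):
    """Vectorized trade-off index; 1 at (toxicity 0, efficacy 1)."""
    x = np.asarray(pi_T, dtype=float) / criteria.pibar_T
    y = (1.0 - np.asarray(pi_E, dtype=float)) / (1.0 - criteria.piunder_E)
    return 1.0 - (x**criteria.q + y**criteria.q) ** (1.0 / criteria.q)


def desirability(pair: MarginalPair, criteria: DesignCriteria) -> float:
    """Trade-off index of one (toxicity, efficacy) probability pair.

    ``1 - [(pi_T/pibar_T)^q + ((1-pi_E)/(1-piunder_E))^q]^(1/q)``; larger is
    more desirable.
    """
    return float(desirability_values(pair.pi_T, pair.pi_E, criteria))


def solve_q(pibar_T: float, piunder_E: float, pistar: Tuple[float, float]) -> float:
    """Contour exponent making the anchor pair ``pistar`` score exactly zero.

    Solves ``D(pistar; q) = 0`` for ``q`` by bracketing; raises if no sign
    change exists on (1e-6, 1e3).
    """
    x = pistar[0] / pibar_T
    y = (1.0 - pistar[1]) / (1.0 - piunder_E)
    if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
        raise ValueError("pistar must lie strictly inside both acceptability anchors")

    a, b = np.log(x), np.log(y)

    def f(q: float) -> float:
        # log-space q-norm; direct powers overflow for small q
        m = max(q * a, q * b)
        log_norm = (m + np.log(np.exp(q * a - m) + np.exp(q * b - m))) / q
        return 1.0 - float(np.exp(log_norm)) if log_norm < 0 else 1.0 - float(np.exp(min(log_norm, 700.0)))

    lo, hi = 1e-6, 1e3
    if f(lo) * f(hi) > 0:
        raise ValueError("no root: desirability does not change sign over the bracket")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-15))


def acceptable_doses(
    pi_T_draws: np.ndarray,
    pi_E_draws: np.ndarray,
    criteria: DesignCriteria,
    grid: DoseGrid = DoseGrid(),
) -> Tuple[int, ...]:
    """Doses whose joint posterior probability of tolerable toxicity and
    sufficient efficacy strictly exceeds the threshold.

    ``pi_T_draws``/``pi_E_draws`` are (n_draws, K) arrays of per-dose
    marginal probabilities.
    """
    pi_T_draws = np.atleast_2d(pi_T_draws)
    pi_E_draws = np.atleast_2d(pi_E_draws)
    if pi_T_draws.shape != pi_E_draws.shape or pi_T_draws.shape[1] != grid.k:
        raise ValueError("draw arrays must both be (n_draws, K)")
    if pi_T_draws.shape[0] < 1:
        raise ValueError("need at least one retained draw")
    ok = (pi_T_draws < criteria.pibar_T) & (pi_E_draws > criteria.piunder_E)
    frac = ok.mean(axis=0)
    return tuple(z for z, f in zip(grid.levels, frac) if f > criteria.p_threshold)


def _argmax_lowest(candidates: Sequence[int], desirability_by_dose: Dict[int, float]) -> int:
    # ties broken toward the lower dose
    best = None
    best_d = -np.inf
    for z in sorted(candidates):
        d = desirability_by_dose[z]
        if d > best_d:
            best, best_d = z, d
    return best


def next_dose(
    highest_tried: int,
    acceptable_set: Sequence[int],
    desirability_by_dose: Dict[int, float],
    at_max_sample_size: bool = False,
) -> DoseDecision:
    """One step of the adaptive dose-finding rule.

    With no acceptable dose the trial stops for futility.  At the maximum
    sample size the most desirable acceptable dose is selected.  Otherwise
    the next cohort is treated at the acceptable dose maximizing the
    desirability index, restricted so escalation never skips a level
    (candidates at most one level above the highest dose tried); if every
    acceptable dose is out of reach the trial escalates a single level
    toward them.
    """
    acceptable = tuple(sorted(acceptable_set))
    if not acceptable:
        return DoseDecision((), dict(desirability_by_dose), "stop_futility")
    if at_max_sample_size:
        z = _argmax_lowest(acceptable, desirability_by_dose)
        return DoseDecision(acceptable, dict(desirability_by_dose), "select", z)
    reachable = [z for z in acceptable if z <= highest_tried + 1]
    if reachable:
        z = _argmax_lowest(reachable, desirability_by_dose)
    else:
        z = highest_tried + 1
    return DoseDecision(acceptable, dict(desirability_by_dose), "treat", z)
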