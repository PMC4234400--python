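"""Dose-response marginals and bivariate binary joint probability models.

Three joint models for a binary (toxicity, efficacy) pair are supported:

* ``braun`` -- an exponential-family model with association parameter
  ``psi`` in (0, 1); ``psi/(1-psi)`` is the odds ratio between the two
  outcomes.  Its ``pi_T``/``pi_E`` parameters are *not* the marginal
  probabilities unless ``psi = 0.5``.
* ``gumbel`` -- an additive (Morgenstern-type) perturbation of the
  independence table with ``psi`` in (-1, 1); it preserves the input
  marginals exactly.
* ``independence`` -- the outer product of the marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "DoseGrid",
    "MarginalParams",
    "MarginalPair",
    "CopulaSpec",
    "JointTable",
    "NegativeCellError",
    "UndefinedConditionalError",
    "InversionError",
    "FAMILIES",
    "marginal_curves",
    "joint_table",
    "braun_true_marginals",
    "conditional_prob",
    "invert_braun_marginals",
]

FAMILIES = ("braun", "gumbel", "independence")


class NegativeCellError(ValueError):
    """A copula parameter combination produced a negative cell probability."""


class UndefinedConditionalError(ZeroDivisionError):
    """Conditioning event has probability zero."""


class InversionError(RuntimeError):
    """The marginal-inversion map failed to reach the requested tolerance."""


@dataclass(frozen=True)
class DoseGrid:
    """Ordered integer dose indices ``z = 1..K``."""

    levels: Tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        levels = tuple(int(z) for z in self.levels)
        object.__setattr__(self, "levels", levels)
        if not levels:
            raise ValueError("dose grid must be non-empty")
        if levels[0] != 1:
            raise ValueError("dose indices must start at 1")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("dose indices must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class MarginalParams:
    """Logistic regression coefficients for the two dose-response curves.

    ``beta0_T``/``beta0_E`` are the log-odds of toxicity/efficacy at the
    first dose level; slopes act per unit dose step (the predictors use
    ``z - 1`` so the intercepts keep that interpretation).
    """

    beta0_T: float
    beta1_T: float
    beta0_E: float
    beta1_E: float
    beta2_E: float = 0.0

    def __post_init__(self) -> None:
        if self.beta1_T <= 0:
            raise ValueError("beta1_T must be positive")
        if self.beta1_E <= 0:
            raise ValueError("beta1_E must be positive")


@dataclass(frozen=True)
class MarginalPair:
    """A (toxicity, efficacy) probability pair, both strictly in (0, 1)."""

    pi_T: float
    pi_E: float

    def __post_init__(self) -> None:
        for name, p in (("pi_T", self.pi_T), ("pi_E", self.pi_E)):
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name}={p!r} must lie strictly in (0, 1)")


@dataclass(frozen=True)
class CopulaSpec:
    """Joint-model family plus its association parameter.

    ``psi`` lives in (0, 1) for ``braun``, (-1, 1) for ``gumbel`` and is
    absent for ``independence``.
    """

    family: str
    psi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.family == "independence":
            if self.psi is not None:
                raise ValueError("independence model carries no association parameter")
        elif self.psi is None:
            raise ValueError(f"{self.family} model requires an association parameter")
        elif self.family == "braun" and not 0.0 < self.psi < 1.0:
            raise ValueError("braun psi must lie in (0, 1)")
        elif self.family == "gumbel" and not -1.0 < self.psi < 1.0:
            raise ValueError("gumbel psi must lie in (-1, 1)")


@dataclass(frozen=True)
class JointTable:
    """2x2 probability table over (y_T, y_E) outcomes at a single dose."""

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self) -> None:
        cells = (self.p11, self.p10, self.p01, self.p00)
        if any(c < 0 for c in cells):
            raise NegativeCellError(f"negative cell in joint table: {cells}")
        if abs(sum(cells) - 1.0) > 1e-12:
            raise ValueError(f"joint table cells sum to {sum(cells)!r}, not 1")

    def as_array(self) -> np.ndarray:
        """Cells in the fixed order (1,1), (1,0), (0,1), (0,0)."""
        return np.array([self.p11, self.p10, self.p01, self.p00])

    @property
    def marginal_T(self) -> float:
        return self.p11 + self.p10

    @property
    def marginal_E(self) -> float:
        return self.p11 + self.p01


def marginal_curves(params: MarginalParams, grid: DoseGrid) -> list[MarginalPair]:
    """Evaluate the logistic dose-toxicity and dose-efficacy curves.

    At dose ``z`` the toxicity probability is
    ``expit(beta0_T + beta1_T * (z - 1))`` and the efficacy probability is
    ``expit(beta0_E + beta1_E * (z - 1) + beta2_E * (z - 1)**2)``.
    """
    pairs = []
    for z in grid.levels:
        d = z - 1
        pi_t = float(expit(params.beta0_T + params.beta1_T * d))
        pi_e = float(expit(params.beta0_E + params.beta1_E * d + params.beta2_E * d * d))
        pairs.append(MarginalPair(pi_t, pi_e))
    return pairs


def _braun_norm_const(pi_t: float, pi_e: float, psi: float) -> float:
    # 1 / [ (1-psi)(1 - pi_T pi_E) + psi pi_T pi_E ]
    return 1.0 / ((1.0 - psi) * (1.0 - pi_t * pi_e) + psi * pi_t * pi_e)


def joint_table(pair: MarginalPair, copula: CopulaSpec) -> JointTable:
    """Build the 2x2 joint table for one dose under the given joint model."""
    pi_t, pi_e = pair.pi_T, pair.pi_E
    if copula.family == "braun":
        psi = copula.psi
        k = _braun_norm_const(pi_t, pi_e, psi)
        p11 = k * pi_t * pi_e * psi
        p10 = k * pi_t * (1.0 - pi_e) * (1.0 - psi)
        p01 = k * (1.0 - pi_t) * pi_e * (1.0 - psi)
        p00 = k * (1.0 - pi_t) * (1.0 - pi_e) * (1.0 - psi)
    elif copula.family == "gumbel":
        delta = pi_t * (1.0 - pi_t) * pi_e * (1.0 - pi_e) * copula.psi
        p11 = pi_t * pi_e + delta
        p10 = pi_t * (1.0 - pi_e) - delta
        p01 = (1.0 - pi_t) * pi_e - delta
        p00 = (1.0 - pi_t) * (1.0 - pi_e) + delta
        if min(p11, p10, p01, p00) < 0:
            raise NegativeCellError(
                f"gumbel psi={copula.psi} with marginals ({pi_t}, {pi_e}) "
                "yields a negative cell"
            )
    else:
        p11 = pi_t * pi_e
        p10 = pi_t * (1.0 - pi_e)
        p01 = (1.0 - pi_t) * pi_e
        p00 = (1.0 - pi_t) * (1.0 - pi_e)
    # renormalize away float round-off only; never clips a genuine cell
    s = p11 + p10 + p01 + p00
    return JointTable(p11 / s, p10 / s, p01 / s, p00 / s)


def braun_true_marginals(pair: MarginalPair, psi1: float) -> MarginalPair:
    """Actual outcome marginals implied by Braun parameters ``(pi_T, pi_E, psi1)``.

    The model's ``pi_T``/``pi_E`` parameters coincide with the marginal
    probabilities only at ``psi1 = 0.5``; otherwise

    ``Pr(Y_T = 1) = k * pi_T * [(1 - pi_E)(1 - psi1) + pi_E * psi1]``

    and symmetrically for efficacy, with ``k`` the normalizing constant.
    """
    if not 0.0 < psi1 < 1.0:
        raise ValueError("psi1 must lie in (0, 1)")
    pi_t, pi_e = pair.pi_T, pair.pi_E
    k = _braun_norm_const(pi_t, pi_e, psi1)
    m_t = k * pi_t * ((1.0 - pi_e) * (1.0 - psi1) + pi_e * psi1)
    m_e = k * pi_e * ((1.0 - pi_t) * (1.0 - psi1) + pi_t * psi1)
    return MarginalPair(m_t, m_e)


def conditional_prob(pair: MarginalPair, copula: CopulaSpec, given_yT: int) -> float:
    """Probability of ``Y_E = 1`` given ``Y_T = given_yT``."""
    if given_yT not in (0, 1):
        raise ValueError("given_yT must be 0 or 1")
    table = joint_table(pair, copula)
    denom = table.p11 + table.p10 if given_yT == 1 else table.p01 + table.p00
    if denom <= 0.0:
        raise UndefinedConditionalError(f"Pr(Y_T={given_yT}) is zero")
    num = table.p11 if given_yT == 1 else table.p01
    return num / denom


def _table_from_margins_and_or(m_t: float, m_e: float, theta: float) -> Tuple[float, float, float, float]:
    """2x2 cell probabilities with given margins and odds ratio ``theta``."""
    lo = max(0.0, m_t + m_e - 1.0)
    hi = min(m_t, m_e)
    if theta == 1.0:
        p11 = m_t * m_e
    else:
        a = theta - 1.0
        s = 1.0 + (m_t + m_e) * a
        disc = s * s - 4.0 * theta * a * m_t * m_e
        if disc < 0:
            raise InversionError("no real solution for the requested margins and odds ratio")
        root = math.sqrt(disc)
        candidates = [(s - root) / (2.0 * a), (s + root) / (2.0 * a)]
        p11 = None
        for c in candidates:
            if lo - 1e-12 <= c <= hi + 1e-12:
                p11 = min(max(c, lo), hi)
                break
        if p11 is None:
            raise InversionError(
                f"no admissible cell for margins ({m_t}, {m_e}) and odds ratio {theta}"
            )
    return p11, m_t - p11, m_e - p11, 1.0 - m_t - m_e + p11


def invert_braun_marginals(target: MarginalPair, psi1: float) -> MarginalPair:
    """Braun parameters whose *realized* marginals equal ``target``.

    Solved in closed form: the Braun table is the unique 2x2 table with odds
    ratio ``psi1/(1-psi1)`` and the realized margins, from which the model
    parameters are recovered as ``pi_T = p10/(p10+p00)`` and
    ``pi_E = p01/(p01+p00)``.  The forward map is verified to reproduce the
    target within 1e-8.
    """
    if not 0.0 < psi1 < 1.0:
        raise ValueError("psi1 must lie in (0, 1)")
    theta = psi1 / (1.0 - psi1)
    p11, p10, p01, p00 = _table_from_margins_and_or(target.pi_T, target.pi_E, theta)
    if p10 + p00 <= 0 or p01 + p00 <= 0:
        raise InversionError("degenerate table during inversion")
    result = MarginalPair(p10 / (p10 + p00), p01 / (p01 + p00))
    realized = braun_true_marginals(result, psi1)
    if abs(realized.pi_T - target.pi_T) > 1e-8 or abs(realized.pi_E - target.pi_E) > 1e-8:
        raise InversionError(
            f"inversion residual exceeds 1e-8 for target {target} at psi1={psi1}"
        )
    return result
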