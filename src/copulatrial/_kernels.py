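"""Numba-compiled numerical core for the posterior sampler.

Everything here works on plain arrays so it can be JIT-compiled; the
user-facing wrappers live in :mod:`copulatrial.inference`.

Parameter vector layout (unconstrained scale)::

    x[0] = beta0_T
    x[1] = log(beta1_T)
    x[2] = beta0_E
    x[3] = log(beta1_E)
    x[4] = beta2_E
    x[5] = logit-type transform of the association parameter

Family codes: 0 = braun, 1 = gumbel, 2 = independence.
Count matrix: shape (K, 4) with cell order (1,1), (1,0), (0,1), (0,0).
"""

import math

import numpy as np
from numba import njit

BRAUN = 0
GUMBEL = 1
INDEPENDENCE = 2

# prior vector layout
_P_B0T_MEAN, _P_B0T_SD = 0, 1
_P_B0E_MEAN, _P_B0E_SD = 2, 3
_P_B2E_MEAN, _P_B2E_SD = 4, 5
_P_SHAPE_T, _P_RATE_T = 6, 7
_P_SHAPE_E, _P_RATE_E = 8, 9

_CLAMP = 1e-12


@njit(cache=True)
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def log_likelihood_counts(x, counts, family):
    """Log likelihood from the per-dose outcome-count contingency table."""
    b0t, b1t = x[0], math.exp(x[1])
    b0e, b1e, b2e = x[2], math.exp(x[3]), x[4]
    out = 0.0
    k_doses = counts.shape[0]
    for kd in range(k_doses):
        d = float(kd)
        pt = _expit(b0t + b1t * d)
        pe = _expit(b0e + b1e * d + b2e * d * d)
        if family == BRAUN:
            psi = _expit(x[5])
            kc = 1.0 / ((1.0 - psi) * (1.0 - pt * pe) + psi * pt * pe)
            c11 = kc * pt * pe * psi
            c10 = kc * pt * (1.0 - pe) * (1.0 - psi)
            c01 = kc * (1.0 - pt) * pe * (1.0 - psi)
            c00 = kc * (1.0 - pt) * (1.0 - pe) * (1.0 - psi)
        elif family == GUMBEL:
            psi = 2.0 * _expit(x[5]) - 1.0
            delta = pt * (1.0 - pt) * pe * (1.0 - pe) * psi
            c11 = pt * pe + delta
            c10 = pt * (1.0 - pe) - delta
            c01 = (1.0 - pt) * pe - delta
            c00 = (1.0 - pt) * (1.0 - pe) + delta
        else:
            c11 = pt * pe
            c10 = pt * (1.0 - pe)
            c01 = (1.0 - pt) * pe
            c00 = (1.0 - pt) * (1.0 - pe)
        # clamp only inside the likelihood, never in table construction
        if c11 < _CLAMP:
            c11 = _CLAMP
        if c10 < _CLAMP:
            c10 = _CLAMP
        if c01 < _CLAMP:
            c01 = _CLAMP
        if c00 < _CLAMP:
            c00 = _CLAMP
        out += (
            counts[kd, 0] * math.log(c11)
            + counts[kd, 1] * math.log(c10)
            + counts[kd, 2] * math.log(c01)
            + counts[kd, 3] * math.log(c00)
        )
    return out


@njit(cache=True)
def _norm_logpdf(v, mean, sd):
    z = (v - mean) / sd
    return -0.5 * z * z - math.log(sd) - 0.9189385332046727


@njit(cache=True)
def _gamma_logpdf(v, shape, rate):
    if v <= 0.0:
        return -np.inf
    return (
        shape * math.log(rate)
        - math.lgamma(shape)
        + (shape - 1.0) * math.log(v)
        - rate * v
    )


@njit(cache=True)
def log_prior_jacobian(x, prior, family):
    """Log prior density of the natural parameters plus transform Jacobians."""
    b1t = math.exp(x[1])
    b1e = math.exp(x[3])
    lp = _norm_logpdf(x[0], prior[_P_B0T_MEAN], prior[_P_B0T_SD])
    lp += _norm_logpdf(x[2], prior[_P_B0E_MEAN], prior[_P_B0E_SD])
    lp += _norm_logpdf(x[4], prior[_P_B2E_MEAN], prior[_P_B2E_SD])
    lp += _gamma_logpdf(b1t, prior[_P_SHAPE_T], prior[_P_RATE_T]) + x[1]
    lp += _gamma_logpdf(b1e, prior[_P_SHAPE_E], prior[_P_RATE_E]) + x[3]
    if family == BRAUN:
        e = _expit(x[5])
        # Uniform(0,1) prior (constant) + logit Jacobian
        lp += math.log(e) + math.log(1.0 - e)
    elif family == GUMBEL:
        e = _expit(x[5])
        # Uniform(-1,1) prior (constant) + scaled-logit Jacobian
        lp += math.log(2.0) + math.log(e) + math.log(1.0 - e)
    return lp


@njit(cache=True)
def _log_target(x, counts, family, prior, use_lik):
    lp = log_prior_jacobian(x, prior, family)
    if use_lik:
        lp += log_likelihood_counts(x, counts, family)
    return lp


@njit(cache=True)
def run_chain(
    counts,
    family,
    prior,
    x0,
    update_mask,
    n_burn,
    n_ret,
    thin,
    adapt_interval,
    target_acc,
    init_scales,
    seed,
    use_lik,
):
    """Adaptive random-walk Metropolis-within-Gibbs.

    Three blocks: toxicity coefficients (0, 1), efficacy coefficients
    (2, 3, 4) and the association transform (5).  Proposal scales adapt
    toward ``target_acc`` during burn-in only, so the retained chain is
    Markov.  Returns (draws, acceptance_rates, final_scales).
    """
    np.random.seed(seed)
    n_par = 6
    x = x0.copy()
    blocks = [
        np.array([0, 1], dtype=np.int64),
        np.array([2, 3, 4], dtype=np.int64),
        np.array([5], dtype=np.int64),
    ]
    n_blocks = 3 if family != INDEPENDENCE else 2
    scales = init_scales.copy()
    cur_lp = _log_target(x, counts, family, prior, use_lik)

    acc = np.zeros(3)
    att = np.zeros(3)
    acc_post = np.zeros(3)
    att_post = np.zeros(3)
    draws = np.empty((n_ret, n_par))
    n_total = n_burn + n_ret * thin
    kept = 0
    prop = np.empty(n_par)
    for it in range(n_total):
        in_burn = it < n_burn
        for b in range(n_blocks):
            idx = blocks[b]
            any_free = False
            for j in idx:
                if update_mask[j]:
                    any_free = True
            if not any_free:
                continue
            for j in range(n_par):
                prop[j] = x[j]
            for j in idx:
                if update_mask[j]:
                    prop[j] = x[j] + scales[b] * np.random.normal()
            new_lp = _log_target(prop, counts, family, prior, use_lik)
            att[b] += 1.0
            if not in_burn:
                att_post[b] += 1.0
            if new_lp - cur_lp > math.log(np.random.random()):
                for j in range(n_par):
                    x[j] = prop[j]
                cur_lp = new_lp
                acc[b] += 1.0
                if not in_burn:
                    acc_post[b] += 1.0
        if in_burn and adapt_interval > 0 and (it + 1) % adapt_interval == 0:
            for b in range(n_blocks):
                if att[b] > 0.0:
                    rate = acc[b] / att[b]
                    scales[b] *= math.exp(0.7 * (rate - target_acc))
                    if scales[b] < 1e-3:
                        scales[b] = 1e-3
                    elif scales[b] > 10.0:
                        scales[b] = 10.0
                acc[b] = 0.0
                att[b] = 0.0
        if not in_burn and (it - n_burn + 1) % thin == 0:
            draws[kept, :] = x
            kept += 1

    rates = np.zeros(3)
    for b in range(3):
        if att_post[b] > 0.0:
            rates[b] = acc_post[b] / att_post[b]
    return draws, rates, scales
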