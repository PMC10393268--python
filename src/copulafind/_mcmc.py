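"""Adaptive random-walk Metropolis kernel for the copula-type models.

The three model parameters are sampled on an unconstrained scale: the
marginal intercepts ``a`` and ``b`` directly, and the interaction ``gamma``
through a link chosen by its admissible space (identity on R, shifted log on
half-lines, logit on bounded intervals).  All proposal noise and the
accept/reject uniforms are pre-generated by the caller from a seeded numpy
Generator and passed in, so draws are reproducible bit-for-bit and do not
depend on numba's internal RNG.

The numpy-side log-posterior in :mod:`copulafind.model` is the reference
implementation; this kernel must agree with it up to additive constants
(unit-tested), and exists purely so that a full simulated trial costs
milliseconds rather than seconds.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# family codes (order matches copulafind.families.CopulaFamily)
FAM_CLAYTON, FAM_GUMM, FAM_GUMH, FAM_FRANK, FAM_AMH, FAM_JOE, FAM_FGM = range(7)

# gamma-link codes
LINK_IDENTITY = 0   # gamma = t
LINK_LOG_LO = 1     # gamma = lo + exp(t)
LINK_NEG_LOG_HI = 2  # gamma = hi - exp(t)
LINK_LOGIT = 3      # gamma = lo + (hi-lo)*sigmoid(t)

# gamma-prior codes
PRIOR_UNIFORM = 0    # constant on its support (support == the space)
PRIOR_TRUNCNORM = 1  # normal(mu, sd) renormalised on the space
PRIOR_GAMMA = 2      # Gamma(shape, rate) on (0, inf)

_NEG_INF = -math.inf


@njit(cache=True)
def _pi_scalar(fam, g, x, y):
    """Joint toxicity probability for margins x, y; mirrors families.py."""
    if x <= 0.0:
        if y <= 0.0:
            return 0.0
        return y
    if y <= 0.0:
        return x
    if x >= 1.0 or y >= 1.0:
        return 1.0
    if fam == FAM_AMH:
        return 1.0 - (1.0 - x) * (1.0 - y) / (1.0 - g * x * y)
    if fam == FAM_FGM:
        return 1.0 - (1.0 - x) * (1.0 - y) * (1.0 + g * x * y)
    if fam == FAM_GUMM:
        return 1.0 - (1.0 - x) * (1.0 - y) * (1.0 + x * y * math.tanh(0.5 * g))
    if fam == FAM_GUMH:
        A = -math.log1p(-x)
        B = -math.log1p(-y)
        if A < B:
            A, B = B, A
        r = B / A
        rg = math.exp(g * math.log(r)) if r < 1.0 else 1.0
        val = math.log1p(rg) / g
        if val > 700.0:
            val = 700.0
        T = A * math.exp(val)
        if T > 700.0:
            T = 700.0
        return -math.expm1(-T)
    if fam == FAM_JOE:
        xa = x if x >= y else y
        xb = y if x >= y else x
        la = math.log(xa)
        w = g * math.log(xb / xa) if xb < xa else 0.0
        r = math.exp(w) * (-math.expm1(g * la))
        logpi = la + math.log1p(r) / g
        if logpi > 0.0:
            logpi = 0.0
        return math.exp(logpi)
    if fam == FAM_CLAYTON:
        if g == 0.0:
            return 1.0 - (1.0 - x) * (1.0 - y)
        if g > 0.0:
            A = -g * math.log1p(-x)
            B = -g * math.log1p(-y)
            M = A if A >= B else B
            logS = M + math.log(math.exp(A - M) + math.exp(B - M) - math.exp(-M))
            return 1.0 - math.exp(-logS / g)
        S = (1.0 - x) ** (-g) + (1.0 - y) ** (-g) - 1.0
        if S <= 0.0:
            return 1.0
        return 1.0 - S ** (-1.0 / g)
    # FAM_FRANK
    u = 1.0 - x
    v = 1.0 - y
    if abs(g) < 1e-6:
        # series around the removable singularity at g = 0
        return 1.0 - u * v * (1.0 + 0.5 * g * (1.0 - u) * (1.0 - v))
    if g > 0.0:
        sm = u if u <= v else v
        tm = v if u <= v else u
        inner = (
            math.exp(-g * (tm - sm))
            - math.exp(-g * tm)
            - math.exp(-g * (1.0 - sm))
        )
        C = sm - (math.log1p(inner) - math.log1p(-math.exp(-g))) / g
        return 1.0 - C
    gn = -g
    tu = gn * u + math.log1p(-math.exp(-gn * u))
    tv = gn * v + math.log1p(-math.exp(-gn * v))
    t1 = gn + math.log1p(-math.exp(-gn))
    z = tu + tv - t1
    if z < 0.0:
        lae = math.log1p(math.exp(z))
    else:
        lae = z + math.log1p(math.exp(-z))
    return 1.0 - lae / gn


@njit(cache=True)
def _gamma_from_t(t, link, lo, hi):
    """Back-transform and log-Jacobian; returns (gamma, logjac, ok)."""
    if link == LINK_IDENTITY:
        return t, 0.0, True
    if link == LINK_LOG_LO:
        if t > 690.0:
            return 0.0, 0.0, False
        return lo + math.exp(t), t, True
    if link == LINK_NEG_LOG_HI:
        if t > 690.0:
            return 0.0, 0.0, False
        return hi - math.exp(t), t, True
    # LINK_LOGIT
    if t >= 0.0:
        s = 1.0 / (1.0 + math.exp(-t))
    else:
        e = math.exp(t)
        s = e / (1.0 + e)
    if s <= 0.0 or s >= 1.0:
        return 0.0, 0.0, False
    g = lo + (hi - lo) * s
    return g, math.log(hi - lo) + math.log(s) + math.log1p(-s), True


@njit(cache=True)
def _logpost(a, b, t, fam, link, lo, hi, prior, pp1, pp2,
             logp, logq, ncells, mcells):
    """Unnormalised log-posterior on the unconstrained scale."""
    g, logjac, ok = _gamma_from_t(t, link, lo, hi)
    if not ok:
        return _NEG_INF
    if g < lo or g > hi:
        return _NEG_INF
    # gamma prior (unnormalised on the space)
    if prior == PRIOR_UNIFORM:
        lp = 0.0
    elif prior == PRIOR_TRUNCNORM:
        z = (g - pp1) / pp2
        lp = -0.5 * z * z
    else:  # PRIOR_GAMMA
        if g <= 0.0:
            return _NEG_INF
        lp = (pp1 - 1.0) * math.log(g) + (-pp2) * g
    lp += logjac - 0.5 * (a * a + b * b)
    if a > 40.0 or a < -40.0 or b > 40.0 or b < -40.0:
        return _NEG_INF
    alpha = math.exp(a)
    beta = math.exp(b)
    for k in range(logp.shape[0]):
        if ncells[k] == 0:
            continue
        x = math.exp(alpha * logp[k])
        y = math.exp(beta * logq[k])
        pi = _pi_scalar(fam, g, x, y)
        if pi < 1e-15:
            pi = 1e-15
        elif pi > 1.0 - 1e-15:
            pi = 1.0 - 1e-15
        lp += mcells[k] * math.log(pi) + (ncells[k] - mcells[k]) * math.log1p(-pi)
    return lp


@njit(cache=True)
def rwm_sample(theta0, scales0, n_iter, burn_in, thin, n_keep, Z, logU,
               adapt_interval, target_accept,
               fam, link, lo, hi, prior, pp1, pp2,
               logp, logq, ncells, mcells):
    """Adaptive random-walk Metropolis; adaptation frozen after burn-in.

    ``Z``: (n_iter, 3) standard-normal increments; ``logU``: (n_iter,) log
    uniforms.  Returns (draws[n_keep, 3] of (a, b, gamma), accepted count
    post burn-in, final scales).
    """
    a, b, t = theta0[0], theta0[1], theta0[2]
    s0, s1, s2 = scales0[0], scales0[1], scales0[2]
    lp = _logpost(a, b, t, fam, link, lo, hi, prior, pp1, pp2,
                  logp, logq, ncells, mcells)
    draws = np.empty((n_keep, 3))
    acc_window = 0
    acc_post = 0
    kept = 0
    for it in range(n_iter):
        pa = a + s0 * Z[it, 0]
        pb = b + s1 * Z[it, 1]
        pt = t + s2 * Z[it, 2]
        lpp = _logpost(pa, pb, pt, fam, link, lo, hi, prior, pp1, pp2,
                       logp, logq, ncells, mcells)
        if lpp - lp > logU[it]:
            a, b, t = pa, pb, pt
            lp = lpp
            acc_window += 1
            if it >= burn_in:
                acc_post += 1
        if it < burn_in and (it + 1) % adapt_interval == 0:
            rate = acc_window / adapt_interval
            fac = math.exp(rate - target_accept)
            s0 *= fac
            s1 *= fac
            s2 *= fac
            if s0 < 1e-3:
                s0 = 1e-3
            if s1 < 1e-3:
                s1 = 1e-3
            if s2 < 1e-3:
                s2 = 1e-3
            if s0 > 50.0:
                s0 = 50.0
            if s1 > 50.0:
                s1 = 50.0
            if s2 > 50.0:
                s2 = 50.0
            acc_window = 0
        if it >= burn_in and (it - burn_in + 1) % thin == 0 and kept < n_keep:
            g, _, _ = _gamma_from_t(t, link, lo, hi)
            draws[kept, 0] = a
            draws[kept, 1] = b
            draws[kept, 2] = g
            kept += 1
    scales = np.empty(3)
    scales[0], scales[1], scales[2] = s0, s1, s2
    return draws, acc_post, scales
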