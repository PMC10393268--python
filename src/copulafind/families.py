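"""Copula-type joint-toxicity surfaces for two-drug combinations.

A copula-type dose-toxicity model expresses the joint DLT probability of a
dose pair as ``pi = 1 - C(1 - p**alpha, 1 - q**beta)`` where ``C`` is a
one-parameter bivariate copula, ``p`` and ``q`` are working (skeleton)
toxicity probabilities for the two drugs, and the copula parameter ``gamma``
encodes the drug-drug toxicity interaction.  Seven classical families are
implemented (Clayton, Gumbel-Murtaugh, Gumbel-Hougaard, Frank,
Ali-Mikhail-Haq, Joe, Farlie-Gumbel-Morgenstern), each with its *original*
parameter space -- the set of ``gamma`` for which the construction is a
genuine joint distribution function with a nonnegative density -- and, for
AMH, GUMH and Joe, an *extended* space obtained by dropping the
density-nonnegativity requirement while keeping ``0 <= pi <= 1``.  The
extension releases the Frechet-Hoeffding upper bound
``pi <= min(p**alpha + q**beta, 1)`` and lets the surface express extreme
synergistic toxicity.

All surface evaluations broadcast over numpy arrays and are numerically
stable for ``|gamma|`` up to ~1e8 (log-space evaluation throughout).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "CopulaFamily",
    "CopulaSpec",
    "ModelParams",
    "MarginalSkeleton",
    "GammaSpaceError",
    "UnsupportedExtensionError",
    "gamma_space",
    "joint_prob_from_margins",
    "joint_tox_prob",
    "independence_gamma",
    "fh_bounds",
    "pi_range",
    "amh_density_sign",
]

_HUGE_GAMMA = 1e8  # finite surrogate realising gamma -> +/-inf limits
_EXP_CLIP = 700.0  # exp() overflow guard


class CopulaFamily(str, enum.Enum):
    """The seven one-parameter copula families."""

    CLAYTON = "Clayton"
    GUMM = "GUMM"  # Gumbel-Murtaugh
    GUMH = "GUMH"  # Gumbel-Hougaard
    FRANK = "Frank"
    AMH = "AMH"  # Ali-Mikhail-Haq
    JOE = "Joe"
    FGM = "FGM"  # Farlie-Gumbel-Morgenstern


class GammaSpaceError(ValueError):
    """Interaction parameter outside the admissible space."""


class UnsupportedExtensionError(ValueError):
    """Extended space requested for a family that has none."""


def _as_family(family) -> CopulaFamily:
    if isinstance(family, CopulaFamily):
        return family
    try:
        return CopulaFamily(str(family))
    except ValueError:
        # tolerate case-insensitive names
        for f in CopulaFamily:
            if f.value.lower() == str(family).lower():
                return f
        raise ValueError(f"unknown copula family: {family!r}") from None


@dataclass(frozen=True)
class CopulaSpec:
    """A copula family together with an admissible space for ``gamma``.

    ``space`` is ``"original"`` (the family's proper copula range) or
    ``"extended"`` (density-sign requirement dropped).  Interval endpoints
    may be ``+-inf``; ``lo_open``/``hi_open`` record openness and
    ``excluded`` lists isolated removable singularities (``{0}`` for
    Clayton and Frank, where the independence surface is the analytic
    limit).
    """

    family: CopulaFamily
    space: str
    gamma_lo: float
    gamma_hi: float
    lo_open: bool
    hi_open: bool
    excluded: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.gamma_lo < self.gamma_hi:
            raise ValueError("gamma_lo must be < gamma_hi")

    def contains(self, gamma: float, *, allow_excluded: bool = False) -> bool:
        """Whether ``gamma`` lies in the space.

        With ``allow_excluded=True`` the removable singularities (routed to
        their analytic limit by the surface evaluator) count as admissible.
        """
        g = float(gamma)
        if not np.isfinite(g):
            return False
        if g < self.gamma_lo or (self.lo_open and g == self.gamma_lo):
            return False
        if g > self.gamma_hi or (self.hi_open and g == self.gamma_hi):
            return False
        if not allow_excluded and g in self.excluded:
            return False
        return True

    def validate_gamma(self, gamma: float, *, allow_excluded: bool = True) -> float:
        if not self.contains(gamma, allow_excluded=allow_excluded):
            raise GammaSpaceError(
                f"gamma={gamma!r} outside the {self.space} space of "
                f"{self.family.value}: {self.describe()}"
            )
        return float(gamma)

    def describe(self) -> str:
        lo = "(" if self.lo_open else "["
        hi = ")" if self.hi_open else "]"
        s = f"{lo}{self.gamma_lo:g}, {self.gamma_hi:g}{hi}"
        if self.excluded:
            s += " \\ {" + ", ".join(f"{e:g}" for e in sorted(self.excluded)) + "}"
        return s


_INF = math.inf

_ORIGINAL: dict[CopulaFamily, CopulaSpec] = {
    # Clayton was introduced with gamma > 0 but the working range is
    # [-1, inf) \ {0}; gamma = -1 attains the upper Frechet-Hoeffding bound.
    CopulaFamily.CLAYTON: CopulaSpec(
        CopulaFamily.CLAYTON, "original", -1.0, _INF, False, True, frozenset({0.0})
    ),
    CopulaFamily.GUMM: CopulaSpec(CopulaFamily.GUMM, "original", -_INF, _INF, True, True),
    CopulaFamily.GUMH: CopulaSpec(CopulaFamily.GUMH, "original", 1.0, _INF, False, True),
    CopulaFamily.FRANK: CopulaSpec(
        CopulaFamily.FRANK, "original", -_INF, _INF, True, True, frozenset({0.0})
    ),
    CopulaFamily.AMH: CopulaSpec(CopulaFamily.AMH, "original", -1.0, 1.0, False, True),
    CopulaFamily.JOE: CopulaSpec(CopulaFamily.JOE, "original", 1.0, _INF, False, True),
    CopulaFamily.FGM: CopulaSpec(CopulaFamily.FGM, "original", -1.0, 1.0, False, True),
}

_EXTENDED: dict[CopulaFamily, CopulaSpec] = {
    CopulaFamily.AMH: CopulaSpec(CopulaFamily.AMH, "extended", -_INF, 1.0, True, True),
    CopulaFamily.GUMH: CopulaSpec(CopulaFamily.GUMH, "extended", 0.0, _INF, True, True),
    CopulaFamily.JOE: CopulaSpec(CopulaFamily.JOE, "extended", 0.0, _INF, True, True),
}


def gamma_space(family, variant: str = "original") -> CopulaSpec:
    """Admissible interaction-parameter space of a family.

    ``variant="extended"`` exists only for AMH, GUMH and Joe, whose spaces
    can be enlarged (to (-inf,1), (0,inf) and (0,inf) respectively) without
    the joint probability ever leaving [0, 1].
    """
    fam = _as_family(family)
    if variant == "original":
        return _ORIGINAL[fam]
    if variant == "extended":
        if fam not in _EXTENDED:
            raise UnsupportedExtensionError(
                f"{fam.value} has no extended gamma space (only AMH, GUMH, Joe do)"
            )
        return _EXTENDED[fam]
    raise ValueError(f"variant must be 'original' or 'extended', got {variant!r}")


@dataclass(frozen=True)
class ModelParams:
    """Unconstrained model parameters.

    The marginal exponents are ``exp(a)`` and ``exp(b)`` so that ``a`` and
    ``b`` live on the whole real line (standard-normal priors apply to the
    intercepts directly); ``gamma`` is the interaction parameter and must
    lie in the active :class:`CopulaSpec`.
    """

    a: float
    b: float
    gamma: float


@dataclass(frozen=True)
class MarginalSkeleton:
    """Strictly increasing working toxicity probabilities per dose level."""

    p: np.ndarray  # drug A, length I
    q: np.ndarray  # drug B, length J

    def __post_init__(self):
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        for name, v in (("p", self.p), ("q", self.q)):
            if v.ndim != 1 or v.size == 0:
                raise ValueError(f"skeleton {name} must be a nonempty 1-D vector")
            if np.any(v <= 0) or np.any(v >= 1):
                raise ValueError(f"skeleton {name} values must lie in (0, 1)")
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"skeleton {name} must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.size, self.q.size


class IndependencePoint(NamedTuple):
    """The gamma at which the surface equals 1-(1-x)(1-y) for all margins.

    ``is_limit`` flags families (Clayton, Frank) where that gamma is an
    excluded removable singularity reached only as a limit.
    """

    gamma: float
    is_limit: bool


def independence_gamma(family) -> IndependencePoint:
    fam = _as_family(family)
    return {
        CopulaFamily.CLAYTON: IndependencePoint(0.0, True),
        CopulaFamily.GUMM: IndependencePoint(0.0, False),
        CopulaFamily.GUMH: IndependencePoint(1.0, False),
        CopulaFamily.FRANK: IndependencePoint(0.0, True),
        CopulaFamily.AMH: IndependencePoint(0.0, False),
        CopulaFamily.JOE: IndependencePoint(1.0, False),
        CopulaFamily.FGM: IndependencePoint(0.0, False),
    }[fam]


def fh_bounds(p_alpha, q_beta):
    """Frechet-Hoeffding bounds ``max(x,y) <= pi <= min(x+y, 1)``.

    Arguments are the transformed margins ``x = p**alpha`` and
    ``y = q**beta``; broadcasts over arrays.
    """
    x = np.asarray(p_alpha, dtype=float)
    y = np.asarray(q_beta, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("margins must be finite")
    if np.any(x < 0) or np.any(x > 1) or np.any(y < 0) or np.any(y > 1):
        raise ValueError("margins must lie in [0, 1]")
    lower = np.maximum(x, y)
    upper = np.minimum(x + y, 1.0)
    if lower.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


# ---------------------------------------------------------------------------
# surface evaluation (vectorised, log-space stable)
# ---------------------------------------------------------------------------


def _independence(x, y):
    return 1.0 - (1.0 - x) * (1.0 - y)


def _pi_clayton(gamma, x, y):
    g = gamma
    one = np.ones_like(x * y * g)
    x, y, g = x * one, y * one, g * one
    out = np.empty_like(x)

    pos = g > 0
    neg = (g < 0) & (g >= -1)
    zer = g == 0

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if np.any(pos):
            gp = np.where(pos, g, 1.0)
            # A, B >= 0; S = e^A + e^B - 1 >= 1
            A = -gp * np.log1p(-x)
            B = -gp * np.log1p(-y)
            M = np.maximum(A, B)
            inner = np.exp(A - M) + np.exp(B - M) - np.exp(-M)
            logS = M + np.log(inner)
            val = 1.0 - np.exp(-logS / gp)
            # x==1 or y==1 -> A or B = inf -> pi = 1
            val = np.where(np.isinf(M), 1.0, val)
            out[pos] = val[pos]
        if np.any(neg):
            gn = np.where(neg, g, -1.0)
            S = np.power(1.0 - x, -gn) + np.power(1.0 - y, -gn) - 1.0
            val = np.where(S > 0, 1.0 - np.power(np.maximum(S, 1e-300), -1.0 / gn), 1.0)
            out[neg] = val[neg]
        if np.any(zer):
            out[zer] = _independence(x, y)[zer]
    return out


def _pi_gumm(gamma, x, y):
    t = np.tanh(np.asarray(gamma, dtype=float) / 2.0)
    return 1.0 - (1.0 - x) * (1.0 - y) * (1.0 + x * y * t)


def _pi_gumh(gamma, x, y):
    g = gamma
    one = np.ones_like(x * y * g)
    x, y, g = x * one, y * one, g * one
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        A = -np.log1p(-x)
        B = -np.log1p(-y)
        Amax = np.maximum(A, B)
        Amin = np.minimum(A, B)
        r = np.where(Amax > 0, Amin / np.where(Amax > 0, Amax, 1.0), 0.0)
        # T = Amax * (1 + r^g)^(1/g), computed as exp(log1p(r^g)/g)
        rg = np.where(r > 0, np.exp(g * np.log(np.where(r > 0, r, 1.0))), 0.0)
        factor = np.exp(np.minimum(np.log1p(rg) / g, _EXP_CLIP))
        T = np.minimum(Amax * factor, _EXP_CLIP)
        T = np.where(np.isinf(Amax), np.inf, T)
        out = -np.expm1(-T)
        out = np.where(Amax == 0, 0.0, out)
    return out


def _pi_frank(gamma, x, y):
    g0 = np.asarray(gamma, dtype=float)
    one = np.ones_like(x * y * g0)
    x, y, g = x * one, y * one, g0 * one
    u = 1.0 - x
    v = 1.0 - y
    out = np.full_like(x, np.nan)
    pos = g >= 1e-6
    neg = g <= -1e-6
    zer = np.abs(g) < 1e-6
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if np.any(pos):
            gp = np.where(pos, g, 1.0)
            # With s = min(u,v), t = max(u,v):
            #   C = s - (1/g) [log1p(e^{-g(t-s)} - e^{-g t} - e^{-g(1-s)})
            #                  - log1p(-e^{-g})]
            # which realises the comonotone limit C -> min(u,v) as g -> inf.
            sm = np.minimum(u, v)
            tm = np.maximum(u, v)
            inner = (
                np.exp(-gp * (tm - sm))
                - np.exp(-gp * tm)
                - np.exp(-gp * (1.0 - sm))
            )
            C = sm - (np.log1p(inner) - np.log1p(-np.exp(-gp))) / gp
            val = 1.0 - C
            val = np.where(u == 0, 1.0, np.where(v == 0, 1.0, val))
            val = np.where((x == 0) | (y == 0), np.maximum(x, y), val)
            out[pos] = val[pos]
        if np.any(neg):
            gn = np.where(neg, -g, 1.0)  # gn = |gamma|
            # C = (1/gn) * log(1 + (e^{gn u}-1)(e^{gn v}-1)/(e^{gn}-1))
            tu = gn * u + np.log1p(-np.exp(-gn * u))
            tv = gn * v + np.log1p(-np.exp(-gn * v))
            t1 = gn + np.log1p(-np.exp(-gn))
            C = np.logaddexp(0.0, tu + tv - t1) / gn
            val = 1.0 - C
            val = np.where(u == 0, 1.0, np.where(v == 0, 1.0, val))
            out[neg] = val[neg]
        if np.any(zer):
            # series around the removable singularity:
            # C = uv (1 + g(1-u)(1-v)/2) + O(g^2)
            val = 1.0 - u * v * (1.0 + 0.5 * g * (1.0 - u) * (1.0 - v))
            out[zer] = val[zer]
    return np.clip(out, 0.0, 1.0)


def _pi_amh(gamma, x, y):
    return 1.0 - (1.0 - x) * (1.0 - y) / (1.0 - gamma * x * y)


def _pi_joe(gamma, x, y):
    g = gamma
    one = np.ones_like(x * y * g)
    x, y, g = x * one, y * one, g * one
    xa = np.maximum(x, y)
    xb = np.minimum(x, y)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # pi^g = xa^g (1 + (xb/xa)^g (1 - xa^g));  log pi = log xa + log1p(r)/g
        la = np.log(np.where(xa > 0, xa, 1.0))
        ratio = np.where(xa > 0, xb / np.where(xa > 0, xa, 1.0), 0.0)
        r = np.where(ratio > 0, np.exp(g * np.log(np.where(ratio > 0, ratio, 1.0))), 0.0)
        r = r * (-np.expm1(g * la))
        logpi = la + np.log1p(r) / g
        out = np.exp(np.minimum(logpi, 0.0))
    out = np.where(xa == 0, 0.0, out)  # both margins zero
    out = np.where((xb == 0) & (xa > 0), xa, out)  # one margin zero -> other
    return out


def _pi_fgm(gamma, x, y):
    return 1.0 - (1.0 - x) * (1.0 - y) * (1.0 + gamma * x * y)


_EVALUATORS = {
    CopulaFamily.CLAYTON: _pi_clayton,
    CopulaFamily.GUMM: _pi_gumm,
    CopulaFamily.GUMH: _pi_gumh,
    CopulaFamily.FRANK: _pi_frank,
    CopulaFamily.AMH: _pi_amh,
    CopulaFamily.JOE: _pi_joe,
    CopulaFamily.FGM: _pi_fgm,
}


def joint_prob_from_margins(family, gamma, p_alpha, q_beta, *, check: bool = True):
    """Joint DLT probability from transformed margins ``x=p**alpha``, ``y=q**beta``.

    Broadcasts over arrays in ``gamma``, ``p_alpha`` and ``q_beta``.  The
    removable singularities of Clayton and Frank at ``gamma=0`` evaluate to
    the independence surface.  Range checks can be disabled for hot loops.
    """
    fam = _as_family(family)
    x = np.asarray(p_alpha, dtype=float)
    y = np.asarray(q_beta, dtype=float)
    if check:
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise ValueError("margins must be finite (no NaN/inf)")
        if np.any((x < 0) | (x > 1)) or np.any((y < 0) | (y > 1)):
            raise ValueError("margins must lie in [0, 1]")
    g = np.asarray(gamma, dtype=float)
    out = _EVALUATORS[fam](g, x, y)
    out = np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def joint_tox_prob(spec: CopulaSpec, params: ModelParams, p, q):
    """Joint toxicity probability ``pi(p, q)`` under ``spec`` at ``params``.

    Forms the margins ``p**exp(a)`` and ``q**exp(b)`` and evaluates the
    family formula; ``gamma`` must lie in the spec's space (the analytic
    independence limit is accepted at excluded points).
    """
    spec.validate_gamma(params.gamma, allow_excluded=True)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(~np.isfinite(q)):
        raise ValueError("p and q must be finite")
    if np.any((p < 0) | (p > 1)) or np.any((q < 0) | (q > 1)):
        raise ValueError("p and q must lie in [0, 1]")
    alpha = math.exp(min(max(params.a, -_EXP_CLIP), _EXP_CLIP))
    beta = math.exp(min(max(params.b, -_EXP_CLIP), _EXP_CLIP))
    with np.errstate(invalid="ignore"):
        x = np.power(p, alpha)
        y = np.power(q, beta)
    return joint_prob_from_margins(spec.family, params.gamma, x, y, check=False)


# ---------------------------------------------------------------------------
# attainable range and density sign
# ---------------------------------------------------------------------------


def _gamma_grid(spec: CopulaSpec, n_linear: int = 2001, n_log: int = 400) -> np.ndarray:
    """A grid over the space's closure; +-inf endpoints by a huge surrogate."""
    lo = max(spec.gamma_lo, -_HUGE_GAMMA)
    hi = min(spec.gamma_hi, _HUGE_GAMMA)
    pieces = [np.linspace(max(lo, -20.0), min(hi, 20.0), n_linear)]
    if hi > 20.0:
        pieces.append(np.power(10.0, np.linspace(np.log10(20.0), np.log10(hi), n_log)))
    if lo < -20.0:
        pieces.append(-np.power(10.0, np.linspace(np.log10(20.0), np.log10(-lo), n_log)))
    # approach open endpoints at zero (extended GUMH/Joe have gamma -> 0+)
    if spec.gamma_lo == 0.0:
        pieces.append(np.power(10.0, np.linspace(-12, 1, 200)))
    if spec.gamma_hi == 0.0:
        pieces.append(-np.power(10.0, np.linspace(-12, 1, 200)))
    grid = np.unique(np.concatenate([np.atleast_1d(p) for p in pieces]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    if spec.lo_open and math.isfinite(spec.gamma_lo):
        grid = grid[grid > spec.gamma_lo]
    if spec.hi_open and math.isfinite(spec.gamma_hi):
        grid = grid[grid < spec.gamma_hi]
    # closure: closed endpoints exactly, open finite endpoints by a nudge
    eps = 1e-9
    lo_pt = lo if (not spec.lo_open or not math.isfinite(spec.gamma_lo)) else lo + eps
    hi_pt = hi if (not spec.hi_open or not math.isfinite(spec.gamma_hi)) else hi - eps
    grid = np.concatenate([grid, [lo_pt, hi_pt]])
    # the excluded points' limits belong to the closure of the attained set
    for e in spec.excluded:
        grid = np.concatenate([grid, [e]])
    return np.unique(grid)


def pi_range(spec: CopulaSpec, p_alpha: float, q_beta: float) -> tuple[float, float]:
    """Infimum and supremum of ``pi`` over the gamma space (closure).

    Every implemented family is monotone in ``gamma``, so the extrema sit at
    the (possibly infinite) endpoints; a dense scan over the whole space is
    used regardless, so no monotonicity is assumed.  At margins 0.15 the
    results reproduce the published per-family ranges to 2 decimals.
    """
    x, y = float(p_alpha), float(q_beta)
    if not (0 < x < 1 and 0 < y < 1):
        if not (0 <= x <= 1 and 0 <= y <= 1):
            raise ValueError("margins must lie in [0, 1]")
    grid = _gamma_grid(spec)
    vals = joint_prob_from_margins(spec.family, grid, x, y, check=False)
    vals = np.atleast_1d(vals)
    return float(np.min(vals)), float(np.max(vals))


def amh_density_sign(gamma: float, grid_resolution: int = 100) -> str:
    """Sign check of the AMH joint density over the unit square.

    The mixed second derivative of the AMH JDF factorises into the positive
    marginal densities times the copula density
    ``c(u, v) = (1 - gamma + 2*gamma*C(u, v)) / D(u, v)**2`` with
    ``D = 1 - gamma*(1-u)*(1-v)`` and ``C = u*v/D``.  For gamma in the
    original space [-1, 1) the density is nonnegative everywhere; in the
    extended space gamma < -1 it goes negative somewhere, which is exactly
    the constraint the extension drops.

    Returns ``"all_nonnegative"`` or ``"negative_somewhere"``.
    """
    g = gamma_space(CopulaFamily.AMH, "extended").validate_gamma(gamma)
    n = int(grid_resolution)
    u = np.linspace(0.0, 1.0, n + 2)[1:-1]
    U, V = np.meshgrid(u, u, indexing="ij")
    D = 1.0 - g * (1.0 - U) * (1.0 - V)
    C = U * V / D
    dens = (1.0 - g + 2.0 * g * C) / (D * D)
    return "negative_somewhere" if np.min(dens) < -1e-12 else "all_nonnegative"
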