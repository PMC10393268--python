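"""Bayesian inference for copula-type dose-toxicity models.

The observational model is binomial over the dose grid: at combination
``(i, j)``, ``m_ij ~ Binomial(n_ij, pi_ij)`` with
``pi_ij = 1 - C(1 - p_i**exp(a), 1 - q_j**exp(b); gamma)`` for the active
copula family.  Priors are standard normal on the intercepts ``a`` and
``b`` and, on ``gamma``, whichever of uniform / truncated-normal / gamma
distribution matches the design; the posterior is explored with an adaptive
random-walk Metropolis sampler on the unconstrained scale.

Usage follows the Model / Results convention::

    model = CombinationToxicityModel(data, spec, skeleton)
    res = model.fit(seed=1)          # full published MCMC effort by default
    summ = res.summaries(phi=0.3, delta=0.1)
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, xlogy

from . import _mcmc
from .families import (
    CopulaFamily,
    CopulaSpec,
    MarginalSkeleton,
    ModelParams,
    joint_prob_from_margins,
    joint_tox_prob,
)

__all__ = [
    "TrialData",
    "UniformInteractionPrior",
    "TruncatedNormalInteractionPrior",
    "GammaInteractionPrior",
    "PriorSpec",
    "McmcSettings",
    "mcmc_profile",
    "default_gamma_prior",
    "CombinationToxicityModel",
    "CombinationToxicityResults",
    "PosteriorSummaries",
    "log_likelihood",
    "log_posterior",
    "sample_posterior",
    "posterior_summaries",
]


# ---------------------------------------------------------------------------
# data
# ---------------------------------------------------------------------------


@dataclass
class TrialData:
    """Per-combination patient and DLT counts over the dose grid."""

    n: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        if self.n.shape != self.m.shape or self.n.ndim != 2:
            raise ValueError("n and m must be 2-D arrays of identical shape")
        if np.any(self.n < 0) or np.any(self.m < 0) or np.any(self.m > self.n):
            raise ValueError("need 0 <= m_ij <= n_ij elementwise")

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "TrialData":
        return cls(np.zeros(shape, dtype=np.int64), np.zeros(shape, dtype=np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.n.shape

    @property
    def total_n(self) -> int:
        return int(self.n.sum())

    @property
    def total_dlt(self) -> int:
        return int(self.m.sum())

    def add(self, cell: tuple[int, int], n_new: int, dlt: int) -> None:
        """Record ``n_new`` patients with ``dlt`` DLTs at 1-based ``cell``."""
        i, j = cell
        if dlt < 0 or dlt > n_new:
            raise ValueError("need 0 <= dlt <= n_new")
        self.n[i - 1, j - 1] += n_new
        self.m[i - 1, j - 1] += dlt

    def treated_cells(self) -> list[tuple[int, int]]:
        """1-based combinations with at least one treated patient."""
        ii, jj = np.nonzero(self.n)
        return [(int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)]

    def copy(self) -> "TrialData":
        return TrialData(self.n.copy(), self.m.copy())


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UniformInteractionPrior:
    """gamma ~ Uniform(lo, hi)."""

    lo: float
    hi: float

    def logpdf(self, g: float) -> float:
        if self.lo <= g <= self.hi:
            return -math.log(self.hi - self.lo)
        return -math.inf

    def median(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def support(self) -> tuple[float, float]:
        return self.lo, self.hi

    def _kernel_code(self):
        return _mcmc.PRIOR_UNIFORM, 0.0, 0.0


@dataclass(frozen=True)
class TruncatedNormalInteractionPrior:
    """gamma ~ N(mean, sd^2) renormalised on [lo, hi]."""

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def _dist(self):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def logpdf(self, g: float) -> float:
        return float(self._dist().logpdf(g))

    def median(self) -> float:
        return float(self._dist().ppf(0.5))

    def support(self) -> tuple[float, float]:
        return self.lo, self.hi

    def _kernel_code(self):
        return _mcmc.PRIOR_TRUNCNORM, float(self.mean), float(self.sd)


@dataclass(frozen=True)
class GammaInteractionPrior:
    """gamma ~ Gamma(shape, rate) on (0, inf); rate parameterisation."""

    shape: float
    rate: float

    def _dist(self):
        return stats.gamma(a=self.shape, scale=1.0 / self.rate)

    def logpdf(self, g: float) -> float:
        if g <= 0:
            return -math.inf
        return float(self._dist().logpdf(g))

    def median(self) -> float:
        return float(self._dist().ppf(0.5))

    def support(self) -> tuple[float, float]:
        return 0.0, math.inf

    def _kernel_code(self):
        return _mcmc.PRIOR_GAMMA, float(self.shape), float(self.rate)


InteractionPrior = Union[
    UniformInteractionPrior, TruncatedNormalInteractionPrior, GammaInteractionPrior
]


@dataclass(frozen=True)
class PriorSpec:
    """Priors: a, b ~ N(0, 1); gamma per the supplied interaction prior."""

    gamma: InteractionPrior

    def validate_against(self, spec: CopulaSpec) -> None:
        lo, hi = self.gamma.support()
        if lo < spec.gamma_lo or hi > spec.gamma_hi:
            raise ValueError(
                f"gamma prior support [{lo:g}, {hi:g}] not contained in the "
                f"{spec.space} space {spec.describe()} of {spec.family.value}"
            )

    def logpdf(self, params: ModelParams) -> float:
        lp = stats.norm.logpdf(params.a) + stats.norm.logpdf(params.b)
        return float(lp + self.gamma.logpdf(params.gamma))


def default_gamma_prior(spec: CopulaSpec) -> InteractionPrior:
    """The published prior for the family/space pairs used by the designs."""
    fam, space = spec.family, spec.space
    if fam is CopulaFamily.AMH and space == "original":
        return UniformInteractionPrior(-1.0, 1.0)
    if fam in (CopulaFamily.GUMH, CopulaFamily.JOE) and space == "original":
        return TruncatedNormalInteractionPrior(1.0, 3.0, lo=1.0)
    if fam is CopulaFamily.AMH and space == "extended":
        return TruncatedNormalInteractionPrior(0.0, 1500.0, hi=1.0)
    if fam in (CopulaFamily.GUMH, CopulaFamily.JOE) and space == "extended":
        return GammaInteractionPrior(0.5, 0.5)
    raise ValueError(
        f"no default interaction prior for {fam.value} ({space}); pass a PriorSpec"
    )


# ---------------------------------------------------------------------------
# sampler settings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McmcSettings:
    """Random-walk Metropolis effort and adaptation knobs.

    Defaults follow the published analysis: 10 000 kept draws after 1000
    burn-in iterations with thinning interval 3 (30 000 post-burn-in
    iterations), one chain.
    """

    n_keep: int = 10000
    burn_in: int = 1000
    thin: int = 3
    n_chains: int = 1
    adapt_interval: int = 50
    target_accept: float = 0.3
    initial_scale: float = 0.5

    def __post_init__(self):
        for name in ("n_keep", "burn_in", "thin", "n_chains", "adapt_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_iter(self) -> int:
        return self.burn_in + self.n_keep * self.thin


_PROFILES = {
    "full": McmcSettings(),
    "desk": McmcSettings(n_keep=2000, burn_in=500, thin=1),
    "smoke": McmcSettings(n_keep=400, burn_in=200, thin=1),
}


def mcmc_profile(name: str) -> McmcSettings:
    """Named effort profiles: 'full' (10000/1000/3), 'desk' (2000/500/1),
    'smoke' (400/200/1, unit tests only)."""
    try:
        return _PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown MCMC profile {name!r}; choose from {sorted(_PROFILES)}"
        ) from None


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def _link_for(spec: CopulaSpec) -> int:
    lo_f, hi_f = math.isfinite(spec.gamma_lo), math.isfinite(spec.gamma_hi)
    if lo_f and hi_f:
        return _mcmc.LINK_LOGIT
    if lo_f:
        return _mcmc.LINK_LOG_LO
    if hi_f:
        return _mcmc.LINK_NEG_LOG_HI
    return _mcmc.LINK_IDENTITY


def _forward_t(gamma: float, link: int, lo: float, hi: float) -> float:
    if link == _mcmc.LINK_IDENTITY:
        return gamma
    if link == _mcmc.LINK_LOG_LO:
        return math.log(max(gamma - lo, 1e-12))
    if link == _mcmc.LINK_NEG_LOG_HI:
        return math.log(max(hi - gamma, 1e-12))
    s = (gamma - lo) / (hi - lo)
    s = min(max(s, 1e-12), 1 - 1e-12)
    return math.log(s / (1 - s))


class CombinationToxicityModel:
    """Copula-type dose-toxicity model over a two-drug dose grid.

    Parameters
    ----------
    data : TrialData
        Patient and DLT counts per combination; shape (I, J).
    spec : CopulaSpec
        Copula family plus gamma-space variant.
    skeleton : MarginalSkeleton
        Working toxicity probabilities per dose level of each drug.
    prior : PriorSpec, optional
        Defaults to the published prior for the family/space pair.
    """

    def __init__(
        self,
        data: TrialData,
        spec: CopulaSpec,
        skeleton: MarginalSkeleton,
        prior: Optional[PriorSpec] = None,
    ):
        if data.shape != skeleton.shape:
            raise ValueError(
                f"data shape {data.shape} does not match skeleton {skeleton.shape}"
            )
        if prior is None:
            try:
                prior = PriorSpec(default_gamma_prior(spec))
            except ValueError:
                prior = None  # likelihood-only use stays possible
        if prior is not None:
            prior.validate_against(spec)
        self.data = data
        self.spec = spec
        self.skeleton = skeleton
        self.prior = prior

    @classmethod
    def from_counts(cls, n, m, spec, skeleton, prior=None) -> "CombinationToxicityModel":
        return cls(TrialData(np.asarray(n), np.asarray(m)), spec, skeleton, prior)

    # -- densities ---------------------------------------------------------

    def pi_surface(self, params: ModelParams) -> np.ndarray:
        """Implied joint-toxicity matrix over the grid (I, J)."""
        P, Q = np.meshgrid(self.skeleton.p, self.skeleton.q, indexing="ij")
        return np.asarray(joint_tox_prob(self.spec, params, P, Q))

    def loglike(self, params: ModelParams) -> float:
        """Binomial log-likelihood (including binomial coefficients)."""
        pi = self.pi_surface(params)
        n, m = self.data.n, self.data.m
        coef = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = coef + xlogy(m, pi) + xlogy(n - m, 1.0 - pi)
        terms = np.where(n == 0, 0.0, terms)
        return float(terms.sum())

    def logprior(self, params: ModelParams) -> float:
        if self.prior is None:
            raise ValueError("no prior specified for this model")
        return self.prior.logpdf(params)

    def logpost(self, params: ModelParams) -> float:
        if not self.spec.contains(params.gamma, allow_excluded=True):
            return -math.inf
        lp = self.logprior(params)
        if not math.isfinite(lp):
            return lp
        return lp + self.loglike(params)

    # -- sampling ----------------------------------------------------------

    def _kernel_args(self):
        if self.prior is None:
            raise ValueError("no prior specified for this model")
        fam_code = list(CopulaFamily).index(self.spec.family)
        link = _link_for(self.spec)
        prior_code, pp1, pp2 = self.prior.gamma._kernel_code()
        P, Q = np.meshgrid(self.skeleton.p, self.skeleton.q, indexing="ij")
        mask = self.data.n.ravel() > 0
        logp = np.log(P.ravel()[mask])
        logq = np.log(Q.ravel()[mask])
        ncells = self.data.n.ravel()[mask].astype(np.float64)
        mcells = self.data.m.ravel()[mask].astype(np.float64)
        if logp.size == 0:  # zero-data grid: kernel loop is empty
            logp = np.zeros(1)
            logq = np.zeros(1)
            ncells = np.zeros(1)
            mcells = np.zeros(1)
        return fam_code, link, prior_code, pp1, pp2, logp, logq, ncells, mcells

    def fit(
        self,
        settings: Optional[McmcSettings] = None,
        seed=None,
        max_init_retries: int = 20,
    ) -> "CombinationToxicityResults":
        """Sample the posterior; identical seed gives identical draws."""
        if settings is None:
            settings = McmcSettings()
        rng = np.random.default_rng(seed)
        fam_code, link, prior_code, pp1, pp2, logp, logq, ncells, mcells = (
            self._kernel_args()
        )
        lo, hi = self.spec.gamma_lo, self.spec.gamma_hi

        g0 = self.prior.gamma.median()
        theta0 = np.array([0.0, 0.0, _forward_t(g0, link, lo, hi)])
        lp0 = _mcmc._logpost(
            theta0[0], theta0[1], theta0[2], fam_code, link, lo, hi,
            prior_code, pp1, pp2, logp, logq, ncells, mcells,
        )
        retries = 0
        while not math.isfinite(lp0):
            retries += 1
            if retries > max_init_retries:
                raise RuntimeError("could not find a finite-posterior starting point")
            theta0 = rng.normal(scale=1.0, size=3)
            lp0 = _mcmc._logpost(
                theta0[0], theta0[1], theta0[2], fam_code, link, lo, hi,
                prior_code, pp1, pp2, logp, logq, ncells, mcells,
            )

        scales0 = np.full(3, settings.initial_scale)
        chains = []
        acc = 0
        for _ in range(settings.n_chains):
            Z = rng.standard_normal((settings.n_iter, 3))
            logU = np.log(rng.random(settings.n_iter))
            draws, acc_post, _ = _mcmc.rwm_sample(
                theta0, scales0, settings.n_iter, settings.burn_in, settings.thin,
                settings.n_keep, Z, logU, settings.adapt_interval,
                settings.target_accept, fam_code, link, lo, hi,
                prior_code, pp1, pp2, logp, logq, ncells, mcells,
            )
            chains.append(draws)
            acc += acc_post
        all_draws = np.vstack(chains)
        accept_rate = acc / (settings.n_chains * (settings.n_iter - settings.burn_in))
        return CombinationToxicityResults(self, all_draws, accept_rate, settings)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PosteriorSummaries:
    """Per-combination posterior summaries used by the trial design."""

    mean_pi: np.ndarray      # E[pi_ij | D]
    pr_below: np.ndarray     # Pr(pi_ij < phi | D)
    pr_above: np.ndarray     # Pr(pi_ij > phi | D)
    pr_interval: np.ndarray  # Pr(pi_ij in [phi-delta, phi+delta] | D)
    phi: float
    delta: float

    def at(self, cell: tuple[int, int]) -> dict:
        i, j = cell
        return {
            "mean_pi": float(self.mean_pi[i - 1, j - 1]),
            "pr_below": float(self.pr_below[i - 1, j - 1]),
            "pr_above": float(self.pr_above[i - 1, j - 1]),
            "pr_interval": float(self.pr_interval[i - 1, j - 1]),
        }

    def frame(self) -> pd.DataFrame:
        I, J = self.mean_pi.shape
        rows = []
        for i in range(1, I + 1):
            for j in range(1, J + 1):
                rows.append({"i": i, "j": j, **self.at((i, j))})
        return pd.DataFrame(rows)


class CombinationToxicityResults:
    """Posterior draws and summaries for a fitted copula-type model.

    ``draws`` is an (n_draws, 3) array of (a, b, gamma); the implied
    toxicity surfaces are computed lazily.
    """

    def __init__(self, model, draws, accept_rate, settings):
        self.model = model
        self.draws = np.asarray(draws, dtype=float)
        self.accept_rate = float(accept_rate)
        self.settings = settings
        self._pi_draws = None

    @property
    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=["a", "b", "gamma"])

    def pi_draws(self) -> np.ndarray:
        """Per-draw toxicity surfaces, shape (n_draws, I, J)."""
        if self._pi_draws is None:
            sk = self.model.skeleton
            a = np.clip(self.draws[:, 0], -40, 40)
            b = np.clip(self.draws[:, 1], -40, 40)
            g = self.draws[:, 2]
            x = np.power(sk.p[None, :], np.exp(a)[:, None])  # (n, I)
            y = np.power(sk.q[None, :], np.exp(b)[:, None])  # (n, J)
            self._pi_draws = joint_prob_from_margins(
                self.model.spec.family,
                g[:, None, None],
                x[:, :, None],
                y[:, None, :],
                check=False,
            )
        return self._pi_draws

    def summaries(self, phi: float = 0.3, delta: float = 0.1) -> PosteriorSummaries:
        pi = self.pi_draws()
        return PosteriorSummaries(
            mean_pi=pi.mean(axis=0),
            pr_below=(pi < phi).mean(axis=0),
            pr_above=(pi > phi).mean(axis=0),
            pr_interval=((pi >= phi - delta) & (pi <= phi + delta)).mean(axis=0),
            phi=phi,
            delta=delta,
        )

    def summary(self, phi: float = 0.3, delta: float = 0.1) -> str:
        """Readable text summary of parameters and the toxicity surface."""
        pf = self.params_frame
        qs = pf.quantile([0.025, 0.5, 0.975])
        tab = pd.DataFrame(
            {
                "mean": pf.mean(),
                "sd": pf.std(),
                "2.5%": qs.loc[0.025],
                "50%": qs.loc[0.5],
                "97.5%": qs.loc[0.975],
            }
        )
        s = self.summaries(phi=phi, delta=delta)
        lines = [
            "Copula-type combination toxicity model",
            f"  family: {self.model.spec.family.value} "
            f"({self.model.spec.space} space {self.model.spec.describe()})",
            f"  data: {self.model.data.total_n} patients, "
            f"{self.model.data.total_dlt} DLTs over grid "
            f"{self.model.data.shape[0]}x{self.model.data.shape[1]}",
            f"  draws: {self.draws.shape[0]}  acceptance: {self.accept_rate:.2f}",
            "",
            tab.to_string(float_format=lambda v: f"{v:10.4f}"),
            "",
            f"Posterior mean toxicity surface (phi={phi:g}):",
            pd.DataFrame(
                s.mean_pi,
                index=[f"i={i}" for i in range(1, s.mean_pi.shape[0] + 1)],
                columns=[f"j={j}" for j in range(1, s.mean_pi.shape[1] + 1)],
            ).to_string(float_format=lambda v: f"{v:6.3f}"),
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        """Export draws (one row per draw: a, b, gamma)."""
        self.params_frame.to_csv(path, index=False)

    def plot_surface(self, ax=None):
        """Heatmap of the posterior-mean toxicity surface."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.summaries()
        im = ax.imshow(s.mean_pi.T, origin="lower", cmap="viridis", vmin=0, vmax=1)
        ax.set_xlabel("drug A level (i)")
        ax.set_ylabel("drug B level (j)")
        ax.figure.colorbar(im, ax=ax, label="posterior mean DLT probability")
        return ax


# ---------------------------------------------------------------------------
# functional wrappers (operation-style API)
# ---------------------------------------------------------------------------


def log_likelihood(spec, params, data, skeleton) -> float:
    return CombinationToxicityModel(data, spec, skeleton).loglike(params)


def log_posterior(spec, params, data, skeleton, prior: PriorSpec) -> float:
    return CombinationToxicityModel(data, spec, skeleton, prior).logpost(params)


def sample_posterior(spec, data, skeleton, prior=None, settings=None, seed=None):
    return CombinationToxicityModel(data, spec, skeleton, prior).fit(
        settings=settings, seed=seed
    )


def posterior_summaries(results: CombinationToxicityResults, phi=0.3, delta=0.1):
    return results.summaries(phi=phi, delta=delta)
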