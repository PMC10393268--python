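"""Two-stage dose-escalation design and MTDC determination.

Stage 1 is rule-based: starting from the lowest combination (1, 1), cohorts
walk up the diagonal dose groups (all combinations with equal ``i + j``),
sampling without replacement within a group, until the first cohort
containing a DLT.  Stage 2 is model-based: after each cohort the posterior
of the copula-type model is refreshed and the dose moves to the adjacent
combination whose posterior-mean toxicity is closest to the target ``phi``
when escalation (``Pr(pi < phi | D) > c_e``) or de-escalation
(``Pr(pi > phi | D) > c_d``) is indicated; with ``c_e + c_d > 1`` the two
can never fire together.  At the end of the trial the MTDC is the treated
combination maximising ``Pr(pi in [phi - delta, phi + delta] | D)``.

An optional safety stop declares the whole grid overly toxic when
``Pr(pi_11 > phi | D) > lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .families import CopulaSpec, MarginalSkeleton, gamma_space
from .model import (
    McmcSettings,
    PosteriorSummaries,
    PriorSpec,
    TrialData,
    TruncatedNormalInteractionPrior,
    default_gamma_prior,
    mcmc_profile,
)

__all__ = [
    "SKELETON_LEVELS",
    "default_skeleton",
    "DESIGN_LABELS",
    "design_config",
    "DesignConfig",
    "TrialState",
    "stage1_next",
    "stage2_next",
    "check_stopping",
    "select_mtdc",
]

# Working toxicity probabilities by number of dose levels.
SKELETON_LEVELS = {
    2: (0.1, 0.3),
    3: (0.1, 0.2, 0.3),
    4: (0.075, 0.15, 0.225, 0.3),
    5: (0.06, 0.12, 0.18, 0.24, 0.30),
}


def default_skeleton(shape: tuple[int, int]) -> MarginalSkeleton:
    """Skeleton auto-selected by grid dimension (2-5 levels per drug)."""
    I, J = shape
    try:
        return MarginalSkeleton(np.array(SKELETON_LEVELS[I]), np.array(SKELETON_LEVELS[J]))
    except KeyError:
        raise ValueError(f"no default skeleton for {I}x{J} grids (levels must be 2-5)")


# Design labels: family + gamma-space variant, with the published priors.
DESIGN_LABELS = {
    "AMH-O": ("AMH", "original"),
    "GUMH-O": ("GUMH", "original"),
    "Joe-O": ("Joe", "original"),
    "AMH-E": ("AMH", "extended"),
    "GUMH-E": ("GUMH", "extended"),
    "Joe-E": ("Joe", "extended"),
}


@dataclass(frozen=True)
class DesignConfig:
    """All knobs of the dose-finding design.

    ``ce``/``cd`` are the escalation / de-escalation posterior thresholds
    (must satisfy ce + cd > 1), ``delta`` the half-width of the target
    interval used for MTDC selection, ``lam`` the early-stopping threshold
    (active only when ``stopping_enabled``).
    """

    spec: CopulaSpec
    skeleton: MarginalSkeleton
    prior: PriorSpec
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    phi: float = 0.3
    ce: float = 0.75
    cd: float = 0.55
    delta: float = 0.1
    lam: float = 0.95
    cohort_size: int = 3
    max_n: int = 30
    stopping_enabled: bool = False
    label: str = ""

    def __post_init__(self):
        if not (0 < self.phi < 1):
            raise ValueError("phi must lie in (0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not self.ce + self.cd > 1:
            raise ValueError("need ce + cd > 1 (escalate/de-escalate exclusivity)")
        if self.cohort_size <= 0 or self.max_n <= 0 or self.max_n % self.cohort_size:
            raise ValueError("max_n must be a positive multiple of cohort_size")
        self.prior.validate_against(self.spec)

    @property
    def shape(self) -> tuple[int, int]:
        return self.skeleton.shape

    @property
    def n_cohorts(self) -> int:
        return self.max_n // self.cohort_size


def design_config(
    label: str,
    shape: tuple[int, int],
    *,
    mcmc: Optional[McmcSettings] = None,
    profile: Optional[str] = None,
    gamma_prior_sd: Optional[float] = None,
    **kwargs,
) -> DesignConfig:
    """Build the configuration for a named design (e.g. ``"AMH-E"``).

    ``gamma_prior_sd`` overrides the prior SD of the AMH-E truncated-normal
    interaction prior (default 1500), supporting prior-sensitivity sweeps.
    """
    try:
        family, variant = DESIGN_LABELS[label]
    except KeyError:
        raise ValueError(
            f"unknown design label {label!r}; known: {', '.join(DESIGN_LABELS)}"
        ) from None
    spec = gamma_space(family, variant)
    gp = default_gamma_prior(spec)
    if gamma_prior_sd is not None:
        if not isinstance(gp, TruncatedNormalInteractionPrior):
            raise ValueError(f"{label} has no truncated-normal gamma prior to rescale")
        gp = replace(gp, sd=float(gamma_prior_sd))
    if mcmc is None:
        mcmc = mcmc_profile(profile) if profile else McmcSettings()
    elif profile is not None:
        raise ValueError("pass either mcmc settings or a profile name, not both")
    return DesignConfig(
        spec=spec,
        skeleton=default_skeleton(shape),
        prior=PriorSpec(gp),
        mcmc=mcmc,
        label=label,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# trial state
# ---------------------------------------------------------------------------

STAGE_RULE = "rule_based"
STAGE_MODEL = "model_based"


@dataclass
class TrialState:
    """Accumulating state of one trial."""

    data: TrialData
    current: tuple[int, int]
    stage: str
    stage1_group: int  # current diagonal index (i + j)
    stage1_remaining: set
    allocation_log: list = field(default_factory=list)

    @classmethod
    def new(cls, shape: tuple[int, int]) -> "TrialState":
        return cls(
            data=TrialData.empty(shape),
            current=(1, 1),
            stage=STAGE_RULE,
            stage1_group=2,
            stage1_remaining=set(),
            allocation_log=[],
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def group_cells(self, g: int) -> list[tuple[int, int]]:
        """Combinations on the diagonal ``i + j == g`` (sorted by i)."""
        I, J = self.shape
        return [(i, g - i) for i in range(1, I + 1) if 1 <= g - i <= J]

    def record(self, cell, n_new: int, dlt: int, rationale: str = "") -> None:
        self.data.add(cell, n_new, dlt)
        self.current = cell
        self.allocation_log.append(
            {
                "cohort": len(self.allocation_log) + 1,
                "i": cell[0],
                "j": cell[1],
                "n": n_new,
                "dlt": dlt,
                "stage": self.stage,
                "rationale": rationale,
            }
        )


# ---------------------------------------------------------------------------
# escalation rules
# ---------------------------------------------------------------------------


def stage1_next(state: TrialState, rng: np.random.Generator) -> tuple[int, int]:
    """Next combination under the rule-based stage.

    The first cohort is (1, 1); subsequent cohorts draw uniformly without
    replacement from the current diagonal dose group, advancing to the next
    diagonal when the group is exhausted.  At the top group the cells are
    re-treated round-robin (unreachable at the packaged sample sizes).
    """
    if state.stage != STAGE_RULE:
        raise RuntimeError("stage1_next called after the model-based switch")
    I, J = state.shape
    if state.data.total_n == 0:
        state.stage1_group = 2
        state.stage1_remaining = set()
        return (1, 1)
    if not state.stage1_remaining:
        if state.stage1_group < I + J:
            state.stage1_group += 1
        state.stage1_remaining = set(state.group_cells(state.stage1_group))
    choices = sorted(state.stage1_remaining)
    cell = choices[int(rng.integers(len(choices)))]
    state.stage1_remaining.discard(cell)
    return cell


_ESCALATE_MOVES = ((1, 0), (0, 1), (1, -1), (-1, 1))
_DEESCALATE_MOVES = ((-1, 0), (0, -1), (1, -1), (-1, 1))


def _closest_to_phi(cells, summaries: PosteriorSummaries, phi: float):
    # tie-break: smaller |mean - phi|, then lower total dose, then lower i
    def key(c):
        m = summaries.mean_pi[c[0] - 1, c[1] - 1]
        return (abs(m - phi), c[0] + c[1], c[0])

    return min(cells, key=key)


def stage2_next(
    state: TrialState, summaries: PosteriorSummaries, config: DesignConfig
) -> tuple[int, int]:
    """Model-based escalation decision for the next cohort."""
    i, j = state.current
    I, J = state.shape
    pb = float(summaries.pr_below[i - 1, j - 1])
    pa = float(summaries.pr_above[i - 1, j - 1])
    escalate = pb > config.ce
    deescalate = pa > config.cd
    if escalate and deescalate:  # impossible when ce + cd > 1
        raise AssertionError("escalate and de-escalate indicated simultaneously")
    if escalate:
        if (i, j) == (I, J):
            return (i, j)
        moves = _ESCALATE_MOVES
    elif deescalate:
        if (i, j) == (1, 1):
            return (i, j)
        moves = _DEESCALATE_MOVES
    else:
        return (i, j)
    cands = [
        (i + di, j + dj)
        for di, dj in moves
        if 1 <= i + di <= I and 1 <= j + dj <= J
    ]
    if not cands:
        return (i, j)
    return _closest_to_phi(cands, summaries, config.phi)


def check_stopping(summaries: PosteriorSummaries, config: DesignConfig) -> bool:
    """Early stop for safety: Pr(pi_11 > phi | D) > lambda."""
    if not config.stopping_enabled:
        return False
    return float(summaries.pr_above[0, 0]) > config.lam


def select_mtdc(
    summaries: PosteriorSummaries, state: TrialState, config: DesignConfig
) -> tuple[int, int]:
    """MTDC: treated combination maximising the target-interval probability.

    Ties break toward the lower total dose, then the lower drug-A level.
    """
    treated = state.data.treated_cells()
    if not treated:
        raise RuntimeError("no combination has been treated")

    def key(c):
        return (-summaries.pr_interval[c[0] - 1, c[1] - 1], c[0] + c[1], c[0])

    return min(treated, key=key)
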