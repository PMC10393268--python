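"""Monte-Carlo trial engine.

Runs complete simulated trials against a true-toxicity scenario: cohort DLT
counts are drawn Binomial(cohort_size, true pi at the allocated cell),
escalation follows the two-stage design, and the MTDC is selected when the
maximum sample size is reached (or the trial stops early when the safety
rule is enabled).  Batches derive per-trial seeds from a master seed via
``numpy.random.SeedSequence.spawn``, so they are reproducible and
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import (
    STAGE_MODEL,
    STAGE_RULE,
    DesignConfig,
    TrialState,
    check_stopping,
    select_mtdc,
    stage1_next,
    stage2_next,
)
from .model import CombinationToxicityModel
from .scenarios import ToxicityScenario

__all__ = ["TrialResult", "SimulationBatch", "run_trial", "run_batch",
           "run_operating_characteristics"]


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial."""

    selected: Optional[tuple[int, int]]
    transcript: tuple  # per-cohort records (dicts)
    n: np.ndarray      # patients per combination
    m: np.ndarray      # DLTs per combination
    total_n: int
    total_dlt: int
    stopped_early: bool

    def transcript_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.transcript))


def _fit(config: DesignConfig, data, seed):
    model = CombinationToxicityModel(data, config.spec, config.skeleton, config.prior)
    return model.fit(settings=config.mcmc, seed=seed)


def run_trial(scenario: ToxicityScenario, config: DesignConfig, seed) -> TrialResult:
    """Simulate one complete trial; fully reproducible from ``seed``.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if config.shape != scenario.shape:
        raise ValueError(
            f"design grid {config.shape} does not match scenario {scenario.shape}"
        )
    rng = np.random.default_rng(seed)
    state = TrialState.new(scenario.shape)
    stopped = False
    for _ in range(config.n_cohorts):
        if state.stage == STAGE_RULE:
            cell = stage1_next(state, rng)
            rationale = "stage1"
        else:
            res = _fit(config, state.data, int(rng.integers(2**31)))
            summ = res.summaries(phi=config.phi, delta=config.delta)
            if check_stopping(summ, config):
                stopped = True
                break
            cell = stage2_next(state, summ, config)
            rationale = "stage2"
        dlt = int(rng.binomial(config.cohort_size, scenario.prob(*cell)))
        state.record(cell, config.cohort_size, dlt, rationale)
        if state.stage == STAGE_RULE and dlt > 0:
            state.stage = STAGE_MODEL
    selected = None
    if not stopped:
        res = _fit(config, state.data, int(rng.integers(2**31)))
        summ = res.summaries(phi=config.phi, delta=config.delta)
        selected = select_mtdc(summ, state, config)
    return TrialResult(
        selected=selected,
        transcript=tuple(state.allocation_log),
        n=state.data.n.copy(),
        m=state.data.m.copy(),
        total_n=state.data.total_n,
        total_dlt=state.data.total_dlt,
        stopped_early=stopped,
    )


@dataclass
class SimulationBatch:
    """Per-trial results of repeated simulations of one scenario x design."""

    scenario_name: str
    design_label: str
    n_sims: int
    master_seed: int
    results: list = field(default_factory=list)

    def selections(self) -> list:
        return [r.selected for r in self.results]


def run_batch(
    scenario: ToxicityScenario,
    config: DesignConfig,
    n_sims: int = 1000,
    master_seed: int = 0,
) -> SimulationBatch:
    """Run ``n_sims`` independent trials with spawned per-trial seeds."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_sims)
    results = [run_trial(scenario, config, child) for child in children]
    return SimulationBatch(
        scenario_name=scenario.name,
        design_label=config.label or config.spec.family.value,
        n_sims=n_sims,
        master_seed=master_seed,
        results=results,
    )


def run_operating_characteristics(
    scenario: ToxicityScenario,
    config: DesignConfig,
    n_sims: int = 1000,
    master_seed: int = 0,
):
    """Run a batch and aggregate it into the six outcome metrics."""
    from .metrics import summarize

    batch = run_batch(scenario, config, n_sims=n_sims, master_seed=master_seed)
    return summarize(batch, scenario)
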