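"""Operating-characteristic metrics for dose-finding simulations.

Six outcome metrics per scenario x design: percentage of correct MTDC
selections, percentage of overdose-combination (OC) selections, the
accuracy index (AI), overall observed-toxicity percentage, and the
percentages of patients allocated to MTDCs and to OCs.  The accuracy index
weighs the selection distribution by distance of the true toxicity from the
target::

    AI = 1 - I*J * sum_ij |pi*_ij - phi| w_ij / sum_ij |pi*_ij - phi|

where ``w_ij`` is the probability of selecting combination (i, j); AI is
reported multiplied by 100 (maximum 100; a uniform selection distribution
scores 0 and concentrating on the worst cell of a two-cell grid scores
-100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import ToxicityScenario

__all__ = ["OperatingCharacteristics", "accuracy_index", "summarize"]


@dataclass(frozen=True)
class OperatingCharacteristics:
    """The six outcome metrics for one scenario x design."""

    scenario: str
    design: str
    n_sims: int
    pct_mtdc_selected: float
    pct_oc_selected: float
    accuracy_index: float
    pct_observed_toxicity: float
    pct_patients_at_mtdc: float
    pct_patients_at_oc: float
    selection_probs: np.ndarray  # w_ij over all simulated trials (sums <= 1)

    def to_dict(self) -> dict:
        d = {
            "scenario": self.scenario,
            "design": self.design,
            "n_sims": self.n_sims,
            "pct_mtdc_selected": self.pct_mtdc_selected,
            "pct_oc_selected": self.pct_oc_selected,
            "accuracy_index": self.accuracy_index,
            "pct_observed_toxicity": self.pct_observed_toxicity,
            "pct_patients_at_mtdc": self.pct_patients_at_mtdc,
            "pct_patients_at_oc": self.pct_patients_at_oc,
        }
        return d

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def accuracy_index(true_probs, selection_probs, phi: float) -> float:
    """Cheung-style accuracy index, scaled by 100.

    ``selection_probs`` must sum to 1 (renormalise over selecting trials
    before calling); raises when every cell is exactly at the target, where
    the index is undefined.
    """
    p = np.asarray(true_probs, dtype=float)
    w = np.asarray(selection_probs, dtype=float)
    if p.shape != w.shape:
        raise ValueError("true_probs and selection_probs shapes differ")
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("selection_probs must sum to 1")
    dist = np.abs(p - phi)
    denom = dist.sum()
    if denom == 0:
        raise ValueError("accuracy index undefined: all cells exactly at target")
    return float((1.0 - p.size * (dist * w).sum() / denom) * 100.0)


def summarize(batch, scenario: ToxicityScenario) -> OperatingCharacteristics:
    """Aggregate a simulation batch into the six outcome metrics.

    Selection percentages use all simulated trials in the denominator, so
    early-stopped trials (no selection) dilute them; the accuracy index
    renormalises the selection distribution over selecting trials only.
    """
    results = batch.results
    if not results:
        raise ValueError("empty batch")
    I, J = scenario.shape
    mtdc = scenario.mtdc_set
    oc = scenario.overdose_set()

    n_total = len(results)
    sel_counts = np.zeros((I, J))
    n_mtdc_sel = 0
    n_oc_sel = 0
    patients = np.zeros((I, J))
    total_n = 0
    total_dlt = 0
    for r in results:
        patients += r.n
        total_n += r.total_n
        total_dlt += r.total_dlt
        if r.selected is None:
            continue
        sel_counts[r.selected[0] - 1, r.selected[1] - 1] += 1
        if r.selected in mtdc:
            n_mtdc_sel += 1
        if r.selected in oc:
            n_oc_sel += 1

    w_all = sel_counts / n_total
    n_selecting = sel_counts.sum()
    if n_selecting > 0:
        ai = accuracy_index(scenario.probs, sel_counts / n_selecting, scenario.phi)
    else:
        ai = float("nan")

    def pct_at(cells):
        if total_n == 0:
            return 0.0
        return 100.0 * sum(patients[i - 1, j - 1] for (i, j) in cells) / total_n

    return OperatingCharacteristics(
        scenario=batch.scenario_name,
        design=batch.design_label,
        n_sims=n_total,
        pct_mtdc_selected=100.0 * n_mtdc_sel / n_total,
        pct_oc_selected=100.0 * n_oc_sel / n_total,
        accuracy_index=ai,
        pct_observed_toxicity=100.0 * total_dlt / max(total_n, 1),
        pct_patients_at_mtdc=pct_at(mtdc),
        pct_patients_at_oc=pct_at(oc),
        selection_probs=w_all,
    )
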