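"""Benchmark true-toxicity scenarios for two-drug dose-finding simulation.

Eighteen scenarios of true DLT probabilities over dose grids of shapes
3x3, 4x4, 4x2 and 5x3 (drug A levels x drug B levels), each with its set of
true maximum tolerated dose combinations (MTDCs).  The target toxicity is
phi = 0.30 and combinations with true probability >= 0.35 are overdose
combinations (OCs).  Eight of the scenarios (4, 5, 6, 7, 8, 14, 15, 16)
exhibit extreme synergistic toxicity around their MTDCs: the joint
probability at an MTDC exceeds what additive marginal increments over the
lower-adjacent combinations can explain, which is precisely the regime in
which proper copula surfaces are pinched by the Frechet-Hoeffding upper
bound.

Coordinates are 1-based pairs ``(i, j)`` with ``i`` the dose level of drug A
and ``j`` the level of drug B; ``probs[i-1, j-1]`` is the matching matrix
entry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ToxicityScenario", "load_scenarios", "get_scenario"]

DEFAULT_PHI = 0.3
DEFAULT_OC_THRESHOLD = 0.35

# Scenarios exhibiting extreme synergistic toxicity per the published
# labelling.  A strict application of the synergy inequality additionally
# flags scenario 11 (0.28 > 0.20 at MTDC (2,2)); is_extreme_synergy()
# reports the strict rule, extreme_synergy_label the published label.
_EXTREME_LABELLED = {4, 5, 6, 7, 8, 14, 15, 16}


@dataclass(frozen=True)
class ToxicityScenario:
    """True DLT-probability matrix with MTDC labelling.

    ``mtdc_set`` holds the 1-based ``(i, j)`` pairs designated as true
    MTDCs; for the packaged library these all have true probability within
    [0.28, 0.34] of the target 0.30.
    """

    name: str
    probs: np.ndarray  # shape (I, J), probs[i-1, j-1]
    mtdc_set: frozenset
    phi: float = DEFAULT_PHI
    oc_threshold: float = DEFAULT_OC_THRESHOLD
    extreme_synergy_label: bool = field(default=False)

    def __post_init__(self):
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if self.probs.ndim != 2:
            raise ValueError("probs must be a 2-D matrix")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("true probabilities must lie in [0, 1]")
        I, J = self.probs.shape
        for (i, j) in self.mtdc_set:
            if not (1 <= i <= I and 1 <= j <= J):
                raise ValueError(f"MTDC {(i, j)} outside the {I}x{J} grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape

    def prob(self, i: int, j: int) -> float:
        return float(self.probs[i - 1, j - 1])

    def overdose_set(self) -> frozenset:
        """All combinations with true probability >= ``oc_threshold``."""
        I, J = self.shape
        return frozenset(
            (i, j)
            for i in range(1, I + 1)
            for j in range(1, J + 1)
            if self.probs[i - 1, j - 1] >= self.oc_threshold
        )

    def is_extreme_synergy(self) -> bool:
        """Strict extreme-synergy rule evaluated at interior MTDCs.

        True iff for some MTDC ``(i, j)`` with ``i > 1`` and ``j > 1``::

            Pr(i,j) > {Pr(i-1,j) - Pr(i-1,j-1)} + {Pr(i,j-1) - Pr(i-1,j-1)}
                      + Pr(i-1,j-1)

        i.e. the joint toxicity exceeds the additive increments over the
        lower-adjacent combinations.  Edge MTDCs (i=1 or j=1) skip the test
        since the (i-1, j-1) reference is undefined.
        """
        P = self.probs
        for (i, j) in self.mtdc_set:
            if i <= 1 or j <= 1:
                continue
            base = P[i - 2, j - 2]
            additive = (P[i - 2, j - 1] - base) + (P[i - 1, j - 2] - base) + base
            if P[i - 1, j - 1] > additive:
                return True
        return False

    def transpose(self) -> "ToxicityScenario":
        """Swap the roles of the two drugs (i and j)."""
        return ToxicityScenario(
            name=self.name + "t",
            probs=self.probs.T,
            mtdc_set=frozenset((j, i) for (i, j) in self.mtdc_set),
            phi=self.phi,
            oc_threshold=self.oc_threshold,
            extreme_synergy_label=self.extreme_synergy_label,
        )

    # -- serialisation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame, drug B levels as rows (descending)."""
        I, J = self.shape
        return pd.DataFrame(
            self.probs.T[::-1],
            index=[f"j={j}" for j in range(J, 0, -1)],
            columns=[f"i={i}" for i in range(1, I + 1)],
        )

    def to_text(self) -> str:
        """Plain-text block; MTDC cells are marked with ``*``."""
        I, J = self.shape
        lines = [f"# {self.name} phi={self.phi:g} oc={self.oc_threshold:g}"]
        for j in range(J, 0, -1):
            cells = []
            for i in range(1, I + 1):
                mark = "*" if (i, j) in self.mtdc_set else ""
                cells.append(f"{self.probs[i - 1, j - 1]:.2f}{mark}")
            lines.append(" ".join(cells))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ToxicityScenario":
        lines = [ln.strip() for ln in io.StringIO(text) if ln.strip()]
        header = lines[0]
        if not header.startswith("#"):
            raise ValueError("scenario block must start with a '# name ...' header")
        parts = header[1:].split()
        name = parts[0]
        kw = dict(p.split("=") for p in parts[1:] if "=" in p)
        rows = [ln.split() for ln in lines[1:]]
        J = len(rows)
        I = len(rows[0])
        probs = np.zeros((I, J))
        mtdc = set()
        for r, row in enumerate(rows):
            j = J - r
            if len(row) != I:
                raise ValueError("ragged scenario matrix")
            for c, tok in enumerate(row):
                if tok.endswith("*"):
                    mtdc.add((c + 1, j))
                    tok = tok[:-1]
                probs[c, j - 1] = float(tok)
        return cls(
            name=name,
            probs=probs,
            mtdc_set=frozenset(mtdc),
            phi=float(kw.get("phi", DEFAULT_PHI)),
            oc_threshold=float(kw.get("oc", DEFAULT_OC_THRESHOLD)),
        )


# ---------------------------------------------------------------------------
# packaged library: rows listed top-down (j = J .. 1), '*' marks an MTDC
# ---------------------------------------------------------------------------

_RAW = {
    "S01": """
        0.30* 0.40  0.50
        0.20  0.30* 0.40
        0.10  0.20  0.30*
    """,
    "S02": """
        0.50  0.70  0.80
        0.30* 0.60  0.70
        0.05  0.30* 0.50
    """,
    "S03": """
        0.40  0.60  0.80
        0.30* 0.50  0.70
        0.05  0.10  0.40
    """,
    "S04": """
        0.15  0.40  0.60
        0.05  0.30* 0.40
        0.01  0.05  0.15
    """,
    "S05": """
        0.30* 0.50  0.65  0.70
        0.10  0.30* 0.60  0.65
        0.05  0.10  0.30* 0.50
        0.01  0.05  0.10  0.30*
    """,
    "S06": """
        0.30* 0.50  0.60  0.70
        0.15  0.40  0.50  0.60
        0.10  0.30* 0.40  0.50
        0.05  0.10  0.15  0.30*
    """,
    "S07": """
        0.40  0.45  0.60  0.85
        0.15  0.30* 0.55  0.60
        0.08  0.15  0.23  0.30*
        0.01  0.02  0.03  0.04
    """,
    "S08": """
        0.15  0.60  0.75  0.80
        0.10  0.45  0.70  0.75
        0.04  0.30* 0.45  0.60
        0.02  0.10  0.15  0.40
    """,
    "S09": """
        0.10  0.20  0.30* 0.40
        0.05  0.10  0.20  0.30*
    """,
    "S10": """
        0.30* 0.40  0.50  0.60
        0.01  0.10  0.20  0.30*
    """,
    "S11": """
        0.15  0.28* 0.32* 0.34*
        0.10  0.15  0.28* 0.32*
    """,
    "S12": """
        0.50  0.60  0.70  0.80
        0.10  0.20  0.30* 0.40
    """,
    "S13": """
        0.25  0.30* 0.40  0.50  0.70
        0.10  0.25  0.30* 0.40  0.50
        0.05  0.10  0.25  0.30* 0.40
    """,
    "S14": """
        0.20  0.45  0.50  0.60  0.75
        0.05  0.30* 0.45  0.55  0.60
        0.01  0.05  0.15  0.30* 0.50
    """,
    "S15": """
        0.30* 0.35  0.40  0.45  0.60
        0.05  0.20  0.30* 0.40  0.45
        0.01  0.05  0.10  0.20  0.30*
    """,
    "S16": """
        0.10  0.20  0.40  0.55  0.65
        0.05  0.10  0.30* 0.50  0.60
        0.01  0.05  0.10  0.20  0.40
    """,
    "S17": """
        0.31* 0.38  0.51
        0.12  0.21  0.37
        0.04  0.14  0.31*
    """,
    "S18": """
        0.31* 0.37  0.41  0.51  0.58
        0.11  0.19  0.24  0.37  0.46
        0.02  0.11  0.16  0.31* 0.41
    """,
}


def _build() -> list[ToxicityScenario]:
    out = []
    for k, (name, block) in enumerate(_RAW.items(), start=1):
        s = ToxicityScenario.from_text(f"# {name}\n{block}")
        out.append(
            ToxicityScenario(
                name=s.name,
                probs=s.probs,
                mtdc_set=s.mtdc_set,
                extreme_synergy_label=(k in _EXTREME_LABELLED),
            )
        )
    return out


_SCENARIOS = _build()
_BY_NAME = {s.name: s for s in _SCENARIOS}


def load_scenarios() -> list[ToxicityScenario]:
    """The 18 packaged scenarios, in order S01..S18."""
    return list(_SCENARIOS)


def get_scenario(name: str) -> ToxicityScenario:
    """Look up a packaged scenario by name ('S02', 's2' and '2' all work)."""
    key = name.upper()
    if not key.startswith("S"):
        key = "S" + key
    if len(key) == 2:
        key = f"S0{key[1]}"
    try:
        return _BY_NAME[key]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; packaged: {', '.join(_BY_NAME)}"
        ) from None
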