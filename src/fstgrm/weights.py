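"""Relative SNP weights from F_ST scores and group-budget weighting scenarios.

A weight vector over N loci is *relative*: it sums to N, so the average
marker carries weight 1.  Score-proportional weights are
``w_i = fst_i / sum_j fst_j * N``.  Budget scenarios split the total weight N
between the prioritized top-k set and the remaining loci by fixed percentage
shares (e.g. 75:25), spread within each group either equally (default) or
proportionally to the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightVector",
    "WeightingScenario",
    "proportional_weights",
    "scenario_weights",
    "standard_scenarios",
]


@dataclass
class WeightVector:
    """Nonnegative per-locus weights with mean 1 over a locus index set."""

    locus_index: np.ndarray  # panel locus indices (into the scored loci)
    w: np.ndarray

    def __post_init__(self) -> None:
        if len(self.locus_index) != len(self.w):
            raise ValueError("locus_index and w lengths differ")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.w)


@dataclass(frozen=True)
class WeightingScenario:
    """A weighting rule for building G.

    ``panel="full"`` uses every locus with total weight N split
    ``top_share``:``rest_share`` (percent) between the top-k set and the rest;
    ``panel="top"`` restricts G to the top-k set.  ``within`` spreads a
    group's budget equally or proportionally to F_ST.  ``within="fst"``
    together with shares ``None`` (scenario "PS") weights every locus by its
    score via the proportional rule.
    """

    name: str
    top_share: float | None = None  # percent; None => score-proportional or equal
    rest_share: float | None = None
    within: str = "equal"  # "equal" | "fst"
    panel: str = "full"  # "full" | "top"

    def __post_init__(self) -> None:
        if self.panel not in ("full", "top"):
            raise ValueError("panel must be 'full' or 'top'")
        if self.within not in ("equal", "fst"):
            raise ValueError("within must be 'equal' or 'fst'")
        if (self.top_share is None) != (self.rest_share is None):
            raise ValueError("top_share and rest_share must be given together")
        if self.top_share is not None:
            if self.top_share < 0 or self.rest_share < 0:
                raise ValueError("shares must be nonnegative")
            if self.panel == "full" and abs(self.top_share + self.rest_share - 100.0) > 1e-9:
                raise ValueError("full-panel shares must sum to 100")


def proportional_weights(scores: np.ndarray) -> np.ndarray:
    """Score-proportional relative weights: w_i = s_i / sum(s) * N."""
    s = np.asarray(scores, dtype=np.float64)
    if np.any(s < 0):
        raise ValueError("scores must be nonnegative")
    tot = s.sum()
    if tot <= 0:
        raise ValueError("all scores are zero; proportional weights undefined")
    return s / tot * len(s)


def _group_weights(scores: np.ndarray, budget: float, within: str) -> np.ndarray:
    """Spread `budget` total weight over one group of loci."""
    m = len(scores)
    if m == 0:
        return np.empty(0)
    if budget == 0.0:
        return np.zeros(m)
    if within == "equal":
        return np.full(m, budget / m)
    return proportional_weights(scores) * (budget / m)


def scenario_weights(
    fst: np.ndarray,
    top_index: np.ndarray,
    scenario: WeightingScenario,
) -> WeightVector:
    """Realize a weighting scenario over the scored loci.

    Returns the panel's locus indices with their weights; for ``panel="full"``
    that is every scored locus (total weight N), for ``panel="top"`` the
    top-k set only (total weight k).
    """
    fst = np.asarray(fst, dtype=np.float64)
    top_index = np.asarray(top_index)
    if top_index.size == 0:
        raise ValueError("top-k locus set is empty")
    n = len(fst)
    in_top = np.zeros(n, dtype=bool)
    in_top[top_index] = True

    if scenario.panel == "top":
        idx = np.flatnonzero(in_top)
        if scenario.within == "equal":
            w = np.ones(len(idx))
        else:
            w = proportional_weights(fst[idx])
        return WeightVector(idx, w)

    idx = np.arange(n)
    if scenario.top_share is None:
        # "PS": score-proportional over the whole panel, or all-equal
        w = np.ones(n) if scenario.within == "equal" else proportional_weights(fst)
        return WeightVector(idx, w)

    w = np.empty(n)
    k = int(in_top.sum())
    top_budget = scenario.top_share / 100.0 * n
    rest_budget = scenario.rest_share / 100.0 * n
    w[in_top] = _group_weights(fst[in_top], top_budget, scenario.within)
    w[~in_top] = _group_weights(fst[~in_top], rest_budget, scenario.within)
    if k == n and rest_budget > 0:
        raise ValueError("nonzero rest share but the top set covers the whole panel")
    return WeightVector(idx, w)


def standard_scenarios() -> list[WeightingScenario]:
    """The seven full-panel budget rows plus the two top-only variants."""
    out = [
        WeightingScenario("100:0", 100, 0),
        WeightingScenario("90:10", 90, 10),
        WeightingScenario("75:25", 75, 25),
        WeightingScenario("50:50", 50, 50),
        WeightingScenario("25:75", 25, 75),
        WeightingScenario("PS", None, None, within="fst"),
        WeightingScenario("equal", None, None, within="equal"),
        WeightingScenario("top-equal", panel="top", within="equal"),
        WeightingScenario("top-fst", panel="top", within="fst"),
    ]
    return out
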