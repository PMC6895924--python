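"""Per-locus fixation-index scores from phenotypic tail subpopulations.

Training phenotypes are split at two empirical quantiles (defaults 5% / 95%)
into a low tail S1, a high tail S2 and the remainder S0.  Nei's global
estimator, F_ST = (H_T - H_S) / H_T with H_T = 2pq from the pooled-tail
frequency and H_S the census-weighted average of the within-tail expected
heterozygosities, scores each locus for allele-frequency differentiation
between the tails.  Loci dragged apart by selection on the trait — those in
LD with QTL — differentiate most, so the top-scoring loci form a prioritized
marker subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubpopulationSplit",
    "FstScores",
    "partition_tails",
    "subpop_freqs",
    "fst_scores",
    "top_k",
]


@dataclass(frozen=True)
class SubpopulationSplit:
    """Index partition of individuals into low tail, middle and high tail."""

    s1: np.ndarray  # row indices, low tail
    s2: np.ndarray  # row indices, high tail
    s0: np.ndarray  # remainder
    q_low: float
    q_high: float


@dataclass
class FstScores:
    """Per-locus F_ST with its heterozygosity components."""

    fst: np.ndarray
    h_t: np.ndarray
    h_s: np.ndarray
    p_total: np.ndarray
    p_s1: np.ndarray
    p_s2: np.ndarray
    n_s1: int
    n_s2: int

    def __len__(self) -> int:
        return len(self.fst)


def partition_tails(
    phenotypes: np.ndarray,
    q_low: float = 0.05,
    q_high: float = 0.95,
) -> SubpopulationSplit:
    """Split individuals at the empirical q_low / q_high phenotype quantiles.

    Exactly ``floor(q_low * n)`` individuals form S1 and
    ``floor((1 - q_high) * n)`` form S2: individuals are ordered by
    (phenotype, position) ascending and the tails taken from the two ends, so
    boundary ties resolve deterministically.  Returns row indices into the
    input order.
    """
    y = np.asarray(phenotypes, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("phenotypes must be one-dimensional")
    if np.isnan(y).any():
        raise ValueError("phenotypes contain missing values")
    if not 0.0 < q_low < q_high < 1.0:
        raise ValueError("need 0 < q_low < q_high < 1")
    n = len(y)
    n1 = int(np.floor(q_low * n))
    n2 = int(np.floor((1.0 - q_high) * n))
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"tails too small (|S1|={n1}, |S2|={n2}); need at least 2 per tail"
        )
    if np.ptp(y) == 0.0:
        warnings.warn("all phenotypes identical; tail membership is positional only")
    order = np.lexsort((np.arange(n), y))  # phenotype asc, then position asc
    return SubpopulationSplit(
        s1=order[:n1],
        s2=order[n - n2 :],
        s0=order[n1 : n - n2],
        q_low=q_low,
        q_high=q_high,
    )


def subpop_freqs(dosages: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Reference-allele frequency per locus: mean dosage / 2 over the rows."""
    rows = np.asarray(rows)
    if rows.size == 0:
        raise ValueError("empty subpopulation")
    return dosages[rows].mean(axis=0) / 2.0


def fst_scores(
    dosages: np.ndarray,
    split: SubpopulationSplit,
    total: str = "pooled_tails",
) -> FstScores:
    """Nei F_ST per locus from the two tail subpopulations.

    ``total`` selects the frequency behind H_T: ``"pooled_tails"`` (default)
    uses the census-weighted S1 ∪ S2 frequency, matching the census-weighted
    H_S; ``"all"`` uses every individual in ``dosages``.  Loci monomorphic in
    the pool (H_T = 0) score 0 — no differentiation information.
    """
    if split.s1.size == 0 or split.s2.size == 0:
        raise ValueError("both tails must be nonempty")
    if total not in ("pooled_tails", "all"):
        raise ValueError("total must be 'pooled_tails' or 'all'")
    n1, n2 = len(split.s1), len(split.s2)
    p1 = subpop_freqs(dosages, split.s1)
    p2 = subpop_freqs(dosages, split.s2)
    if total == "pooled_tails":
        p = (n1 * p1 + n2 * p2) / (n1 + n2)
    else:
        p = dosages.mean(axis=0) / 2.0
    h_t = 2.0 * p * (1.0 - p)
    h_s = (n1 * 2.0 * p1 * (1.0 - p1) + n2 * 2.0 * p2 * (1.0 - p2)) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(h_t > 0.0, (h_t - h_s) / h_t, 0.0)
    fst = np.clip(fst, 0.0, 1.0)  # guard rounding at the boundaries
    return FstScores(
        fst=fst, h_t=h_t, h_s=h_s, p_total=p, p_s1=p1, p_s2=p2, n_s1=n1, n_s2=n2
    )


def top_k(
    fst: np.ndarray,
    k: int,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the k highest-scoring loci, ties broken by genome order.

    With ``chrom``/``pos`` given, equal scores rank by (chromosome, position);
    otherwise by input order.  The result is returned in ascending locus
    order.
    """
    fst = np.asarray(fst, dtype=np.float64)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(fst):
        raise ValueError(f"k={k} exceeds the {len(fst)} scored loci")
    if chrom is None or pos is None:
        order = np.lexsort((np.arange(len(fst)), -fst))
    else:
        order = np.lexsort((np.asarray(pos), np.asarray(chrom), -fst))
    return np.sort(order[:k])
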