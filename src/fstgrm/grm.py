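"""Weighted VanRaden genomic relationship matrix and off-diagonal summaries.

With dosage matrix M (n x m) over the panel loci, reference frequencies p and
nonnegative locus weights w, the matrix is

    Z = M - 2p,   G = Z diag(w) Z' / (2 * sum_i w_i p_i (1 - p_i)).

With w = 1 this is VanRaden's first method.  The weighted normalization keeps
the expected diagonal near 1 under any weight budget and makes G invariant to
rescaling all weights by a positive constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["GRM", "build_grm", "blend", "offdiag_histogram", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = (-0.05, -0.03, -0.01, 0.01, 0.03, 0.05)


@dataclass
class GRM:
    """Symmetric realized-relationship matrix over identified individuals."""

    values: np.ndarray  # (n, n) float64
    ids: np.ndarray  # (n,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("GRM must be square")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("id count does not match GRM order")

    def rows_for(self, ids: np.ndarray) -> np.ndarray:
        """Row indices of the given ids (error on any missing id)."""
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[v] for v in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"id {e.args[0]!r} not present in the GRM") from None


def build_grm(
    dosages: np.ndarray,
    ids: np.ndarray,
    panel_index: np.ndarray | None = None,
    w: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    meta: dict | None = None,
) -> GRM:
    """Weighted VanRaden G over the rows of ``dosages``.

    ``panel_index`` selects the marker columns (default: all); ``w`` aligns
    with the panel (default: all ones); ``freqs`` are per-panel-locus
    reference-allele frequencies for centering and normalization (default:
    computed from the rows given, i.e. the combined genotyped set).  Loci
    monomorphic in the frequency reference contribute nothing to either the
    cross-products or the normalization; they are dropped with a logged count.
    """
    if dosages.shape[0] != len(ids):
        raise ValueError("dosage rows and ids differ in length")
    if panel_index is None:
        panel_index = np.arange(dosages.shape[1])
    M = dosages[:, panel_index]
    m = M.shape[1]
    if w is None:
        w = np.ones(m)
    w = np.asarray(w, dtype=np.float64)
    if len(w) != m:
        raise ValueError("weights do not align with the panel loci")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if freqs is None:
        p = M.mean(axis=0) / 2.0
    else:
        p = np.asarray(freqs, dtype=np.float64)
        if len(p) != m:
            raise ValueError("freqs do not align with the panel loci")

    poly = (p > 0.0) & (p < 1.0)
    n_dropped = int(m - poly.sum())
    if n_dropped:
        logger.info("dropping %d monomorphic panel loci from G", n_dropped)
    p = p[poly]
    wp = w[poly]
    denom = 2.0 * float(np.sum(wp * p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError(
            "normalization constant 2*sum(w*p*q) is not positive; "
            "panel has no weighted polymorphic loci"
        )
    Z = M[:, poly].astype(np.float64)
    Z -= 2.0 * p
    Zw = Z * np.sqrt(wp)
    G = (Zw @ Zw.T) / denom
    G = 0.5 * (G + G.T)  # enforce exact symmetry
    info = {"panel_size": m, "n_dropped_monomorphic": n_dropped, "denom": denom}
    if meta:
        info.update(meta)
    return GRM(values=G, ids=np.asarray(ids), meta=info)


def blend(g: GRM, alpha: float = 0.01) -> GRM:
    """Numerically stabilized G* = (1 - alpha) G + alpha I."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    values = (1.0 - alpha) * g.values + alpha * np.eye(len(g.ids))
    meta = dict(g.meta, blend_alpha=alpha)
    return GRM(values=values, ids=g.ids, meta=meta)


def offdiag_histogram(
    g: GRM,
    row_ids: np.ndarray,
    col_ids: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Percent of row x col relationship entries per threshold bin.

    Bins are lower-inclusive half-open intervals covering the real line:
    (-inf, t1), [t1, t2), ..., [tk, inf).  ``row_ids`` and ``col_ids`` must be
    disjoint (training vs validation individuals), so every entry of the
    rectangle is an off-diagonal element of G.  Returns (bin edges as given,
    percentages summing to 100).
    """
    row_ids = np.asarray(row_ids)
    col_ids = np.asarray(col_ids)
    if row_ids.size == 0 or col_ids.size == 0:
        raise ValueError("row and column id sets must be nonempty")
    if np.intersect1d(row_ids, col_ids).size:
        raise ValueError("row and column id sets must be disjoint")
    t = np.asarray(thresholds, dtype=np.float64)
    if np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    block = g.values[np.ix_(g.rows_for(row_ids), g.rows_for(col_ids))].ravel()
    bins = np.digitize(block, t, right=False)  # t[i-1] <= x < t[i]
    counts = np.bincount(bins, minlength=len(t) + 1)
    return t, counts / block.size * 100.0
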