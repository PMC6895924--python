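"""End-to-end scenario study: simulate, score, weight, build G, fit, evaluate.

One replicate = one simulated population.  F_ST scores come from the
phenotypic tails of the full training generation (G6); the analysis then
samples training and validation animals (defaults 2,000 of G6, 1,000 of G7),
builds one genomic relationship matrix per weighting scenario, fits the GBLUP
model by REML, predicts validation GEBVs and summarizes accuracy, bias and
the train x validation relationship distribution.  Replicates are seeded
deterministically from the plan's base seed.

Full-panel scenarios that spread each group's budget equally reuse two
per-group cross-products (top set, remainder), so the whole Table of budget
scenarios costs two large matrix products per replicate; the assembled G is
algebraically identical to :func:`fstgrm.grm.build_grm`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import fst as fst_mod
from . import mixedmodel as mm
from .grm import GRM, DEFAULT_THRESHOLDS, blend, build_grm, offdiag_histogram
from .sim import SimConfig, adjacent_r2, simulate
from .weights import WeightingScenario, scenario_weights, standard_scenarios

logger = logging.getLogger(__name__)

__all__ = ["ExperimentPlan", "ScenarioReport", "run_replicate", "run_experiment", "write_report"]


@dataclass(frozen=True)
class ExperimentPlan:
    """The reduced-scale scenario study (overridable throughout)."""

    sim: SimConfig = field(default_factory=SimConfig)
    scenarios: tuple[WeightingScenario, ...] = tuple(standard_scenarios())
    n_replicates: int = 5
    base_seed: int = 1
    train_sample: int = 2000
    val_sample: int = 1000
    top_k: int = 1000
    q_low: float = 0.05
    q_high: float = 0.95
    blend_alpha: float = 0.01
    train_generation: int = 6
    val_generation: int = 7
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    compute_ld: bool = True

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("scenario list must be nonempty")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if self.top_k <= 0:
            raise ValueError("top_k must be positive")


@dataclass
class ScenarioReport:
    """Per-replicate results plus across-replicate summaries."""

    base_stats: pd.DataFrame  # one row per replicate
    generation_response: pd.DataFrame  # mean TBV per generation per replicate
    results: pd.DataFrame  # one row per (replicate, scenario)
    histograms: pd.DataFrame  # long: replicate, scenario, bin, percent

    def summary_varcomps(self) -> pd.DataFrame:
        """Across-replicate mean (SD) of variance components, Table-1 layout."""
        return self._summarize(["sigma_u2", "sigma_e2", "h2"])

    def summary_fit_bias(self) -> pd.DataFrame:
        """Residual variance, bias regression and deviance, Table-4 layout."""
        return self._summarize(["sigma_e2", "intercept", "slope", "minus2logl"])

    def summary_accuracy(self) -> pd.DataFrame:
        return self._summarize(["accuracy"])

    def summary_histograms(self) -> pd.DataFrame:
        """Mean off-diagonal bin percentages per scenario (Table-2/3 layout)."""
        mean = (
            self.histograms.groupby(["scenario", "bin"], sort=False)["percent"]
            .mean()
            .reset_index()
        )
        table = mean.pivot(index="bin", columns="scenario", values="percent")
        # preserve threshold order and scenario order instead of lexicographic
        return table.reindex(index=self.histograms["bin"].unique(),
                             columns=self.histograms["scenario"].unique())

    def _summarize(self, cols: list[str]) -> pd.DataFrame:
        g = self.results.groupby("scenario", sort=False)[cols]
        mean = g.mean().add_suffix("_mean")
        sd = g.std(ddof=1).add_suffix("_sd")
        return pd.concat([mean, sd], axis=1).sort_index(
            axis=1, key=lambda c: [cols.index(x.rsplit("_", 1)[0]) for x in c]
        )


def _replicate_seed(base_seed: int, rep: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base_seed), int(rep), int(stream)])


def _bin_labels(thresholds: tuple[float, ...]) -> list[str]:
    t = list(thresholds)
    labels = [f"OD < {t[0]}"]
    labels += [f"{lo} <= OD < {hi}" for lo, hi in zip(t[:-1], t[1:])]
    labels.append(f"OD >= {t[-1]}")
    return labels


def _scenario_grms(
    dosages: np.ndarray,
    ids: np.ndarray,
    snp_fst: np.ndarray,
    top_idx: np.ndarray,
    scenarios: tuple[WeightingScenario, ...],
):
    """Yield (scenario, GRM) reusing per-group cross-products where possible."""
    n_panel = dosages.shape[1]
    in_top = np.zeros(n_panel, dtype=bool)
    in_top[top_idx] = True
    rest_idx = np.flatnonzero(~in_top)
    p = dosages.mean(axis=0) / 2.0
    Z = dosages.astype(np.float64) - 2.0 * p
    pq = p * (1.0 - p)

    cache: dict[str, tuple[np.ndarray, float]] = {}

    def group_cross(idx: np.ndarray, key: str) -> tuple[np.ndarray, float]:
        if key not in cache:
            Zg = Z[:, idx]
            cache[key] = (Zg @ Zg.T, float(pq[idx].sum()))
        return cache[key]

    for sc in scenarios:
        if sc.panel == "top" or sc.within == "fst":
            # top-only panels and score-proportional weightings get their own
            # (cheap or unavoidable) weighted product
            wv = scenario_weights(snp_fst, top_idx, sc)
            yield sc, build_grm(
                dosages, ids, wv.locus_index, wv.w, meta={"scenario": sc.name}
            )
            continue
        # full panel, equal weights within groups: assemble from cross-products
        if sc.top_share is None:  # all loci weight 1
            a = b = 1.0
        else:
            a = sc.top_share / 100.0 * n_panel / len(top_idx)
            b = sc.rest_share / 100.0 * n_panel / max(len(rest_idx), 1)
        c_top, s_top = group_cross(top_idx, "top")
        c_rest, s_rest = group_cross(rest_idx, "rest")
        denom = 2.0 * (a * s_top + b * s_rest)
        if denom <= 0:
            raise ValueError(f"scenario {sc.name}: non-positive normalization")
        values = (a * c_top + b * c_rest) / denom
        values = 0.5 * (values + values.T)
        yield sc, GRM(values=values, ids=ids, meta={"scenario": sc.name, "denom": denom})


def run_replicate(plan: ExperimentPlan, rep: int) -> dict:
    """Simulate one replicate and evaluate every scenario on it."""
    t0 = time.time()
    sim_seed = int(_replicate_seed(plan.base_seed, rep, 0).generate_state(1)[0] % 2**31)
    config = replace(plan.sim, seed=sim_seed)
    result = simulate(config)
    rng = np.random.default_rng(_replicate_seed(plan.base_seed, rep, 1))

    base = result.generations[0]
    base_row = {
        "replicate": rep,
        "sim_seed": sim_seed,
        "var_tbv": float(np.var(base.tbv)),
        "var_phen": float(np.var(base.phenotype)),
        "h2_realized": float(np.var(base.tbv) / np.var(base.phenotype)),
    }
    snp_idx = np.flatnonzero(~result.locus_map["is_qtl"].to_numpy())
    train_pop = result.generations[plan.train_generation]
    val_pop = result.generations[plan.val_generation]
    if plan.compute_ld:
        base_row["adjacent_r2"] = adjacent_r2(
            base.dosages[:, snp_idx], result.locus_map.iloc[snp_idx]
        )

    response = pd.DataFrame(
        {
            "replicate": rep,
            "generation": [p.generation for p in result.generations],
            "mean_tbv": [float(p.tbv.mean()) for p in result.generations],
            "var_tbv": [float(p.tbv.var()) for p in result.generations],
        }
    )

    # F_ST from the full training generation's phenotypic tails (pre-sampling)
    split = fst_mod.partition_tails(train_pop.phenotype, plan.q_low, plan.q_high)
    snp_dos_train = train_pop.dosages[:, snp_idx]
    scores = fst_mod.fst_scores(snp_dos_train, split)
    chrom = result.locus_map["chrom"].to_numpy()[snp_idx]
    pos = result.locus_map["pos_cM"].to_numpy()[snp_idx]
    top_idx = fst_mod.top_k(scores.fst, plan.top_k, chrom, pos)

    train_rows = np.sort(rng.choice(train_pop.n, size=plan.train_sample, replace=False))
    val_rows = np.sort(rng.choice(val_pop.n, size=plan.val_sample, replace=False))
    train_ids = train_pop.ids[train_rows]
    val_ids = val_pop.ids[val_rows]
    y = train_pop.phenotype[train_rows]
    tbv_val = val_pop.tbv[val_rows]
    dosages = np.vstack(
        [train_pop.dosages[train_rows][:, snp_idx], val_pop.dosages[val_rows][:, snp_idx]]
    )
    all_ids = np.concatenate([train_ids, val_ids])

    labels = _bin_labels(plan.thresholds)
    # bins whose lower edge is at or above 0.03 (the paper's similarity mass)
    above = [i for i in range(1, len(plan.thresholds) + 1)
             if plan.thresholds[i - 1] >= 0.03 - 1e-12]
    rows, hist_rows = [], []
    for sc, g in _scenario_grms(dosages, all_ids, scores.fst, top_idx, plan.scenarios):
        try:
            g_star = blend(g, plan.blend_alpha)
            tr = g_star.rows_for(train_ids)
            fit = mm.reml_fit(y, g_star.values[np.ix_(tr, tr)])
            gebv = mm.gebv_blup(y, g_star, train_ids, fit.sigma_u2, fit.sigma_e2)
            ev = mm.evaluate(tbv_val, gebv[g_star.rows_for(val_ids)])
            _, pct = offdiag_histogram(g, train_ids, val_ids, plan.thresholds)
        except Exception:
            logger.exception("replicate %d scenario %s failed; skipped", rep, sc.name)
            continue
        rows.append(
            {
                "replicate": rep,
                "scenario": sc.name,
                "sigma_u2": fit.sigma_u2,
                "sigma_e2": fit.sigma_e2,
                "h2": fit.h2,
                "minus2logl": fit.minus2logl,
                "n_iter": fit.n_iter,
                "converged": fit.converged,
                "accuracy": ev.accuracy,
                "intercept": ev.intercept,
                "slope": ev.slope,
                "od_above_003": float(pct[above].sum()),
            }
        )
        for lab, val in zip(labels, pct):
            hist_rows.append(
                {"replicate": rep, "scenario": sc.name, "bin": lab, "percent": val}
            )
    logger.info("replicate %d done in %.1f s", rep, time.time() - t0)
    return {
        "base": base_row,
        "response": response,
        "results": pd.DataFrame(rows),
        "histograms": pd.DataFrame(hist_rows),
    }


def run_experiment(plan: ExperimentPlan, out_dir: str | Path | None = None) -> ScenarioReport:
    """Run every replicate of the plan; optionally write the report CSVs."""
    base_rows, responses, results, hists = [], [], [], []
    for rep in range(plan.n_replicates):
        out = run_replicate(plan, rep)
        base_rows.append(out["base"])
        responses.append(out["response"])
        results.append(out["results"])
        hists.append(out["histograms"])
    report = ScenarioReport(
        base_stats=pd.DataFrame(base_rows),
        generation_response=pd.concat(responses, ignore_index=True),
        results=pd.concat(results, ignore_index=True),
        histograms=pd.concat(hists, ignore_index=True),
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: ScenarioReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.summary_varcomps().to_csv(out / "table1.csv")
    report.summary_histograms().to_csv(out / "table2_3.csv")
    report.summary_fit_bias().to_csv(out / "table4.csv")
    report.summary_accuracy().to_csv(out / "fig1.csv")
    report.base_stats.to_csv(out / "base_stats.csv", index=False)
    report.generation_response.to_csv(out / "generation_response.csv", index=False)
    report.results.to_csv(out / "replicate_results.csv", index=False)
    report.histograms.to_csv(out / "replicate_histograms.csv", index=False)
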