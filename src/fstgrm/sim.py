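"""Forward-in-time simulation of a breeding population under truncation selection.

The generator produces the substrate for the weighted-GRM study: a neutral,
randomly mating historical population that builds up linkage disequilibrium by
drift, a base population (G0) founded from it, and seven discrete offspring
generations (G1..G7) bred by selecting parents on estimated breeding values.
A quantitative trait is controlled by non-genotyped biallelic QTL with
Gamma-distributed effect magnitudes; the residual variance is scaled so the
base-generation heritability and phenotypic variance hit their targets
(defaults 0.3 and 1.0) exactly.

All randomness flows through one :class:`numpy.random.SeedSequence` derived
from ``SimConfig.seed``, so a configuration reproduces bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "QtlSet",
    "Population",
    "SimResult",
    "simulate",
    "simulate_history",
    "sample_qtl",
    "scale_residual",
    "breed",
    "adjacent_r2",
    "qtl_variance_shares",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated population and trait.

    The defaults are a desk-scale study: 2 chromosomes of 100 cM carrying
    20,000 equidistant SNPs plus 100 non-genotyped QTL, a base population of
    200 sires and 3,000 dams, and 3,000 offspring per generation for seven
    generations — one fifth of the full-scale design in every census count,
    with the marker:QTL ratio preserved.

    ``hist_pop_size_schedule`` lists per-generation census sizes for the
    historical phase, right-aligned: when the schedule is shorter than
    ``n_hist_generations`` the first entry is reused for all earlier
    generations.  The default holds 250 individuals for 198 generations and
    then expands (1,600 → 6,400) so founders can be drawn.
    """

    n_hist_generations: int = 200
    hist_pop_size_schedule: tuple[int, ...] = (250, 1600, 6400)
    n_founder_males: int = 200
    n_founder_females: int = 3000
    n_offspring_generations: int = 7
    offspring_per_generation: int = 3000
    male_replacement: float = 0.5
    female_replacement: float = 0.2
    sex_ratio: float = 0.5
    n_chromosomes: int = 2
    chrom_length_cM: float = 100.0
    n_snp: int = 20000
    n_qtl: int = 100
    qtl_gamma_shape: float = 0.4
    qtl_gamma_scale: float = 0.15
    h2_target: float = 0.3
    vp_target: float = 1.0
    mutation_rate: float = 2.5e-5
    selection: str = "ebv"  # "ebv" | "phenotype" | "random"
    seed: int = 1

    def __post_init__(self) -> None:
        counts = {
            "n_hist_generations": self.n_hist_generations,
            "n_founder_males": self.n_founder_males,
            "n_founder_females": self.n_founder_females,
            "n_offspring_generations": self.n_offspring_generations,
            "offspring_per_generation": self.offspring_per_generation,
            "n_chromosomes": self.n_chromosomes,
            "n_snp": self.n_snp,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")
        if not self.hist_pop_size_schedule or any(
            s <= 0 for s in self.hist_pop_size_schedule
        ):
            raise ValueError("hist_pop_size_schedule must be nonempty positive sizes")
        for name, value in (
            ("male_replacement", self.male_replacement),
            ("female_replacement", self.female_replacement),
            ("sex_ratio", self.sex_ratio),
        ):
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if not 0.0 < self.h2_target < 1.0:
            raise ValueError("h2_target must be in (0, 1)")
        if self.vp_target <= 0:
            raise ValueError("vp_target must be > 0")
        if self.chrom_length_cM <= 0:
            raise ValueError("chrom_length_cM must be > 0")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if self.selection not in ("ebv", "phenotype", "random"):
            raise ValueError("selection must be 'ebv', 'phenotype' or 'random'")

    @property
    def n_loci(self) -> int:
        return self.n_snp + self.n_qtl

    def hist_sizes(self) -> np.ndarray:
        """Per-generation historical census sizes (right-aligned schedule)."""
        sched = np.asarray(self.hist_pop_size_schedule, dtype=int)
        n = self.n_hist_generations
        if len(sched) >= n:
            return sched[len(sched) - n :]
        pad = np.full(n - len(sched), sched[0], dtype=int)
        return np.concatenate([pad, sched])


def make_locus_map(config: SimConfig) -> pd.DataFrame:
    """Equidistant loci along each chromosome; QTL flags start all-False."""
    per_chrom = np.full(config.n_chromosomes, config.n_loci // config.n_chromosomes)
    per_chrom[: config.n_loci % config.n_chromosomes] += 1
    chroms, pos = [], []
    for c, lc in enumerate(per_chrom, start=1):
        if lc == 0:
            raise ValueError("more chromosomes than loci")
        step = config.chrom_length_cM / lc
        chroms.append(np.full(lc, c))
        pos.append((np.arange(lc) + 0.5) * step)
    return pd.DataFrame(
        {
            "chrom": np.concatenate(chroms).astype(int),
            "pos_cM": np.concatenate(pos),
            "is_qtl": np.zeros(config.n_loci, dtype=bool),
        }
    )


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-dosage matrix with its locus map."""

    dosages: np.ndarray  # (n, L) int8, values in {0,1,2}
    ids: np.ndarray  # (n,) int
    locus_map: pd.DataFrame  # chrom, pos_cM, is_qtl

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.locus_map):
            raise ValueError("locus count mismatch between dosages and locus_map")
        if self.dosages.shape[0] != len(self.ids):
            raise ValueError("row count mismatch between dosages and ids")

    @property
    def allele_freq(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    @property
    def snp_index(self) -> np.ndarray:
        """Column indices of the genotyped SNP panel (QTL excluded)."""
        return np.flatnonzero(~self.locus_map["is_qtl"].to_numpy())

    def snp_panel(self) -> np.ndarray:
        return self.dosages[:, self.snp_index]


@dataclass
class QtlSet:
    """Causal loci: positions within the locus map, signed additive effects."""

    index: np.ndarray  # (q,) locus indices
    effects: np.ndarray  # (q,) |effect| magnitudes (Gamma draws, possibly rescaled)
    signs: np.ndarray  # (q,) +-1

    @property
    def signed_effects(self) -> np.ndarray:
        return self.effects * self.signs

    def rescaled(self, factor: float) -> "QtlSet":
        return QtlSet(self.index, self.effects * factor, self.signs)


@dataclass
class Population:
    """One discrete generation (or the founder cohort)."""

    ids: np.ndarray  # (n,) int
    sire: np.ndarray  # (n,) int, -1 for unknown
    dam: np.ndarray  # (n,) int, -1 for unknown
    sex: np.ndarray  # (n,) bool, True = male
    generation: int
    haplotypes: np.ndarray  # (n, 2, L) uint8
    tbv: np.ndarray | None = None
    phenotype: np.ndarray | None = None
    ebv: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1, dtype=np.int8)

    def genotypes(self, locus_map: pd.DataFrame) -> GenotypeMatrix:
        return GenotypeMatrix(self.dosages, self.ids, locus_map)


@dataclass
class SimResult:
    """Everything a downstream evaluation needs, G0..G7."""

    config: SimConfig
    locus_map: pd.DataFrame
    qtl: QtlSet
    sigma_e: float
    tbv_offset: float
    generations: list[Population]  # index 0 = base generation G0

    def pedigree(self) -> pd.DataFrame:
        frames = []
        for pop in self.generations:
            frames.append(
                pd.DataFrame(
                    {
                        "id": pop.ids,
                        "sire": pop.sire,
                        "dam": pop.dam,
                        "sex": np.where(pop.sex, "M", "F"),
                        "generation": pop.generation,
                        "phenotype": pop.phenotype,
                        "tbv": pop.tbv,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# gamete formation


def _chrom_slices(locus_map: pd.DataFrame) -> list[tuple[slice, np.ndarray]]:
    out = []
    chrom = locus_map["chrom"].to_numpy()
    pos = locus_map["pos_cM"].to_numpy()
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        out.append((slice(idx[0], idx[-1] + 1), pos[idx]))
    return out


def _meiosis(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    chrom_slices: list[tuple[slice, np.ndarray]],
    chrom_length_cM: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombine paired parental haplotypes into gametes.

    Crossover counts per chromosome are Poisson(length in Morgan) with uniform
    placement and no interference; each chromosome starts from a random
    parental strand.
    """
    n, L = hap_a.shape
    gamete = np.empty((n, L), dtype=np.uint8)
    morgans = chrom_length_cM / 100.0
    for sl, pos in chrom_slices:
        lc = sl.stop - sl.start
        n_cross = rng.poisson(morgans, size=n)
        total = int(n_cross.sum())
        cuts = rng.uniform(0.0, chrom_length_cM, size=total)
        gidx = np.repeat(np.arange(n), n_cross)
        # locus index of the first locus at or after each cut
        cut_idx = np.searchsorted(pos, cuts)
        counts = np.zeros((n, lc + 1), dtype=np.uint8)
        np.add.at(counts, (gidx, cut_idx), 1)
        parity = np.cumsum(counts[:, :lc], axis=1, dtype=np.uint8) & 1
        start = rng.integers(0, 2, size=(n, 1), dtype=np.uint8)
        use_b = parity ^ start
        np.copyto(gamete[:, sl], np.where(use_b == 1, hap_b[:, sl], hap_a[:, sl]))
    return gamete


def _mutate(gametes: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Recurrent biallelic mutation: flip alleles in place at the given rate."""
    if rate <= 0:
        return
    n, L = gametes.shape
    n_mut = rng.binomial(n * L, rate)
    if n_mut == 0:
        return
    flat = rng.integers(0, n * L, size=n_mut)
    gametes.reshape(-1)[flat] ^= 1


def _make_offspring_haps(
    parents: Population,
    sire_rows: np.ndarray,
    dam_rows: np.ndarray,
    chrom_slices: list[tuple[slice, np.ndarray]],
    chrom_length_cM: float,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
    dam_pop: Population | None = None,
) -> np.ndarray:
    """Gametes from indexed sires/dams; ``dam_pop`` when dams live elsewhere."""
    dpop = parents if dam_pop is None else dam_pop
    pat = _meiosis(
        parents.haplotypes[sire_rows, 0],
        parents.haplotypes[sire_rows, 1],
        chrom_slices,
        chrom_length_cM,
        rng,
    )
    mat = _meiosis(
        dpop.haplotypes[dam_rows, 0],
        dpop.haplotypes[dam_rows, 1],
        chrom_slices,
        chrom_length_cM,
        rng,
    )
    _mutate(pat, mutation_rate, rng)
    _mutate(mat, mutation_rate, rng)
    return np.stack([pat, mat], axis=1)


# ---------------------------------------------------------------------------
# historical phase


def simulate_history(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Population, pd.DataFrame]:
    """Random-mating history establishing LD; returns the founder cohort (G0).

    The initial generation draws alleles Bernoulli(0.5) per haplotype and
    locus (linkage equilibrium, frequency 0.5); drift over the configured
    generations then builds LD between tightly linked loci and spreads the
    allele-frequency distribution.  Mutation, when enabled, acts during this
    phase only.  The founder cohort pools ``n_founder_males`` males and
    ``n_founder_females`` females sampled from the final historical
    generation.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    locus_map = make_locus_map(config)
    slices = _chrom_slices(locus_map)
    sizes = config.hist_sizes()

    n0 = int(sizes[0])
    haps = rng.integers(0, 2, size=(n0, 2, config.n_loci), dtype=np.uint8)
    sex = rng.random(n0) < 0.5
    pop = Population(
        ids=-np.ones(n0, dtype=np.int64),
        sire=-np.ones(n0, dtype=np.int64),
        dam=-np.ones(n0, dtype=np.int64),
        sex=sex,
        generation=-config.n_hist_generations,
        haplotypes=haps,
    )
    for g in range(1, config.n_hist_generations + 1):
        n_next = int(sizes[g]) if g < len(sizes) else int(sizes[-1])
        males = np.flatnonzero(pop.sex)
        females = np.flatnonzero(~pop.sex)
        if len(males) == 0 or len(females) == 0:
            raise RuntimeError("historical generation lost one sex entirely")
        sire_rows = rng.choice(males, size=n_next, replace=True)
        dam_rows = rng.choice(females, size=n_next, replace=True)
        haps = _make_offspring_haps(
            pop, sire_rows, dam_rows, slices, config.chrom_length_cM, rng,
            mutation_rate=config.mutation_rate,
        )
        pop = Population(
            ids=-np.ones(n_next, dtype=np.int64),
            sire=-np.ones(n_next, dtype=np.int64),
            dam=-np.ones(n_next, dtype=np.int64),
            sex=rng.random(n_next) < 0.5,
            generation=g - config.n_hist_generations,
            haplotypes=haps,
        )

    males = np.flatnonzero(pop.sex)
    females = np.flatnonzero(~pop.sex)
    if len(males) < config.n_founder_males or len(females) < config.n_founder_females:
        raise ValueError(
            "final historical generation too small to draw "
            f"{config.n_founder_males} male and {config.n_founder_females} female founders "
            f"(has {len(males)} males, {len(females)} females); "
            "grow the end of hist_pop_size_schedule"
        )
    sires = rng.choice(males, size=config.n_founder_males, replace=False)
    dams = rng.choice(females, size=config.n_founder_females, replace=False)
    rows = np.concatenate([sires, dams])
    n_f = len(rows)
    founders = Population(
        ids=np.arange(n_f, dtype=np.int64),
        sire=-np.ones(n_f, dtype=np.int64),
        dam=-np.ones(n_f, dtype=np.int64),
        sex=np.concatenate(
            [np.ones(len(sires), dtype=bool), np.zeros(len(dams), dtype=bool)]
        ),
        generation=0,
        haplotypes=pop.haplotypes[rows],
    )
    mono = int(np.sum((founders.dosages.sum(axis=0) == 0)
                      | (founders.dosages.sum(axis=0) == 2 * n_f)))
    if mono:
        warnings.warn(f"{mono} loci are monomorphic in the founder cohort (retained)")
    return founders, locus_map


def adjacent_r2(dosages: np.ndarray, locus_map: pd.DataFrame) -> float:
    """Mean squared correlation between adjacent polymorphic loci, within chromosome."""
    chrom = locus_map["chrom"].to_numpy()
    d = dosages.astype(np.float32)
    mean = d.mean(axis=0)
    sd = d.std(axis=0)
    r2s = []
    for c in np.unique(chrom):
        idx = np.flatnonzero((chrom == c) & (sd > 0))
        if len(idx) < 2:
            continue
        a, b = idx[:-1], idx[1:]
        cov = (d[:, a] * d[:, b]).mean(axis=0) - mean[a] * mean[b]
        r = cov / (sd[a] * sd[b])
        r2s.append((r * r).astype(np.float64))
    if not r2s:
        raise ValueError("no adjacent polymorphic locus pairs")
    return float(np.concatenate(r2s).mean())


# ---------------------------------------------------------------------------
# trait architecture


def sample_qtl(
    config: SimConfig,
    founders: Population,
    locus_map: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> QtlSet:
    """Draw QTL positions and Gamma-distributed signed effects.

    ``n_qtl`` loci are chosen uniformly among loci polymorphic in the founder
    cohort; they are flagged in ``locus_map`` (in place) and thereby excluded
    from every SNP panel downstream — QTL are never genotyped, and a locus is
    never both marker and QTL.  Effect magnitudes are i.i.d.
    Gamma(shape, scale); each sign is +-1 with probability 1/2.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.n_qtl == 0:
        locus_map["is_qtl"] = False
        return QtlSet(
            np.empty(0, dtype=int), np.empty(0), np.empty(0)
        )
    freq = founders.dosages.mean(axis=0) / 2.0
    candidates = np.flatnonzero((freq > 0) & (freq < 1))
    if len(candidates) < config.n_qtl:
        raise ValueError(
            f"only {len(candidates)} polymorphic loci available for {config.n_qtl} QTL"
        )
    index = np.sort(rng.choice(candidates, size=config.n_qtl, replace=False))
    effects = rng.gamma(config.qtl_gamma_shape, config.qtl_gamma_scale, size=config.n_qtl)
    signs = rng.choice([-1.0, 1.0], size=config.n_qtl)
    locus_map["is_qtl"] = False
    locus_map.loc[index, "is_qtl"] = True
    return QtlSet(index, effects, signs)


def true_breeding_values(
    dosages: np.ndarray, qtl: QtlSet, offset: float = 0.0
) -> np.ndarray:
    """TBV = dosage . signed effect over QTL, minus the centering constant."""
    if len(qtl.index) == 0:
        return np.zeros(dosages.shape[0])
    return dosages[:, qtl.index].astype(np.float64) @ qtl.signed_effects - offset


def qtl_variance_shares(freqs: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """Each QTL's share of the summed additive genetic variance.

    Under Hardy-Weinberg and linkage equilibrium a biallelic locus with allele
    frequency p and additive effect a contributes 2 p (1-p) a^2; shares are
    these contributions normalized to sum to one.  Signs and any common
    rescaling of the effects cancel.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    effects = np.asarray(effects, dtype=np.float64)
    if freqs.shape != effects.shape:
        raise ValueError("freqs and effects must align")
    var = 2.0 * freqs * (1.0 - freqs) * effects**2
    total = var.sum()
    if total <= 0:
        raise ValueError("total genetic variance is zero")
    return var / total


def scale_residual(
    config: SimConfig, qtl: QtlSet, founders: Population
) -> tuple[float, QtlSet]:
    """Calibrate the trait so base heritability and phenotypic variance hit target.

    QTL effects are rescaled by a common factor so the empirical variance of
    founder TBVs equals ``h2_target * vp_target`` exactly; the residual s.d.
    is then ``sqrt((1 - h2_target) * vp_target)``.  Returns
    ``(sigma_e, rescaled_qtl)``.
    """
    sigma_e = float(np.sqrt((1.0 - config.h2_target) * config.vp_target))
    if len(qtl.index) == 0:
        if config.h2_target > 0:
            raise ValueError("cannot reach a positive h2_target with zero QTL")
        return sigma_e, qtl
    raw = true_breeding_values(founders.dosages, qtl)
    var_g = float(np.var(raw))
    if var_g == 0.0:
        raise ValueError("base-generation TBV variance is zero; cannot scale to h2 > 0")
    factor = float(np.sqrt(config.h2_target * config.vp_target / var_g))
    return sigma_e, qtl.rescaled(factor)


# ---------------------------------------------------------------------------
# breeding with selection


def _rank_key(
    pop_like: dict, mode: str, rng: np.random.Generator
) -> np.ndarray:
    if mode == "ebv":
        return pop_like["ebv"]
    if mode == "phenotype":
        return pop_like["phen_dev"]
    return rng.random(len(pop_like["ebv"]))


def breed(
    config: SimConfig,
    founders: Population,
    qtl: QtlSet,
    sigma_e: float,
    locus_map: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Produce G0..G_n under EBV truncation selection with partial replacement.

    Each generation, a fraction (``male_replacement``/``female_replacement``)
    of the sire and dam pools is replaced by the top-ranked young candidates;
    retained parents are the top-ranked of the existing pool.  Ranking uses a
    pedigree-index EBV, ``h2 * (y - generation mean) + (EBV_sire + EBV_dam)/2``
    (founders: ``h2 * (y - mean)``), a cheap surrogate for a per-generation
    BLUP evaluation; ``selection='phenotype'`` ranks on phenotype deviations
    and ``selection='random'`` disables ranking.  Matings are random within
    the selected pools, one progeny per mating, offspring sex Bernoulli
    (``sex_ratio``).  Phenotype = TBV + N(0, sigma_e^2); the TBV centering
    constant is fixed in G0 so the base generation has mean TBV zero.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    slices = _chrom_slices(locus_map)
    h2 = config.h2_target

    raw0 = true_breeding_values(founders.dosages, qtl)
    offset = float(raw0.mean())
    founders.tbv = raw0 - offset
    founders.phenotype = founders.tbv + rng.normal(0.0, sigma_e, size=founders.n)
    founders.ebv = h2 * (founders.phenotype - founders.phenotype.mean())

    generations = [founders]
    # pools may mix individuals from several cohorts; store per-pool arrays
    sire_pool = _pool_from(founders, np.flatnonzero(founders.sex))
    dam_pool = _pool_from(founders, np.flatnonzero(~founders.sex))
    next_id = founders.n

    for g in range(1, config.n_offspring_generations + 1):
        n_off = config.offspring_per_generation
        if len(sire_pool["ids"]) == 0 or len(dam_pool["ids"]) == 0:
            raise RuntimeError("selected parent pool is empty")
        sire_pick = rng.integers(0, len(sire_pool["ids"]), size=n_off)
        if n_off <= len(dam_pool["ids"]):
            dam_pick = rng.permutation(len(dam_pool["ids"]))[:n_off]
        else:
            dam_pick = rng.integers(0, len(dam_pool["ids"]), size=n_off)

        pat = _meiosis(
            sire_pool["hap"][sire_pick, 0],
            sire_pool["hap"][sire_pick, 1],
            slices,
            config.chrom_length_cM,
            rng,
        )
        mat = _meiosis(
            dam_pool["hap"][dam_pick, 0],
            dam_pool["hap"][dam_pick, 1],
            slices,
            config.chrom_length_cM,
            rng,
        )
        haps = np.stack([pat, mat], axis=1)
        pop = Population(
            ids=np.arange(next_id, next_id + n_off, dtype=np.int64),
            sire=sire_pool["ids"][sire_pick],
            dam=dam_pool["ids"][dam_pick],
            sex=rng.random(n_off) < config.sex_ratio,
            generation=g,
            haplotypes=haps,
        )
        next_id += n_off
        pop.tbv = true_breeding_values(pop.dosages, qtl, offset)
        pop.phenotype = pop.tbv + rng.normal(0.0, sigma_e, size=n_off)
        parent_mid = 0.5 * (sire_pool["ebv"][sire_pick] + dam_pool["ebv"][dam_pick])
        pop.ebv = h2 * (pop.phenotype - pop.phenotype.mean()) + parent_mid
        generations.append(pop)

        if g < config.n_offspring_generations:
            sire_pool = _refresh_pool(
                sire_pool, pop, True, config.male_replacement,
                config.n_founder_males, config.selection, rng,
            )
            dam_pool = _refresh_pool(
                dam_pool, pop, False, config.female_replacement,
                config.n_founder_females, config.selection, rng,
            )

    return SimResult(
        config=config,
        locus_map=locus_map,
        qtl=qtl,
        sigma_e=sigma_e,
        tbv_offset=offset,
        generations=generations,
    )


def _pool_from(pop: Population, rows: np.ndarray) -> dict:
    return {
        "ids": pop.ids[rows],
        "hap": pop.haplotypes[rows],
        "ebv": pop.ebv[rows],
        "phen_dev": pop.phenotype[rows] - pop.phenotype.mean(),
    }


def _refresh_pool(
    pool: dict,
    young: Population,
    male: bool,
    replacement: float,
    pool_size: int,
    selection: str,
    rng: np.random.Generator,
) -> dict:
    """Replace the worst `replacement` fraction of the pool with top young animals."""
    n_new = int(round(replacement * pool_size))
    n_keep = pool_size - n_new
    cand_rows = np.flatnonzero(young.sex == male)
    cand = _pool_from(young, cand_rows)
    n_new = min(n_new, len(cand["ids"]))
    key_young = _rank_key(cand, selection, rng)
    take_young = np.argsort(-key_young, kind="stable")[:n_new]
    key_old = _rank_key(pool, selection, rng)
    keep_old = np.argsort(-key_old, kind="stable")[:n_keep]
    return {
        k: np.concatenate([pool[k][keep_old], cand[k][take_young]])
        for k in ("ids", "hap", "ebv", "phen_dev")
    }


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: history -> QTL -> trait calibration -> breeding."""
    root = np.random.SeedSequence(config.seed)
    rng_hist, rng_qtl, rng_breed = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    founders, locus_map = simulate_history(config, rng_hist)
    qtl = sample_qtl(config, founders, locus_map, rng_qtl)
    sigma_e, qtl = scale_residual(config, qtl, founders)
    return breed(config, founders, qtl, sigma_e, locus_map, rng_breed)
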