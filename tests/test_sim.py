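import numpy as np
import pandas as pd
import pytest

from fstgrm.sim import (
    QtlSet,
    adjacent_r2,
    make_locus_map,
    sample_qtl,
    scale_residual,
    simulate,
    simulate_history,
    true_breeding_values,
)
from conftest import tiny_config


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        tiny_config(n_chromosomes=0)
    with pytest.raises(ValueError):
        tiny_config(n_snp=0)
    with pytest.raises(ValueError):
        tiny_config(h2_target=1.2)
    with pytest.raises(ValueError):
        tiny_config(male_replacement=0.0)


def test_history_schedule_right_aligned():
    cfg = tiny_config(n_hist_generations=6, hist_pop_size_schedule=(50, 100, 200))
    assert list(cfg.hist_sizes()) == [50, 50, 50, 50, 100, 200]


def test_locus_positions_equidistant_within_chromosome():
    cfg = tiny_config(n_snp=90, n_qtl=10, n_chromosomes=2)
    lm = make_locus_map(cfg)
    assert len(lm) == 100
    for _, sub in lm.groupby("chrom"):
        steps = np.diff(sub["pos_cM"].to_numpy())
        assert np.allclose(steps, steps[0])
        assert sub["pos_cM"].max() < cfg.chrom_length_cM


def test_single_generation_no_mutation_preserves_mean_frequency(rng):
    # drift-free expectation: one round of random mating keeps mean freq ~ 0.5
    cfg = tiny_config(n_hist_generations=1, hist_pop_size_schedule=(600,),
                      mutation_rate=0.0, n_founder_males=100, n_founder_females=180)
    founders, _ = simulate_history(cfg)
    mean_freq = founders.dosages.mean() / 2.0
    assert abs(mean_freq - 0.5) < 0.01


def test_simulation_is_deterministic_under_fixed_seed():
    cfg = tiny_config(seed=9)
    a, b = simulate(cfg), simulate(cfg)
    for pa, pb in zip(a.generations, b.generations):
        assert np.array_equal(pa.haplotypes, pb.haplotypes)
        assert np.array_equal(pa.phenotype, pb.phenotype)
    assert np.array_equal(a.qtl.index, b.qtl.index)
    assert np.allclose(a.qtl.signed_effects, b.qtl.signed_effects)


def test_tbv_is_exact_dot_product_of_qtl_dosages(tiny_sim):
    qtl = tiny_sim.qtl
    for pop in tiny_sim.generations:
        expected = (
            pop.dosages[:, qtl.index].astype(float) @ qtl.signed_effects
            - tiny_sim.tbv_offset
        )
        np.testing.assert_array_almost_equal(pop.tbv, expected, decimal=12)


def test_dosages_in_range_and_freq_identity(tiny_sim):
    base = tiny_sim.generations[0]
    d = base.dosages
    assert set(np.unique(d)) <= {0, 1, 2}
    g = base.genotypes(tiny_sim.locus_map)
    np.testing.assert_allclose(g.allele_freq, d.mean(axis=0) / 2.0)


def test_qtl_never_overlap_snp_panel(tiny_sim):
    g = tiny_sim.generations[0].genotypes(tiny_sim.locus_map)
    assert len(np.intersect1d(g.snp_index, tiny_sim.qtl.index)) == 0
    assert len(tiny_sim.qtl.index) == tiny_sim.config.n_qtl
    assert g.snp_panel().shape[1] == tiny_sim.config.n_snp


def test_gamma_effect_magnitudes_match_closed_form_mean(rng):
    # mean of Gamma(0.4, 0.15) is 0.06
    draws = rng.gamma(0.4, 0.15, size=100_000)
    assert abs(draws.mean() - 0.06) < 0.002
    cfg = tiny_config()
    founders, lm = simulate_history(cfg)
    qtl = sample_qtl(cfg, founders, lm)
    assert np.all(qtl.effects >= 0)
    assert set(np.unique(qtl.signs)) <= {-1.0, 1.0}
    assert lm.loc[qtl.index, "is_qtl"].all()


def test_zero_qtl_means_zero_tbv_everywhere():
    cfg = tiny_config(n_qtl=0, h2_target=0.3)
    founders, lm = simulate_history(cfg)
    qtl = sample_qtl(cfg, founders, lm)
    assert len(qtl.index) == 0
    with pytest.raises(ValueError):
        scale_residual(cfg, qtl, founders)
    assert np.all(true_breeding_values(founders.dosages, qtl) == 0)


def test_residual_scaling_algebra(tiny_sim):
    cfg = tiny_sim.config
    base = tiny_sim.generations[0]
    # effects were rescaled so var(TBV) = h2 * Vp exactly; sigma_e closes Vp
    assert np.var(base.tbv) == pytest.approx(cfg.h2_target * cfg.vp_target, rel=1e-12)
    assert tiny_sim.sigma_e == pytest.approx(
        np.sqrt((1 - cfg.h2_target) * cfg.vp_target), rel=1e-12
    )


def test_h2_one_gives_zero_residual():
    cfg = tiny_config(h2_target=1 - 1e-12)
    res = simulate(cfg)
    base = res.generations[0]
    assert res.sigma_e == pytest.approx(0.0, abs=1e-5)
    np.testing.assert_allclose(base.phenotype, base.tbv, atol=1e-4)


def test_selection_increases_mean_tbv(tiny_sim):
    means = [p.tbv.mean() for p in tiny_sim.generations]
    # positive response overall, and G7 well above the base generation
    assert means[-1] > means[0] + 3 * np.std(tiny_sim.generations[0].tbv) / np.sqrt(180)
    assert np.all(np.diff(means[1:]) > -0.05)  # non-decreasing up to noise


def test_random_selection_full_replacement_shows_no_trend():
    reps = []
    for seed in (1, 2, 3, 4, 5):
        cfg = tiny_config(
            selection="random", male_replacement=1.0, female_replacement=1.0, seed=seed
        )
        res = simulate(cfg)
        reps.append(res.generations[-1].tbv.mean() - res.generations[0].tbv.mean())
    # drift-only: mean change across replicates is centred on zero
    assert abs(np.mean(reps)) < 0.25


def test_realized_base_heritability_near_target():
    h2s, vps = [], []
    for seed in range(5):
        res = simulate(tiny_config(seed=100 + seed))
        base = res.generations[0]
        h2s.append(np.var(base.tbv) / np.var(base.phenotype))
        vps.append(np.var(base.phenotype))
    assert np.mean(h2s) == pytest.approx(0.3, abs=0.05)
    assert np.mean(vps) == pytest.approx(1.0, abs=0.1)


def test_offspring_dosages_mendelian_consistent(tiny_sim):
    # every trio: child dosage must be reachable from parental gamete alleles
    feasible = {0: {0}, 1: {0, 1}, 2: {1}}
    dosage_of = {}
    for pop in tiny_sim.generations:
        d = pop.dosages
        for row, ident in enumerate(pop.ids):
            dosage_of[ident] = d[row]
    rng = np.random.default_rng(5)
    pop = tiny_sim.generations[3]
    d = pop.dosages
    for row in rng.choice(pop.n, size=10, replace=False):
        ds, dd = dosage_of[pop.sire[row]], dosage_of[pop.dam[row]]
        for locus in rng.choice(d.shape[1], size=200, replace=False):
            allowed = {a + b for a in feasible[ds[locus]] for b in feasible[dd[locus]]}
            assert int(d[row, locus]) in allowed


def test_parents_come_from_known_individuals(tiny_sim):
    known = set()
    for pop in tiny_sim.generations:
        if pop.generation > 0:
            assert set(pop.sire).issubset(known)
            assert set(pop.dam).issubset(known)
        known.update(pop.ids)


def test_adjacent_r2_requires_polymorphic_pairs():
    lm = pd.DataFrame({"chrom": [1, 1], "pos_cM": [0.5, 1.5], "is_qtl": [False, False]})
    with pytest.raises(ValueError):
        adjacent_r2(np.ones((10, 2), dtype=np.int8), lm)


def test_qtl_rescale_keeps_signs():
    q = QtlSet(np.array([0, 1]), np.array([1.0, 2.0]), np.array([1.0, -1.0]))
    q2 = q.rescaled(0.5)
    np.testing.assert_allclose(q2.signed_effects, [0.5, -1.0])
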