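import numpy as np
import pytest

from fstgrm.pipeline import ExperimentPlan, run_experiment
from fstgrm.sim import SimConfig, simulate


def tiny_config(**overrides) -> SimConfig:
    """A seconds-scale simulation: same structure, desk-toy census sizes."""
    base = dict(
        n_hist_generations=25,
        hist_pop_size_schedule=(80, 160, 360),
        n_founder_males=30,
        n_founder_females=150,
        n_offspring_generations=7,
        offspring_per_generation=180,
        n_chromosomes=2,
        n_snp=600,
        n_qtl=30,
        seed=123,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_sim():
    return simulate(tiny_config())


@pytest.fixture(scope="session")
def tiny_plan():
    return ExperimentPlan(
        sim=tiny_config(),
        n_replicates=2,
        base_seed=42,
        train_sample=120,
        val_sample=60,
        top_k=30,
        compute_ld=False,
    )


@pytest.fixture(scope="session")
def reduced_study():
    """The default reduced-scale scenario study: 5 replicates, all scenarios.

    This is the package's headline experiment (2 chromosomes x 100 cM, 20K
    SNPs, 100 QTL, 7 generations of EBV selection, 2,000 training / 1,000
    validation animals, top-k = 1,000); several acceptance checks read
    different summaries off the same report.
    """
    return run_experiment(ExperimentPlan())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
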