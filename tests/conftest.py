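import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssblup.pedigree import PedigreeRecord, sort_and_validate
from ssblup.pipeline import prepare_context
from ssblup.synthetic import (
    SimulationConfig,
    default_variance_components,
    simulate_phenotypes,
    simulate_population,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_pedigree(seed: int, n: int = 200, n_founders: int = 20, p_known: float = 0.9):
    """A random multi-generation pedigree with occasional unknown parents."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        sex = "M" if i % 2 else "F"
        if i < n_founders:
            recs.append(PedigreeRecord(f"x{i}", None, None, 2000, sex))
            continue
        cand = list(range(max(0, i - 3 * n_founders), i))
        males = [j for j in cand if j % 2 == 1]
        females = [j for j in cand if j % 2 == 0]
        s = f"x{rng.choice(males)}" if males and rng.random() < p_known else None
        d = f"x{rng.choice(females)}" if females and rng.random() < p_known else None
        recs.append(PedigreeRecord(f"x{i}", s, d, 2000 + i // (2 * n_founders), sex))
    perm = rng.permutation(len(recs))
    return sort_and_validate([recs[int(j)] for j in perm])


@pytest.fixture
def trio_ped():
    return sort_and_validate(
        [
            PedigreeRecord("3", "1", "2", 2001, "M"),
            PedigreeRecord("1", None, None, 2000, "M"),
            PedigreeRecord("2", None, None, 2000, "F"),
        ]
    )


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        n_founder_males=10,
        n_founder_females=60,
        n_generations=3,
        n_sires=10,
        dams_per_sire=6,
        offspring_per_dam=1,
        m_markers=300,
        n_chromosomes=5,
        large_qtl_chromosomes=(1, 3, 5),
        n_large_qtl=6,
        p_genotyped=(0.1, 0.2, 0.4, 0.6),
        n_herds=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_pop():
    """One small simulated population (250 animals, 300 markers) shared
    across solver tests: population, phenotypes, genotypes and the
    prepared evaluation context."""
    cfg = small_config()
    pop = simulate_population(cfg, seed=3)
    phen = simulate_phenotypes(pop, seed=4)
    geno = pop.observed_genotypes(np.random.default_rng(5))
    ctx = prepare_context(pop.ped, geno, cfg.vc, cfg.traits, groups=pop.groups)
    return {"cfg": cfg, "pop": pop, "phen": phen, "geno": geno, "ctx": ctx}
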