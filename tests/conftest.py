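import numpy as np
import pytest

from xopaint.config import SimulationConfig
from xopaint import simkit
from xopaint import painting as pt


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down design for fast unit tests: 5 Mb chromosome, two dense
    blocks, small population; rates and suppression as in the full design."""
    return SimulationConfig(
        chrom_len=5_000_000,
        dense_regions=(("A", 1_000_000, 2_000_000), ("B", 3_000_000, 3_500_000)),
        causal_regions=("A",),
        effect_sizes={"A": 1000.0},
        n_founder_hi_females=20,
        n_founder_lo_males=15,
        generations=6,
        pop_size=120,
        n_assayed_males=80,
        pool_size=15,
        seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_study(default_config):
    """Default design, no dropout and no genotyping error, 60 assayed males:
    painting should recover truth exactly up to crossover-to-SNP gaps."""
    cfg = SimulationConfig(
        **{
            **default_config.to_dict(),
            "dropout_prob": 0.0,
            "genotype_error_prob": 0.0,
            "parental_het_frac": (0.079, 0.058),
            "n_assayed_males": 60,
            "pool_size": 15,
            "seed": 11,
        }
    )
    return cfg, simkit.simulate_study(cfg)


@pytest.fixture(scope="session")
def painted_noise_free(noise_free_study):
    cfg, study = noise_free_study
    parental = study["parental"]
    sites = pt.select_informative_sites(
        parental.positions, study["parental_calls"], 3, cfg.chrom_len
    )
    idx = np.searchsorted(parental.positions, sites.positions)
    paintings = [
        pt.paint_fly(study["calls"][i, idx], sites, fly_id=f"fly{i}")
        for i in range(len(study["cohort"]))
    ]
    return cfg, study, sites, paintings
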