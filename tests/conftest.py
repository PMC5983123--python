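import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from socer import (
    ExpressionMatrix,
    SeedType,
    SimulationConfig,
    TargetSite,
    simulate_expression,
    simulate_target_sites,
)


def make_site(mirna="miR-1", gene="G1", c=1.0, e=-1.0, a=1.0, seed_type=SeedType.MER8):
    return TargetSite(
        mirna_id=mirna,
        gene_id=gene,
        conservation=c,
        energy=e,
        alignment_score=a,
        seed_type=seed_type,
    )


def constant_matrix(levels: dict[str, float], n_samples: int = 4) -> ExpressionMatrix:
    """Matrix whose rows are constant, so row means equal the given levels.

    Used to build instances where the score can be computed by hand.
    """
    return ExpressionMatrix(
        pd.DataFrame(
            {f"S{i}": list(levels.values()) for i in range(n_samples)},
            index=list(levels.keys()),
        )
    )


def random_small_instance(seed: int):
    """A random scorer-sized instance: <= 5 genes, <= 5 miRNAs, dense enough
    in MREs that shared pools are common."""
    rng = np.random.default_rng(seed)
    config = SimulationConfig(
        n_genes=int(rng.integers(2, 6)),
        n_mirnas=int(rng.integers(1, 6)),
        n_samples=int(rng.integers(3, 12)),
        mre_rate=float(rng.uniform(0.5, 2.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    genes, mirnas = simulate_expression(config)
    # force at least one shared pool so instances are rarely all-zero
    sites = simulate_target_sites(
        config, shared_pairs=[(config.gene_ids[0], config.gene_ids[1], [config.mirna_ids[0]])]
    )
    return genes, mirnas, sites


@pytest.fixture
def fixture_dir(tmp_path):
    """A small on-disk fixture: genes.tsv / mirnas.tsv / sites.tsv with a
    planted co-expressed block sharing miRNAs."""
    from socer import write_expression, write_target_sites

    config = SimulationConfig(
        n_genes=10,
        n_mirnas=5,
        n_samples=60,
        mre_rate=1.0,
        planted_blocks=(((0, 1, 2), 0.95),),
        seed=11,
    )
    genes, mirnas = simulate_expression(config)
    sites = simulate_target_sites(
        config,
        shared_pairs=[
            ("G0000", "G0001", ["miR-1", "miR-2"]),
            ("G0000", "G0002", ["miR-3"]),
        ],
    )
    write_expression(genes, tmp_path / "genes.tsv")
    write_expression(mirnas, tmp_path / "mirnas.tsv")
    write_target_sites(sites, tmp_path / "sites.tsv")
    return tmp_path
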