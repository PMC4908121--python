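import numpy as np
import pandas as pd
import pytest

from gbscompare.genotypes import MISSING, SITE_COLUMNS, GenotypeMatrix
from gbscompare.sim import SimConfig, simulate


def make_gm(G, demes=None, contig="c0", positions=None):
    """GenotypeMatrix from a plain list-of-lists (rows = samples)."""
    G = np.asarray(G, dtype=np.int8)
    n_samples, n_sites = G.shape
    positions = positions if positions is not None else list(range(n_sites))
    sites = pd.DataFrame(
        {
            "site_id": [f"{contig}:{p}" for p in positions],
            "contig": contig,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        },
        columns=SITE_COLUMNS,
    )
    return GenotypeMatrix(
        samples=[f"S{i:03d}" for i in range(n_samples)], sites=sites, G=G, demes=demes
    )


@pytest.fixture(scope="session")
def small_sim():
    """One modest noisy simulation shared by read-level tests."""
    config = SimConfig(
        n_individuals=8,
        n_contigs=25,
        contig_length=1000,
        theta_per_site=0.005,
        mean_depth=12.0,
        depth_dispersion=10.0,
        seq_error_rate=0.002,
        pcr_duplicate_rate=0.05,
        seed=123,
    )
    ref, truth, reads, key = simulate(config)
    return {"config": config, "ref": ref, "truth": truth, "reads": reads, "key": key}


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free, dropout-free simulation for exact-recovery tests."""
    config = SimConfig(
        n_individuals=6,
        n_contigs=20,
        contig_length=1000,
        theta_per_site=0.004,
        mean_depth=25.0,
        depth_dispersion=20.0,
        seq_error_rate=0.0,
        pcr_duplicate_rate=0.0,
        allelic_dropout=False,
        seed=321,
    )
    ref, truth, reads, key = simulate(config)
    return {"config": config, "ref": ref, "truth": truth, "reads": reads, "key": key}
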