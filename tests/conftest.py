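import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from medipmap.genemodel import derive_features
from medipmap.simulate import SimConfig, simulate_genome, simulate_methylome


SMALL_SIM_KWARGS = dict(
    chrom_length=300_000,
    n_genes=20,
    n_intergenic_cgis=3,
    n_repeats={
        "LINE": 10,
        "SINE": 10,
        "LTR": 6,
        "DNA": 4,
        "satellite": 2,
        "simple": 3,
        "low_complexity": 3,
    },
)


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared across tests: genome, genes,
    repeats, annotation, per-sample peaks/reads and truth."""
    cfg = SimConfig(seed=11, **SMALL_SIM_KWARGS)
    genome, genes, repeats, gtruth = simulate_genome(cfg)
    annotation = derive_features(genes, genome.index, cfg.flank, repeats)
    peaks, reads, mtruth = simulate_methylome(cfg, annotation)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "repeats": repeats,
        "annotation": annotation,
        "peaks": peaks,
        "reads": reads,
        "truth_genome": gtruth,
        "truth_methylome": mtruth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
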