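import numpy as np
import pytest

from earlyburst.formats import GeneRecord, GenomeAnnotation, dedupe_to_species
from earlyburst.pipeline import RunConfig, two_step_mapping
from earlyburst.simulate import SimConfig, simulate_experiment


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def toy_genome() -> GenomeAnnotation:
    """A deterministic 6-kb genome with three genes for arithmetic tests."""
    rng = np.random.default_rng(20240901)
    seq = random_dna(rng, 6000)
    genes = [GeneRecord("gA", 500, 1499, "+", rank=1),
             GeneRecord("gB", 2000, 2899, "-", rank=2),
             GeneRecord("gC", 3500, 4399, "+", rank=3)]
    return GenomeAnnotation("virus", seq, genes)


@pytest.fixture(scope="session")
def small_experiment():
    """Error-free synthetic infection shared across recovery tests."""
    cfg = SimConfig(n_genes=20, base_depth=4000, host_len=30000, error_rate=0.0)
    genome, truth, readsets, host = simulate_experiment(cfg, seed=5)
    reads = [(r.sequence, tp) for tp, rs in readsets.items() for r in rs.reads]
    species = dedupe_to_species(reads)
    config = RunConfig(sim=cfg, seed=5)
    alignments, split_hits, unmapped = two_step_mapping(species, genome, host,
                                                        config)
    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "readsets": readsets,
        "host": host,
        "species": species,
        "alignments": alignments,
        "split_hits": split_hits,
        "unmapped": unmapped,
    }
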