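import numpy as np
import pandas as pd
import pytest

from genodim import SimConfig, simulate
from genodim.simpop import GenomeMap, Population


def desk_config(**overrides) -> SimConfig:
    """A configuration small enough for second-scale runs."""
    base = dict(
        n_chromosomes=2,
        total_length=2.0,
        n_snp_target=800,
        n_qtn_target=30,
        hist_schedule=((-80, 60), (-40, 250), (0, 120)),
        n_sires=8,
        n_dams=100,
        n_generations_recent=20,
        genotyped_generations=(16, 17, 18, 19, 20),
        phenotyped_generations=tuple(range(11, 21)),
        h2=0.9,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def desk_sim():
    """One shared end-to-end desk-scale simulation."""
    return simulate(desk_config())


def toy_population(haplotypes, chrom=None, pos=None, cls=None, generation=None,
                   sex=None) -> Population:
    """Population from an explicit (n, 2, L) haplotype array."""
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    n, _, L = haplotypes.shape
    table = pd.DataFrame(
        {
            "chrom": np.ones(L, dtype=int) if chrom is None else chrom,
            "pos": np.linspace(0.0, 1.0, L) if pos is None else pos,
            "locus_id": np.arange(L),
            "cls": ["SNP"] * L if cls is None else cls,
        }
    )
    ped = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sire": 0,
            "dam": 0,
            "sex": np.zeros(n, dtype=np.int8) if sex is None else sex,
            "generation": np.zeros(n, dtype=int) if generation is None else generation,
            "genotyped": True,
        }
    )
    return Population(ped, haplotypes, GenomeMap(table))
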