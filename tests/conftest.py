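import numpy as np
import pytest

from introsim import experiments as ex
from introsim.engine import Engine
from introsim.genome import GenomeStructure, GenomicElement, RecombinationMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def all_exon_structure(length: int = 100_000, r: float = 1e-8) -> GenomeStructure:
    return GenomeStructure(length, [GenomicElement("exon", 0, length)],
                           RecombinationMap.uniform(r, length))


def half_exon_structure(length: int = 100_000, r: float = 1e-8) -> GenomeStructure:
    half = length // 2
    return GenomeStructure(
        length,
        [GenomicElement("exon", 0, half),
         GenomicElement("intergenic", half, length)],
        RecombinationMap.uniform(r, length))


def tiny_engine(structure=None, *, dominance="additive", mu=1.5e-8, r=1e-8,
                seed=0, N_A=20, neutral=False, track_neutral=True,
                x_mode=False) -> Engine:
    """A small engine whose internals (mutation, recombination, fitness)
    can be exercised directly without running a full simulation."""
    structure = structure if structure is not None else all_exon_structure(r=r)
    cfg = ex.build_config(model=0, dominance=dominance, r=r,
                          N_A=N_A, L=structure.length, c=1.0, mu=mu,
                          structure=structure, seed=seed, neutral=neutral,
                          track_neutral=track_neutral, x_mode=x_mode)
    return Engine(cfg)
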