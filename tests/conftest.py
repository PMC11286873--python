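import numpy as np
import pytest

from ecvmate.population import GeneticMap, HaplotypePopulation, TraitArchitecture


def make_map(n_loci: int, r: float | np.ndarray = 0.2, classes=None, chromosome=None) -> GeneticMap:
    r_vec = np.full(n_loci - 1, r) if np.isscalar(r) else np.asarray(r, dtype=float)
    chrom = np.zeros(n_loci, dtype=int) if chromosome is None else np.asarray(chromosome)
    if classes is None:
        classes = ("qtl",) * n_loci
    return GeneticMap(
        locus_id=tuple(f"L{i}" for i in range(n_loci)),
        chromosome=chrom,
        locus_class=tuple(classes),
        r_adjacent=r_vec,
    )


def make_pop(alleles: np.ndarray, gmap: GeneticMap | None = None) -> HaplotypePopulation:
    alleles = np.asarray(alleles, dtype=np.int8)
    if gmap is None:
        gmap = make_map(alleles.shape[1])
    ids = tuple(f"ind{k}" for k in range(alleles.shape[0]))
    return HaplotypePopulation(alleles=alleles, individual_id=ids, map=gmap)


def random_pop(K: int, n_loci: int, rng: np.random.Generator, gmap=None) -> HaplotypePopulation:
    return make_pop(rng.integers(0, 2, (K, n_loci, 2), dtype=np.int8), gmap)


def single_trait_arch(n_loci: int, trait_id: str = "t") -> TraitArchitecture:
    return TraitArchitecture(
        trait_ids=(trait_id,),
        qtl_indices={trait_id: np.arange(n_loci)},
        desirable_allele={trait_id: np.ones(n_loci, dtype=np.int8)},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240702)
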