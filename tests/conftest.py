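import numpy as np
import pytest

from ssrpanel import cohort as co
from ssrpanel import simdata as sd


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_design():
    """A compact study-like design: 3 sub-populations, quick to simulate."""
    return sd.study_design(
        11,
        populations={"alpha": 4, "beta": 6, "gamma": 3},
        private_pop="gamma",
        n_private_fixed=3,
        n_private_seg=2,
        n_shared=4,
        n_monomorphic=1,
        chrom_lengths={"1": 12_000, "2": 12_000},
        interior_margin=1_600,
    )


@pytest.fixture(scope="session")
def small_truth(small_design):
    genome = sd.generate_genome(small_design)
    truth = sd.generate_cohort(small_design, genome)
    return small_design, genome, truth


def tiny_cohort():
    """Hand-built two-population cohort used by filter unit tests.

    Locus 0: allele 2 private to and fixed in pop B (a doubleton).
    Locus 1: allele 2 private to pop B but one member heterozygous.
    Locus 2: monomorphic.
    """
    samples = ["a1", "a2", "a3", "b1", "b2"]
    assignment = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
    loci = [
        co.LocusGenotypes(
            chrom="1", pos=100, alleles=("ACACACACACACAC", "ACACACACAC",
                                         "ACACACACACACACACACACACACAC"),
            genotypes=[(0, 1), (0, 0), (1, 1), (2, 2), (2, 2)],
            motif="AC",
        ),
        co.LocusGenotypes(
            chrom="1", pos=500, alleles=("AGAGAGAGAGAGAG", "AGAGAGAGAG",
                                         "AGAGAGAGAGAGAGAGAGAGAGAGAG"),
            genotypes=[(0, 1), (0, 0), (1, 1), (2, 2), (2, 0)],
            motif="AG",
        ),
        co.LocusGenotypes(
            chrom="1", pos=900, alleles=("ATATATATATATAT",),
            genotypes=[(0, 0)] * 5,
            motif="AT",
        ),
    ]
    return (
        co.CohortGenotypes(samples=samples, loci=loci),
        co.PopulationAssignment(assignment),
    )


@pytest.fixture
def two_pop_cohort():
    return tiny_cohort()
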