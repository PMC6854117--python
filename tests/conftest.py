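import numpy as np
import pytest

from invadepop.io_formats import GenotypeMatrix, PopulationMap


def toy_matrix(genotypes, region_id=None, position=None, qual=None,
               individual_ids=None, ref="A", alt="T"):
    """Build a GenotypeMatrix from a dosage array (sites x individuals)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = g.shape
    region_id = region_id or [f"r{i}" for i in range(n_sites)]
    position = position if position is not None else list(range(1, n_sites + 1))
    qual = qual if qual is not None else [-np.inf] * n_sites
    individual_ids = individual_ids or [f"i{j}" for j in range(n_ind)]
    return GenotypeMatrix(
        locus_id=[f"{r}_{p}" for r, p in zip(region_id, position)],
        region_id=list(region_id),
        position=np.array(position),
        ref_allele=[ref] * n_sites,
        alt_allele=[alt] * n_sites,
        qual=np.array(qual, dtype=float),
        genotypes=g,
        individual_ids=list(individual_ids),
    )


@pytest.fixture
def two_pop_map():
    def make(gm, split):
        return PopulationMap(assignments={
            ind: ("P1" if k < split else "P2")
            for k, ind in enumerate(gm.individual_ids)
        })
    return make


@pytest.fixture(scope="session")
def small_fixture():
    """Desk-scale synthetic dataset shared across test modules."""
    from invadepop.synth import FixtureSpec, simulate_fixture

    gm, pm, truth = simulate_fixture(FixtureSpec(scale=0.012, seed=20240917))
    return gm, pm, truth


HANDWRITTEN_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB
chr1\t5\tsnp1\tA\tG\t50\t.\t.\tGT\t0/0\t0/1
chr1\t9\tsnp2\tC\tT\t.\t.\t.\tGT\t1/1\t./.
chr1\t14\tsnp3\tG\tA\t12.5\t.\t.\tGT\t0/1\t1/1
"""


@pytest.fixture
def handwritten_vcf(tmp_path):
    path = tmp_path / "hand.vcf"
    path.write_text(HANDWRITTEN_VCF)
    return path
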