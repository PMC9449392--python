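import numpy as np
import pytest

from sweepscan.core_io import VariantMatrix


VCF_FIXTURE = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tT\t50\tPASS\t.\tGT\t0/0\t0/1
chr1\t103\t.\tG\tC\t50\tPASS\t.\tGT\t0/1\t0/1
chr1\t500\t.\tT\tG\t50\tPASS\t.\tGT\t1/1\t0/0
"""

VCF_PHASED = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tT\t50\tPASS\t.\tGT\t0|1\t0|1
chr1\t200\t.\tG\tC\t50\tPASS\t.\tGT\t1|1\t0|1
chr1\t300\t.\tT\tG\t50\tPASS\t.\tGT\t0|0\t1|0
"""

VCF_TRIALLELIC = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tT\t50\tPASS\t.\tGT\t0/1\t0/0
chr1\t200\t.\tG\tC,T\t50\tPASS\t.\tGT\t1/2\t0/1
chr1\t300\t.\tT\tG\t50\tPASS\t.\tGT\t0/1\t1/1
"""


@pytest.fixture
def vcf_file(tmp_path):
    p = tmp_path / "basic.vcf"
    p.write_text(VCF_FIXTURE)
    return p


@pytest.fixture
def vcf_phased(tmp_path):
    p = tmp_path / "phased.vcf"
    p.write_text(VCF_PHASED)
    return p


@pytest.fixture
def vcf_triallelic(tmp_path):
    p = tmp_path / "tri.vcf"
    p.write_text(VCF_TRIALLELIC)
    return p


def random_matrix(rng, n_snps=50, n_samples=10, contig="chr1", span=1_000_000,
                  phased=True, missing_frac=0.0):
    """Random phased VariantMatrix used by the oracle-equivalence tests."""
    positions = np.sort(rng.choice(span, size=n_snps, replace=False)) + 1
    haps = rng.integers(0, 2, size=(n_snps, 2 * n_samples)).astype(np.int8)
    genotypes = (haps[:, 0::2] + haps[:, 1::2]).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random(genotypes.shape) < missing_frac
        genotypes[mask] = -1
        haps = None
    return VariantMatrix(
        contig=contig,
        positions=positions,
        genotypes=genotypes,
        sample_ids=[f"s{i}" for i in range(n_samples)],
        quality=np.full(n_snps, 60.0),
        haplotypes=haps,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
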