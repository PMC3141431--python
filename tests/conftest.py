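import numpy as np
import pytest

from balsel.regionio import HaplotypeAlignment, Region


def make_alignment(matrix, L=None, populations=None, positions=None,
                   name="test") -> HaplotypeAlignment:
    """Build an alignment from a (n x m) code matrix with evenly spaced
    positions inside a region of length L (default: m, or 1 for empty)."""
    matrix = np.asarray(matrix, dtype=np.int8)
    n, m = matrix.shape
    L = L if L is not None else max(m, 1)
    positions = (np.asarray(positions) if positions is not None
                 else np.arange(m))
    populations = populations if populations is not None else ["CEU"] * n
    return HaplotypeAlignment(
        region=Region("chrT", 0, L, name),
        haplotypes=matrix,
        positions=positions,
        populations=np.array(populations, dtype=object),
    )


@pytest.fixture
def small_fasta(tmp_path):
    """The 4-haplotype toy alignment with 3 polymorphic columns."""
    fasta = tmp_path / "toy.fa"
    fasta.write_text(">h1\nAAA\n>h2\nAAT\n>h3\nATT\n>h4\nTTT\n")
    pop_map = tmp_path / "toy.popmap.tsv"
    pop_map.write_text("h1\tCEU\nh2\tCEU\nh3\tCEU\nh4\tCEU\n")
    return fasta, pop_map


@pytest.fixture
def phased_vcf(tmp_path):
    """Two diploid samples, two phased SNPs (one outside the test region),
    one triallelic SNP."""
    vcf = tmp_path / "toy.vcf"
    vcf.write_text("\n".join([
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=chr6>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampA\tsampB",
        "chr6\t101\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1",
        "chr6\t150\t.\tG\tT,A\t.\tPASS\t.\tGT\t0|1\t2|0",
        "chr6\t500\t.\tC\tG\t.\tPASS\t.\tGT\t0|1\t0|0",
    ]) + "\n")
    pop_map = tmp_path / "toy_vcf.popmap.tsv"
    pop_map.write_text("sampA\tCEU\nsampB\tCEU\n")
    return vcf, pop_map
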