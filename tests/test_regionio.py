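import numpy as np
import pytest

from balsel.regionio import (
    HaplotypeAlignment,
    Region,
    RegionFormatError,
    SampleMappingError,
    SiteClass,
    attach_outgroup,
    read_haplotype_fasta,
    read_vcf_region,
    write_haplotype_fasta,
)

from conftest import make_alignment


class TestRegion:
    def test_length(self):
        assert Region("chr6", 100, 350, "r").length == 250

    @pytest.mark.parametrize("start,end", [(10, 10), (10, 5)])
    def test_empty_or_inverted_rejected(self, start, end):
        with pytest.raises(ValueError):
            Region("chr6", start, end)


class TestFastaReading:
    def test_variant_columns_and_length(self, small_fasta):
        aln = read_haplotype_fasta(*small_fasta)
        # all three columns segregate (col 1 is A,A,A,T)
        assert (aln.n, aln.m, aln.L) == (4, 3, 3)
        assert aln.alleles == ["AT", "AT", "AT"]
        # lexicographic coding: A=0, T=1
        assert aln.haplotypes[:, 1].tolist() == [0, 0, 1, 1]

    def test_single_record_rejected(self, tmp_path):
        fa = tmp_path / "one.fa"
        fa.write_text(">h1\nACGT\n")
        with pytest.raises(RegionFormatError, match=">= 2"):
            read_haplotype_fasta(fa, {"h1": "CEU"})

    def test_unequal_lengths_rejected(self, tmp_path):
        fa = tmp_path / "bad.fa"
        fa.write_text(">h1\nACGT\n>h2\nACG\n")
        with pytest.raises(RegionFormatError, match="unequal"):
            read_haplotype_fasta(fa, {"h1": "CEU", "h2": "CEU"})

    def test_unknown_sample_rejected(self, small_fasta):
        fasta, _ = small_fasta
        with pytest.raises(SampleMappingError):
            read_haplotype_fasta(fasta, {"h1": "CEU"})

    def test_indel_column_excluded(self, tmp_path):
        fa = tmp_path / "gap.fa"
        fa.write_text(">h1\nA-A\n>h2\nATT\n")
        aln = read_haplotype_fasta(fa, {"h1": "CEU", "h2": "CEU"})
        assert aln.excluded_positions == [1]
        assert aln.m == 1  # only the A/T column at position 2

    def test_round_trip_byte_identical(self, small_fasta, tmp_path):
        aln = read_haplotype_fasta(*small_fasta)
        out = tmp_path / "rt.fa"
        write_haplotype_fasta(aln, out)
        again = read_haplotype_fasta(out, small_fasta[1])
        assert again.full_sequences == aln.full_sequences
        assert again.sample_ids == aln.sample_ids

    def test_synthetic_round_trip(self, tmp_path):
        aln = make_alignment([[0, 1], [1, 0], [0, 0]], L=10)
        out = tmp_path / "synth.fa"
        write_haplotype_fasta(aln, out)
        again = read_haplotype_fasta(
            out, {s: "CEU" for s in aln.sample_ids})
        assert np.array_equal(again.haplotypes, aln.haplotypes)
        assert np.array_equal(again.positions, aln.positions)


class TestVcfReading:
    def test_two_haplotypes_per_sample(self, phased_vcf):
        region = Region("chr6", 100, 200, "r")
        aln = read_vcf_region(*[phased_vcf[0], region, phased_vcf[1]])
        assert aln.n == 4
        assert aln.m == 2  # SNP at 500 is outside
        assert aln.L == 100

    def test_positions_zero_based(self, phased_vcf):
        region = Region("chr6", 100, 200, "r")
        aln = read_vcf_region(phased_vcf[0], region, phased_vcf[1])
        assert aln.positions.tolist() == [100, 149]

    def test_triallelic_codes(self, phased_vcf):
        region = Region("chr6", 100, 200, "r")
        aln = read_vcf_region(phased_vcf[0], region, phased_vcf[1])
        # site 150: REF G, ALT T,A -> lexicographic A,G,T
        j = aln.positions.tolist().index(149)
        assert aln.alleles[j] == "AGT"
        assert set(aln.haplotypes[:, j]) == {0, 1, 2}

    def test_empty_region_gives_zero_columns(self, phased_vcf):
        region = Region("chr6", 10_000, 11_000, "empty")
        aln = read_vcf_region(phased_vcf[0], region, phased_vcf[1])
        assert (aln.n, aln.m, aln.L) == (4, 0, 1000)

    def test_unphased_het_rejected_unless_flagged(self, tmp_path, phased_vcf):
        vcf = tmp_path / "unphased.vcf"
        vcf.write_text(phased_vcf[0].read_text().replace("0|1\t1|1",
                                                         "0/1\t1|1"))
        region = Region("chr6", 100, 200, "r")
        with pytest.raises(RegionFormatError, match="unphased"):
            read_vcf_region(vcf, region, phased_vcf[1])
        with pytest.warns(UserWarning, match="unphased"):
            aln = read_vcf_region(vcf, region, phased_vcf[1],
                                  allow_unphased=True)
        assert aln.n == 4


class TestOutgroup:
    def test_site_classification_partitions_length(self):
        aln = make_alignment([[0, 1], [1, 0]], L=5, positions=[1, 3])
        # sequences consistent with the matrix (alleles A/C at both sites)
        aln.full_sequences = ["AAACA", "ACAAA"]
        # outgroup: fixed difference at 0, gap at 4, matches elsewhere
        og = attach_outgroup(aln, "GAAA-")
        counts = og.class_counts()
        assert sum(counts.values()) == aln.L
        assert counts["fixed_difference"] == 1
        assert counts["unalignable"] == 1
        assert counts["polymorphic"] == 2
        assert counts["monomorphic_shared"] == 1

    def test_polarization(self):
        aln = make_alignment([[0], [1], [1]], L=3, positions=[1])
        aln.populations = np.array(["CEU"] * 3, dtype=object)
        og = attach_outgroup(aln, "AAA")  # outgroup A matches allele 0
        assert og.ancestral_code[0] == 0

    def test_unmatched_outgroup_base_unpolarized(self):
        aln = make_alignment([[0], [1]], L=1)
        og = attach_outgroup(aln, "G")  # alleles are A/C; G matches neither
        assert og.ancestral_code[0] == -1
        assert og.site_class[0] == SiteClass.POLYMORPHIC

    def test_length_mismatch_rejected(self):
        aln = make_alignment([[0], [1]], L=4)
        with pytest.raises(RegionFormatError, match="length"):
            attach_outgroup(aln, "AA")


class TestAlignmentInvariants:
    def test_min_two_haplotypes(self):
        with pytest.raises(ValueError):
            make_alignment([[0, 1]])

    def test_positions_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            make_alignment([[0, 1], [1, 0]], L=5, positions=[3, 1])

    def test_population_subset_redrops_monomorphic(self):
        aln = make_alignment([[0, 1], [0, 0], [1, 0], [1, 1]],
                             populations=["CEU", "CEU", "YRI", "YRI"])
        sub = aln.subset_population("CEU")
        assert sub.n == 2
        assert sub.m == 1  # first column is monomorphic within CEU
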