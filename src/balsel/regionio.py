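"""Reading/writing region data and building haplotype matrices.

Conventions
-----------
* Coordinates are BED-style 0-based half-open internally; VCF positions are
  converted on read.
* Haplotype matrices hold small integer allele codes per variant column
  (0/1 for biallelic, 0/1/2 for triallelic, ``-1`` for missing). Codes are
  assigned by lexicographic order of the observed bases.
* Sites containing alignment gaps (``-``) are treated as indels and excluded
  from the variant matrix (recorded in ``excluded_positions``); all
  downstream statistics are SNP-based.
* Monomorphic columns are not stored in the matrix but the surveyed length
  ``L`` always refers to the full region, which is what per-site estimators
  divide by.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

MISSING = -1
_MISSING_CHARS = {"N", "n", "?"}
_GAP_CHARS = {"-", "."}


class RegionFormatError(ValueError):
    """Malformed input (unequal FASTA lengths, bad BED line, ...)."""


class SampleMappingError(KeyError):
    """A sequence/sample id is absent from the population map."""


class SiteClass(IntEnum):
    """Per-site classification of an ingroup/outgroup alignment."""

    POLYMORPHIC = 0
    FIXED_DIFFERENCE = 1
    MONOMORPHIC_SHARED = 2
    UNALIGNABLE = 3


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"Region end must exceed start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HaplotypeAlignment:
    """Phased haplotypes for one region.

    Parameters
    ----------
    region
        Genomic interval surveyed; ``region.length`` is the per-site
        denominator ``L``.
    haplotypes
        ``n x m`` integer matrix of allele codes over the m variant columns.
    positions
        Absolute 0-based bp coordinate of each variant column, strictly
        increasing, within the region bounds.
    populations
        Population label per haplotype row.
    sample_ids
        Identifier per haplotype row (two rows per diploid sample for VCF
        input).
    alleles
        Base string per column, index = allele code (e.g. ``"AT"``).
    full_sequences
        Optional verbatim sequences (one per row) used for byte-identical
        FASTA round trips; synthetic alignments may omit them.
    """

    region: Region
    haplotypes: np.ndarray
    positions: np.ndarray
    populations: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    alleles: list[str] = field(default_factory=list)
    full_sequences: list[str] | None = None
    excluded_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.n < 2:
            raise ValueError(f"need at least 2 haplotypes, got {self.n}")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("positions do not match matrix columns")
        if len(self.populations) != self.n:
            raise ValueError("one population label per haplotype required")
        if len(self.positions) > 0:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            if self.positions[0] < self.region.start or self.positions[-1] >= self.region.end:
                raise ValueError("variant positions outside region bounds")
            counts = (self.haplotypes != MISSING).sum(axis=0)
            if np.any(counts == 0):
                raise ValueError("every column needs at least one called allele")
        if not self.sample_ids:
            self.sample_ids = [f"hap{i}" for i in range(self.n)]
        if not self.alleles:
            self.alleles = ["ACG"[: int(self.haplotypes[:, j].max()) + 1] if self.m else ""
                            for j in range(self.m)]

    @property
    def n(self) -> int:
        """Number of chromosomes sampled."""
        return self.haplotypes.shape[0]

    @property
    def m(self) -> int:
        """Number of variant columns."""
        return self.haplotypes.shape[1]

    @property
    def L(self) -> int:
        """Surveyed length in bp."""
        return self.region.length

    def subset_population(self, population: str) -> "HaplotypeAlignment":
        """Restrict to the haplotypes of one population, re-deriving
        variant columns (sites monomorphic within the population drop out)."""
        mask = self.populations == population
        if mask.sum() < 2:
            raise ValueError(f"fewer than 2 haplotypes labelled {population!r}")
        sub = self.haplotypes[mask]
        keep = _segregating_columns(sub)
        return HaplotypeAlignment(
            region=self.region,
            haplotypes=sub[:, keep],
            positions=self.positions[keep],
            populations=self.populations[mask],
            sample_ids=[s for s, k in zip(self.sample_ids, mask) if k],
            alleles=[self.alleles[j] for j in np.flatnonzero(keep)],
            excluded_positions=list(self.excluded_positions),
        )

    def subset_window(self, window: Region) -> "HaplotypeAlignment":
        """Restrict to variant columns inside ``window`` (same haplotypes)."""
        keep = (self.positions >= window.start) & (self.positions < window.end)
        return HaplotypeAlignment(
            region=window,
            haplotypes=self.haplotypes[:, keep],
            positions=self.positions[keep],
            populations=self.populations,
            sample_ids=list(self.sample_ids),
            alleles=[self.alleles[j] for j in np.flatnonzero(keep)],
        )


def _segregating_columns(matrix: np.ndarray) -> np.ndarray:
    """Boolean mask of columns with >= 2 distinct non-missing alleles."""
    keep = np.zeros(matrix.shape[1], dtype=bool)
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        called = col[col != MISSING]
        keep[j] = called.size > 0 and np.unique(called).size >= 2
    return keep


@dataclass
class OutgroupAlignment:
    """Ingroup alignment plus a single aligned outgroup sequence.

    ``site_class`` covers every surveyed site; ``ancestral_code`` gives the
    outgroup-matching allele code per variant column (``-1`` when the site
    cannot be polarized).
    """

    alignment: HaplotypeAlignment
    outgroup_allele: np.ndarray  # length-L array of bases ('' = missing)
    site_class: np.ndarray       # length-L array of SiteClass codes
    ancestral_code: np.ndarray   # per variant column; -1 = unpolarized

    @property
    def fixed_differences(self) -> int:
        return int((self.site_class == SiteClass.FIXED_DIFFERENCE).sum())

    @property
    def aligned_length(self) -> int:
        return int((self.site_class != SiteClass.UNALIGNABLE).sum())

    def class_counts(self) -> dict[str, int]:
        return {c.name.lower(): int((self.site_class == c).sum()) for c in SiteClass}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_pop_map(path: str | Path) -> dict[str, str]:
    """Read a TSV sample->population map (columns: sample_id, population)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     names=["sample_id", "population"], header=None)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SampleMappingError(f"duplicate sample ids in pop map: {dups}")
    return dict(zip(df["sample_id"], df["population"]))


def read_bed(path: str | Path) -> list[Region]:
    """Read BED3/BED4 intervals as :class:`Region` objects."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise RegionFormatError(f"bad BED line: {line!r}")
        name = parts[3] if len(parts) > 3 else ""
        regions.append(Region(parts[0], int(parts[1]), int(parts[2]), name))
    return regions


def read_haplotype_fasta(
    path: str | Path,
    pop_map: str | Path | dict[str, str],
    region: Region | None = None,
) -> HaplotypeAlignment:
    """Read phased haplotypes from a FASTA alignment (one record per
    chromosome).

    All records must be equal length; the surveyed length L is the alignment
    length (coordinates are region-local unless ``region`` is given). Sites
    containing gap characters are excluded as indels.
    """
    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise RegionFormatError(f"need >= 2 haplotype records, got {len(records)}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise RegionFormatError(f"unequal record lengths: {sorted(lengths)}")
    L = lengths.pop()
    missing_ids = [r.id for r in records if r.id not in pop_map]
    if missing_ids:
        raise SampleMappingError(f"ids absent from pop map: {missing_ids}")
    if region is None:
        region = Region("region", 0, L, Path(str(path)).stem)
    elif region.length != L:
        raise RegionFormatError(
            f"region length {region.length} != alignment length {L}")

    seqs = [str(r.seq).upper() for r in records]
    codes_cols, positions, alleles, excluded = [], [], [], []
    offset = region.start
    for j in range(L):
        column = [s[j] for s in seqs]
        if any(c in _GAP_CHARS for c in column):
            excluded.append(offset + j)
            continue
        observed = sorted({c for c in column if c not in _MISSING_CHARS})
        if len(observed) < 2:
            continue
        if len(observed) > 3:
            raise RegionFormatError(
                f"more than 3 alleles at column {j}: {observed}")
        code_of = {b: k for k, b in enumerate(observed)}
        codes_cols.append([code_of.get(c, MISSING) if c not in _MISSING_CHARS
                           else MISSING for c in column])
        positions.append(offset + j)
        alleles.append("".join(observed))
    if excluded:
        logger.info("excluded %d indel-containing columns", len(excluded))

    matrix = (np.array(codes_cols, dtype=np.int8).T if codes_cols
              else np.zeros((len(records), 0), dtype=np.int8))
    return HaplotypeAlignment(
        region=region,
        haplotypes=matrix,
        positions=np.array(positions, dtype=np.int64),
        populations=np.array([pop_map[r.id] for r in records], dtype=object),
        sample_ids=[r.id for r in records],
        alleles=alleles,
        full_sequences=[str(r.seq) for r in records],
        excluded_positions=excluded,
    )


def write_haplotype_fasta(aln: HaplotypeAlignment, path: str | Path,
                          background_base: str = "A") -> None:
    """Write one FASTA record per haplotype.

    Uses the verbatim input sequences when available (byte-identical round
    trip); otherwise synthesizes sequences with ``background_base`` at
    invariant sites and the column alleles at variant sites.
    """
    if aln.full_sequences is not None:
        records = [SeqRecord(Seq(s), id=sid, description="")
                   for sid, s in zip(aln.sample_ids, aln.full_sequences)]
    else:
        records = []
        local = aln.positions - aln.region.start
        for i, sid in enumerate(aln.sample_ids):
            chars = [background_base] * aln.L
            for j, p in enumerate(local):
                code = aln.haplotypes[i, j]
                chars[p] = "N" if code == MISSING else aln.alleles[j][code]
            records.append(SeqRecord(Seq("".join(chars)), id=sid, description=""))
    SeqIO.write(records, str(path), "fasta-2line")


def read_vcf_region(
    path: str | Path,
    region: Region,
    pop_map: str | Path | dict[str, str],
    allow_unphased: bool = False,
) -> HaplotypeAlignment:
    """Read phased diploid genotypes from a VCF into a haplotype matrix.

    Two haplotype rows per sample; only SNP records inside ``region`` are
    kept (indels logged and skipped); multiallelic SNPs get codes 0/1/2.
    ``L`` is the region length regardless of variant count.
    """
    import pysam

    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)
    with pysam.VariantFile(str(path)) as vf:
        samples = [s for s in vf.header.samples if s in pop_map]
        absent = [s for s in vf.header.samples if s not in pop_map]
        if absent:
            logger.info("samples without population label skipped: %s", absent)
        if not samples:
            raise SampleMappingError("no VCF sample matches the population map")
        codes_cols, positions, alleles, excluded = [], [], [], []
        for rec in vf:
            pos0 = rec.pos - 1  # VCF is 1-based
            if rec.chrom != region.chrom or not (region.start <= pos0 < region.end):
                continue
            alts = [a for a in (rec.alts or ())]
            site_alleles = [rec.ref] + alts
            if any(len(a) != 1 for a in site_alleles):
                excluded.append(pos0)
                continue
            if len(site_alleles) > 3:
                excluded.append(pos0)
                continue
            # recode by lexicographic order of bases for consistency with FASTA
            order = sorted(range(len(site_alleles)), key=lambda k: site_alleles[k])
            recode = {old: new for new, old in enumerate(order)}
            col = []
            for s in samples:
                sample = rec.samples[s]
                gt = sample["GT"]
                phased = sample.phased
                if gt is None or len(gt) != 2:
                    col.extend([MISSING, MISSING])
                    continue
                if not phased and gt[0] != gt[1]:
                    if not allow_unphased:
                        raise RegionFormatError(
                            f"unphased heterozygote at {rec.chrom}:{rec.pos} "
                            f"sample {s}; pass allow_unphased=True to override")
                    warnings.warn(
                        f"treating unphased genotype at {rec.chrom}:{rec.pos} "
                        f"({s}) as phased", stacklevel=2)
                col.extend(MISSING if a is None else recode[a] for a in gt)
            codes_cols.append(col)
            positions.append(pos0)
            alleles.append("".join(site_alleles[k] for k in order))
        if excluded:
            logger.info("skipped %d non-SNP/multi-allelic records", len(excluded))

    populations, ids = [], []
    for s in samples:
        populations.extend([pop_map[s]] * 2)
        ids.extend([f"{s}_1", f"{s}_2"])
    matrix = (np.array(codes_cols, dtype=np.int8).T if codes_cols
              else np.zeros((2 * len(samples), 0), dtype=np.int8))
    # drop columns monomorphic within the mapped samples
    keep = _segregating_columns(matrix) if matrix.shape[1] else np.zeros(0, bool)
    return HaplotypeAlignment(
        region=region,
        haplotypes=matrix[:, keep],
        positions=np.array(positions, dtype=np.int64)[keep],
        populations=np.array(populations, dtype=object),
        sample_ids=ids,
        alleles=[alleles[j] for j in np.flatnonzero(keep)],
        excluded_positions=excluded,
    )


def attach_outgroup(aln: HaplotypeAlignment, outgroup: str) -> OutgroupAlignment:
    """Attach a pre-aligned single outgroup sequence and classify sites.

    ``outgroup`` must have length ``aln.L`` (same coordinates); gap/N
    characters mark unalignable sites. Polymorphic sites are polarized
    (ancestral = outgroup allele) when the outgroup base matches one
    segregating allele; otherwise they are flagged unpolarized.
    """
    outgroup = outgroup.upper()
    if len(outgroup) != aln.L:
        raise RegionFormatError(
            f"outgroup length {len(outgroup)} != surveyed length {aln.L}")
    if aln.full_sequences is not None:
        ingroup_seqs = [s.upper() for s in aln.full_sequences]
    else:
        ingroup_seqs = None

    local_pos = {int(p - aln.region.start): j for j, p in enumerate(aln.positions)}
    site_class = np.full(aln.L, SiteClass.MONOMORPHIC_SHARED, dtype=np.int8)
    out_alleles = np.array(list(outgroup), dtype=object)
    ancestral = np.full(aln.m, MISSING, dtype=np.int8)

    for j_local in range(aln.L):
        ob = outgroup[j_local]
        if ob in _MISSING_CHARS or ob in _GAP_CHARS:
            site_class[j_local] = SiteClass.UNALIGNABLE
            out_alleles[j_local] = ""
            continue
        col_idx = local_pos.get(j_local)
        if col_idx is not None:
            site_class[j_local] = SiteClass.POLYMORPHIC
            seg = aln.alleles[col_idx]
            if ob in seg:
                ancestral[col_idx] = seg.index(ob)
            continue
        if j_local + aln.region.start in aln.excluded_positions:
            site_class[j_local] = SiteClass.UNALIGNABLE
            continue
        if ingroup_seqs is not None:
            chars = {s[j_local] for s in ingroup_seqs} - _MISSING_CHARS
            if not chars:
                site_class[j_local] = SiteClass.UNALIGNABLE
                continue
            shared = ob in chars
        else:
            shared = ob == "A"  # synthetic background base
        if not shared:
            site_class[j_local] = SiteClass.FIXED_DIFFERENCE
    return OutgroupAlignment(
        alignment=aln,
        outgroup_allele=out_alleles,
        site_class=site_class,
        ancestral_code=ancestral,
    )
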