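"""Read-level editing primitives.

Everything here operates on coordinate-sorted indexed BAMs and identifies a
record by ``(read name, is_read1)``; fragment-level decisions use the name
alone so mates always share a fate. Allele evidence rules:

* SNV: the aligned base at the variant position (mismatch to both alleles,
  or a gap at the position, is "other").
* INS: an insertion operation of the alt length at the junction after the
  anchor base; spanning the junction gaplessly is reference evidence.
* DEL: a deletion operation covering exactly the deleted interval; aligned
  bases across the whole interval are reference evidence.
* Reads overlapping but not fully spanning the variant's reference footprint
  (e.g. clipped at the locus) are "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .core import (AlignmentSet, CnaEvent, GermlineVariant,
                   HeaderIncompatibilityError, InvalidParameterError,
                   TumormixError, fragment_fate, index_bam)

RecordKey = tuple[str, bool]  # (read name, is_read1)

_CONSUME_REF = {0, 2, 3, 7, 8}   # M, D, N, =, X
_CONSUME_QRY = {0, 1, 4, 7, 8}   # M, I, S, =, X
_ALIGN_OPS = {0, 7, 8}


def record_key(read: pysam.AlignedSegment) -> RecordKey:
    return (read.query_name, read.is_read1)


@dataclass
class LocusReadClasses:
    """Partition of the reads spanning one variant locus by allele."""

    variant: GermlineVariant
    alt_reads: set[RecordKey] = field(default_factory=set)
    ref_reads: set[RecordKey] = field(default_factory=set)
    other_reads: set[RecordKey] = field(default_factory=set)

    @property
    def depth(self) -> int:
        return len(self.alt_reads) + len(self.ref_reads) + len(self.other_reads)

    def names(self, which: str) -> set[str]:
        return {k[0] for k in getattr(self, which + "_reads")}


def allele_of_read(read: pysam.AlignedSegment, variant: GermlineVariant) -> Optional[str]:
    """Classify one read at one variant: 'alt', 'ref', 'other', or None when
    the alignment does not overlap the variant's reference footprint."""
    span_start, span_end = variant.span
    if read.reference_start >= span_end or read.reference_end <= span_start:
        return None
    if read.reference_start > span_start or read.reference_end < span_end:
        return "other"  # overlaps but does not span

    p0 = variant.pos - 1
    vt = variant.vtype
    ref_pos = read.reference_start
    qry_pos = 0
    cig = read.cigartuples or []

    if vt == "SNV":
        for op, ln in cig:
            if op in _ALIGN_OPS and ref_pos <= p0 < ref_pos + ln:
                base = read.query_sequence[qry_pos + (p0 - ref_pos)]
                if base == variant.alt:
                    return "alt"
                if base == variant.ref:
                    return "ref"
                return "other"
            if op == 2 and ref_pos <= p0 < ref_pos + ln:  # deleted here
                return "other"
            if op in _CONSUME_REF:
                ref_pos += ln
            if op in _CONSUME_QRY:
                qry_pos += ln
        return "other"

    if vt == "INS":
        k = len(variant.alt) - 1
        junction = p0 + 1
        for op, ln in cig:
            if op == 1 and ref_pos == junction:
                return "alt" if ln == k else "other"
            if op in _CONSUME_REF:
                ref_pos += ln
        # no insertion op at the junction; reference iff aligned through it
        return _spans_gapless(read, p0, p0 + 2)

    # DEL
    k = len(variant.ref) - 1
    del_start, del_end = p0 + 1, p0 + 1 + k
    for op, ln in cig:
        if op == 2 and ref_pos == del_start:
            return "alt" if ln == k else "other"
        if op in _CONSUME_REF:
            ref_pos += ln
    return _spans_gapless(read, p0, del_end)


def _spans_gapless(read: pysam.AlignedSegment, start: int, end: int) -> str:
    """'ref' when every reference base in [start, end) is covered by an
    aligned (M/=/X) op and no insertion sits strictly inside, else 'other'."""
    ref_pos = read.reference_start
    covered = 0
    for op, ln in (read.cigartuples or []):
        if op in _ALIGN_OPS:
            a = max(ref_pos, start)
            b = min(ref_pos + ln, end)
            if b > a:
                covered += b - a
        elif op == 1 and start < ref_pos < end:
            return "other"
        elif op in (2, 3):
            a = max(ref_pos, start)
            b = min(ref_pos + ln, end)
            if b > a:
                return "other"
        if op in _CONSUME_REF:
            ref_pos += ln
    return "ref" if covered == end - start else "other"


def classify_reads_at_locus(aln: AlignmentSet | pysam.AlignmentFile,
                            variant: GermlineVariant) -> LocusReadClasses:
    """Partition every read overlapping the variant footprint into
    alt / ref / other evidence classes."""
    close = False
    if isinstance(aln, AlignmentSet):
        aln = aln.open()
        close = True
    try:
        span_start, span_end = variant.span
        out = LocusReadClasses(variant=variant)
        for read in aln.fetch(variant.chrom, span_start, span_end):
            if read.is_unmapped:
                continue
            cls = allele_of_read(read, variant)
            if cls == "alt":
                out.alt_reads.add(record_key(read))
            elif cls == "ref":
                out.ref_reads.add(record_key(read))
            elif cls == "other":
                out.other_reads.add(record_key(read))
        return out
    finally:
        if close:
            aln.close()


# ---------------------------------------------------------------------------
# Genotype switching

@dataclass
class SwitchLocusReport:
    variant: GermlineVariant
    removed: int
    replaced: int
    skipped: bool


@dataclass
class SwitchReport:
    loci: list[SwitchLocusReport]

    @property
    def n_skipped(self) -> int:
        return sum(1 for l in self.loci if l.skipped)

    def to_tsv(self, path: Path | str) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tvtype\tremoved\treplaced\tskipped\n")
            for l in self.loci:
                v = l.variant
                fh.write(f"{v.chrom}\t{v.pos}\t{v.vtype}\t{l.removed}\t"
                         f"{l.replaced}\t{int(l.skipped)}\n")
        return path


def genotype_switch(aln: AlignmentSet, loci: Sequence[GermlineVariant],
                    seed: int, out_bam: Path | str
                    ) -> tuple[AlignmentSet, SwitchReport]:
    """Convert heterozygous loci to homozygous reference at the read level.

    At each locus every alt-carrying record is removed and replaced by a
    renamed copy of a ref-carrying record sampled (with replacement) at the
    same locus, so the spanning-read count is conserved exactly. Replacement
    candidates that carry the alternative allele at any other switched locus
    are avoided when possible. Loci whose ref class is empty are skipped and
    flagged rather than failing. Records not overlapping any locus are passed
    through untouched.
    """
    out_bam = Path(out_bam)
    loci = sorted(loci, key=lambda v: (v.chrom, v.pos))
    for v in loci:
        if v.genotype != "het":
            raise InvalidParameterError(
                f"genotype switch requires het loci; {v.chrom}:{v.pos} is {v.genotype}")
    rng = np.random.default_rng(seed)

    with aln.open() as fh:
        classes = [classify_reads_at_locus(fh, v) for v in loci]
    tainted_names = set()
    for c in classes:
        tainted_names |= c.names("alt")

    removal: set[RecordKey] = set()
    additions: dict[RecordKey, list[str]] = {}
    reports: list[SwitchLocusReport] = []
    counter = 0
    for v, c in zip(loci, classes):
        n_alt = len(c.alt_reads)
        if not c.ref_reads:
            reports.append(SwitchLocusReport(v, removed=0, replaced=0,
                                             skipped=n_alt > 0))
            continue
        clean = sorted(k for k in c.ref_reads if k[0] not in tainted_names)
        candidates = clean if clean else sorted(c.ref_reads)
        removal |= c.alt_reads
        for _ in range(n_alt):
            src = candidates[int(rng.integers(0, len(candidates)))]
            additions.setdefault(src, []).append(f"{src[0]}.sw{counter}")
            counter += 1
        reports.append(SwitchLocusReport(v, removed=n_alt, replaced=n_alt,
                                         skipped=False))

    with aln.open() as src, pysam.AlignmentFile(
            str(out_bam), "wb", template=src) as out:
        header = out.header
        for read in src:
            key = record_key(read)
            if key in removal:
                continue
            out.write(read)
            if key in additions:
                d = read.to_dict()
                for new_name in additions[key]:
                    d["name"] = new_name
                    out.write(pysam.AlignedSegment.from_dict(d, header))
    index_bam(out_bam)
    return AlignmentSet(out_bam), SwitchReport(reports)


# ---------------------------------------------------------------------------
# Subsampling

def keep_fragment(name: str, fraction: float, seed: int) -> bool:
    """Mate-consistent keep/drop decision for one fragment."""
    return fragment_fate(name, seed)[0] < fraction


def subsample(aln: AlignmentSet, fraction: float, seed: int,
              out_bam: Path | str) -> AlignmentSet:
    """Seeded name-hash subsampling: both mates of a fragment are kept or
    dropped together, each with probability ``fraction``."""
    if not 0 <= fraction <= 1:
        raise InvalidParameterError("fraction must be in [0, 1]")
    out_bam = Path(out_bam)
    with aln.open() as src, pysam.AlignmentFile(
            str(out_bam), "wb", template=src) as out:
        for read in src:
            if keep_fragment(read.query_name, fraction, seed):
                out.write(read)
    index_bam(out_bam)
    return AlignmentSet(out_bam)


# ---------------------------------------------------------------------------
# Allele-aware CNA read sets

def extract_allele_sets(aln: AlignmentSet, event: CnaEvent,
                        region_variants: Sequence[GermlineVariant],
                        seed: int) -> tuple[set[str], set[str]]:
    """Pick the fragments that realise one allele of a CNA region.

    ``alt_set``: fragments carrying the alternative allele at >= 1 het variant
    in the region (the phased-haplotype side). Fragments that are
    ref-informative somewhere (and never alt-informative) belong to the other
    haplotype and are excluded entirely. The remaining, allele-uninformative
    fragments are halved by a seeded name hash (``ref_half_set``), since an
    uninformative fragment comes from either haplotype with equal probability.
    Together the two sets represent a single allele: about half the region's
    fragments, carrying all of its alt alleles.
    """
    alt_names: set[str] = set()
    refinf_names: set[str] = set()
    with aln.open() as fh:
        for v in region_variants:
            if v.genotype != "het":
                continue
            c = classify_reads_at_locus(fh, v)
            alt_names |= c.names("alt")
            refinf_names |= c.names("ref")
        region_names = {r.query_name
                        for r in fh.fetch(event.chrom, event.start, event.end)}
    refinf_names -= alt_names
    uninformative = region_names - alt_names - refinf_names
    ref_half = {n for n in uninformative if fragment_fate(n, seed)[1] < 0.5}
    return alt_names & region_names, ref_half


def apply_duplication(aln: AlignmentSet, event: CnaEvent,
                      allele_sets: tuple[set[str], set[str]], seed: int,
                      out_bam: Path | str) -> AlignmentSet:
    """Append renamed copies of the one-allele read set inside the event
    region (region fragment count -> ~3/2 of the input); everything outside
    the region is written byte-identically."""
    if event.kind != "duplication":
        raise InvalidParameterError("event is not a duplication")
    dup_names = allele_sets[0] | allele_sets[1]
    out_bam = Path(out_bam)
    suffix = f".dup{event.chrom}_{event.start}"
    with aln.open() as src, pysam.AlignmentFile(
            str(out_bam), "wb", template=src) as out:
        header = out.header
        for read in src:
            out.write(read)
            if (read.query_name in dup_names
                    and read.reference_name == event.chrom
                    and read.reference_start < event.end
                    and (read.reference_end or read.reference_start) > event.start):
                # the copy keeps one fresh name per *fragment* so both mates
                # of a duplicated pair stay joined under the new name
                d = read.to_dict()
                d["name"] = read.query_name + suffix
                out.write(pysam.AlignedSegment.from_dict(d, header))
    index_bam(out_bam)
    return AlignmentSet(out_bam)


def apply_deletion(event: CnaEvent, allele_sets: tuple[set[str], set[str]],
                   removal_pool: set[str], mode: str = "single_copy",
                   aln: Optional[AlignmentSet] = None) -> set[str]:
    """Add the event's doomed fragment names to the shared removal pool.

    ``single_copy`` pools the one-allele set (region coverage -> 1/2 after
    removal); ``two_copy`` pools every fragment in the region (coverage -> 0)
    and needs the alignment handle to enumerate them. The pool is a plain
    name set, so overlapping events deduplicate naturally; final-product
    assembly drops every pooled name once.
    """
    if event.kind != "deletion":
        raise InvalidParameterError("event is not a deletion")
    if mode == "single_copy":
        removal_pool |= allele_sets[0] | allele_sets[1]
    elif mode == "two_copy":
        if aln is None:
            raise InvalidParameterError("two_copy mode requires the alignment")
        with aln.open() as fh:
            removal_pool |= {r.query_name
                             for r in fh.fetch(event.chrom, event.start, event.end)}
    else:
        raise InvalidParameterError(f"unknown deletion mode {mode!r}")
    return removal_pool


def write_removal_pool(pool: set[str], path: Path | str) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(pool):
            fh.write(name + "\n")
    return path


def drop_names(aln: AlignmentSet, names: set[str], out_bam: Path | str) -> AlignmentSet:
    """Remove every record whose fragment name is pooled for deletion."""
    out_bam = Path(out_bam)
    with aln.open() as src, pysam.AlignmentFile(
            str(out_bam), "wb", template=src) as out:
        for read in src:
            if read.query_name not in names:
                out.write(read)
    index_bam(out_bam)
    return AlignmentSet(out_bam)


# ---------------------------------------------------------------------------
# Merging

def merge_alignments(aln_list: Sequence[AlignmentSet],
                     out_bam: Path | str) -> AlignmentSet:
    """samtools-style merge of coordinate-sorted sets sharing one contig
    space; read groups are preserved."""
    if not aln_list:
        raise InvalidParameterError("nothing to merge")
    contigs = aln_list[0].contigs()
    for a in aln_list[1:]:
        if a.contigs() != contigs:
            raise HeaderIncompatibilityError(
                f"contig mismatch between {aln_list[0].path} and {a.path}")
    out_bam = Path(out_bam)
    pysam.merge("-f", "-c", "-p", str(out_bam), *[str(a.path) for a in aln_list])
    index_bam(out_bam)
    return AlignmentSet(out_bam)
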