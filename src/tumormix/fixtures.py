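"""Miniature synthetic normal-sample inputs: reference, germline truth, reads.

The simulator here only exists to provide testable inputs with known truth;
the editing pipeline itself never fabricates reads. Two explicit haplotypes
are materialised: homozygous variants sit on both, every heterozygous variant
is phased onto haplotype B. Fragments are drawn uniformly along a haplotype
(no GC or mappability bias) and sequencing error is a uniform per-base
substitution. Planted variants keep a minimum spacing of twice the read
length so that any read overlaps at most one variant, which makes per-locus
read classification exactly decidable.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .core import (AlignmentSet, CapacityError, GermlineVariant,
                   InvalidParameterError, VALID_BASES, index_bam)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ReferenceSequence:
    name: str
    seq: str

    def __post_init__(self):
        if len(self.seq) == 0:
            raise InvalidParameterError("reference must be non-empty")
        if not set(self.seq) <= VALID_BASES:
            raise InvalidParameterError("reference alphabet must be A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadSimParams:
    depth: float = 100.0
    read_len: int = 100
    frag_mean: float = 300.0
    frag_sd: float = 60.0
    err_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise InvalidParameterError("depth must be positive")
        if not self.read_len < self.frag_mean:
            raise InvalidParameterError("read_len must be smaller than frag_mean")
        if not 0 <= self.err_rate < 1:
            raise InvalidParameterError("err_rate must be in [0, 1)")


def make_reference(length_bp: int, gc_fraction: float, seed: int,
                   name: str = "chrS") -> ReferenceSequence:
    """Random reference with exact-count base composition.

    G+C bases number ``round(gc_fraction * length_bp)`` exactly (split as
    evenly as possible between G and C), then the whole sequence is shuffled,
    so the empirical GC content is within 1/length of the request at any size.
    """
    if length_bp <= 0:
        raise InvalidParameterError("length_bp must be positive")
    if not 0 < gc_fraction < 1:
        raise InvalidParameterError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_gc = round(gc_fraction * length_bp)
    n_at = length_bp - n_gc
    arr = np.concatenate([
        np.full(n_gc // 2, b"G", dtype="S1"),
        np.full(n_gc - n_gc // 2, b"C", dtype="S1"),
        np.full(n_at // 2, b"A", dtype="S1"),
        np.full(n_at - n_at // 2, b"T", dtype="S1"),
    ])
    rng.shuffle(arr)
    return ReferenceSequence(name=name, seq=arr.tobytes().decode())


def write_fasta(ref: ReferenceSequence, path: Path | str) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        fh.write(textwrap.fill(ref.seq, 60))
        fh.write("\n")
    pysam.faidx(str(path))
    return path


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def plant_germline_variants(ref: ReferenceSequence, n_snv: int, n_ins: int,
                            n_del: int, het_fraction: float, seed: int,
                            read_len: int = 100,
                            max_indel: int = 10) -> list[GermlineVariant]:
    """Plant SNVs and small InDels with guaranteed inter-variant spacing.

    Positions are drawn without replacement from a grid with step
    ``2 * read_len`` so any read (and the classification at any locus) sees at
    most one variant. Heterozygous counts are exact per variant class:
    ``round(het_fraction * n)``. InDel lengths are uniform on 1..max_indel.
    """
    if not 0 <= het_fraction <= 1:
        raise InvalidParameterError("het_fraction must be in [0, 1]")
    n_total = n_snv + n_ins + n_del
    if n_total == 0:
        return []
    spacing = 2 * read_len
    margin = 2 * read_len
    slots = np.arange(margin, ref.length - margin - max_indel - 1, spacing)
    if n_total > len(slots):
        raise CapacityError(
            f"cannot place {n_total} variants with {spacing} bp spacing in a "
            f"{ref.length} bp reference (capacity {len(slots)})")
    rng = np.random.default_rng(seed)
    positions = rng.choice(slots, size=n_total, replace=False)
    positions.sort()
    # interleave types randomly across positions, then genotypes per type
    types = np.array(["SNV"] * n_snv + ["INS"] * n_ins + ["DEL"] * n_del)
    rng.shuffle(types)
    variants: list[GermlineVariant] = []
    per_type_index: dict[str, int] = {"SNV": 0, "INS": 0, "DEL": 0}
    het_flags = {}
    for t, n in (("SNV", n_snv), ("INS", n_ins), ("DEL", n_del)):
        n_het = round(het_fraction * n)
        flags = np.array([True] * n_het + [False] * (n - n_het))
        rng.shuffle(flags)
        het_flags[t] = flags
    for pos0, t in zip(positions, types):
        pos0 = int(pos0)
        anchor = ref.seq[pos0]
        if t == "SNV":
            ref_a, alt_a = anchor, _other_base(rng, anchor)
        elif t == "INS":
            k = int(rng.integers(1, max_indel + 1))
            ins = "".join(_BASES[rng.integers(0, 4, size=k)].tobytes().decode())
            ref_a, alt_a = anchor, anchor + ins
        else:  # DEL
            k = int(rng.integers(1, max_indel + 1))
            ref_a, alt_a = ref.seq[pos0:pos0 + k + 1], anchor
        gt = "het" if het_flags[t][per_type_index[t]] else "hom"
        per_type_index[t] += 1
        variants.append(GermlineVariant(chrom=ref.name, pos=pos0 + 1,
                                        ref=ref_a, alt=alt_a, genotype=gt))
    return variants


# ---------------------------------------------------------------------------
# Truth VCF I/O

def _vcf_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.contigs.add(name, length=length)
    h.formats.add("GT", 1, "String", "Genotype")
    h.add_sample("SAMPLE")
    return h


def write_vcf(variants: list[GermlineVariant], contigs: dict[str, int],
              path: Path | str) -> Path:
    path = Path(path)
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref, v.alt))
            rec.samples["SAMPLE"]["GT"] = (0, 1) if v.genotype == "het" else (1, 1)
            rec.samples["SAMPLE"].phased = False
            out.write(rec)
    return path


def read_vcf(path: Path | str) -> list[GermlineVariant]:
    """Parse a germline VCF into variants.

    Multi-allelic and half-called genotypes are skipped: switching such a
    locus to homozygous reference is ill-defined.
    """
    out = []
    with pysam.VariantFile(str(path)) as vf:
        sample = list(vf.header.samples)[0] if list(vf.header.samples) else None
        for rec in vf:
            if len(rec.alts or ()) != 1:
                continue
            if sample is not None:
                gt = rec.samples[sample].get("GT")
                if gt is None or None in gt or len(gt) != 2:
                    continue
                alleles = set(gt)
                if alleles == {0, 1}:
                    genotype = "het"
                elif alleles == {1}:
                    genotype = "hom"
                else:
                    continue
            else:
                genotype = "het"
            out.append(GermlineVariant(chrom=rec.chrom, pos=rec.pos,
                                       ref=rec.ref, alt=rec.alts[0],
                                       genotype=genotype))
    return out


# ---------------------------------------------------------------------------
# Haplotype construction and read simulation

class _Haplotype:
    """One haplotype sequence plus the piecewise map back to the reference.

    The map is a list of alignment pieces in haplotype order. M pieces carry
    (hap_start, ref_start, length); insertion pieces carry hap-only bases.
    Deletions appear as gaps between consecutive M pieces' ref coordinates.
    """

    def __init__(self, ref: ReferenceSequence, variants: list[GermlineVariant]):
        seq_parts: list[str] = []
        pieces: list[tuple[int, int, int, bool]] = []  # (hap_start, len, ref_start, is_ins)
        hap_pos = 0
        ref_pos = 0
        m_start_hap = 0
        m_start_ref = 0

        def close_m(end_ref: int):
            nonlocal hap_pos, m_start_hap, m_start_ref
            length = end_ref - m_start_ref
            if length > 0:
                pieces.append((m_start_hap, length, m_start_ref, False))

        for v in sorted(variants, key=lambda x: x.pos):
            p0 = v.pos - 1
            if v.vtype == "SNV":
                continue  # substitutions handled on the sequence array below
            # copy reference up to and including the anchor base
            seg = ref.seq[ref_pos:p0 + 1]
            seq_parts.append(seg)
            hap_pos += len(seg)
            ref_pos = p0 + 1
            if v.vtype == "INS":
                close_m(ref_pos)
                ins = v.alt[1:]
                pieces.append((hap_pos, len(ins), -1, True))
                seq_parts.append(ins)
                hap_pos += len(ins)
                m_start_hap, m_start_ref = hap_pos, ref_pos
            else:  # DEL: skip deleted reference bases
                close_m(ref_pos)
                ref_pos += len(v.ref) - 1
                m_start_hap, m_start_ref = hap_pos, ref_pos
        seq_parts.append(ref.seq[ref_pos:])
        hap_pos += len(ref.seq) - ref_pos
        close_m(ref.length)

        arr = np.frombuffer("".join(seq_parts).encode(), dtype="S1").copy()
        # apply substitutions (SNVs): map ref coordinate -> hap coordinate
        for v in variants:
            if v.vtype != "SNV":
                continue
            h = self._static_ref_to_hap(pieces, v.pos - 1)
            arr[h] = v.alt.encode()
        self.seq = arr
        self.length = len(arr)
        self.pieces = pieces
        self.piece_hap_starts = np.array([p[0] for p in pieces], dtype=np.int64)
        self.piece_lens = np.array([p[1] for p in pieces], dtype=np.int64)
        self.piece_ref_starts = np.array([p[2] for p in pieces], dtype=np.int64)
        self.piece_is_ins = np.array([p[3] for p in pieces], dtype=bool)
        # reference start an alignment would get if the read begins inside
        # each piece: for M pieces ref_start - hap_start offset; for insertion
        # pieces the ref start of the following M piece.
        offs = np.empty(len(pieces), dtype=np.int64)
        ins_ref = np.zeros(len(pieces), dtype=np.int64)
        for i, (hs, ln, rs, is_ins) in enumerate(pieces):
            if is_ins:
                offs[i] = 0
                ins_ref[i] = pieces[i + 1][2] if i + 1 < len(pieces) else -1
            else:
                offs[i] = rs - hs
        self._offsets = offs
        self._ins_ref = ins_ref

    @staticmethod
    def _static_ref_to_hap(pieces, ref0: int) -> int:
        for hs, ln, rs, is_ins in pieces:
            if not is_ins and rs <= ref0 < rs + ln:
                return hs + (ref0 - rs)
        raise ValueError(f"reference position {ref0} not on haplotype")

    def ref_starts(self, hap_starts: np.ndarray) -> np.ndarray:
        """Vectorised: reference alignment start for reads beginning at the
        given haplotype coordinates."""
        idx = np.searchsorted(self.piece_hap_starts, hap_starts, side="right") - 1
        base = hap_starts + self._offsets[idx]
        return np.where(self.piece_is_ins[idx], self._ins_ref[idx], base)

    def read_alignment(self, h: int, rl: int) -> tuple[int, list[tuple[int, int]]]:
        """CIGAR and reference start for a read of length ``rl`` at haplotype
        coordinate ``h``. Terminal partial insertions become soft clips."""
        end = h + rl
        idx = int(np.searchsorted(self.piece_hap_starts, h, side="right")) - 1
        cig: list[tuple[int, int]] = []  # (op, len): 0=M, 1=I, 2=D, 4=S
        ref_start = -1
        last_ref_end = -1
        i = idx
        while i < len(self.pieces):
            hs, ln, rs, is_ins = self.pieces[i]
            if hs >= end:
                break
            a = max(h, hs)
            b = min(end, hs + ln)
            ov = b - a
            if ov <= 0:
                i += 1
                continue
            if is_ins:
                if ref_start < 0:
                    cig.append((4, ov))          # leading soft clip
                elif b == end and b < hs + ln:
                    cig.append((4, ov))          # read ends inside insertion
                elif b == end:
                    cig.append((4, ov))          # insertion is last op
                else:
                    cig.append((1, ov))
            else:
                piece_ref_a = rs + (a - hs)
                if ref_start < 0:
                    ref_start = piece_ref_a
                elif piece_ref_a > last_ref_end:
                    cig.append((2, piece_ref_a - last_ref_end))  # deletion
                if cig and cig[-1][0] == 0:
                    cig[-1] = (0, cig[-1][1] + ov)
                else:
                    cig.append((0, ov))
                last_ref_end = piece_ref_a + ov
            i += 1
        # merge trailing soft clips (possible S,S when read ends inside ins)
        merged: list[tuple[int, int]] = []
        for op, ln in cig:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + ln)
            else:
                merged.append((op, ln))
        return ref_start, merged


def simulate_reads(ref: ReferenceSequence, variants: list[GermlineVariant],
                   params: ReadSimParams, out_bam: Path | str,
                   sample: str = "normal") -> AlignmentSet:
    """Simulate paired reads from the two haplotypes and write a sorted,
    indexed BAM.

    Each fragment picks a haplotype with probability 1/2 (so heterozygous
    sites are covered by the two alleles at 1/2 each), a length from a clipped
    normal, and a uniform start. Reads get exact CIGARs against the reference
    including the planted InDels; uniform substitution errors are applied to
    the final sequences and never touch the CIGAR. Every fragment name is
    unique and both mates are emitted. Haplotype of origin is recorded in the
    ``XH`` tag (A/B) for truth-oracle use.
    """
    out_bam = Path(out_bam)
    rl = params.read_len
    hap_a = _Haplotype(ref, [v for v in variants if v.genotype == "hom"])
    hap_b = _Haplotype(ref, list(variants))
    haps = (hap_a, hap_b)

    rng = np.random.default_rng(params.seed)
    n_frags = int(round(ref.length * params.depth / (2 * rl)))
    frag_len = rng.normal(params.frag_mean, params.frag_sd, size=n_frags)
    frag_len = np.clip(np.rint(frag_len), rl, None).astype(np.int64)
    which_hap = rng.integers(0, 2, size=n_frags)
    hap_lens = np.array([hap_a.length, hap_b.length])
    frag_len = np.minimum(frag_len, hap_lens[which_hap])
    starts = (rng.random(n_frags) * (hap_lens[which_hap] - frag_len + 1)).astype(np.int64)

    # per-read haplotype start and reference start (reads 2i and 2i+1)
    h1 = starts
    h2 = starts + frag_len - rl
    ref_start = np.empty(2 * n_frags, dtype=np.int64)
    for hap_idx in (0, 1):
        m = which_hap == hap_idx
        ref_start[0::2][m] = haps[hap_idx].ref_starts(h1[m])
        ref_start[1::2][m] = haps[hap_idx].ref_starts(h2[m])

    n_err = rng.binomial(rl, params.err_rate, size=2 * n_frags)
    order = np.argsort(ref_start, kind="stable")

    # fast path: reads whose window lies inside a single M piece need no
    # CIGAR walk (the overwhelming majority; indel pieces are sparse)
    pure_m = np.empty(2 * n_frags, dtype=bool)
    for hap_idx in (0, 1):
        m = which_hap == hap_idx
        hp = haps[hap_idx]
        for half, hh in ((0, h1), (1, h2)):
            i0 = np.searchsorted(hp.piece_hap_starts, hh[m], side="right") - 1
            i1 = np.searchsorted(hp.piece_hap_starts, hh[m] + rl - 1, side="right") - 1
            pure_m[half::2][m] = (i0 == i1) & ~hp.piece_is_ins[i0]
    full_match = [(0, rl)]

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.name, "LN": ref.length}],
        "RG": [{"ID": sample, "SM": sample}],
    }
    qual = pysam.qualitystring_to_array("I" * rl)
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as out:
        for ridx in order:
            fidx = ridx // 2
            is_r1 = (ridx % 2) == 0
            hap = haps[which_hap[fidx]]
            h = int(h1[fidx] if is_r1 else h2[fidx])
            if pure_m[ridx]:
                rstart, cig = int(ref_start[ridx]), full_match
            else:
                rstart, cig = hap.read_alignment(h, rl)
            seq = hap.seq[h:h + rl].tobytes().decode()
            ne = int(n_err[ridx])
            if ne:
                sarr = list(seq)
                for p in rng.integers(0, rl, size=ne):
                    sarr[p] = _other_base(rng, sarr[p])
                seq = "".join(sarr)
            a = pysam.AlignedSegment()
            a.query_name = f"f{fidx:08d}"
            a.query_sequence = seq
            a.flag = 99 if is_r1 else 147
            a.reference_id = 0
            a.reference_start = int(rstart)
            a.mapping_quality = 60
            a.cigartuples = cig
            a.next_reference_id = 0
            mate = int(ref_start[2 * fidx + (1 if is_r1 else 0)])
            a.next_reference_start = mate
            tl = int(frag_len[fidx])
            a.template_length = tl if is_r1 else -tl
            a.query_qualities = qual
            a.set_tag("RG", sample)
            a.set_tag("XH", "B" if which_hap[fidx] else "A")
            out.write(a)
    index_bam(out_bam)
    return AlignmentSet(out_bam)
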