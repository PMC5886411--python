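"""Independent oracles used by the tests.

The pileup oracle classifies reads through pysam's ``get_aligned_pairs``
rather than the package's own CIGAR walk, so agreement is a genuine
cross-check of two implementations.
"""

from tumormix import AlignmentSet, GermlineVariant


def oracle_counts(aln: AlignmentSet, v: GermlineVariant):
    """(alt, ref, other) counts at a variant via aligned-pairs inspection."""
    span_start, span_end = v.span
    p0 = v.pos - 1
    alt = ref = other = 0
    with aln.open() as fh:
        for read in fh.fetch(v.chrom, span_start, span_end):
            if read.reference_start > span_start or read.reference_end < span_end:
                other += 1
                continue
            pairs = read.get_aligned_pairs()
            if v.vtype == "SNV":
                hit = [q for q, r in pairs if r == p0]
                if not hit or hit[0] is None:
                    other += 1
                elif read.query_sequence[hit[0]] == v.alt:
                    alt += 1
                elif read.query_sequence[hit[0]] == v.ref:
                    ref += 1
                else:
                    other += 1
            elif v.vtype == "INS":
                k = len(v.alt) - 1
                # inserted bases appear as (qpos, None) between ref p0 and p0+1
                seen_anchor = False
                n_ins = 0
                aligned_next = False
                for q, r in pairs:
                    if r == p0 and q is not None:
                        seen_anchor = True
                    elif seen_anchor and r is None and q is not None:
                        n_ins += 1
                    elif seen_anchor and r == p0 + 1:
                        aligned_next = q is not None
                        break
                if not seen_anchor or not aligned_next:
                    other += 1
                elif n_ins == k:
                    alt += 1
                elif n_ins == 0:
                    ref += 1
                else:
                    other += 1
            else:  # DEL
                k = len(v.ref) - 1
                dele = [q for q, r in pairs
                        if r is not None and p0 + 1 <= r < p0 + 1 + k]
                gapped = sum(1 for q in dele if q is None)
                if len(dele) != k:
                    other += 1
                elif gapped == k:
                    alt += 1
                elif gapped == 0:
                    ref += 1
                else:
                    other += 1
    return alt, ref, other
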