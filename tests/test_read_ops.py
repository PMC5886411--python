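"""Read-level editing primitives: classification, switching, subsampling,
allele-aware CNA read sets, merging."""

import collections

import numpy as np
import pysam
import pytest
from scipy import stats

from tumormix import (AlignmentSet, CnaEvent, GermlineVariant,
                      HeaderIncompatibilityError, InvalidParameterError,
                      genotype_switch, merge_alignments, subsample)
from tumormix.read_ops import (classify_reads_at_locus, extract_allele_sets,
                               apply_deletion, apply_duplication, drop_names,
                               keep_fragment)
from helpers import oracle_counts


def _xh_tags(aln, variant):
    tags = {}
    with aln.open() as fh:
        for r in fh.fetch(variant.chrom, *variant.span):
            tags[(r.query_name, r.is_read1)] = r.get_tag("XH")
    return tags


class TestClassification:
    def test_error_free_partition_no_other_snv(self, clean_sample):
        for v in clean_sample["het"]:
            if v.vtype != "SNV":
                continue
            c = classify_reads_at_locus(clean_sample["aln"], v)
            assert len(c.other_reads) == 0
            assert c.depth == len(c.alt_reads) + len(c.ref_reads)
            assert not (c.alt_reads & c.ref_reads)

    def test_haplotype_truth_oracle(self, clean_sample):
        """Alt reads are exactly the haplotype-B reads; ref reads hap-A."""
        for v in clean_sample["het"][:40]:
            c = classify_reads_at_locus(clean_sample["aln"], v)
            tags = _xh_tags(clean_sample["aln"], v)
            assert all(tags[k] == "B" for k in c.alt_reads)
            assert all(tags[k] == "A" for k in c.ref_reads)

    def test_hom_variant_all_alt(self, clean_sample):
        for v in clean_sample["variants"]:
            if v.genotype == "hom" and v.vtype == "SNV":
                c = classify_reads_at_locus(clean_sample["aln"], v)
                assert len(c.ref_reads) == 0 and len(c.alt_reads) > 0
                break

    def test_agrees_with_aligned_pairs_oracle(self, clean_sample):
        for v in clean_sample["variants"][::7]:
            c = classify_reads_at_locus(clean_sample["aln"], v)
            assert (len(c.alt_reads), len(c.ref_reads),
                    len(c.other_reads)) == oracle_counts(clean_sample["aln"], v)


@pytest.fixture(scope="module")
def switched(clean_sample, tmp_path_factory):
    d = tmp_path_factory.mktemp("switch")
    loci = clean_sample["het"][:60]
    out, report = genotype_switch(clean_sample["aln"], loci, 11,
                                  d / "switched.bam")
    return {"loci": loci, "aln": out, "report": report}


class TestGenotypeSwitch:
    def test_zero_residual_and_depth_conservation(self, clean_sample, switched):
        for v in switched["loci"]:
            before = classify_reads_at_locus(clean_sample["aln"], v)
            after = classify_reads_at_locus(switched["aln"], v)
            assert len(after.alt_reads) == 0
            assert after.depth == before.depth

    def test_pileup_oracle_hom_ref(self, switched):
        for v in switched["loci"]:
            alt, ref, other = oracle_counts(switched["aln"], v)
            assert alt == 0 and ref > 0

    def test_untouched_records_identical(self, clean_sample, switched):
        """Records not overlapping any switched locus pass through bytewise."""
        spans = [(v.span[0] - 1, v.span[1] + 1) for v in switched["loci"]]

        def untouched(read):
            return all(read.reference_end <= s or read.reference_start >= e
                       for s, e in spans)

        with clean_sample["aln"].open() as fa, switched["aln"].open() as fb:
            before = {r.to_string() for r in fa if untouched(r)}
            after = {r.to_string() for r in fb if untouched(r)}
        assert before == after

    def test_report_accounting(self, clean_sample, switched):
        rep = switched["report"]
        assert len(rep.loci) == len(switched["loci"])
        for line in rep.loci:
            assert line.removed == line.replaced
            assert not line.skipped

    def test_all_alt_locus_skipped(self, clean_sample, outdir):
        """A locus whose reads all look alt (ref class empty) is skipped and
        flagged, not fatal."""
        ref = clean_sample["ref"]
        p = 30_001
        while any(abs(p - v.pos) < 150 for v in clean_sample["variants"]):
            p += 10
        actual = ref.seq[p - 1]
        fake_ref = "A" if actual != "A" else "C"
        fake = GermlineVariant(chrom=ref.name, pos=p, ref=fake_ref,
                               alt=actual, genotype="het")
        out, report = genotype_switch(clean_sample["aln"], [fake], 1,
                                      outdir / "skip.bam")
        assert report.n_skipped == 1
        before = classify_reads_at_locus(clean_sample["aln"], fake)
        after = classify_reads_at_locus(out, fake)
        assert len(after.alt_reads) == len(before.alt_reads) > 0

    def test_non_het_locus_rejected(self, clean_sample, outdir):
        hom = next(v for v in clean_sample["variants"] if v.genotype == "hom")
        with pytest.raises(InvalidParameterError):
            genotype_switch(clean_sample["aln"], [hom], 1, outdir / "x.bam")


class TestSubsample:
    def test_identity_and_empty(self, clean_sample, outdir):
        full = subsample(clean_sample["aln"], 1.0, 3, outdir / "full.bam")
        assert full.n_records() == clean_sample["aln"].n_records()
        empty = subsample(clean_sample["aln"], 0.0, 3, outdir / "empty.bam")
        assert empty.n_records() == 0

    def test_half_within_binomial_bounds(self, clean_sample, outdir):
        half = subsample(clean_sample["aln"], 0.5, 9, outdir / "half.bam")
        n = clean_sample["aln"].n_records() // 2  # fragments
        kept = half.n_records() // 2
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.5)
        assert lo <= kept <= hi

    def test_mate_consistency(self, clean_sample, outdir):
        half = subsample(clean_sample["aln"], 0.3, 5, outdir / "third.bam")
        counts = collections.Counter()
        with half.open() as fh:
            for r in fh:
                counts[r.query_name] += 1
        assert set(counts.values()) == {2}

    def test_unbiased_over_seeds(self, clean_sample):
        """Mean kept fraction over 20 seeds within 3 sigma of p."""
        with clean_sample["aln"].open() as fh:
            names = list({r.query_name for r in fh})
        p = 0.35
        fracs = [np.mean([keep_fragment(n, p, s) for n in names])
                 for s in range(20)]
        sigma = np.sqrt(p * (1 - p) / len(names)) / np.sqrt(20)
        assert abs(np.mean(fracs) - p) <= 3 * sigma

    def test_invalid_fraction(self, clean_sample, outdir):
        with pytest.raises(InvalidParameterError):
            subsample(clean_sample["aln"], 1.5, 1, outdir / "x.bam")


class TestAlleleSets:
    def test_no_variant_region(self, cna_sample, outdir):
        ev = CnaEvent(chrom=cna_sample["ref"].name, start=270_000, end=295_000,
                      kind="duplication", clone="c1")
        alt, half = extract_allele_sets(cna_sample["aln"], ev, [], seed=2)
        assert alt == set()
        with cna_sample["aln"].open() as fh:
            n = len({r.query_name for r in fh.fetch(ev.chrom, ev.start, ev.end)})
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.5)
        assert lo <= len(half) <= hi

    def test_haplotype_truth_and_disjoint(self, cna_sample):
        ev = cna_sample["dup"]
        reg = [v for v in cna_sample["variants"]
               if ev.start <= v.pos - 1 < ev.end]
        alt, half = extract_allele_sets(cna_sample["aln"], ev, reg, seed=21)
        assert not (alt & half)
        # alt set == hap-B fragments informative at >= 1 het site
        expect = set()
        with cna_sample["aln"].open() as fh:
            for v in reg:
                if v.genotype != "het":
                    continue
                c = classify_reads_at_locus(fh, v)
                tags = _xh_tags(cna_sample["aln"], v)
                expect |= {k[0] for k in c.alt_reads if tags[k] == "B"}
        assert alt == expect


def _region_fragments(aln, chrom, start, end):
    with aln.open() as fh:
        return {r.query_name for r in fh.fetch(chrom, start, end)}


class TestCnaApplication:
    def test_duplication_closed_form(self, cna_sample, outdir):
        ev = cna_sample["dup"]
        reg = [v for v in cna_sample["variants"]
               if ev.start <= v.pos - 1 < ev.end]
        sets = extract_allele_sets(cna_sample["aln"], ev, reg, seed=21)
        dup = apply_duplication(cna_sample["aln"], ev, sets, 5,
                                outdir / "dup.bam")
        before = _region_fragments(cna_sample["aln"], ev.chrom, ev.start, ev.end)
        after = _region_fragments(dup, ev.chrom, ev.start, ev.end)
        assert 1.45 <= len(after) / len(before) <= 1.55
        # BAF at het sites inside the event shifts toward 2/3
        from tumormix import compute_baf, pileup_counts
        counts = pileup_counts(dup, [v for v in reg if v.genotype == "het"
                                     and v.vtype == "SNV"])
        bafs = [compute_baf(c) for c in counts]
        assert abs(np.mean(bafs) - 2 / 3) < 0.02
        # outside the region: byte identical record sets
        def outside(aln):
            with aln.open() as fh:
                return [r.to_string() for r in fh.fetch(ev.chrom, 270_000, 299_000)]
        assert outside(dup) == outside(cna_sample["aln"])

    def test_deletion_closed_forms(self, cna_sample, outdir):
        ev = cna_sample["del"]
        reg = [v for v in cna_sample["variants"]
               if ev.start <= v.pos - 1 < ev.end]
        sets = extract_allele_sets(cna_sample["aln"], ev, reg, seed=22)
        pool = apply_deletion(ev, sets, set())
        out = drop_names(cna_sample["aln"], pool, outdir / "del1.bam")
        before = _region_fragments(cna_sample["aln"], ev.chrom, ev.start, ev.end)
        after = _region_fragments(out, ev.chrom, ev.start, ev.end)
        assert 0.45 <= len(after) / len(before) <= 0.55
        # two-copy mode removes everything strictly inside
        pool2 = apply_deletion(ev, sets, set(), mode="two_copy",
                               aln=cna_sample["aln"])
        out2 = drop_names(cna_sample["aln"], pool2, outdir / "del2.bam")
        inner = _region_fragments(out2, ev.chrom, ev.start + 400, ev.end - 400)
        assert len(inner) == 0

    def test_overlapping_deletions_deduplicate(self, cna_sample):
        ev = cna_sample["del"]
        reg = [v for v in cna_sample["variants"]
               if ev.start <= v.pos - 1 < ev.end]
        sets = extract_allele_sets(cna_sample["aln"], ev, reg, seed=22)
        pool = apply_deletion(ev, sets, set())
        size_once = len(pool)
        pool = apply_deletion(ev, sets, pool)
        assert len(pool) == size_once


class TestMerge:
    def test_additivity_and_sortedness(self, clean_sample, outdir):
        a = subsample(clean_sample["aln"], 0.3, 1, outdir / "a.bam")
        b = subsample(clean_sample["aln"], 0.2, 2, outdir / "b.bam")
        merged = merge_alignments([a, b], outdir / "m.bam")
        assert merged.n_records() == a.n_records() + b.n_records()
        with merged.open() as fh:
            last = -1
            for r in fh:
                assert r.reference_start >= last
                last = r.reference_start

    def test_identity(self, clean_sample, outdir):
        m = merge_alignments([clean_sample["aln"]], outdir / "one.bam")
        assert m.n_records() == clean_sample["aln"].n_records()

    def test_contig_mismatch_rejected(self, clean_sample, outdir):
        other_ref = pytest.importorskip("tumormix").make_reference(5000, 0.5, 1,
                                                                   name="chrX")
        from tumormix import plant_germline_variants, simulate_reads
        from tumormix.fixtures import ReadSimParams
        aln2 = simulate_reads(other_ref, [], ReadSimParams(depth=5, seed=1),
                              outdir / "other.bam")
        with pytest.raises(HeaderIncompatibilityError):
            merge_alignments([clean_sample["aln"], aln2], outdir / "bad.bam")
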