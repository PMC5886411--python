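"""Validation statistics: pileup BAF, expected-vs-observed AF concordance,
read-count log2 ratios, coverage-ratio distributions, and caller scoring.

BAF is the fraction of reads at a variant position carrying the alternative
(B) allele; gap-aware evidence rules are shared with the read-editing
primitives so observed and truth counts are commensurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clone_factory import CoverageSummary
from .core import (AlignmentSet, GermlineVariant, InvalidLocusError,
                   InvalidParameterError, UndefinedCorrelationError)
from .read_ops import classify_reads_at_locus


@dataclass(frozen=True)
class PileupCounts:
    variant: GermlineVariant
    ref_count: int
    alt_count: int
    other_count: int

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_count


def pileup_counts(aln: AlignmentSet,
                  loci: Sequence[GermlineVariant]) -> list[PileupCounts]:
    """Per-locus allele counts using the same evidence rules as read
    classification (a native replacement for an mpileup+postprocess chain)."""
    contigs = aln.contigs()
    out = []
    with aln.open() as fh:
        for v in loci:
            if v.chrom not in contigs or not 1 <= v.pos <= contigs[v.chrom]:
                raise InvalidLocusError(f"locus {v.chrom}:{v.pos} outside contigs")
            c = classify_reads_at_locus(fh, v)
            out.append(PileupCounts(variant=v, ref_count=len(c.ref_reads),
                                    alt_count=len(c.alt_reads),
                                    other_count=len(c.other_reads)))
    return out


def compute_baf(counts: PileupCounts) -> Optional[float]:
    """Alt reads over total reads at the position; None (excluded, to be
    flagged by the caller) when nothing covers the locus."""
    if counts.depth == 0:
        return None
    return counts.alt_count / counts.depth


def expected_af(carrier_sets: dict[tuple, Iterable[str]],
                fractions: dict[str, float]) -> dict[tuple, float]:
    """Model-based expected allele fraction: 0.5 x summed carrier fractions
    (0 for rows carried by nothing, 0.5 when every clone carries)."""
    out = {}
    for key, carriers_ in carrier_sets.items():
        af = 0.0
        for c in carriers_:
            if c not in fractions:
                raise InvalidParameterError(f"unknown clone {c!r} in carriers")
            af += fractions[c]
        out[key] = 0.5 * af
    return out


@dataclass
class ConcordanceReport:
    pearson_r: float
    frac_within_0p1: float
    n_loci: int
    per_type: dict[str, "ConcordanceReport"] = field(default_factory=dict)
    bin_table: Optional[pd.DataFrame] = None


def af_concordance(expected: Sequence[float], observed: Sequence[float],
                   vtypes: Optional[Sequence[str]] = None,
                   bins: Optional[Sequence[float]] = None) -> ConcordanceReport:
    """Pearson correlation between expected and observed AF plus the fraction
    of loci deviating by less than 0.1, optionally split by variant class and
    binned by expected AF for violin-style summaries."""
    exp = np.asarray(expected, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if exp.shape != obs.shape:
        raise InvalidParameterError("expected/observed length mismatch")
    if len(exp) < 3:
        raise UndefinedCorrelationError("need at least 3 paired loci")
    if np.ptp(exp) == 0 or np.ptp(obs) == 0:
        raise UndefinedCorrelationError("zero variance in one series")
    r = float(stats.pearsonr(exp, obs).statistic)
    frac = float(np.mean(np.abs(obs - exp) < 0.1))
    report = ConcordanceReport(pearson_r=r, frac_within_0p1=frac, n_loci=len(exp))
    if vtypes is not None:
        vt = np.asarray(vtypes)
        for t in sorted(set(vt)):
            m = vt == t
            if m.sum() >= 3 and np.ptp(exp[m]) > 0 and np.ptp(obs[m]) > 0:
                report.per_type[t] = af_concordance(exp[m], obs[m])
    if bins is not None:
        idx = np.digitize(exp, bins)
        rows = []
        for b in sorted(set(idx)):
            m = idx == b
            rows.append((b, int(m.sum()), float(exp[m].mean()),
                         float(obs[m].mean()), float(obs[m].std())))
        report.bin_table = pd.DataFrame(
            rows, columns=["bin", "n", "mean_expected", "mean_observed",
                           "sd_observed"])
    return report


def rc_log2_ratio(tumor_aln: AlignmentSet, normal_aln: AlignmentSet,
                  intervals: Sequence[tuple[str, int, int]]) -> pd.DataFrame:
    """Normalized read-count log2 ratio per interval.

    RC = distinct fragments overlapping the interval, normalized by the
    sample's total mapped fragments; the tumor/normal ratio is log2
    transformed. Intervals with zero normal RC are flagged NaN.
    """
    if not intervals:
        raise InvalidParameterError("need at least one interval")

    def frag_counts(aln):
        with aln.open() as fh:
            total = max(fh.mapped, 1) / 2.0
            per = []
            for chrom, start, end in intervals:
                per.append(len({r.query_name for r in fh.fetch(chrom, start, end)}))
        return per, total

    t_counts, t_total = frag_counts(tumor_aln)
    n_counts, n_total = frag_counts(normal_aln)
    rows = []
    for (chrom, start, end), tc, nc in zip(intervals, t_counts, n_counts):
        if nc == 0:
            rows.append((chrom, start, end, tc, nc, float("nan"), True))
            continue
        ratio = (tc / t_total) / (nc / n_total)
        rows.append((chrom, start, end, tc, nc,
                     math.log2(ratio) if ratio > 0 else float("-inf"), False))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tumor_rc",
                                       "normal_rc", "log2_ratio", "undefined"])


def coverage_ratio_stats(sub_cov: CoverageSummary, full_cov: CoverageSummary
                         ) -> dict:
    """Per-window subsample/full coverage ratios with mean and variance;
    windows with zero full coverage are excluded and counted."""
    sub = sub_cov.windows.set_index(["chrom", "start", "end"])["mean_depth"]
    full = full_cov.windows.set_index(["chrom", "start", "end"])["mean_depth"]
    if not sub.index.equals(full.index):
        raise InvalidParameterError("coverage summaries use different windows")
    ok = full > 0
    ratios = (sub[ok] / full[ok]).to_numpy()
    return {
        "ratios": ratios,
        "mean": float(ratios.mean()) if len(ratios) else float("nan"),
        "variance": float(ratios.var(ddof=1)) if len(ratios) > 1 else float("nan"),
        "n_windows": int(ok.sum()),
        "n_excluded": int((~ok).sum()),
    }


# ---------------------------------------------------------------------------
# Caller scoring

def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> tuple:
    """Left-align a biallelic variant: trim shared trailing then leading
    bases (advancing pos), keeping at least one base per allele."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def _norm_set(calls: Iterable) -> set[tuple]:
    out = set()
    for c in calls:
        if isinstance(c, GermlineVariant):
            out.add(normalize_variant(c.chrom, c.pos, c.ref, c.alt))
        else:
            out.add(normalize_variant(*c))
    return out


@dataclass
class CallScore:
    true_positives: int
    called_total: int
    truth_total: int

    @property
    def precision(self) -> Optional[float]:
        """TP / called; not applicable (None) for an empty call set, which is
        deliberately not rewarded with a precision of 1."""
        if self.called_total == 0:
            return None
        return self.true_positives / self.called_total

    @property
    def recall(self) -> float:
        if self.truth_total == 0:
            return 0.0
        return self.true_positives / self.truth_total

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        if p is None or p + r == 0:
            return 0.0
        return 2 * p * r / (p + r)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    denom = max(a[1] - a[0], b[1] - b[0])
    return inter / denom if denom else 0.0


def score_calls(called: Iterable, truth: Iterable, kind: str = "small",
                min_reciprocal_overlap: float = 0.5) -> CallScore:
    """Precision/recall/F against a truth set.

    Small variants match on identical normalized (chrom, pos, ref, alt); CNA
    calls (tuples of chrom, start, end, kind) match on same kind and
    reciprocal overlap >= the threshold, each truth event claimed once.
    """
    if kind == "small":
        c = _norm_set(called)
        t = _norm_set(truth)
        tp = len(c & t)
        return CallScore(true_positives=tp, called_total=len(c), truth_total=len(t))
    if kind != "cna":
        raise InvalidParameterError(f"unknown call kind {kind!r}")
    called = list(called)
    truth = list(truth)
    unclaimed = set(range(len(truth)))
    tp = 0
    for chrom, start, end, k in called:
        best, best_ov = None, min_reciprocal_overlap
        for i in unclaimed:
            tch, ts, te, tk = truth[i]
            if tch != chrom or tk != k:
                continue
            ov = min(reciprocal_overlap((start, end), (ts, te)),
                     reciprocal_overlap((ts, te), (start, end)))
            if ov >= best_ov:
                best, best_ov = i, ov
        if best is not None:
            unclaimed.discard(best)
            tp += 1
    return CallScore(true_positives=tp, called_total=len(called),
                     truth_total=len(truth))


def combine_callsets(callsets: Sequence[Iterable], mode: str) -> set[tuple]:
    """Union (present in >= 1 set) or intersection (present in all) of
    normalized call sets."""
    if len(callsets) < 2:
        raise InvalidParameterError("need at least two callsets")
    sets = [_norm_set(c) for c in callsets]
    if mode == "union":
        return set().union(*sets)
    if mode == "intersection":
        return set.intersection(*sets)
    raise InvalidParameterError(f"unknown mode {mode!r}")
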