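"""Mixing pipeline: plan validation, clone subsampling, CNA application,
merging, and truth emission.

Fragments are partitioned disjointly across clones by a seeded hash of the
read name, with bucket widths proportional to the mixture fractions; each
bucket is then thinned to hit the requested final coverage. The disjoint
partition means no fragment name can appear twice in the final product, an
artifact merging independent subsamples of one source would create.
Duplications are applied inside each carrier clone's contribution before
merging; deletion events contribute their one-allele name pool, which is
dropped from carrier contributions during final assembly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from tempfile import TemporaryDirectory
from typing import Optional, Sequence

import numpy as np
import pysam

from .architecture import (ROOT, CloneTree, SomaticTruthRecord, truth_records,
                           write_truth_table)
from .clone_factory import ClonePackage, CoverageSummary, write_manifest
from .core import (AlignmentSet, CnaEvent, GermlineVariant,
                   IncompatiblePlanError, InvalidParameterError, fragment_fate,
                   index_bam)
from .fixtures import _vcf_header
from .read_ops import (classify_reads_at_locus, extract_allele_sets,
                       merge_alignments, record_key)


@dataclass
class MixturePlan:
    """Validated per-clone mixture: fractions (sum 1), final coverage, and
    the per-clone fragment-keep rates that realise it."""

    fractions: dict[str, float]          # clone -> fraction in [0, 1]
    final_coverage: float
    subsample_rates: dict[str, float]    # clone -> fraction * final / input cov
    input_coverages: dict[str, float]

    @property
    def boundaries(self) -> list[tuple[str, float, float]]:
        """Half-open [lo, hi) hash intervals per clone, in insertion order."""
        out = []
        cum = 0.0
        for clone, f in self.fractions.items():
            out.append((clone, cum, cum + f))
            cum += f
        return out

    def bucket_of(self, u: float) -> Optional[str]:
        for clone, lo, hi in self.boundaries:
            if lo <= u < hi:
                return clone
        return None

    def effective_keep_rate(self, clone: str) -> float:
        """Keep probability conditional on a fragment hashing into the
        clone's bucket (= final coverage / that clone's input coverage)."""
        f = self.fractions[clone]
        if f == 0:
            return 0.0
        return min(self.subsample_rates[clone] / f, 1.0)


def validate_plan(fractions: dict[str, float], final_coverage: float,
                  cov_summaries: dict[str, "CoverageSummary | float"]
                  ) -> MixturePlan:
    """Check mixture percentages and final coverage against input coverage.

    ``fractions`` are percentages per clone (control included) and must sum
    to 100. The derived per-clone keep rate is
    ``fraction x final_coverage / input_coverage``; any rate above 1 means
    the inputs cannot supply the requested product and the process stops.
    """
    if set(fractions) != set(cov_summaries):
        raise InvalidParameterError("fractions must cover exactly the provided clones")
    total = sum(fractions.values())
    if not math.isclose(total, 100.0, abs_tol=1e-9):
        raise InvalidParameterError(f"percentages must sum to 100, got {total}")
    if final_coverage <= 0:
        raise InvalidParameterError("final coverage must be positive")
    covs = {c: (s.mean_coverage if isinstance(s, CoverageSummary) else float(s))
            for c, s in cov_summaries.items()}
    rates = {}
    for clone, pct in fractions.items():
        f = pct / 100.0
        if covs[clone] <= 0 and f > 0:
            raise IncompatiblePlanError(f"clone {clone} has zero input coverage")
        rates[clone] = f * final_coverage / covs[clone] if f > 0 else 0.0
    bad = {c: r for c, r in rates.items() if r > 1.0 + 1e-12}
    if bad:
        worst = max(bad, key=bad.get)
        achievable = min(covs[c] / (fractions[c] / 100.0)
                         for c in fractions if fractions[c] > 0)
        raise IncompatiblePlanError(
            f"clone {worst} would need keep rate {bad[worst]:.3f} > 1; "
            f"maximum achievable final coverage for these percentages is "
            f"{achievable:.1f}x")
    return MixturePlan(fractions={c: p / 100.0 for c, p in fractions.items()},
                       final_coverage=final_coverage,
                       subsample_rates=rates, input_coverages=covs)


@dataclass
class TruthBundle:
    """Machine-readable truth for one blended sample."""

    somatic: list[SomaticTruthRecord]
    cna_rows: list[dict]
    somatic_vcf: Optional[Path] = None
    cna_tsv: Optional[Path] = None
    manifest: Optional[Path] = None


def expected_log2_ratio(kind: str, tumor_fraction: float,
                        mode: str = "single_copy") -> float:
    """Closed-form read-count log2 ratio for a CNA at tumor fraction t:
    duplication log2((2+t)/2); single-copy deletion log2((2-t)/2); two-copy
    deletion log2(1-t)."""
    t = tumor_fraction
    if kind == "duplication":
        return math.log2((2 + t) / 2)
    if mode == "two_copy":
        return math.log2(1 - t) if t < 1 else float("-inf")
    return math.log2((2 - t) / 2)


def _event_carriers(event: CnaEvent, tree: Optional[CloneTree]) -> frozenset:
    if tree is None or event.clone not in tree.nodes:
        return frozenset({event.clone})
    return frozenset({event.clone} | tree.descendants(event.clone))


def _write_truth_vcf(records: Sequence[SomaticTruthRecord],
                     contigs: dict[str, int], path: Path) -> Path:
    header = _vcf_header(contigs)
    header.info.add("EAF", 1, "Float", "Expected somatic allele fraction")
    header.info.add("CARRIERS", 1, "String", "Carrier clones")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            v = r.variant
            rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref, v.alt))
            rec.info["EAF"] = round(r.expected_af, 6)
            rec.info["CARRIERS"] = ",".join(sorted(r.carriers))
            rec.samples["SAMPLE"]["GT"] = (0, 1)
            out.write(rec)
    return path


def blend(clone_packages: Sequence[ClonePackage], plan: MixturePlan,
          seed: int, out_prefix: Path | str,
          tree: Optional[CloneTree] = None,
          edge_variants: Optional[dict[str, list[GermlineVariant]]] = None,
          region_variants: Optional[Sequence[GermlineVariant]] = None,
          deletion_mode: str = "single_copy",
          sample_name: str = "tumor") -> tuple[AlignmentSet, TruthBundle]:
    """Mix clone alignments into one blended sample with its truth bundle.

    Each record is kept iff its fragment hashes into its own clone's bucket
    and survives the coverage thinning. Duplication copies are appended for
    kept one-allele fragments inside each carrier clone's contribution;
    deletion pools are dropped from carrier contributions. ``region_variants``
    supplies the germline het variants used to build allele sets for CNA
    regions (defaults to each clone package's carried+switched pool).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    by_clone = {p.clone: p for p in clone_packages}
    if set(plan.fractions) != set(by_clone):
        raise InvalidParameterError("plan clones do not match packages")

    # Pre-compute CNA allele sets from each owning clone's alignment
    dup_sets: list[tuple[CnaEvent, frozenset, set[str]]] = []
    del_pools: list[tuple[CnaEvent, frozenset, set[str]]] = []
    all_events: list[CnaEvent] = []
    for pkg in clone_packages:
        for ev in pkg.cna_events:
            all_events.append(ev)
            if region_variants is not None:
                reg_vars = [v for v in region_variants
                            if v.chrom == ev.chrom and ev.start <= v.pos - 1 < ev.end]
            else:
                pool = (pkg.carried or []) + (pkg.switched or [])
                reg_vars = [v for v in pool
                            if v.chrom == ev.chrom and ev.start <= v.pos - 1 < ev.end]
            alt_set, ref_half = extract_allele_sets(pkg.alignment, ev, reg_vars,
                                                    seed=seed + 1)
            carr = _event_carriers(ev, tree)
            if ev.kind == "duplication":
                dup_sets.append((ev, carr, alt_set | ref_half))
            else:
                if deletion_mode == "two_copy":
                    with pkg.alignment.open() as fh:
                        names = {r.query_name
                                 for r in fh.fetch(ev.chrom, ev.start, ev.end)}
                    del_pools.append((ev, carr, names))
                else:
                    del_pools.append((ev, carr, alt_set | ref_half))

    boundaries = plan.boundaries
    final_bam = Path(str(out_prefix) + f".{sample_name}.bam")
    with TemporaryDirectory(dir=out_prefix.parent) as tmp:
        parts = []
        for clone, lo, hi in boundaries:
            pkg = by_clone[clone]
            rate = plan.effective_keep_rate(clone)
            part_path = Path(tmp) / f"{clone}.bam"
            my_dups = [(ev, names) for ev, carr, names in dup_sets
                       if clone in carr]
            my_dels = set()
            for ev, carr, names in del_pools:
                if clone in carr:
                    my_dels |= names
            with pkg.alignment.open() as src, pysam.AlignmentFile(
                    str(part_path), "wb", template=src) as out:
                header = out.header
                for read in src:
                    name = read.query_name
                    u1, u2 = fragment_fate(name, seed)
                    if not (lo <= u1 < hi) or u2 >= rate:
                        continue
                    if name in my_dels:
                        continue
                    out.write(read)
                    for ev, names in my_dups:
                        if (name in names
                                and read.reference_name == ev.chrom
                                and read.reference_start < ev.end
                                and (read.reference_end or 0) > ev.start):
                            # one fresh name per fragment per event so mates
                            # of a duplicated pair stay joined
                            d = read.to_dict()
                            d["name"] = f"{name}.{clone}.dup{ev.chrom}_{ev.start}"
                            out.write(pysam.AlignedSegment.from_dict(d, header))
            parts.append(AlignmentSet(part_path))
        merged = merge_alignments(parts, final_bam)

    # Truth bundle
    somatic: list[SomaticTruthRecord] = []
    if tree is not None and edge_variants is not None:
        somatic = truth_records(tree, edge_variants, plan.fractions)
    else:
        # carrier sets recoverable from the per-clone truth VCFs alone
        carrier_map: dict[tuple, tuple[GermlineVariant, set]] = {}
        for pkg in clone_packages:
            for v in pkg.carried or []:
                carrier_map.setdefault(v.key, (v, set()))[1].add(pkg.clone)
        somatic = sorted(
            (SomaticTruthRecord(
                variant=v, carriers=frozenset(cs),
                expected_af=0.5 * sum(plan.fractions.get(c, 0.0) for c in cs))
             for v, cs in carrier_map.values()),
            key=lambda r: (r.variant.chrom, r.variant.pos))
    cna_rows = []
    for ev in all_events:
        carr = _event_carriers(ev, tree)
        t = sum(plan.fractions.get(c, 0.0) for c in carr)
        cna_rows.append({
            "chrom": ev.chrom, "start": ev.start, "end": ev.end,
            "kind": ev.kind, "clone": ev.clone, "tumor_fraction": round(t, 6),
            "expected_log2_ratio": round(expected_log2_ratio(
                ev.kind, t, deletion_mode), 6),
        })

    contigs = clone_packages[0].alignment.contigs()
    vcf_path = Path(str(out_prefix) + ".somatic.truth.vcf")
    _write_truth_vcf(somatic, contigs, vcf_path)
    cna_path = Path(str(out_prefix) + ".cna.truth.tsv")
    with open(cna_path, "w") as fh:
        cols = ["chrom", "start", "end", "kind", "clone", "tumor_fraction",
                "expected_log2_ratio"]
        fh.write("\t".join(cols) + "\n")
        for row in cna_rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    manifest_path = write_manifest(
        Path(str(out_prefix) + ".manifest.json"),
        seed=seed,
        fractions={c: round(f, 9) for c, f in plan.fractions.items()},
        final_coverage=plan.final_coverage,
        subsample_rates={c: round(r, 9) for c, r in plan.subsample_rates.items()},
        input_coverages={c: round(v, 6) for c, v in plan.input_coverages.items()},
        deletion_mode=deletion_mode,
        n_somatic=len(somatic), n_cna=len(cna_rows))
    bundle = TruthBundle(somatic=somatic, cna_rows=cna_rows,
                         somatic_vcf=vcf_path, cna_tsv=cna_path,
                         manifest=manifest_path)
    return merged, bundle


def blended_baf_at_loci(clone_packages: Sequence[ClonePackage],
                        plan: MixturePlan, seed: int,
                        loci: Sequence[GermlineVariant]
                        ) -> dict[tuple, tuple[int, int]]:
    """Observed (alt count, depth) at each locus of the blended sample,
    without materialising it.

    Applies the exact per-fragment fate rule :func:`blend` uses to the reads
    spanning each locus in each clone's alignment, so the counts agree with a
    pileup of the full blended BAM wherever no CNA event overlaps the locus.
    """
    counts: dict[tuple, list[int]] = {v.key: [0, 0] for v in loci}
    for clone, lo, hi in plan.boundaries:
        pkg = next(p for p in clone_packages if p.clone == clone)
        rate = plan.effective_keep_rate(clone)
        if hi - lo <= 0 or rate <= 0:
            continue
        with pkg.alignment.open() as fh:
            for v in loci:
                c = classify_reads_at_locus(fh, v)
                for group, is_alt in ((c.alt_reads, True),
                                      (c.ref_reads, False),
                                      (c.other_reads, False)):
                    for name, _ in group:
                        u1, u2 = fragment_fate(name, seed)
                        if lo <= u1 < hi and u2 < rate:
                            counts[v.key][1] += 1
                            if is_alt:
                                counts[v.key][0] += 1
    return {k: (a, d) for k, (a, d) in counts.items()}


def make_contamination_grid(clone_packages: Sequence[ClonePackage],
                            grid_spec: Sequence[tuple[str, float, float]],
                            seed: int, out_dir: Path | str,
                            cov_summaries: dict[str, "CoverageSummary | float"],
                            tree: Optional[CloneTree] = None,
                            edge_variants=None
                            ) -> list[tuple[AlignmentSet, TruthBundle]]:
    """Blend one sample per (role, contamination %, coverage) grid point.

    ``role='tumor'``: the control contributes ``contamination`` percent and
    the subclones split the rest equally (normal tissue contaminating a tumor
    sample). ``role='normal'``: the subclones contribute ``contamination``
    percent total (tumor contaminating a normal sample). A manifest records
    the full grid.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subclones = [p.clone for p in clone_packages if p.clone != ROOT]
    if not subclones or ROOT not in {p.clone for p in clone_packages}:
        raise InvalidParameterError("need a control package and >= 1 subclone")
    results = []
    grid_manifest = []
    for i, (role, contamination, coverage) in enumerate(grid_spec):
        if not 0 <= contamination <= 100:
            raise InvalidParameterError(
                f"contamination must be in [0, 100], got {contamination}")
        if role == "tumor":
            ctrl_pct = contamination
        elif role == "normal":
            ctrl_pct = 100.0 - contamination
        else:
            raise InvalidParameterError(f"unknown role {role!r}")
        sub_pct = (100.0 - ctrl_pct) / len(subclones)
        fractions = {ROOT: ctrl_pct, **{c: sub_pct for c in subclones}}
        plan = validate_plan(fractions, coverage, cov_summaries)
        prefix = out_dir / f"{role}_cont{contamination:g}_cov{coverage:g}"
        aln, bundle = blend(clone_packages, plan, seed + i, prefix, tree=tree,
                            edge_variants=edge_variants, sample_name=role)
        results.append((aln, bundle))
        grid_manifest.append({"role": role, "contamination": contamination,
                              "coverage": coverage, "prefix": str(prefix)})
    write_manifest(out_dir / "grid.manifest.json", seed=seed, grid=grid_manifest)
    return results
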