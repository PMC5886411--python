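"""Initialization pipeline: coverage estimation, clone generation by
cumulative genotype switching along the clone tree, and CNA plan generation.

Each clone's alignment is derived independently from the terminal input
sample by switching every somatic variant the clone does *not* carry back to
homozygous reference; the root clone (the matched normal) has everything
switched. Deriving each clone directly from the input, rather than clone from
clone, keeps clones exchangeable and avoids compounding replacement sampling.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .architecture import ROOT, CloneTree, carriers
from .core import (AlignmentSet, CapacityError, CnaEvent, GermlineVariant,
                   InvalidParameterError, spawn_seeds)
from .fixtures import write_vcf
from .read_ops import SwitchReport, genotype_switch, index_bam


@dataclass
class CoverageSummary:
    """Mean fold-coverage plus a windowed depth table for one alignment."""

    mean_coverage: float
    windows: pd.DataFrame  # columns: chrom, start, end, mean_depth
    source: str

    def write(self, path: Path | str) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"#source\t{self.source}\n")
            fh.write(f"#mean_coverage\t{self.mean_coverage:.6f}\n")
            fh.write("chrom\tstart\tend\tmean_depth\n")
            for r in self.windows.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.mean_depth:.6f}\n")
        return path

    @classmethod
    def read(cls, path: Path | str) -> "CoverageSummary":
        path = Path(path)
        source = ""
        mean = 0.0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#source"):
                    source = line.rstrip("\n").split("\t")[1]
                elif line.startswith("#mean_coverage"):
                    mean = float(line.split("\t")[1])
                else:
                    break
        windows = pd.read_csv(path, sep="\t", comment="#")
        return cls(mean_coverage=mean, windows=windows, source=source)


def compute_coverage(aln: AlignmentSet,
                     target_regions: Optional[list[tuple[str, int, int]]] = None,
                     window: int = 10_000) -> CoverageSummary:
    """Per-base spanning-read depth, averaged genome-wide (or over the target)
    and per window. An empty alignment yields mean 0."""
    rows = []
    total = 0.0
    n_pos = 0
    with aln.open() as fh:
        for contig, length in zip(fh.references, fh.lengths):
            cov = np.zeros(length, dtype=np.int64)
            acgt = fh.count_coverage(contig, 0, length, quality_threshold=0)
            for arr in acgt:
                cov += np.asarray(arr, dtype=np.int64)
            if target_regions is not None:
                mask = np.zeros(length, dtype=bool)
                for c, s, e in target_regions:
                    if c == contig:
                        mask[s:e] = True
            else:
                mask = np.ones(length, dtype=bool)
            total += float(cov[mask].sum())
            n_pos += int(mask.sum())
            for start in range(0, length, window):
                end = min(start + window, length)
                wmask = mask[start:end]
                if not wmask.any():
                    continue
                rows.append((contig, start, end, float(cov[start:end][wmask].mean())))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_depth"])
    mean = total / n_pos if n_pos else 0.0
    return CoverageSummary(mean_coverage=mean, windows=windows,
                           source=str(aln.path))


def generate_cna_plan(n_events: int, length_bp: int, genome: dict[str, int],
                      clones: Sequence[str], seed: int,
                      target_regions=None) -> list[CnaEvent]:
    """Place ``n_events`` non-overlapping intervals of exactly ``length_bp``.

    Intervals are drawn from a disjoint slot grid (slot width = event length),
    guaranteeing non-overlap; kind is duplication/deletion with equal
    probability and clone ownership is round-robin from a seeded start.
    """
    if n_events < 0 or length_bp < 100:
        raise InvalidParameterError("need n_events >= 0 and length_bp >= 100")
    slots: list[tuple[str, int]] = []
    for contig, length in genome.items():
        for s in range(0, length - length_bp + 1, length_bp):
            if target_regions is None or any(
                    c == contig and s < e and s + length_bp > b
                    for c, b, e in target_regions):
                slots.append((contig, s))
    if n_events > len(slots):
        raise CapacityError(
            f"cannot place {n_events} non-overlapping events of {length_bp} bp "
            f"(capacity {len(slots)})")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(slots), size=n_events, replace=False)
    kinds = rng.integers(0, 2, size=n_events)
    start_clone = int(rng.integers(0, len(clones)))
    events = []
    for i, slot_i in enumerate(sorted(int(c) for c in chosen)):
        contig, s = slots[slot_i]
        events.append(CnaEvent(
            chrom=contig, start=s, end=s + length_bp,
            kind="duplication" if kinds[i] else "deletion",
            clone=clones[(start_clone + i) % len(clones)]))
    return events


def write_cna_plan(events: Sequence[CnaEvent], path: Path | str) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tkind\tclone\n")
        for e in events:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.kind}\t{e.clone}\n")
    return path


def read_cna_plan(path: Path | str) -> list[CnaEvent]:
    df = pd.read_csv(path, sep="\t")
    return [CnaEvent(chrom=r.chrom, start=int(r.start), end=int(r.end),
                     kind=r.kind, clone=r.clone)
            for r in df.itertuples(index=False)]


@dataclass
class ClonePackage:
    """One generated clone: its alignment, somatic truth split, CNA events."""

    clone: str
    alignment: AlignmentSet
    carried: list[GermlineVariant]
    switched: list[GermlineVariant]
    cna_events: list[CnaEvent] = field(default_factory=list)
    truth_vcf: Optional[Path] = None
    switch_report: Optional[SwitchReport] = None


def generate_clones(input_aln: AlignmentSet,
                    germline_variants: Sequence[GermlineVariant],
                    tree: CloneTree,
                    edge_variants: dict[str, list[GermlineVariant]],
                    label: str, seed: int, out_dir: Path | str,
                    cna_plan: Optional[Sequence[CnaEvent]] = None,
                    nodes: Optional[Sequence[str]] = None) -> list[ClonePackage]:
    """Derive every clone's alignment from the input by genotype switching.

    The input is the fully-derived terminal sample: a clone's BAM is the input
    with every *non-carried* selected variant switched back to hom-ref. The
    root gets all of them switched (it is the matched normal); a terminal
    clone carrying everything is an untouched copy. Emits per-clone truth
    VCFs of the carried somatic variants.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    selected = sorted((v for vs in edge_variants.values() for v in vs),
                      key=lambda v: (v.chrom, v.pos))
    selected_keys = {v.key for v in selected}
    for v in selected:
        if v.genotype != "het":
            raise InvalidParameterError("selected somatic loci must be het")
    carr = carriers(tree, edge_variants)
    contigs = input_aln.contigs()
    todo = list(nodes) if nodes is not None else list(tree.nodes)
    seeds = dict(zip(todo, spawn_seeds(seed, len(todo))))

    packages = []
    for node in todo:
        carried = [v for v in selected if node in carr[v.key]]
        switched = [v for v in selected if node not in carr[v.key]]
        bam_path = out_dir / f"{label}.{node}.bam"
        report = None
        if switched:
            clone_aln, report = genotype_switch(input_aln, switched,
                                                seeds[node], bam_path)
        else:
            shutil.copyfile(input_aln.path, bam_path)
            if input_aln.index_path.exists():
                shutil.copyfile(input_aln.index_path, Path(str(bam_path) + ".bai"))
            else:
                index_bam(bam_path)
            clone_aln = AlignmentSet(bam_path)
        vcf_path = out_dir / f"{label}.{node}.vcf"
        write_vcf(carried, contigs, vcf_path)
        events = [e for e in (cna_plan or []) if e.clone == node]
        packages.append(ClonePackage(clone=node, alignment=clone_aln,
                                     carried=carried, switched=switched,
                                     cna_events=events, truth_vcf=vcf_path,
                                     switch_report=report))
    return packages


def write_manifest(path: Path | str, **params) -> Path:
    """JSON run manifest with the seed and every parameter that shaped a run."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
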