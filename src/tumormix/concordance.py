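"""Allele-fraction concordance experiment.

End-to-end validation of the simulator's central promise: that subsampling,
genotype switching and mixing preserve somatic allele fractions. A synthetic
normal sample is generated, a single-subclone architecture is derived (the
matched normal is the input with every somatic locus switched back to
hom-ref), and two-clone tumor mixtures are formed over a grid of tumor
purities and final coverages, with replicate blends per grid point.

Observed BAF at each truth locus is computed with the exact per-fragment
fate rule the blender uses (hash partition + coverage thinning), applied to
the locus-spanning reads of each clone; expected AF is the carrier fraction
times the locus's allele fraction in the input sample (the allele-depth
analogue of a germline caller's REF/ALT counts). Following the construction
of the original validation figures, the BAF entering the correlation is
averaged across the coverage grid and the replicates, while the per-locus
deviation fractions are kept per coverage and averaged across replicates
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .architecture import build_architecture, select_somatic_loci
from .clone_factory import compute_coverage, generate_clones
from .core import AlignmentSet, GermlineVariant, fate_arrays, spawn_seeds
from .evaluation import af_concordance
from .fixtures import (ReadSimParams, make_reference, plant_germline_variants,
                       simulate_reads, write_fasta, write_vcf)
from .read_ops import classify_reads_at_locus


@dataclass(frozen=True)
class AfConcordanceParams:
    """Study conditions for the concordance experiment.

    Defaults mirror the validation design: a 1 Mb reference at 41% GC, a deep
    (250x) input so every final coverage on the 50-200x grid is reachable,
    ~0.1% base error, >=1000 heterozygous SNVs plus >=200 heterozygous
    insertions and deletions available, 500/200/200 somatic loci, tumor
    purities 90..50% against the matched control, and three replicate blends
    per grid point.
    """

    ref_len: int = 1_000_000
    gc_fraction: float = 0.41
    n_snv: int = 1300
    n_ins: int = 280
    n_del: int = 280
    het_fraction: float = 0.8
    input_depth: float = 250.0
    err_rate: float = 0.001
    read_len: int = 100
    n_somatic_snv: int = 500
    n_somatic_ins: int = 200
    n_somatic_del: int = 200
    tumor_pcts: tuple = (90, 80, 70, 60, 50)
    coverages: tuple = (50, 100, 150, 200)
    replicates: int = 3


@dataclass
class AfConcordanceResult:
    pearson_r: dict[str, float]           # per variant class
    pct_within_0p1: dict[str, float]      # "SNV" and "InDel", in percent
    n_loci: dict[str, int]
    n_pairs: dict[str, int]
    input_coverage: float
    params: AfConcordanceParams = field(repr=False, default=None)


def _locus_tables(aln: AlignmentSet, loci: Sequence[GermlineVariant]):
    """Flattened per-record tables over all loci: record names, locus index,
    and alt flags."""
    names: list[str] = []
    locus_idx: list[int] = []
    is_alt: list[bool] = []
    with aln.open() as fh:
        for i, v in enumerate(loci):
            c = classify_reads_at_locus(fh, v)
            for group, flag in ((c.alt_reads, True), (c.ref_reads, False),
                                (c.other_reads, False)):
                for name, _ in group:
                    names.append(name)
                    locus_idx.append(i)
                    is_alt.append(flag)
    return names, np.asarray(locus_idx), np.asarray(is_alt)


def run_af_concordance(seed: int, work_dir: Path | str,
                       params: AfConcordanceParams = AfConcordanceParams()
                       ) -> AfConcordanceResult:
    """Run the full concordance experiment and pool the statistics."""
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    p = params
    s_ref, s_plant, s_reads, s_sel, s_clone, s_grid = spawn_seeds(seed, 6)

    ref = make_reference(p.ref_len, p.gc_fraction, s_ref)
    write_fasta(ref, work_dir / "ref.fa")
    variants = plant_germline_variants(ref, p.n_snv, p.n_ins, p.n_del,
                                       p.het_fraction, s_plant,
                                       read_len=p.read_len)
    write_vcf(variants, {ref.name: ref.length}, work_dir / "germline.vcf")
    sim = ReadSimParams(depth=p.input_depth, read_len=p.read_len,
                        err_rate=p.err_rate, seed=s_reads)
    input_aln = simulate_reads(ref, variants, sim, work_dir / "input.bam")
    input_cov = compute_coverage(input_aln).mean_coverage

    sel_seeds = spawn_seeds(s_sel, 3)
    loci = (select_somatic_loci(variants, p.n_somatic_snv, seed=sel_seeds[0], vtype="SNV")
            + select_somatic_loci(variants, p.n_somatic_ins, seed=sel_seeds[1], vtype="INS")
            + select_somatic_loci(variants, p.n_somatic_del, seed=sel_seeds[2], vtype="DEL"))
    loci = sorted(loci, key=lambda v: v.pos)
    vtypes = np.array([v.vtype for v in loci])
    n_loci = len(loci)

    tree = build_architecture(1, "linear", s_clone)
    edge_variants = {"c1": loci}
    clones = generate_clones(input_aln, variants, tree, edge_variants,
                             label="afexp", seed=s_clone, out_dir=work_dir)
    by_clone = {c.clone: c for c in clones}

    # per-record tables: tumor clone (the untouched input) and the control
    t_names, t_idx, t_alt = _locus_tables(by_clone["c1"].alignment, loci)
    n_names, n_idx, _ = _locus_tables(by_clone["normal"].alignment, loci)

    # expected AF: carrier fraction (tumor purity) x input allele fraction
    alt_in = np.bincount(t_idx[t_alt], minlength=n_loci)
    depth_in = np.bincount(t_idx, minlength=n_loci)
    baf_in = np.divide(alt_in, depth_in, out=np.zeros(n_loci), where=depth_in > 0)

    # every (replicate, coverage) grid cell is an independently seeded blend,
    # like the independently generated samples of the original validation --
    # nesting the coverage subsamples would correlate them and defeat the
    # averaging the figures apply
    n_mix, n_cov, n_rep = len(p.tumor_pcts), len(p.coverages), p.replicates
    baf = np.full((n_loci, n_mix, n_cov, n_rep), np.nan)
    cell_seeds = np.array(spawn_seeds(s_grid, n_rep * n_cov)).reshape(n_rep, n_cov)
    for r in range(n_rep):
        for c, cov in enumerate(p.coverages):
            rs = int(cell_seeds[r, c])
            tu1, tu2 = fate_arrays(t_names, rs)
            nu1, nu2 = fate_arrays(n_names, rs)
            rho = cov / input_cov
            for m, pct in enumerate(p.tumor_pcts):
                f_ctrl = 1.0 - pct / 100.0
                t_keep = (tu1 >= f_ctrl) & (tu2 < rho)
                alt = np.bincount(t_idx[t_keep & t_alt], minlength=n_loci)
                depth = (np.bincount(t_idx[t_keep], minlength=n_loci)
                         + np.bincount(n_idx[(nu1 < f_ctrl) & (nu2 < rho)],
                                       minlength=n_loci))
                ok = depth > 0
                baf[ok, m, c, r] = alt[ok] / depth[ok]

    purity = np.asarray(p.tumor_pcts, dtype=float) / 100.0
    expected = baf_in[:, None] * purity[None, :]            # (loci, mix)
    obs_mean = np.nanmean(baf, axis=(2, 3))                 # avg coverages+reps
    obs_per_cov = np.nanmean(baf, axis=3)                   # (loci, mix, cov)

    pearson: dict[str, float] = {}
    n_pairs: dict[str, int] = {}
    counts: dict[str, int] = {}
    for t in ("SNV", "INS", "DEL"):
        m = vtypes == t
        e = expected[m].ravel()
        o = obs_mean[m].ravel()
        keep = ~np.isnan(o)
        rep = af_concordance(e[keep], o[keep])
        pearson[t] = rep.pearson_r
        n_pairs[t] = rep.n_loci
        counts[t] = int(m.sum())

    dev = np.abs(obs_per_cov - expected[:, :, None])
    pct_within = {}
    for label, mask in (("SNV", vtypes == "SNV"),
                        ("InDel", np.isin(vtypes, ("INS", "DEL")))):
        d = dev[mask].ravel()
        d = d[~np.isnan(d)]
        pct_within[label] = float(np.mean(d < 0.1) * 100.0)

    _write_locus_table(work_dir / "concordance.tsv", loci, baf_in, purity,
                       expected, obs_mean)
    return AfConcordanceResult(pearson_r=pearson, pct_within_0p1=pct_within,
                               n_loci=counts, n_pairs=n_pairs,
                               input_coverage=input_cov, params=p)


def _write_locus_table(path: Path, loci, baf_in, purity, expected, obs_mean):
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tvtype\tinput_baf\ttumor_purity\texpected_af\t"
                 "observed_baf\n")
        for i, v in enumerate(loci):
            for m, t in enumerate(purity):
                fh.write(f"{v.chrom}\t{v.pos}\t{v.vtype}\t{baf_in[i]:.4f}\t"
                         f"{t:.2f}\t{expected[i, m]:.4f}\t{obs_mean[i, m]:.4f}\n")
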