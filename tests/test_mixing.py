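"""Mixing pipeline: plan validation, blending, truth bundles, grids."""

import collections
import json

import numpy as np
import pytest
from scipy import stats

from tumormix import (IncompatiblePlanError, InvalidParameterError, blend,
                      build_architecture, compute_coverage, pileup_counts,
                      rc_log2_ratio, validate_plan)
from tumormix.clone_factory import ClonePackage
from tumormix.mixing import (blended_baf_at_loci, expected_log2_ratio,
                             make_contamination_grid)
from tumormix.read_ops import genotype_switch


class TestValidatePlan:
    def test_rate_arithmetic(self):
        plan = validate_plan({"A": 50.0, "B": 50.0}, 50.0, {"A": 100.0, "B": 100.0})
        assert plan.subsample_rates == {"A": 0.25, "B": 0.25}
        plan = validate_plan({"A": 10.0, "B": 90.0}, 150.0, {"A": 150.0, "B": 150.0})
        assert plan.subsample_rates["A"] == pytest.approx(0.10)
        assert plan.subsample_rates["B"] == pytest.approx(0.90)

    def test_incompatible_stops_with_diagnosis(self):
        with pytest.raises(IncompatiblePlanError) as e:
            validate_plan({"A": 20.0, "B": 80.0}, 100.0, {"A": 50.0, "B": 50.0})
        assert "B" in str(e.value)
        assert "62.5" in str(e.value)  # max achievable final coverage

    def test_fraction_validation(self):
        with pytest.raises(InvalidParameterError):
            validate_plan({"A": 60.0, "B": 50.0}, 10.0, {"A": 100.0, "B": 100.0})
        with pytest.raises(InvalidParameterError):
            validate_plan({"A": 100.0}, 10.0, {"A": 100.0, "B": 100.0})


@pytest.fixture(scope="module")
def two_clone_setup(clean_sample, tmp_path_factory):
    """Control (all loci switched) + tumor clone (the input) at 60x."""
    d = tmp_path_factory.mktemp("mix")
    loci = clean_sample["het"][:80]
    normal, _ = genotype_switch(clean_sample["aln"], loci, 12, d / "norm.bam")
    pkgs = [
        ClonePackage(clone="normal", alignment=normal, carried=[], switched=loci),
        ClonePackage(clone="c1", alignment=clean_sample["aln"], carried=loci,
                     switched=[]),
    ]
    cov = compute_coverage(clean_sample["aln"]).mean_coverage
    tree = build_architecture(1, "linear", 0)
    return {"dir": d, "loci": loci, "pkgs": pkgs, "cov": cov, "tree": tree,
            "edge": {"c1": loci}}


@pytest.fixture(scope="module")
def blended(two_clone_setup, tmp_path_factory):
    d = tmp_path_factory.mktemp("blended")
    s = two_clone_setup
    plan = validate_plan({"normal": 50.0, "c1": 50.0}, 50.0,
                         {"normal": s["cov"], "c1": s["cov"]})
    aln, bundle = blend(s["pkgs"], plan, 99, d / "b", tree=s["tree"],
                        edge_variants=s["edge"])
    return {"aln": aln, "bundle": bundle, "plan": plan, "prefix": d / "b"}


class TestBlend:
    def test_baf_within_binomial_interval(self, blended, two_clone_setup):
        """Private variant at 50 % purity: pooled BAF ~ 0.25."""
        counts = pileup_counts(blended["aln"], two_clone_setup["loci"])
        alt = sum(c.alt_count for c in counts)
        depth = sum(c.depth for c in counts)
        lo, hi = stats.binom.ppf([0.005, 0.995], depth, 0.25)
        assert lo <= alt <= hi

    def test_no_duplicate_fragments(self, blended):
        counts = collections.Counter()
        with blended["aln"].open() as fh:
            for r in fh:
                counts[(r.query_name, r.is_read1)] += 1
        assert max(counts.values()) == 1

    def test_realized_coverage_within_5pct(self, blended):
        cov = compute_coverage(blended["aln"]).mean_coverage
        assert 47.5 <= cov <= 52.5

    def test_truth_bundle_expected_af(self, blended):
        for rec in blended["bundle"].somatic:
            assert rec.expected_af == pytest.approx(0.25)
        assert blended["bundle"].somatic_vcf.exists()
        manifest = json.loads(blended["bundle"].manifest.read_text())
        assert manifest["seed"] == 99

    def test_fast_path_matches_full_blend(self, blended, two_clone_setup):
        """The fate-rule BAF shortcut reproduces the blended pileup exactly."""
        fast = blended_baf_at_loci(two_clone_setup["pkgs"], blended["plan"],
                                   99, two_clone_setup["loci"])
        counts = pileup_counts(blended["aln"], two_clone_setup["loci"])
        for c in counts:
            assert (c.alt_count, c.depth) == fast[c.variant.key]

    def test_deterministic_truth_and_fragments(self, two_clone_setup,
                                               tmp_path_factory):
        d = tmp_path_factory.mktemp("det")
        s = two_clone_setup
        plan = validate_plan({"normal": 60.0, "c1": 40.0}, 40.0,
                             {"normal": s["cov"], "c1": s["cov"]})
        names = []
        texts = []
        for run in ("x", "y"):
            aln, bundle = blend(s["pkgs"], plan, 7, d / run, tree=s["tree"],
                                edge_variants=s["edge"])
            with aln.open() as fh:
                names.append({r.query_name for r in fh})
            texts.append(bundle.somatic_vcf.read_text()
                         + bundle.cna_tsv.read_text())
        assert names[0] == names[1]
        assert texts[0] == texts[1]

    def test_zero_control_keeps_het_baf(self, two_clone_setup, tmp_path_factory):
        d = tmp_path_factory.mktemp("pure")
        s = two_clone_setup
        plan = validate_plan({"normal": 0.0, "c1": 100.0}, 50.0,
                             {"normal": s["cov"], "c1": s["cov"]})
        fast = blended_baf_at_loci(s["pkgs"], plan, 5, s["loci"])
        alt = sum(a for a, d_ in fast.values())
        depth = sum(d_ for a, d_ in fast.values())
        assert abs(alt / depth - 0.5) < 0.02


def test_af_calibration_regression(two_clone_setup):
    """Across 20 blend seeds, observed BAF regressed on expected AF has slope
    ~1 and intercept ~0 (error-free fixture aggregate)."""
    s = two_clone_setup
    plan = validate_plan({"normal": 40.0, "c1": 60.0}, 50.0,
                         {"normal": s["cov"], "c1": s["cov"]})
    sums = collections.defaultdict(lambda: [0, 0])
    for seed in range(20):
        fast = blended_baf_at_loci(s["pkgs"], plan, seed, s["loci"])
        for k, (a, d) in fast.items():
            sums[k][0] += a
            sums[k][1] += d
    obs = np.array([a / d for a, d in sums.values()])
    # expected AF per locus: purity x input allele fraction
    inp = pileup_counts(s["pkgs"][1].alignment, s["loci"])
    exp = np.array([0.6 * c.alt_count / c.depth for c in inp])
    slope, intercept = np.polyfit(exp, obs, 1)
    assert 0.95 <= slope <= 1.05
    assert -0.02 <= intercept <= 0.02


class TestCnaInBlend:
    @pytest.mark.parametrize("purity", [20.0, 50.0, 80.0])
    def test_log2_closed_forms(self, cna_sample, tmp_path_factory, purity):
        """Measured read-count log2 ratios match log2((2 +/- t)/2) within 0.1."""
        d = tmp_path_factory.mktemp(f"cnablend{int(purity)}")
        ref = cna_sample["ref"]
        som = [v for v in cna_sample["variants"]
               if v.genotype == "het" and v.vtype == "SNV"
               and not (50_000 <= v.pos - 1 < 260_000)][:20]
        normal, _ = genotype_switch(cna_sample["aln"], som, 9, d / "n.bam")
        pkgs = [ClonePackage(clone="normal", alignment=normal, carried=[],
                             switched=som),
                ClonePackage(clone="c1", alignment=cna_sample["aln"],
                             carried=som, switched=[],
                             cna_events=[cna_sample["dup"], cna_sample["del"]])]
        cov = compute_coverage(cna_sample["aln"]).mean_coverage
        t = purity / 100.0
        plan = validate_plan({"normal": 100 - purity, "c1": purity}, 80.0,
                             {"normal": cov, "c1": cov})
        tumor, bundle = blend(pkgs, plan, 31, d / "t",
                              region_variants=cna_sample["variants"])
        plan_n = validate_plan({"normal": 100.0, "c1": 0.0}, 80.0,
                               {"normal": cov, "c1": cov})
        match_normal, _ = blend(pkgs, plan_n, 32, d / "n", sample_name="normal")
        df = rc_log2_ratio(tumor, match_normal,
                           [(ref.name, 50_000, 150_000),
                            (ref.name, 160_000, 260_000)])
        assert df.log2_ratio[0] == pytest.approx(
            expected_log2_ratio("duplication", t), abs=0.1)
        assert df.log2_ratio[1] == pytest.approx(
            expected_log2_ratio("deletion", t), abs=0.1)
        by_kind = {row["kind"]: row["expected_log2_ratio"]
                   for row in bundle.cna_rows}
        assert by_kind["duplication"] == pytest.approx(np.log2((2 + t) / 2), abs=1e-6)
        assert by_kind["deletion"] == pytest.approx(np.log2((2 - t) / 2), abs=1e-6)


class TestContaminationGrid:
    def test_grid_delegation_and_truth_scaling(self, two_clone_setup,
                                               tmp_path_factory):
        d = tmp_path_factory.mktemp("grid")
        s = two_clone_setup
        covs = {"normal": s["cov"], "c1": s["cov"]}
        grid = [("tumor", 0.0, 40.0), ("tumor", 25.0, 40.0)]
        results = make_contamination_grid(s["pkgs"], grid, 3, d, covs,
                                          tree=s["tree"], edge_variants=s["edge"])
        assert len(results) == 2
        af0 = results[0][1].somatic[0].expected_af
        af25 = results[1][1].somatic[0].expected_af
        assert af0 == pytest.approx(0.5)          # pure tumor, all carried
        assert af25 == pytest.approx(0.375)       # (1 - 0.25) x 0.5

    def test_negative_contamination_rejected(self, two_clone_setup, outdir):
        s = two_clone_setup
        covs = {"normal": s["cov"], "c1": s["cov"]}
        with pytest.raises(InvalidParameterError):
            make_contamination_grid(s["pkgs"], [("tumor", -5.0, 40.0)], 1,
                                    outdir, covs)
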