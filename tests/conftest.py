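import numpy as np
import pytest
from hypothesis import settings

from tumormix import (AlignmentSet, CnaEvent, make_reference,
                      plant_germline_variants, simulate_reads, write_fasta,
                      write_vcf)
from tumormix.fixtures import ReadSimParams

settings.register_profile("derandomized", derandomize=True, max_examples=50)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def clean_sample(tmp_path_factory):
    """Error-free 120 kb normal sample at 60x with planted germline truth."""
    d = tmp_path_factory.mktemp("clean")
    ref = make_reference(120_000, 0.41, 7)
    write_fasta(ref, d / "ref.fa")
    variants = plant_germline_variants(ref, 200, 40, 40, 0.8, 3)
    write_vcf(variants, {ref.name: ref.length}, d / "germline.vcf")
    params = ReadSimParams(depth=60, read_len=100, err_rate=0.0, seed=5)
    aln = simulate_reads(ref, variants, params, d / "input.bam")
    return {"dir": d, "ref": ref, "variants": variants, "aln": aln,
            "params": params,
            "het": [v for v in variants if v.genotype == "het"]}


@pytest.fixture(scope="session")
def cna_sample(tmp_path_factory):
    """Error-free 300 kb sample at 100x with two 100 kb CNA regions."""
    d = tmp_path_factory.mktemp("cna")
    ref = make_reference(300_000, 0.41, 17)
    variants = plant_germline_variants(ref, 300, 30, 30, 0.8, 4)
    params = ReadSimParams(depth=100, read_len=100, err_rate=0.0, seed=6)
    aln = simulate_reads(ref, variants, params, d / "input.bam")
    dup = CnaEvent(chrom=ref.name, start=50_000, end=150_000,
                   kind="duplication", clone="c1")
    dele = CnaEvent(chrom=ref.name, start=160_000, end=260_000,
                    kind="deletion", clone="c1")
    return {"dir": d, "ref": ref, "variants": variants, "aln": aln,
            "dup": dup, "del": dele}


@pytest.fixture()
def outdir(tmp_path):
    return tmp_path
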