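# tumormix

Synthetic tumor/normal sequencing samples built by **editing real aligned
reads** — never by spiking in artificial mutations.

Benchmarking somatic variant callers needs tumor samples whose mutations are
known exactly. Read simulators provide truth but cannot reproduce the
non-random error structure of real sequencing; spike-in tools inherit real
errors but inject synthetic alleles. `tumormix` takes the third route: start
from a real (or fixture) normal sample with its germline calls, and *remove*
variation. Selected heterozygous loci are switched to homozygous reference at
the read level — every alt-carrying read is replaced by a renamed copy of a
ref-carrying read at the same locus, so local depth is conserved exactly.
Each switch moves the sample one step back in tumor evolution, yielding
ancestral clones; mixing clones at chosen percentages then produces a
heterogeneous tumor with known subclonal architecture, somatic SNV/InDel
content, allele-aware copy-number alterations, and a machine-readable truth
bundle. The matched normal is the same sample with *all* selected loci
switched.

Key quantities:

* **BAF** (B-allele frequency): alt-read count / total reads at a locus.
* **Expected somatic AF** for a variant carried by clone set *C* under
  mixture fractions *f*: `0.5 x sum(f_c for c in C)` (model form), or the
  carrier fraction times the locus's allele fraction in the input sample
  (allele-depth form, used for concordance validation).
* **CNA read-count log2 ratio** at tumor fraction *t*: `log2((2+t)/2)` for a
  one-allele duplication, `log2((2-t)/2)` for a one-allele deletion.
* Caller scoring: precision `TP/called`, recall `TP/truth`,
  F-measure `2PR/(P+R)`.

## Worked example

```bash
# 1. a miniature normal sample: 60 kb reference, 140 germline variants, 40x
tumormix simulate-input --length 60000 --n-snv 120 --n-ins 10 --n-del 10 \
    --depth 40 --err-rate 0 --seed 3 --out-prefix work/mini

# 2. derive clones: 2 subclones on a linear tree, 40 somatic variants
tumormix init-clones --bam work/mini.bam --vcf work/mini.vcf --label mini \
    --subclones 2 --variants 40 --seed 4 --out-dir work/clones
# -> generated 3 clones in work/clones (input coverage 40.0x)

# 3. mix: 20% control, 30% c1, 50% c2 at 30x final coverage
tumormix blend --clones-dir work/clones --label mini \
    --percentages 20,30,50 --final-coverage 30 --seed 5 --out-prefix work/mix
# -> wrote work/mix.tumor.bam with truth bundle work/mix.manifest.json

# 4. score allele-fraction fidelity at the truth loci
tumormix evaluate af --bam work/mix.tumor.bam \
    --truth work/mix.somatic.truth.vcf --out work/af.json
# -> R = 0.5885 over 40 loci -> work/af.json
```

The blend emits `mix.tumor.bam`, a truth VCF whose `EAF` field holds each
variant's expected allele fraction under the mixture (here 0.40 for the 20
trunk variants carried by both subclones, 0.25 for the 20 private to c2), a
CNA truth table with expected log2 ratios, and a JSON manifest of seeds,
rates and coverages. The reported `R` is the Pearson correlation between
expected and observed BAF. At this deliberately tiny scale it is dominated
by 30x binomial counting noise (only two expected-AF tiers 0.15 apart
against a per-locus BAF standard deviation of ~0.08), so 0.59 is the
statistically expected outcome; the full-scale validation below, with wide
AF tiers, deep input and replicate averaging, recovers R >= 0.98.

The same operations are available as a library (`tumormix.blend`,
`tumormix.genotype_switch`, `tumormix.score_calls`, ...); see
`docs/methods.md` for the model and its assumptions.

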