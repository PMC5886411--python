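# Methods

## The editing model

`tumormix` synthesises tumor/normal pairs by three read-level operations on a
coordinate-sorted alignment of a normal sample, all of which conserve the
statistical texture of the original data because every read in the product is
(a possibly renamed copy of) a real input read.

**Genotype switching.** A somatic variant is created *in reverse*: the locus
is heterozygous in the input, and ancestral clones are produced by switching
it to homozygous reference. At each selected locus the reads are partitioned
into alt-carrying, ref-carrying and uninformative ("other") classes; every
alt record is removed and replaced by a renamed copy of a ref record sampled
(with replacement) at the same locus. The spanning-read count is therefore
conserved *exactly*, which is what keeps local coverage — the quantity
downstream CNA callers react to — untouched. Replacement candidates that
carry the alternative allele at another switched locus are avoided whenever
an alternative candidate exists, so switching one locus cannot re-introduce
alt evidence at a neighbour. A locus whose ref class is empty cannot be
switched; it is skipped and flagged in the switch report rather than
failing the run. Only the spanning record is replaced, not its mate; mate
coordinates are unchanged, so pairing metadata stays self-consistent.

Evidence rules: SNV — the aligned base at the position; insertion — an
insertion operation of the alt length at the junction after the anchor base;
deletion — a deletion operation covering exactly the deleted interval.
Reads that overlap but do not fully span the variant footprint (clipped or
terminating inside it) are "other" and are neither removed nor copied.

**Clone derivation.** Clones live on a rooted tree whose root is the matched
normal; a variant sits on one edge and is carried by the edge's child and
all of its descendants, so carried sets are nested along any root-to-leaf
path. Each clone's alignment is derived *independently from the input* by
switching everything the clone does not carry (the root gets everything
switched). Deriving clones independently rather than incrementally keeps
them exchangeable and avoids compounding replacement sampling; in
expectation it is equivalent to iterative backward derivation. Somatic
variants are apportioned across edges as evenly as integer division allows,
remainder to the root-proximal edges — a deterministic choice that yields
distinct expected-AF tiers per clone. Branched topologies are built as a
mandatory trunk edge followed by uniformly random attachment of each further
clone to an existing tumor clone.

**Mixing.** Every stochastic per-fragment decision is a keyed hash of the
read name (two independent uniforms per name, one for partition-style
choices, one for keep/drop), so mates always share a fate and any decision
can be recomputed from `(name, seed)` alone. A blend partitions fragments
disjointly across clones with bucket widths proportional to the mixture
fractions, then thins each bucket by `final_coverage / input_coverage`. The
disjoint partition is a deliberate design choice: merging independent
subsamples of the same source would let one physical fragment appear in two
clones' contributions — an artifact no real tumor has — and the hash
partition eliminates it by construction. The per-clone keep rate
`fraction x final / input` is validated up front; any rate above 1 aborts
with the offending clone and the maximum achievable final coverage.

**Copy-number events.** A CNA is realised by adding or removing the read set
of *one allele* of the region. The alt-informative fragments (alternative
allele at >= 1 heterozygous region variant) anchor the set; fragments that
are ref-informative belong to the other haplotype and are excluded; the
allele-uninformative remainder is halved by a seeded name hash. Duplication
appends renamed copies of this set inside each carrier clone's kept
contribution (region fragment count -> 3/2 of input at purity 1, in-event
het BAF -> 2/3); deletion pools the set's names and final assembly drops
them from carrier contributions (count -> 1/2). A `two_copy` deletion mode
pools every region fragment instead (count -> 0). Because the fragment
partition is disjoint, deletion removal is restricted to records whose
partition fate lies in a carrier clone; removing pooled names blindly would
deplete the normal contribution too and the coverage ratio would lose its
dependence on tumor fraction. Expected log2 read-count ratios at tumor
fraction *t* are `log2((2+t)/2)` (duplication), `log2((2-t)/2)` (one-allele
deletion) and `log2(1-t)` (two-copy deletion). Duplications are applied
before merging; deletion pools at final assembly.

## Expected allele fraction

Two forms are exposed. The model form is `0.5 x sum of carrier fractions` —
exact in expectation over the randomness of the input sample. The
allele-depth form multiplies the carrier fraction by the locus's *measured*
input allele fraction (alt / total from the same gap-aware pileup used for
observation). The concordance validation uses the allele-depth form: the
input sample's own binomial scatter around 0.5 (sd ~0.032 at 250x) is real,
is inherited by every derived sample, and is not an error of the mixing
machinery; conditioning on it isolates the fidelity of the operations under
test.

## The fixture generator

The bundled simulator supplies testable inputs; the editing pipeline itself
never fabricates a read. It materialises two explicit haplotypes (hom
variants on both, every het variant phased onto haplotype B, recorded per
read in the `XH` tag so tests have a per-read truth oracle), draws fragments
uniformly along a haplotype with normal fragment lengths (default mean
300 bp, sd 60 bp, reads 100 bp), and applies a uniform per-base substitution
error (default 0.1%) that never alters the CIGAR. Planted variants keep a
minimum spacing of twice the read length so each read overlaps at most one
variant and per-locus classification is exactly decidable; InDel lengths are
uniform on 1-10 bp. What it does *not* model — quality-score structure, GC
and mappability bias, PCR duplicates, real error hotspots — is precisely
what the editing approach inherits from real data in production use; tests
on the fixture therefore validate the *operations*, not the realism of any
error profile. Reference composition is exact-count (GC bases counted, then
shuffled) so the GC postcondition holds at any length.

## The concordance experiment

`tumormix.concordance.run_af_concordance` regenerates the validation study:
1 Mb reference, 41% GC, 1300/280/280 planted SNV/INS/DEL (80% het), input
depth 250x (the smallest round value above the largest requested final
coverage), error 0.1%; 500 somatic SNVs plus 200 insertions and 200
deletions; a single subclone mixed against the control at tumor purities
90/80/70/60/50% and final coverages 50/100/150/200x; three independently
seeded replicate blends per (purity, coverage) cell. Observed BAF at each
locus is computed with the same per-fragment fate rule the blender applies,
restricted to the locus-spanning reads — a pure optimisation, verified
bitwise against a full-blend pileup in the test suite. Each grid cell uses
its own seed: nesting the coverage subsamples under one seed would correlate
them and defeat the averaging below.

Pooling follows the construction of the original validation figures: the
BAF entering the per-class Pearson correlation is the per-locus mean across
the four coverages and three replicates, pooled over the five mixtures
(2500 SNV and 1000+1000 InDel pairs); the |deviation| < 0.1 fractions keep
one value per (locus, mixture, coverage), averaging across replicates only.
Under this design the predicted residual variance (~1.5e-4 against an
expected-AF variance of ~5.5e-3) puts the SNV correlation near 0.987, which
is what the experiment measures; insertions and deletions behave almost
identically because the gap-aware evidence rules lose only edge-spanning
reads.

## Numerical and interface conventions

* Variant positions are 1-based (VCF); intervals 0-based half-open (BED);
  conversions happen only at the type boundary (`GermlineVariant.span`).
* All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning; per-fragment decisions use a keyed
  BLAKE2b hash of the read name, so identical seeds and inputs give
  byte-identical truth bundles and identical kept-fragment sets.
* Pearson correlation is undefined (an error, not a number) for fewer than
  3 pairs or a zero-variance series; zero-depth loci are excluded and
  flagged; an empty call set has precision "not applicable", never 1.
* Variant matching for scoring is exact on left-aligned biallelic
  (chrom, pos, ref, alt); CNA matching requires the same kind and
  reciprocal overlap >= 0.5.

## Known limitations

* The replacement mechanism preserves spanning-read counts exactly but
  leaves the mates of removed/copied records as name-singletons; tools that
  require strict pair completeness should deduplicate by name first.
* Genotype switching assumes biallelic heterozygous input loci; multi-allelic
  and half-called genotypes are excluded from the eligible pool.
* CNA regions are single intervals per event; no breakpoint-spanning
  (split-read) evidence is created, so only read-depth and BAF signals of
  the event are simulated.
* The fixture's minimum variant spacing makes per-read classification
  unambiguous; real data violates this, and per-locus classes may then
  overlap across loci (handled, but the exactness guarantees of the tests
  no longer apply).
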