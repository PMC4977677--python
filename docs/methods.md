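# Methods

## The classification model

Plants keep transposable elements (TEs) silent partly through RNA-directed
DNA methylation (RdDM), read out here as asymmetric CHH-context methylation,
which decays unless actively re-deposited. Comparing a reference methylome
against mutants of the small-RNA machinery reveals *which* route targets each
TE. The package works from the weighted methylation level of a feature,

    m = Σ n_meth / Σ n_total

summed over covered cytosines of one context inside the feature — a
read-weighted average rather than a mean of per-site fractions, so deeply
covered cytosines count proportionally to their evidence.

A TE "loses" methylation in a mutant when the drop is strictly more than
`fold_loss_threshold`-fold (default 2): `m_mut < m_ref / 2`. Exactly 2-fold
does not qualify. A zero reference has nothing to lose; a zero mutant level
under a positive reference always qualifies.

Each TE covered (≥ `min_covered_cytosines`, default 1, covered cytosines) in
every required genotype is assigned the first matching category:

1. **NO_CHH** — reference CHH level below 1 %.
2. **POLIV_RDDM** — loss in *pol IV* and *pol V*; no loss in *rdr6*
   (vs reference) nor in *pol IV rdr6* (vs *pol IV*).
3. **RDR6_RDDM** — loss in *rdr6* and *pol V*; no loss in *pol IV*
   (vs reference) nor in *pol IV rdr6* (vs *rdr6*).
4. **DCL3_RDDM** — loss in *dcl3* and *pol V*; no loss in *pol IV*, *rdr6*
   or *pol IV rdr6* (all vs reference).
5. **COREGULATED** — loss in *pol IV rdr6* vs reference, with no
   single-pathway rule satisfied.
6. **MAINTENANCE** — methylated but matching none of the above (in
   particular, no *pol V* loss means no RdDM at all).

The criteria are near-disjoint by construction but not provably so; we fix
the evaluation order above and resolve any residual overlap by first match.
`rule_trace` records every comparison per TE, so a TE matching two rules is
auditable rather than silent. In the TE-active context the same rules run
with *ddm1* as reference and the *ddm1* double mutants as mutants. The
below-1 % gate is applied to whichever reference the background uses — its
stated form concerns the wild-type background only; symmetric application to
*ddm1* is this package's choice and is visible in `rule_trace`.

Uncovered TEs are reported as `UNCOVERED`, never dropped, so category counts
always partition the input. Levels of bystander genotypes (*rdr2*, *ago1*,
*ago6*, *drm2*) are carried in the matrix for reporting but never enter the
rules.

## DMS/DMR calling

Differential methylation is assessed per cytosine covered in both
genotypes with a two-sided Fisher exact test on
`[[n_meth_a, n_unmeth_a], [n_meth_b, n_unmeth_b]]`, Benjamini–Hochberg
adjusted; sites with adjusted p < `dms_alpha` (default 0.01) are DMSs. The
per-site test is this package's choice of a standard exact test — the
upstream merging rule is the specified part: successive DMSs at most
`dmr_max_gap` = 250 bp apart (gap measured between site positions, not
cluster edges) chain by single linkage, and chains with at least
`dmr_min_dms` = 4 members are reported as regions spanning first to last
site. Hyper- and hypo-DMSs chain together; direction is kept per site.
Duplicate positions are collapsed before chaining, making the output
invariant to repeated input.

Note on power: a single cytosine at ~20× coverage essentially cannot reach
genome-wide significance under an exact test; per-site DMS calling is
meaningful from roughly 50–100× up. The pipeline therefore treats the DMR
stage as coverage-dependent, and by default tests one informative genotype
pair (reference vs *pol V* — the mutant every RdDM route passes through)
rather than all pairs; the pair list is configurable.

## Meta-plots

Profiles are binned at `metaplot_bin` = 100 bp over the body and
`metaplot_flank` = 2 kb of flank. Within a bin, a feature contributes its
read-weighted level; across features the profile is the unweighted mean with
a 95 % normal-approximation band (mean ± 1.96·sd/√n; a t-interval is
indistinguishable at the element counts involved). Minus-strand features are
flipped so offsets follow the annotation's biological orientation. Sign
conventions (the published analysis states none): for the 5′ anchor, offset
0 is the first body base and negative offsets are upstream flank; for the 3′
anchor, negative offsets walk back into the body and offset 0 is the first
downstream base; DMRs use their left genomic edge with no flip. Features
contribute only up to their own length (display cap `metaplot_body_cap`,
default 3 kb); bins with no covered cytosine are undefined and excluded from
that bin's n. Overlapping neighbours are not masked out of flanks.

## TE structure

Length classes compare the annotated TE length to its family consensus
length: `FULL_LENGTH` strictly above 80 %, `FRAGMENT` strictly below 20 %,
and the unlabelled 20–80 % span is reported as `INTERMEDIATE` rather than
folded into either class. Consensus alignments arrive as precomputed
interval tables (any aligner); a landmark is "present" in a copy only if its
consensus interval is fully contained in the covered union, with the partial
covered fraction reported alongside. Domain detection is likewise consumed
as a hit table; hits must cover >90 % of the domain model, and LTRs more
than 50 bp internal to both TE edges are discarded (side assigned by the
nearer edge, ties to LTR5). Observed/expected domain enrichment divides a
category's domain frequency by the all-TE frequency; the all-TE
pseudo-category is identically 1 by construction, which the tests assert.

Mappability uses an exact k-mer index (k = `read_length`, default 150): the
fraction of read-length windows starting inside the TE (for TEs shorter than
a read, all windows overlapping it) whose sequence occurs exactly once in
the genome counting both strands. `perfect` = 1, `non` = 0, otherwise
`semi`. This is a declared, self-contained definition suited to compact
genomes; windows running past a chromosome end are skipped.

## Small RNAs and cleavage

Size profiles normalize raw uniquely-and-perfectly-mapped counts per size
class (18–28 nt) to reads per million genome-matched 18–28 nt reads, and
RPKM further divides by region length in kb. Cleavage sites survive at
p < 0.05 (strict). Comparing libraries with and without functional RDR6,
sites present in the rdr6-mutant library are primary; sites present only
with RDR6 are secondary. A TE is `SECONDARY_INVOLVED` with any
RDR6-dependent site, `PRIMARY_ONLY` if cleaved otherwise, else `UNCLEAVED`.
Site identity across libraries and contexts is exact-coordinate by default
(`tolerance` configurable; no matching window is stated for the original
analysis). Between contexts, a TE cleaved in both is `RETAINED_AND_GAINED`
when any silent-context site reappears in the active context and
`NOT_RETAINED_DISTINCT` when none does; one-sided and empty cases get their
own labels. Transcriptional competence requires ≥1 RPM of derepressed
mRNA-seq signal, ≥10 RPM of 21–22 nt siRNA in the derepressed background,
or any surviving cleavage site (all thresholds inclusive).

## The synthetic generator

`simulate()` emits everything the pipeline reads, plus a truth table. Study
conditions are the defaults: 500 TEs on two 340 kb chromosomes, per-cytosine
depth Poisson(20), effect factor 4, base CHH 0.15 within TEs (CG 0.85, CHG
0.45), below-threshold 0.002 for NO_CHH TEs, background levels
CG/CHG/CHH = 0.10/0.03/0.005 outside TEs. Mean TE length ~0.7 kb gives
roughly 200 CHH cytosines per TE at the simulated base composition.
Category proportions differ between backgrounds (more RDR6-RdDM and
co-regulated targeting when TEs are active), chosen once as plausible for a
derepressed genome. Per cytosine, `n_total ~ Poisson(depth)` and
`n_meth ~ Binomial(n_total, p)`, with p determined by context, TE
membership, and the planted category's epistasis pattern — the inverse image
of the classifier rules (e.g. a planted RDR6 target loses CHH in *rdr6*,
*pol V* and the double mutant only). The generator and classifier are
deliberately developed against each other so the rules are falsifiable.

TE copies are substrings of family consensus sequences (four synthetic
families, 0.7–2.6 kb) with 2 % per-copy divergence; coverage intervals,
domain-hit fractions and landmark content follow mechanically from the
planted length class. Exact-duplicate pairs are planted to exercise
mappability classes: plain copies (identical bodies, unique flanks →
semi-mappable) and "buried" copies sharing 149 bp flanks (→ non-mappable).
Active RDR6 targets carry ≥1 RDR6-dependent cleavage site and strong
21–22 nt siRNA mass in the derepressed library; decoy sites draw p ≥ 0.05.
Margins between planted-competent and incompetent expression levels are wide
enough that recovery is essentially noise-free at the default library depth
(2 × 10⁶ reads).

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: read-level artefacts (bisulfite non-conversion,
mapping bias, PCR duplicates), spatial autocorrelation of methylation within
TEs, partial or heterogeneous methylation loss across a TE body, TE
nesting/overlap, cross-mapping between diverged family members, and
count-level overdispersion beyond binomial. Recovery rates on synthetic data
are upper bounds.

## Numerical choices

* Weighted levels are exact integer-sum ratios; an uncovered feature is
  undefined (NA), never 0.
* Fisher p-values are memoized on the count 4-tuple; BH adjustment uses the
  standard step-up.
* The post-hoc test after the chi-squared homogeneity test is Marascuilo's
  simultaneous proportion-contrast procedure (family-wise critical value
  from the χ² quantile), valid for unequal group sizes; pairwise z-tests
  with Bonferroni are available behind a flag. The original figure names no
  specific procedure.
* The permutation check of the chi-squared test conditions on both table
  margins and is discrete; the test-suite comparison uses a mid-p count
  (ties weighted half) and allows the O(N^-1/2) conditional-vs-unconditional
  gap (0.05 on the p scale) on top of Monte-Carlo error, with counts kept in
  the asymptotic regime (expected cells ≫ 5).
* Degenerate inputs fail loudly: empty profiles, one-row contingency tables
  and zero margins raise; a degenerate size-class table skips the test with
  a warning instead of fabricating a p-value.
* All simulation randomness flows from one `numpy` Generator seeded by
  `SimulationParams.seed`; identical seeds give byte-identical file sets.

## Problem sizes used by the test and acceptance runs

Unit and property tests run on 60–100-TE simulations (two 60–70 kb
chromosomes); the acceptance checks run the standard 500-TE conditions at
depths 20 and 200, 1000 random weighted-level fixtures, 200 random DMS sets
(n ≤ 200, gaps 1–600 bp), 100 enrichment-null resamples, 20 permutation
tables at 10⁴ permutations each, and toy mappability genomes ≤ 100 kb. The
whole suite completes in well under five minutes on one CPU.

## Known limitations

* The per-site DMS test is this package's standard substitute for the
  original study's unpublished site test; only the merge rule is matched
  exactly.
* Classification is hard (first match wins); no uncertainty accompanies a
  category call beyond the rule trace and the levels themselves.
* The mappability definition is window-exact-match, not an aligner's
  mismatch-tolerant uniqueness.
* Genome-scale headline counts from the original study (tens of thousands
  of TEs, fold-changes between backgrounds) require the deposited sequencing
  data and are outside what the synthetic conditions reproduce; the report
  stage computes the same ratios on whatever data it is given.
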