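# Methods

This note documents the models and procedures behind `mendelscope`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data do and do not establish.

## Coordinates and file handling

All coordinates are 1-based inclusive, matching the g./c. notation of
variant reports and the VCF convention. VCF input/output is delegated to
pysam; only the GT and AD FORMAT fields are consumed, and multiallelic
sites are decomposed at load time into one biallelic record per ALT with
per-allele dosages recomputed (total allele count per sample is conserved).
Missing genotypes (`./.`) stay missing — nothing is imputed; each filter
declares its own missingness policy (below). Male X calls are re-coded
hemizygous when a pedigree supplies sex; pseudoautosomal regions are not
modeled. Coverage windows are `(chrom, 1-based start, end, count)` rows;
the terminal window of a chromosome may be short and is flagged partial.

## Mode-of-inheritance filters

Each filter is a deterministic predicate over case, parent and control
genotypes; retained variants are sorted by (chrom, pos, alt) so output is
reproducible byte for byte. "Private" means zero carriers among controls
for the dominant hypothesis; for the recessive hypothesis only
homozygous-alternate controls are excluded, because heterozygous carriers
of a recessive allele are expected to segregate in the population. For
compound heterozygosity, controls may carry either allele singly — the
published compound pairs had hundreds of single-copy carriers — but never
both simultaneously nor either in homozygosity, and with sampled parents
the two alleles must be explainable as one from each parent (trans). With
a single sampled parent the trans check degrades to that parent carrying
exactly one of the two alleles; with no sampled parent it cannot refute
and passes.

Missingness policy (config-exposed): a missing **control** genotype is
treated as reference (the permissive reading — absence of a call is not
evidence of carriage), while a missing **case** genotype fails the filter
(a case must positively show the required genotype). Control genotypes are
accepted as called; no depth/quality re-thresholding is applied by
default (knob provided).

De novo assessment requires both parents called 0/0 with at most
`max_parent_alt_reads` (default 0) alternate reads at depth ≥ 10. A 0/0
parent with more alternate reads than the per-read error rate explains
(one-sided exact binomial, ε = 0.005, α = 0.05) yields
`mosaic_parent_suspected` rather than `de_novo`; a missing parent yields
`undetermined`.

The classification ladder is an operational approximation of published
variant-classification guidance, since the full rubric is not reproduced
here: *pathogenic* requires (truncating consequence or a known
disease-allele match) and privacy and segregation consistency and (de
novo/mosaic support or multiple affected carriers); *likely pathogenic*
relaxes the consequence to missense/in-frame with ≥ 2 of the recognized
in-silico predictors calling the variant deleterious; everything else is
*uncertain*. It is validated only against the case-series labels it
reproduces. External predictors are consumed as annotations, never run;
a user-supplied gene panel may rank candidates but never excludes them.

## Read-depth karyotyping

Windows are normalized as per-bp count rate divided by a robust autosomal
reference rate. **Design choice:** the reference is the autosomal
*median*, not a lightly trimmed mean. On the compact five-chromosome test
genome, a whole trisomic chromosome contributes roughly a third of the
autosomal windows; any small trimmed mean absorbs that contamination and
drags every ratio off the 0.5/1.0/1.5 bands, whereas the median tolerates
up to half the windows being aberrant. A trimmed mean (default 1% per
tail) remains available via `CnvConfig(reference="trimmed_mean")` for
genomes where events are a negligible fraction. No GC or mappability
correction is applied — the simulator generates none, and the method
consumes plain read counts.

Whole-chromosome calls compare the median window ratio against the
expected ratio for the chromosome class and sex (autosome 1.0; X 0.5 in
males; Y 0.5 in males, absent in females): trisomy at 1.5 ± δ, monosomy
at 0.5 ± δ, normal at 1.0 ± δ, with δ = 0.15 and a minimum of 10
supporting windows. δ and the window minimum are operational defaults
chosen so that the two published event types (a full trisomy at ~19×; a
2.7 Mb terminal loss at ~14×) are called at both 10 kb and 200 kb window
resolutions; both are config-exposed. Chromosomes that fit no band are
scanned for a single terminal changepoint: the breakpoint minimizing the
squared error of a two-level model (expected level on the body, 0.5× or
1.5× on the terminal segment), computed in O(n) with prefix sums, scanning
both chromosome ends. A call additionally requires the terminal segment to
span ≥ 10 windows with mean ratio within δ of its level and the body
within δ of expectation. Interior segments are out of scope for calling
but visible in the Manhattan-style export table.

## Parental origin and mosaicism

Origin inference assumes reads sample the three copies of a trisomic
chromosome uniformly (no reference-bias correction). At sites where only
the sire carries the alternate allele and the extra copy is paternal, the
offspring carries the alternate on two of three copies, so the expected
alternate-read fraction is 2/3; at dam-only sites it is 1/3; the maternal
hypothesis mirrors these. The call is by binomial log-likelihood ratio
pooled over informative sites, with |LLR| > 10 nats required (default);
read counts are pooled across sites rather than voted per site, matching
aggregate read-fraction reporting. The estimator is exactly antisymmetric
under swapping parental labels.

For a hemizygous (partial-monosomy) region the same machinery reports
which parental haplotype was retained. Reporting *heterozygous* sites
inside a truly hemizygous region is internally contradictory — a
hemizygous region has one haplotype — so the module frames the question
as "the retained haplotype matches which parent" rather than reproducing
that framing.

The mosaicism test is a one-sided exact binomial test of the alternate
fraction against the error rate ε = 0.005: `low_level_mosaic` when
rejected at α = 0.05 with fraction below 0.35; `constitutive_het` for
fractions in [0.35, 0.65]; `absent` otherwise; `undetermined` below 10×
depth. ε and the heterozygote band are invented operational thresholds
(the source evidence is qualitative: "low proportion" in semen, none in
blood) and are config-exposed. Semen-positive with blood-negative is
classified germline (gonadal) mosaicism; a single negative tissue is
indeterminate, not negative.

## Parentage verification

Identity-by-descent is estimated by the classical method of moments:
observed identity-by-state counts are compared with their frequency-based
expectations under IBD states 0/1/2, the linear system is solved state by
state, estimates are truncated to [0,1] and renormalized, and
π̂ = P(IBD=1)/2 + P(IBD=2). No small-sample frequency corrections are
applied — control cohorts here are large relative to the pair being
tested, and simulation shows π̂ recovery within ±0.05 at 10⁴ informative
sites for parent-offspring, full-sib, half-sib and unrelated pairs. Sites
are restricted to cohort allele frequencies in [0.05, 0.95]. A
parent-offspring verdict requires π̂ ∈ [0.4, 0.6], P(IBD=0) < 0.05 and an
opposing-homozygote rate ≤ 0.001 (the genotyping-error allowance for ~20×
short reads); the frequency window and acceptance band are operational
defaults, not sourced values. Opposing homozygotes (one sample 0/0, the
other 1/1) are impossible for true parent-offspring pairs absent error,
which makes their rate the per-site exclusion signature.

## Synthetic data: what it emulates, and what passing tests show

The generator reproduces the statistical structure the analyses assume:

* control cohorts under Hardy-Weinberg equilibrium with site frequencies
  drawn from Beta(0.5, 0.5) truncated to [0.01, 0.99] — a U-shaped site
  frequency spectrum typical of sequenced cohorts; the real cohorts being
  emulated (10³ bovine, 10² ovine genomes) are represented desk-scale by
  500 controls by default;
* families by Mendelian transmission over trio, single-parent,
  paternal-half-sib and single-case designs, with the causal variant
  planted per scenario (de novo dominant, recessive homozygous, compound
  heterozygous in trans, X-linked de novo in a female, mosaic-sire
  transmission at semen fraction 0.1);
* allele depths: per-sample site depth ~ Poisson(20 × ploidy/2) — the
  cohort's average sequencing depth — with alternate reads binomial at
  the genotype fraction (ε, 0.5, 1−ε; copy-dosage/3 at trisomic sites;
  the mosaic fraction in mosaic tissue);
* coverage: window counts ~ Poisson(rate × width × ploidy/2) over a toy
  genome of three autosomes (25/20/15 Mb) plus X (20 Mb) and Y (5 Mb) —
  full livestock chromosome complements are unnecessary for the
  statistics exercised; planted events set ploidy 3 (trisomy) or 1
  (terminal segment).

Background sites are unlinked: none of the implemented inferences uses
linkage disequilibrium, so simulating it would add cost without power.
The generator produces no GC/mappability structure, no alignment
artifacts, no relatedness among controls, and no genotyping error beyond
the per-read miscall rate ε = 0.005. Consequently, passing tests
demonstrate correctness of the inference logic under the stated sampling
models — they do not certify performance on real alignments, where
mapping bias, batch effects and cohort substructure add failure modes
this package does not model.

Determinism: every simulation derives its generator from the seed plus a
fixed component tag; a fixed seed gives identical outputs across runs.

## Problem sizes used in the test and acceptance runs

Filter/oracle equivalence uses 1000 random cohorts of ≤ 8 samples × ≤ 50
variants (exhaustive re-evaluation is tractable there); planted-recovery
runs use 500 controls × 200 background sites over 50 seeds per scenario;
changepoint recovery uses 200 seeded genomes at 14× with a 270-window
terminal loss; origin inference uses 2000 informative sites × 200 seeds;
kinship uses 10⁴ sites × 100 seeds; the mosaicism null uses 10⁴
replicates at depth 40. These sizes keep each property at the scale where
its expected behavior is sharp while the full suite stays fast.

## Known limitations

* The classification ladder is a documented approximation; borderline
  evidence combinations can differ from expert curation.
* The CNV caller models exactly one terminal event per chromosome;
  interior or multiple events are surfaced only via the export table.
* Origin inference ignores reference bias and does not distinguish
  meiosis-I from meiosis-II non-disjunction, and no read-level phasing is
  attempted.
* The IBD estimator is method-of-moments, not likelihood-based; very
  small or strongly stratified control cohorts will bias the frequency
  estimates it depends on.
* Intronic c. positions (offset notation) are parsed and stored but
  excluded from codon arithmetic; non-codon-aligned in-frame deletions
  report the spanned codon range without 3'-rule re-normalization, so
  descriptions are not re-shifted relative to their source.
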