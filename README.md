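# mendelscope

Diagnosis and classification of congenital skeletal disorders in cattle and
sheep from whole-genome sequencing, as a tested, reusable pipeline. The
package is written for veterinary geneticists and livestock-genomics groups
who work from called variants (VCF), pedigree records (PED) and windowed
read counts, and who need the individual analysis steps — not just their
outcome — to be inspectable and reproducible.

## What it does

Rare congenital skeletal defects in ruminants are usually sporadic, so a
diagnosis rests on mode-of-inheritance (MOI) reasoning over small families
against a large control cohort. `mendelscope` implements that reasoning
end to end:

* **MOI filtering** (`mendelscope.filters`) — hypothesis-driven filters
  over trio / single-parent / paternal-half-sib / single-case designs:
  - *recessive*: homozygous-alternate in every case, never homozygous in
    any control (carriers permitted), available parents heterozygous;
  - *compound heterozygous*: gene-wise allele pairs, each case
    heterozygous for both, no control carrying both simultaneously or
    either in homozygosity, alleles in trans by pedigree;
  - *dominant / X-linked*: heterozygous (hemizygous on the male X) in
    every case and carried by **no** control, unaffected parents 0/0.
* **De novo vs germline mosaicism** (`filters.assess_de_novo`,
  `mendelscope.origin`) — a parent called 0/0 whose alternate reads exceed
  the sequencing-error expectation (one-sided exact binomial test at
  error rate ε = 0.005) is flagged as a suspected mosaic; semen-positive /
  blood-negative is the gonadal-mosaic signature.
* **Read-depth karyotyping** (`mendelscope.cnv`) — 10 kb / 200 kb window
  counts normalized to the robust autosomal level with sex-aware expected
  ratios (male X at 0.5); whole-chromosome trisomy/monosomy calls from
  median ratio bands, and a least-squares single-changepoint scan for
  terminal losses.
* **Parental origin of aneuploidies** (`mendelscope.origin`) — at sites
  where exactly one parent carries the alternate allele, a trisomic
  offspring's alternate-read fraction separates a paternal from a maternal
  extra copy (2/3 vs 1/3 expected); a binomial log-likelihood ratio makes
  the call.
* **Parentage verification** (`mendelscope.kinship`) — opposing-homozygote
  counting and method-of-moments identity-by-descent estimation
  (π̂ = P(IBD=1)/2 + P(IBD=2); parent-offspring pairs expect π̂ ≈ 0.5).
* **Machine-readable nosology** (`mendelscope.catalog`) — the disorder
  nosology and the 39-case series as validated TSV tables with the query
  operations (distinct counts, classification tallies, diagnostic rate).
* **HGVS arithmetic** (`mendelscope.hgvs`) — coding-DNA position to codon
  (`ceil(c/3)`), span lengths, frame effects, in-frame residue ranges.
* **Synthetic data** (`mendelscope.simulate`) — Hardy-Weinberg control
  cohorts, Mendelian families with planted causal variants per MOI
  scenario, binomial allele depths at ~20×, and Poisson coverage tracks
  with planted trisomies and terminal losses — with recorded ground truth
  for recovery scoring.
* **Pipeline + CLI** (`mendelscope.pipeline`, `mendelscope` command) —
  parentage check → MOI filters → classification → CNV fallback → origin
  inference, with a per-stage audit trail.

## Worked example

Simulate a recessive trio against 500 controls, then run the matching
filter:

```bash
mendelscope simulate --scenario recessive_hom --seed 4 --out-dir demo/
mendelscope filter --scenario recessive --vcf demo/cohort.vcf --ped demo/cohort.ped
```

```
Chr1	8333333	T	A	CAUSAL1
# retained 1 of 201
```

The filter reduces 201 sites to exactly the planted causal variant
(chromosome, position, ref/alt, gene). Parentage and the karyotype scan on
the same dataset:

```bash
mendelscope kinship --vcf demo/cohort.vcf --ped demo/cohort.ped
mendelscope cnv-scan --coverage demo/coverage.tsv --windows 10000 --sex male
```

```
child	parent	pi_hat	p_ibd0	opposing	verdict
case	sire	0.500	0.000	0	parent_offspring_consistent
case	dam	0.500	0.000	0	parent_offspring_consistent
Chr1	disomy	1.000	2500	.
Chr2	disomy	1.000	2000	.
Chr3	disomy	1.001	1500	.
ChrX	disomy	0.501	2000	.
ChrY	disomy	0.499	500	.
```

π̂ = 0.5 for both recorded parent links (as expected for true
parent-offspring pairs), every autosome sits at the diploid ratio 1.0 and
the male sex chromosomes at 0.5. Catalog and coordinate queries:

```bash
mendelscope catalog count --table nosology --field category   # -> 21
mendelscope catalog rate                                      # -> 27/39 = 69.2%
mendelscope hgvs codon "c.2908G>A"                            # -> 970
```

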