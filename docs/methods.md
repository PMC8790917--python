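# Methods

## Scope and model

`driverscape` operationalizes a comparative analysis of driver genes of
cancer and of non-malignant somatic clonal expansion. It treats driver
status as a *curated* input (gene lists from canonical sources and
sequencing screens) and computes three things on top of it: a deterministic
bookkeeping of the driver repertoire, a rule-based per-sample somatic
alteration classifier, and group-level statistical contrasts of
systems-level gene properties and pathway membership. No statistical driver
*detection* is performed; that is the role of the upstream screens whose
gene lists the catalog consumes.

## Catalog curation

Genes are keyed by uppercase, whitespace-stripped symbol. Canonical-source
merging takes any number of source lists, a false-positive verdict table
(`keep_canonical` / `keep_candidate` / `remove`) and a fusion-gene
exclusion list; verdicts are curation products and are never recomputed.
The overlap histogram counts canonical genes by the number of listing
sources and partitions the canonical set by construction.

Driver-group assignment is a pure set operation and therefore idempotent
and order-independent: healthy drivers split into canonical-healthy
(also in the canonical set), candidate-healthy (reported by cancer screens
only) and healthy-only; the remaining genes into canonical-cancer and
candidate-cancer. Canonical genes never reported by any screen are flagged
*undetected* without changing their group.

Non-coding support levels codify a rule that mixes screen recurrence with
experimental evidence: level = min(screen hits, 4), raised to at least 2
when experimental evidence or canonical status exists. The source material
is ambiguous on whether evidence should imply a higher level; the codified
table reproduces every stated case while keeping the level monotone in the
number of screens.

Organ-system summaries de-duplicate genes across a system's screens, use
the conventional median (mean of the two middle values for even counts) and
Spearman rank correlation with average ranks for ties (scipy).

## Alteration classification

Rule constants live in a `Thresholds` preset; the `tcga` preset encodes:

| rule | constant |
|---|---|
| missense damaging | ≥ 7 of 10 predictor votes |
| splicing damaging | ≥ 1 of 2 method votes |
| CNV assignment | ≥ 25% of transcribed length covered |
| gain candidate | CN > 2 × sample ploidy (strict) |
| homozygous loss | CN = 0 and FPKM/purity < 1 |
| heterozygous loss | CN = 1, or CN = 0 and FPKM/purity > 1 |
| gain retention | Wilcoxon BH FDR < 0.05 and higher gain-group median |

The `cell_line` preset replaces the loss rules with ploidy-relative bands
(homozygous: CN < 0.25 × ploidy and expression < 1 TPM; heterozygous:
0.25–0.75 × ploidy) and applies no purity correction.

Numerical choices:

- Gene-level CN from multiple segments is the coverage-weighted mean over
  covered bases; the integer rules "CN = 0" and "CN = 1" are tested with a
  ±0.1 tolerance because weighted means of real segment values are
  fractional.
- "FPKM < 1 over purity" is read as FPKM/purity < 1 (purity-corrected
  expression); values exactly equal to the cutoff satisfy neither the
  deletion nor the rescue inequality and fall back to neutral.
- Hotspot precedence: a hotspot-flagged mutation is GoF even when its
  predictor votes are damaging, so LoF and GoF event tallies stay disjoint
  at the record level. A (gene, sample) pair can still hold one LoF and one
  GoF call from different evidence; both are recorded and counted once per
  category (the partition invariant `lof + gof = total` is tested).
- Double hits require heterozygous loss at CN ≈ 1 (same tolerance) plus a
  LoF damaging mutation; the call's evidence carries both the mutation
  label and `double_hit`.
- Putative TSG/OG roles follow a strict majority of *distinct* damaged
  samples per category; ties, including 0 vs 0, stay unclassified.
- Hotspot flags are expected as precomputed input. The `--naive-hotspots`
  fallback flags protein positions mutated in ≥ 3 distinct samples
  cohort-wide; it is a recurrence rule, not a positional-clustering method,
  and its calls are labelled `naive_recurrence` in the output.

### Statistical policy

All rank comparisons share one Wilcoxon implementation: exact null
enumeration when both groups have ≤ 25 observations and the pooled sample
is tie-free, otherwise the normal approximation with tie correction and
continuity correction (scipy `mannwhitneyu`). Fisher tests use scipy's
exact implementation. BH correction (statsmodels) is applied per family:
across genes for gain retention, within each property across groups for
property contrasts, across tested pathways for enrichment.

## Systems-level properties

Duplication flags genes sharing ≥ 60% of their protein sequence with any
partner; the shared fraction is expected relative to the longer protein of
the pair (the conservative denominator — the convention is not forced by
the data model and can be changed upstream of the flag). Pre-metazoan
origin is presence of an ortholog in prokaryotes, eukaryotes or
opisthokonts. Expression breadth counts tissues at TPM ≥ 1 (inclusive).
Network degree, unnormalized endpoint-excluded betweenness, and local
clustering come from networkx on a simple graph; clustering is reported as
missing for degree < 2 rather than 0, so undefined values cannot dilute
group contrasts. Germline burden is damaging variants (and separately SVs)
per coding bp. Essentiality is called per cell line (CERES or DEMETER
< −1, Bayes factor > 5, strict inequalities) and summarized both as the
fraction of lines with data and as a binary any-line flag, since group
tests on either convention are plausible.

### Normalized property score

For property *p* and group *d*, Δ_d is the median (continuous) or
proportion (categorical) difference, group minus rest. The score is the
signed min–max rescaling of |Δ| over the normalization roster; the roster
is the compared groups plus the rest-of-genes baseline, whose Δ against
itself is 0. Including the baseline anchors min |Δ| at 0, makes the score
well defined even with a single compared group, and mirrors the convention
that the background population is itself one of the scored groups. When
all |Δ| coincide the formula is 0/0 and every score is defined as 0 (no
contrast). Note that with few groups the score rescales whatever contrast
exists — a tiny but nonzero |Δ| can still attain ±1 — so scores should be
read jointly with the FDR of the underlying test.

## Pathway enrichment

One-sided (greater) Fisher tests on (in set vs rest) × (in pathway vs not),
restricted to hierarchy levels 2–8, BH across tested pathways, enrichment
at FDR < 0.05 (strict). The universe defaults to all genes carrying
pathway annotation — only annotated genes are testable — and can be
overridden. Rollup tallies enriched pathways by their level-1 ancestor;
proportions sum to 1 whenever anything is enriched. The hierarchy is a
flat child → level-1 map; cycles are rejected.

## Synthetic data

The cohort generator emulates the statistical structure the classifier
assumes, not real tumor biology. Defaults (the reference study conditions
used throughout the tests): 500 samples; 200 planted TSGs receiving
truncating mutations (p = 0.06/sample), homozygous deletions (0.04) and
heterozygous losses (0.04, enabling double hits when they coincide with a
truncating event); 200 planted OGs receiving hotspot-flagged missense at
one recurrent position per gene (0.06) and gains at CN > 2 × ploidy with
expression multiplied by e^1.5 (0.05); 1600 passengers receiving only
non-damaging background mutations (rate 0.01: "other" effects or missense
with ≤ 6 votes). Expression is log-normal FPKM with per-gene log-means
around log 10 (sd 0.7 between genes, 0.5 between samples), chosen so the
gain-retention Wilcoxon has high power at the default log-fold-change;
deleted genes are silenced to ~1% of baseline. Ploidy is Normal(2, 0.1),
purity Uniform(0.5, 0.95). Genes are non-overlapping 1 kb blocks spaced
2 kb apart on one synthetic chromosome, which keeps per-sample segments
disjoint by construction.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: mutational signatures and covariates of
mutation rate, subclonality and purity-driven CN blur, correlated
expression programs, genes with both TSG and GoF behavior across tissues,
and annotation error in the input columns. Recovery results on synthetic
cohorts measure the correctness of the rule pipeline under its stated
assumptions, not real-world driver-classification accuracy.

The property-table generator draws continuous properties from
Normal(0, 1) plus planted per-(group, property) offsets and categorical
properties from Bernoulli(0.3 + offset); offsets that push a proportion
outside [0, 1] are rejected. The catalog fixture generator constructs
source lists, screen hits and healthy lists whose classification equals a
designed count vector exactly, with emission order shuffled by seed to
exercise order independence.

All generators take a mandatory seed and are pure functions of their spec;
repeated runs are identical element-wise, and the pipeline derives
per-stage sub-seeds from one master seed.

## Problem sizes and runtime

The default verification suite runs the full cohort (500 × 2000) once
(~4 s), 100 property-table replicates for planted-effect recovery (~10 s),
an exhaustive Fisher-vs-hypergeometric sweep over all 2×2 tables with
margins ≤ 30 (~90 s), exact Wilcoxon enumeration for group sizes ≤ 5, and
betweenness/clustering oracles over every connected graph with ≤ 7 nodes.

## Known limitations

- The classifier consumes precomputed damaging-predictor votes and hotspot
  flags; it does not annotate variants.
- Gain retention tests each gene against all non-gain samples of the whole
  cohort; no per-cancer-type stratification is implemented.
- The curation module models bookkeeping only; literature review,
  abstract screening and expert reconciliation are outside its scope, as
  are fusion and epigenetic drivers.
- Organ-system mapping must be supplied as a tissue → system table; there
  is no built-in ontology.
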