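# Methods

## The burden model

The core statistic is a collapsing (gene-based burden) test for a small
case cohort against a much larger population-control cohort. Let
`x_case` and `x_control` be the counts of qualifying variant observations
in a gene (or gene set) among `n_case` cases and `n_control` controls.
Under the null hypothesis that per-subject qualifying-variant rates are
equal in the two cohorts, conditioning on the pooled total
`T = x_case + x_control` gives

    x_case | T  ~  Binomial(T, ρ),    ρ = n_case / (n_case + n_control),

and the one-sided p-value is the exact upper tail `P(X ≥ x_case)`. The
alternative is one-sided ("greater") because the scientific question is
enrichment in cases; depletion is not of interest at these sample sizes.
The enrichment rate is reported as the per-subject frequency ratio

    (x_case / n_case) / (x_control / n_control),

which is algebraically identical to the odds of the binomial proportion
estimate `x_case / T` against the null odds `ρ/(1−ρ)` (both identities
are unit-tested).

The counting unit is the qualifying variant *observation* (an
allele-bearing genotype record), not the distinct carrier: a subject with
two qualifying variants in a gene contributes 2. At the allele
frequencies involved (AF < 0.01%) carriers and observations almost always
coincide.

Multiple testing across a scan of `m` genes uses the Bonferroni threshold
`α/m` (0.05 / 17,701 = 2.8e-6 at the default scan size) for genome-wide
significance claims, with Benjamini–Hochberg step-up q-values reported
alongside for ranking. `bh_fdr` delegates to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")` and is
verified against an independent textbook step-up implementation.

Because cases and population controls are typically sequenced and
processed on different platforms, a batch-effect calibration repeats the
pooled exome-wide test on rare *synonymous* variants, a class expected to
be neutral: pooled enrichment outside the band [0.9, 1.1] raises a flag.
The band is configurable; the default brackets the ~1% deviations seen in
well-matched cohorts.

### Conservativeness of the exact test

With expected per-gene totals of order 5–10, the exact binomial test is
discrete and therefore conservative: its attained size at nominal
α = 0.001 under the default study conditions is a few 1e-4, not 1e-3.
The calibration test asserts the empirical type-I rate over 10,000 null
genes lies within three binomial standard errors of the nominal level and
never above it; the measured rate sits below nominal, as an exact
discrete test should.

## QC filters

Boundary semantics are literal complements of the exclusion rules: a
genotype fails when depth ≤ 8, allele balance ≤ 0.20, or GQ < 30, so
depth 9, AB 0.201 and GQ 30 all pass. Allele balance (alt reads / total
reads) is only meaningful for heterozygous calls; homozygous-alt calls
are exempt from the AB filter since the filter targets suspect het calls.
Site-level: missingness > 0.10, mappability < 1 (150 bp fragments), VQSR
tranche < 99.6, FILTER ≠ PASS, or position outside the capture BED
exclude. A plain PASS FILTER is treated as tranche ≥ 99.6; a
`VQSRTrancheSNP99.60to99.80`-style label yields its lower bound.
Multi-allelic records are decomposed to bi-allelic sites before
filtering; region membership is tested on the variant's 1-based start
against the half-open 0-based BED intervals, so it is invariant to how
the interval union is split. Sites whose genotype calls all fail are
retained with the failing calls set to missing — they contribute zero
carriers rather than disappearing, which keeps filtering idempotent.

## Classification

Rare: AF < 1e-4 in both of two population references, with an absent
frequency treated as 0 (an allele unseen in ~10⁵ reference subjects is
rare by any standard). LGD: stopgain, frameshift indel, canonical splice
(the 2 intronic bases at each exon boundary), exon deletion. D-mis:
missense with REVEL strictly > 0.5. In-frame indels are "other" — they do
not disrupt the reading frame and are excluded from the gene-disrupting
class. Missense with no REVEL score available cannot be called damaging
and falls to "other" with a warning rather than an error. CADD is carried
as metadata only.

## De novo expectation

A trinucleotide mutation-rate table maps (5' base, ref, 3' base, alt) to
a per-site per-generation substitution probability. For a consequence
class `c`, the expected count in a trio cohort is

    m0(c) = 2 · n_trios · Σ_{positions p, alts a : class(p,a) = c} rate(p, a),

the factor 2 counting the two transmitted genomes per trio; CpG
hypermutability enters through the context itself. `annotate_cds`
derives `class(p, a)` for an in-frame CDS by codon translation: a change
producing a stop codon before the final codon is LGD (premature
stopgain); stop-retained changes count as synonymous; stop loss is
"other". Positions lacking a flanking base (sequence edges with no
provided flank) are skipped with a logged count. Observed counts are
tested with the exact one-sided Poisson tail `P(X ≥ m1)`, `X ~
Poisson(m0)`. The published rate tables are consumed as input files and
are not reprinted here; the tests use a documented toy table (3:1
transition bias, 10× CpG elevation). Only substitutions are
rate-modelled; de novo indels are counted but carry no expectation.

Trio inheritance: de novo = child carries the alt with both parents
hom-ref; a carrying parent makes the call inherited (maternal/paternal/
biparental); a missing parent with the other hom-ref yields the standard
"<parent> or de novo" unknown. A hom-alt child with fewer than two
carrier parents is flagged as a Mendelian violation.

## Expression overlap

Per-tissue quantile ranks use pandas average-rank `rank(pct=True)`, so
they are invariant to monotone transformations of the raw values; "top
quartile" means rank quantile ≥ 0.75 (ties share the average rank — no
extra tie rule is imposed). The statistic is the count of focal genes
double-top in both tissues. The null resamples size-|focal| subsets
without replacement from the background of variant-carrying genes; the
implementation draws each subset by taking the k smallest of i.i.d.
uniform keys per permutation (an exact uniform k-subset, vectorised in
chunks). The empirical p-value uses the pseudocount rule
`(1 + #{null ≥ observed}) / (1 + n_perm)` and so is never zero; with
100,000 permutations its floor is ≈ 1e-5.

## The synthetic-data generator

The generator emulates the sufficient statistics of the analysis rather
than raw reads:

* **Cohort.** Per-gene qualifying-variant counts are independent
  Poissons: control ~ Poisson(n_control·r), case ~
  Poisson(n_case·r·multiplier). Defaults are the modelled study's
  conditions: 144 cases, 7509 controls, 17,701 genes, one planted risk
  gene at multiplier 52 with baseline rate r = 5/7509 (≈6.7e-4 per
  subject per gene) so controls show ~5 carriers — genome-wide this
  yields ~12 rare deleterious qualifying variants per subject.
  Synonymous variants are generated at 1.5e-3 per gene per subject (a
  few-fold more common than the deleterious class), with an optional
  batch-shift multiplier on the control synonymous rate. Case counts are
  expanded into annotated records (consequence ~half LGD / half missense
  with REVEL in (0.55, 1), absent population AFs) so classification
  recovers the generated counts exactly.
* **Trios.** The total event count is Poisson with mean m0(all) from the
  same rate table and coding model used for the expectation, events
  landing on (position, alt) proportional to rate — so enrichment is 1
  by construction and simulation recovers it within sampling error.
* **Expression.** Background genes get independent Uniform(0,1) values
  per tissue (double-top probability exactly 1/16); a planted signal
  boosts a fixed number round(s·|signal|) of focal genes strictly above
  the background range in both tissues, so the expected double-top
  fraction is s + (1−s)/16 and `signal_strength_for_fraction` inverts
  this.
* **QC fixtures and phenotypes.** Genotype-level sites exercising each
  filter, and an onset-stratified phenotype table whose default sex
  composition is the modelled cohort's (53 M/91 F pediatric, 24 M/88 F
  adult).

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, ancestry stratification, per-site sequencing-depth
heterogeneity between platforms, correlated gene-level mutation-rate
variation, and real expression correlation structure between tissues.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under the assumed sampling model, not
robustness to those real-data complications (the synonymous calibration
stage is the in-analysis guard for platform artifacts).

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to what
the checks need: 10,000 genes for null-scan calibration, 20 seeds for
planted-gene recovery at the 1,001-gene scale (the planted regime's
per-seed detection probability is ≈0.57 by direct computation, so a
majority over 20 seeds is the expected outcome), 100,000 permutations
for the overlap test on a 2,000-gene background, and a 10-gene ×
~1.5 kb coding model at a uniform 1e-5 rate for de novo
self-consistency (m0 ≈ 54, giving ~14% relative sampling noise on the
enrichment). Exact tails come from `scipy.stats` survival functions
(`binom.sf(k-1, ...)`, `poisson.sf(m1-1, ...)`); Fisher's exact test is
scipy's two-sided minimum-likelihood rule, cross-checked against full
hypergeometric enumeration. Genes with zero pooled counts get p = 1.
Zero control counts give an infinite enrichment rate with a valid
p-value and an explanatory note. All generators accept integer seeds and
are bit-reproducible.

## Open design points, resolved

* The attributable-fraction estimate uses the carrier-frequency
  difference `100·(x_case/n_case − x_control/n_control)` and records the
  formula name in its output; other conventions exist, and published
  figures derived from unstated formulas can differ by a few tenths of a
  percent (this regime gives ≈3.4%).
* The burden scan defaults to 144 cases; cohort sizes are explicit
  arguments everywhere, so a 143-case analysis is a parameter change,
  not a code change.
* An in-frame deletion is never auto-classified as deleterious; studies
  that include a specific in-frame variant on external evidence can pass
  it through as a pre-annotated `exon_deletion`/curated consequence.

## Known limitations

No covariate-adjusted or dispersion-robust burden tests (SKAT-style), no
ancestry inference (cases are assumed pre-subset to match the control
population), no per-gene de novo significance testing (class/set level
only), and no transcript-model resolution beyond one consequence per
variant.
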