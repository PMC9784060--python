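# Methods

## Model and procedure

`stratpgx` analyses diploid genotype dosages over candidate pharmacogene
regions, stratified by self-identified super-population (default labels
AFR, AMR, EUR, EAS, SAS). The unit of analysis is the biallelic variant:
multi-allelic VCF rows are split into one record per alternate allele on
read, and each record receives a deterministic coordinate-style ID
`<chrom>:<pos><ref>-<alt>` (no internal whitespace, so IDs are safe join
keys). Phase is discarded; every downstream statistic depends only on
allele counts, so dosages in {0, 1, 2, missing} are sufficient.

Preparation order is: trim to gene regions → per-sample call-rate filter →
annotation. Trimming before filtering matters: the call rate is evaluated
over the region-restricted variant set, so a sample is only excluded for
missingness inside the analysed regions. Regions are 1-based inclusive on
both ends; regions on the same chromosome must not overlap so that each
variant maps to exactly one gene. No coordinate liftover is performed — the
configuration declares an assembly label and mixed-assembly input is the
caller's error.

### Frequencies, allelic status, partitions

The per-population alternate-allele frequency is
`alt_count / called_count` with `called_count = 2 × non-missing samples`;
missing genotypes are excluded from numerator and denominator. With the
default 100%-call-rate filter this exclusion is moot, but the module is
correct standalone on incomplete matrices (zero-called cells report
frequency 0 and are flagged).

Allelic status uses an **inclusive** cut-off, `frequency ≥ 0.01`: the
governing phrasing for the threshold is "1% or more", and inclusivity is
applied uniformly. The partition profile covers only variants passing
overall allelic status; within that set, "presence" in a population means
`alt_count > 0` (observed at least once). This reconciles the ≥1% gate on
the profiled set with presence/absence semantics of intersection
(UpSet-style) analysis. Each profiled variant belongs to exactly one
partition, so partition counts sum to the allelic total; per-population
"containing-partition" totals (sum over partitions containing the
population) are reported alongside.

### Exact association testing

For each variant and comparison population, the 2×2 table rows are
(reference population, comparison population) and columns (alternate,
reference allele counts). Populations with zero called alleles yield an
UNTESTABLE marker rather than an error. The two-tailed p-value is the
conventional exact two-sided test: the sum of hypergeometric point
probabilities, over all tables with the observed margins, that do not
exceed the observed table's probability. Point probabilities are computed
in log-space (`gammaln`) and ties are admitted within relative tolerance
1e−12. Degenerate column margins (the alternate allele observed in neither
or both-fully) admit a single table and return p = 1.

The reported odds ratio is the sample cross-product ratio `ad/bc` — the
unconditional MLE for a 2×2 table — with no Haldane/continuity correction:
a zero cell yields 0 or ∞, both still classifiable as "lower/higher in the
reference population"; `0/0` is undefined and carries no direction.

Bonferroni correction is grouped per (gene, comparison population):
`m` = testable variants in the group, significance is the strict
`p < α/m`, α = 0.05. Tests are computed for **all** variants and
cross-filtered by allelic status downstream, matching a report layout with
separate allelic and significant columns; an alternative grouping
(`m` = allelic testable variants only) is a configuration switch
(`bonferroni_mode: allelic`). Direction is assigned only to significant
results (OR > 1 ⇒ higher in reference).

### Consensus deleteriousness and clinical subsets

SIFT (lower = deleterious) and PolyPhen (higher = deleterious) are inputs,
never recomputed. The consensus score is the weighted complementary
average `(w_s(1−s) + w_p·p)/(w_s+w_p)`; the full published CONDEL instead
weights algorithms by score distributions over validated
deleterious/neutral sets, which needs external training data, so this
package exposes per-algorithm weights (defaults 0.5/0.5) and a consensus
cut-off (default 0.522, the published CONDEL threshold) as configuration.
Per-algorithm deleterious flags default to SIFT < 0.05 and
PolyPhen > 0.446 (conventional thresholds; configurable). Degree of
support counts deleterious calls among {SIFT, PolyPhen, consensus}:
singleton/doubleton/consensus, with `none` naming the zero-support class;
when a score is absent the count runs over available flags and the
denominator is recorded.

A variant is **novel** when it matches neither the rsID table nor the
effect-score table. Novel variants are reported with position, alleles and
consequence class; a missing consequence is labelled `mapping_failure`.

The clinical subset requires (1) evidence — phenotype association and/or a
computable consensus score; whether these combine by OR (default) or AND
is a configuration switch, since either reading of "both … were
considered" is defensible — and (2) allelic status in ≥ 1 population and
(3) a significant frequency difference vs ≥ 1 comparison population.
Per-population higher/lower markers relative to the reference are emitted
only for the significant comparisons.

## The synthetic cohort generator

The generator emulates a stratified candidate-gene cohort: per variant and
population a true alternate-allele frequency is fixed, and each sample's
dosage is Binomial(2, p) — Hardy–Weinberg equilibrium — with optional
independent missingness. The demo specification mirrors the emulated
study's conditions: population sizes 1992/347/503/504/489 and per-gene
variant totals 413/1586/2469 for CYP2A6/CYP2B6/UGT2B7, both multiplied by
a single scale factor; gene regions default to the bundled GRCh38-style
coordinates. Site frequencies follow a rare-skewed Beta(0.3, 2.5) base,
with 35% of sites receiving independent per-population logit perturbations
(sd 1.0) and 12% private to one population at 1–12% frequency — chosen
once as a realistic mix of shared, differentiated and population-private
variation for continental-scale panels. The annotation fixture assigns
rsIDs to a configurable known fraction (default 0.8), SIFT/PolyPhen scores
to 60% of known variants (deleterious fraction drawn from SIFT < 0.04,
PolyPhen > 0.7 ranges), and curated phenotype strings (including
antiretroviral-metabolism terms) to 30%.

What the generator does **not** emulate: linkage disequilibrium between
sites (no downstream statistic uses it), admixture or within-population
structure, genotyping error and platform-specific missingness patterns, or
realistic site-frequency spectra from demographic history. Passing tests
therefore demonstrate correctness of the counting, testing and selection
machinery under idealised HWE sampling — not robustness to structure or
differential genotyping quality in real consortium data.

Reproducibility: `numpy.random.SeedSequence(seed)` is spawned into one
child stream per concern (genotypes, missingness; annotations derive a
separate sequence from the cohort seed and the annotation seed), so each
stage's draws are independently reproducible and identical specs give
byte-identical cohorts.

## Numerical and reporting choices

- Exact-test tie tolerance: point probabilities within a relative 1e−12 of
  the observed table's probability count as "at least as extreme".
- `p < α/m` and `frequency ≥ cutoff` are deliberately strict/inclusive as
  stated; boundary cases are covered by tests.
- Percentages in reports are printed to 2 decimals with half-up rounding.
- UpSet export orders partitions by descending count with lexicographic
  population-set tie-breaks, making output byte-deterministic.
- Degenerate inputs: empty matrices pass through trimming; a filter that
  removes every sample returns an empty matrix with a warning (not an
  error); zero-called frequency cells report 0 and are flagged; undefined
  odds ratios (0/0) propagate as missing.

## Problem sizes in the shipped checks

The test-suite and the acceptance script scale the study conditions so a
run completes in minutes on one core, as the package's own default desk
scale: the exact-test oracle sweep covers the symmetry-reduced set of all
margin configurations ≤ 60 (row/column-swap invariance is asserted
separately, so coverage of the full set follows); null calibration uses
1000 equal-frequency variants over 50 gene groups × 4 comparisons of 120
samples per population; power uses 200 replicates at 500 samples per
population; frequency recovery uses 300 variants × 5 populations at 500
samples; the acceptance pipeline run uses a quarter-scale cohort
(959 samples, ~1100 variants).

## Known limitations

- Region sizes are `stop − start`; for one of the three bundled regions
  this differs from an externally printed size (61,824 vs 61,624 bp for
  the UGT2B7 coordinates). The subtraction rule is kept because it is
  consistent for the other two regions and is the only rule derivable from
  the coordinates themselves.
- Indels are processed identically to SNVs; no left-alignment or
  normalisation beyond multi-allelic splitting is attempted.
- The reported frequency is always the VCF alternate-allele frequency,
  also when it exceeds 50%; no major/minor allele folding.
- Haplotype (star-allele) strings are pass-through annotation; no
  diplotype calling. No admixture analysis; population labels are taken
  from the manifest as-is.
- Phenotype matching is exact-string on the curated terms in the local
  annotation table; no ontology expansion.
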