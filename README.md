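# stratpgx

Population-stratified pharmacogenetic variant analysis for candidate-gene
cohorts.

## The problem

Drug-metabolising enzymes such as CYP2A6, CYP2B6 and UGT2B7 — the primary
metabolisers of the antiretrovirals Efavirenz and Nevirapine — are highly
polymorphic, and the frequency of function-altering variants differs sharply
between continental populations. Prescription guidelines calibrated on
European-ancestry reference panels can therefore misjudge expected drug
response in African populations, where HIV treatment is most widespread and
genomic reference data are scarcest. `stratpgx` is for researchers who have
multi-population genotype data over candidate pharmacogene regions and want
to ask: *which variants are common in at least one population, how is variant
presence shared across populations, which variants sit at significantly
different frequencies relative to an African reference, and which of those
carry clinical or deleteriousness evidence?*

## The method

Given a multi-sample VCF, a sample→super-population manifest
(AFR/AMR/EUR/EAS/SAS), a gene-region table and a local annotation table
(dbSNP-style rsIDs + SIFT/PolyPhen scores + phenotype strings), the pipeline:

1. **Prepares** the cohort: trims variants to the gene regions, removes
   samples below a 100% genotype call rate, renames variants to
   coordinate-style IDs (`chr19:40849872C-T`) and attaches annotations.
2. **Profiles frequencies**: per population *P* and variant *v*,
   `f(v,P) = alt_count / (2 · called samples)`. A variant is **allelic**
   when `f ≥ 0.01` in ≥ 1 population; allelic variants are partitioned by
   the exact subset of populations in which the alternate allele was
   observed (UpSet-style intersection analysis).
3. **Tests associations**: for each variant and comparison population a
   2×2 allele-count table against the reference population (AFR) is tested
   with a two-tailed Fisher exact test (hypergeometric enumeration in
   log-space, implemented here), with the sample odds ratio `ad/bc` and
   Bonferroni correction per (gene, comparison population) group:
   significant ⇔ `p < α/m`, α = 0.05.
4. **Predicts effects**: a consensus deleteriousness score
   `c = (w_s(1−SIFT) + w_p·PolyPhen)/(w_s+w_p)` (CONDEL-style, cut-off
   0.522), degree of support (singleton/doubleton/consensus over the three
   deleterious calls), novelty flags (no rsID and no effect scores), and the
   clinical subset: phenotype/consensus evidence ∧ allelic ∧ significantly
   different frequency vs ≥ 1 population.

A synthetic cohort generator (`stratpgx.synthetic_data`) draws
Hardy–Weinberg genotypes from known per-population frequencies, mirroring
the emulated study's population sizes (1992 AFR / 347 AMR / 503 EUR /
504 EAS / 489 SAS) and per-gene variant totals (413/1586/2469), so every
stage can be validated against a ground truth.

## Worked example

Simulate a cohort at 10% of the study scale and run the pipeline:

```bash
stratpgx simulate --out-dir demo --scale 0.1 --seed 1
# simulated 383 samples x 447 variants -> demo

cat > demo/config.yaml <<EOF
vcf: demo/cohort.vcf
manifest: demo/manifest.tsv
regions: demo/regions.tsv
annotations: demo/annotations.tsv
out_dir: demo/out
EOF
stratpgx run --config demo/config.yaml
# pipeline complete: 447 variants, 383 samples -> demo/out
```

`demo/out/gene_summaries.tsv` then begins:

```
gene    variants_identified  allelic_count  significant_count  sig_AMR  sig_pct_AMR ...
CYP2A6  41                   35             7                  3        7.32
CYP2B6  159                  132            32                 7        4.40
UGT2B7  247                  192            41                 9        3.64
TOTAL   447                  359            80                 19
```

Per gene: how many variants were found in its region, how many reached the
1% allelic cut-off in ≥ 1 population, how many differ significantly in
frequency from the African reference in ≥ 1 population (then per-population
counts, percentages of the gene total, and odds-ratio direction counts).
`partitions.tsv` shows variant sharing — here 192 allelic variants (53.5%)
were observed in all five populations — while `novel_variants.tsv` (89
variants with no annotation match, by construction ~20% of the simulated
sites) and `clinical_subset.tsv` (43 variants with clinical evidence at
significantly different frequencies) mirror the novelty and
clinical-interest reports. Outputs also include the frequency table,
association results (2×2 cells, p, OR, m, direction), effect predictions
and an UpSet-ready membership matrix.

The library API mirrors the pipeline stages
(`compute_frequencies`, `allelic_status`, `partition_profile`,
`run_association`, `predict_effects`, `select_clinical_subset`); see module
docstrings.

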