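# proxyhap

Tools for linking causal flowering-time alleles to genotyping-array
markers in soybean germplasm, and for the downstream analyses that use
those links: geographic distribution of allele combinations and
reproductive-timing field phenotypes.

## The problem

Causal flowering-gene mutations — such as the *e1-as* allele of *E1* or
the K82E missense allele of *E1La* — are known only in accessions with
whole-genome resequencing data. Most germplasm-bank accessions instead
carry ~50k-marker array genotypes (SoySNP50k-style). To study where a
causal allele occurs across thousands of accessions, one selects a
**proxy SNP**: an array marker whose alleles travel with the causal
haplotype, scored on a resequenced panel where both are observed.

The association score is the **combined pessimistic accuracy**. For a
marker and a causal site, over *N* panel accessions:

```
accuracy = 100 × (n_correct_WT + n_correct_MUT) / N
```

where an accession counts as *correct* only if both calls are
homozygous and non-missing and the marker allele maps to the causal
allele under the chosen REF/ALT ↔ WT/MUT orientation (taken as the
orientation that maximises accuracy). Heterozygous or missing calls
never count in the numerator but always in the denominator — the
"pessimistic" rule, which folds sensitivity, specificity and missing
data into one number. The top-scoring marker within 1 Mbp of the
causal site becomes the proxy; its homozygous array calls are then
imputed to WT/MUT causal alleles in array-only accessions
(heterozygous/missing calls are excluded).

Downstream, accessions are grouped by their two-locus allele
combination and summarised: mean latitude per group with compact-letter
significance groups (one-way ANOVA, Fisher's LSD on the pooled MSE,
Benjamini–Hochberg FDR at α = 0.05), country-of-origin frequencies, and
plot-ready coordinate tables (groups capped at 200 by random
downsampling, ±0.4° jitter). A phenology module handles replicated
field trials: days-after-planting arithmetic, frost censoring of
maturity (R8), test-minus-control deltas of days to flower and days to
maturity, and vegetative/reproductive phase partitioning.

A synthetic-data module generates panels, array matrices, geographic
metadata, and plot-level phenology with known ground truth, so every
stage is testable without external data.

## Worked example

Simulate a 100-accession panel with one marker planted at haplotype
concordance 0.94 (background 0.70, 2% missing array calls), then scan
the 1-Mbp window around the causal site:

```sh
$ proxyhap simulate panel --config panel.yaml --seed 3 --out sim
$ proxyhap select --vcf sim/panel.vcf --array sim/array.tsv \
      --causal causal.yaml --out ranked.tsv
best proxy for e1la:K82E: sim002 (accuracy 93.0%, REF<->WT, 1000 bp away)

$ head -3 ranked.tsv
marker_id  chrom  pos       distance_bp  orientation  n_correct_wt  n_correct_mut  n_total  accuracy_pct
sim002     Gm04   28295378  1000         REF<->WT     64            29             100      93.0
sim001     Gm04   28289378  5000         REF<->WT     51            21             100      72.0
```

The planted marker ranks first. Its accuracy (93.0%) sits below its
planted concordance (94%) because the 2% missing array calls count
against it — exactly the pessimistic rule. The orientation column says
the marker's REF allele travels with the wild-type causal haplotype, so
`impute_causal` maps REF-homozygous array calls to WT; 64 accessions
were correctly WT-associated and 29 correctly MUT-associated out of
100 scored.

The library surface mirrors the CLI: `simulate_panel`, `scan_window`,
`select_proxy`, `impute_causal`, `assign_combinations`,
`latitude_summary`, `censor_at_frost`, `group_delta`, and friends — see
the module docstrings.

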