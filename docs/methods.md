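# Methods

This note documents the models, conventions and numerical choices
behind `proxyhap`, and what the synthetic-data tests do and do not
establish about real data.

## Data model

Diploid genotypes are collapsed to four states — `REF_HOM`, `ALT_HOM`,
`HET`, `MISSING` — throughout. Inbred soybean germplasm is almost
entirely homozygous, so the collapse loses nothing the analyses need.
Positions are 1-based inclusive (VCF convention); chromosome names are
exact strings. On an array matrix, REF/ALT are taken from the matrix
header and never re-derived; how they map onto a causal site's WT/MUT
alleles (the *orientation*) is resolved by the concordance scorer.

## Combined pessimistic accuracy

For proxy-call vector *p* and causal-call vector *c* over *N*
accessions, and an orientation *o* ∈ {REF↔WT, REF↔MUT}:

* correct-WT: *pᵢ* homozygous for the allele that *o* maps to WT, and
  *cᵢ* = WT-homozygous;
* correct-MUT: symmetric;
* accuracy(*o*) = 100 · (#correct-WT + #correct-MUT) / *N*.

The reported result uses the orientation with the higher accuracy,
ties broken to REF↔WT. Design choices, with rationale:

* **Heterozygous and missing calls count in the denominator and never
  in the numerator.** The statistic is meant to be pessimistic and to
  absorb missing data; treating HET as incorrect is the conservative
  reading and matches the later imputation rule, which only accepts
  homozygous proxy calls.
* **The denominator is every accession in the intersected panel**, even
  when the causal call itself is missing — a marker cannot score well
  on a panel it cannot be validated on.
* **Window rule:** markers on the causal chromosome with
  |pos − causal| ≤ 1,000,000 bp inclusive. Ranking is accuracy
  descending, then distance ascending, then position ascending, so ties
  are deterministic.

Imputation maps REF_HOM/ALT_HOM through the selected proxy's
orientation to WT/MUT; HET and MISSING accessions are dropped with a
logged reason and surface in an exclusion table.

## Group comparisons

One-way fixed-effects ANOVA with the pooled mean-square error exposed;
Fisher's (protected) LSD pairwise t statistics use that MSE and the
within-group degrees of freedom; raw p-values are Benjamini–Hochberg
adjusted (the conventional FDR method in the R workflows this
reproduces); α defaults to 0.05. Letters come from the
insert-and-absorb compact-letter-display algorithm, which is a faithful
encoding by construction: two groups share a letter iff their adjusted
p ≥ α. Letters are assigned a, b, c, … with the highest group mean
lettered "a", the common agronomy convention. The field design these
trials use is a randomized complete block, but the analysis is plain
ANOVA + LSD without a block term, matching how such trials are commonly
reported; adding a block term would shrink the MSE and is a possible
extension. Zero-variance degenerate data (MSE = 0) are handled by
declaring pairs significant iff their means differ, with a
`degenerate` flag on the result.

Welch's unequal-variance t (Satterthwaite df) is provided for
two-group contrasts of per-plot derived quantities such as the percent
of life span spent in the reproductive phase.

## Geography

Accessions resolved at both causal loci are labelled with one of four
allele combinations (e.g. "E1 / e1la:K82E"); unresolved accessions are
dropped and logged. Latitude summaries (group mean °N, letters) always
use the full record set. Two plotting-only transforms never feed back
into statistics: seeded downsampling of groups above a cap
(default 200, reduced to exactly the cap without replacement) and
seeded uniform coordinate jitter (default ±0.4°, applied independently
to latitude and longitude, originals kept alongside). The jitter
magnitude is a visual-separation choice — large enough to separate
accessions geocoded to the same province centroid, small on a
continental map. Country frequencies report missing country as
"Unknown". Geocoding is out of scope: a user-supplied offline
state/province → (lat, lon) lookup TSV fills missing coordinates, which
keeps runs reproducible without network calls.

## Phenology

Days after planting (DAP) is the whole calendar-day difference with
planting = day 0; the packaged trial dates validate this convention
(planting 2019-05-31 → first frost 2019-10-12 = day 134; 2020-06-01 →
2020-10-16 = day 137). One transcribed report value ("day 152" for a
2018-10-16 frost from 2018-05-15 planting, which is 154 calendar days)
does not match this arithmetic; the packaged table keeps the printed
value and the discrepancy is noted here rather than silently
corrected.

Frost censoring assigns the frost DAP to any plot without a recorded
R8 and flags it censored; a recorded R8 after the frost day is
rejected as inconsistent input. Censoring is idempotent. Group deltas
(ΔDTF, ΔDTM) are test-minus-control means rounded half away from zero
to one decimal for report tables; raw means are retained. Phase
partitioning takes vegetative = mean R1, reproductive = mean R8 − mean
R1, percentages of mean R8; groups containing censored plots carry a
caveat flag because their reproductive phase is truncated at frost and
understates the true length.

## Synthetic data

The generators define the study conditions for every stochastic test.

* **Panel** (`simulate_panel`): each accession draws a causal allele
  (Bernoulli at `causal_maf`); each marker copies the accession's
  causal state with probability equal to its planted concordance and
  flips otherwise, under a planted REF↔WT orientation. Accessions are
  simulated fully inbred and then array calls are corrupted to MISSING
  / HET by a single categorical draw at the requested rates.
  Corruption applies to array-marker calls only; the causal-site calls
  emulate curated resequencing genotypes and stay clean — so the
  expected accuracy of a marker with concordance *q* and call rate
  (1 − miss − het) is *q* · (1 − miss − het). The truth record stores
  each marker's realized concordance counted on the pre-corruption
  haplotypes, which is what the planted-vs-realized binomial invariant
  refers to. There is no recombination or LD-decay model: the point is
  a controllable accuracy surface, not population-genetic realism, so
  passing recovery tests shows the scorer finds the best marker under
  the stated noise, not that 94%-accurate proxies exist in any given
  real panel.
* **Geography** (`simulate_geography`): per-group normal latitudes
  around planted means (default scenario plants the wild-panel cline:
  36.1 °N for the double wild-type group, 51.4 and 55.0 °N for the
  single-mutant groups, sd 3°), weighted country draws, and a
  configurable missing-country fraction. Real passport coordinates are
  not normal within groups; the simulation only supports mean/letter
  recovery checks.
* **Phenology** (`simulate_phenology`): group means for (R1, R8) plus
  independent normal replicate noise, `n_lines` × `n_reps` plots per
  group (defaults 5 × 3, the replication structure of a small RCBD
  trial); a plot whose simulated R8 exceeds the frost day is emitted
  with R8 missing for downstream censoring. R8 is floored at R1 so
  maturity never precedes flowering. No year, block or line random
  effects are modelled.

All generators are seeded (`numpy.random.default_rng`) and
byte-reproducible.

## Problem sizes

The simulation studies use panels of 500 accessions × 5 markers
(100 replicates) for proxy recovery, 1,000 random grouped datasets for
letter-display fidelity and null error-rate checks, 50 accessions per
group for cline recovery, and a 100-codon gene for the exhaustive
variant-classification check; these sizes give binomial/SE margins
comfortably tighter than the assertions while keeping the default test
run fast.

## Known limitations

* No phasing, multi-allelic sites, or r²/D′ LD statistics; proxies are
  single markers, not haplotypes.
* Variant classification handles substitutions only (no indels or
  splice effects); start-codon loss is reported as missense at
  position 1.
* The latitude letters use all records, not the downsampled plotting
  set; with very unbalanced groups the two could differ.
* Published panel-scale accuracies (94.1% / 92.0% on a 775-accession
  panel) require the external resequencing and array data and are not
  recomputed here; the desk-scale stand-in is seeded parameter
  recovery at planted concordance 0.94.
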