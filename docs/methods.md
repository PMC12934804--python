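# Methods

## The problem

Somatic mutations accumulate in normal (non-cancerous) human tissues
throughout life. Many mutagenic mechanisms leave a recognizable footprint:
a short sequence context (a *mutational motif*) in which they
preferentially create a specific base substitution. Examples are
spontaneous deamination of methylated CpG (C→T in `nCg`), UV photoproducts
(C→T in `yCn`), small-epoxide / S_N_2 electrophiles (T→C in `aTn`) and
APOBEC cytidine deaminases (C→T and C→G in `tCw`). `motifload` measures,
per sample, whether mutations are statistically over-represented in such
motifs and converts the excess into an interpretable mutation count.

## The core statistic

For a sample's SNV catalogue and a motif (written pyrimidine-canonical,
the mutated base uppercase — e.g. `aTn→aCn`) four counts are formed:

* `mut_in_motif` — mutations matching the full motif on either strand;
* `mut_in_class` — mutations of the motif's substitution class (e.g. all
  T→C together with their reverse complement A→G);
* `ctx_motif`, `ctx_center` — occurrences of the lowercase motif pattern
  (`atn`) and of the mutated base alone (`t`) in the ±20 bp windows around
  the sample's mutations, counted on both strands with overlaps.

The enrichment ratio compares the observed in-motif fraction to the
fraction expected from local sequence composition:

```
enrichment = (mut_in_motif × ctx_center) / (mut_in_class × ctx_motif)
```

Over-representation is tested one-sided by Fisher's exact test on
`[[mut_in_motif, mut_in_class − mut_in_motif], [ctx_motif, ctx_center −
ctx_motif]]`, and p-values are Benjamini–Hochberg corrected across all
samples of the run, within each motif. Samples passing the gate
(enrichment > 1 and q ≤ 0.05) receive a **Minimal Estimate of Mutation
Load**:

```
MEML = mut_in_motif × (enrichment − 1) / enrichment
```

which is the in-motif count minus its random-mutagenesis expectation.
All other samples are recorded with MEML = 0. *Complex* mutations — calls
≤ 10 bp apart within a sample, candidate single multi-base events — are
removed before any counting.

### Why "minimal", quantitatively

Writing ρ = `ctx_motif`/`ctx_center` for the context fraction, MEML equals
`mut_in_motif − ρ·mut_in_class`. If a process injects `n` genuinely
in-motif mutations on top of background, those mutations also enlarge the
class denominator, so the expected MEML is `(1 − ρ)·n`, not `n`: the
estimator is biased low by about the context fraction. For a trinucleotide
motif with one constrained flank, ρ ≈ the frequency of the constraining
base (≈ 0.2–0.3 in practice). This is a property of the statistic, not an
implementation artifact, and it motivates the design of the recovery
benchmark below.

### Context accumulation

Context windows are summed over **all** (complex-excluded) mutations of
the sample, not only mutations of the motif's substitution class: the
windows stand in for the sequenced-and-callable part of the genome, which
is the same territory regardless of which substitution is being scored.
`class_windows=True` restricts the sums to same-class windows for
sensitivity analysis. The central base of each window contributes to the
single-base context count (the window is defined around it). Windows at
contig edges are truncated, never padded or dropped; overlapping windows
of nearby mutations are counted independently; `N` bases never match any
pattern position but do not invalidate a window.

## Motifs and sub-motifs

The built-in registry holds eleven knowledge-derived motifs (`aTn`, `yCn`,
`nCg`, `nTt`, `tCw→tTw`, `tCw→tGw`, `tgC`, `hTg`, `aCy`, `gCn`, `cTg`),
four sub-motifs used to disentangle overlapping mechanisms (`aTr` — the
part of `aTn` that excludes the minor-UV `nTt` context; `rCg`/`yCg` — the
CpG motif split by whether UV dimers are possible at the 5′ side; `yCh` —
UV-compatible but CpG-free), the combined APOBEC motif `tCw` (C→T | C→G)
and the APOBEC3A/3B tetranucleotides `ytCa`/`rtCa`. Motifs are stored
pyrimidine-canonical; matching reverse-complements internally, so a
forward A→G call can satisfy `aTn`. The registry is user-extensible from
a TSV (name, ref_pattern, mutant_bases).

The `aCy` motif is implemented as C→T within `aCy` (the S_N_1-alkylation
mechanism); published tabulations of this motif print the reference and
mutant triplets inconsistently, and the implementation follows the
substitution named by the motif's correlation label `aCy→aTy`.

## Clusters and APOBEC dissection

APOBEC attacks single-stranded DNA, producing runs of same-strand C (or
G) mutations with inter-mutation distances of roughly 10–10⁴ bp. Clusters
are called as maximal runs of same-contig mutations with every consecutive
gap ≤ `max_imd` (default 10⁴ bp; a p-value-based caller is intentionally
out of scope, and the ~10 bp lower bound is enforced by the prior complex
exclusion). Coordination labels: all-G or all-C reference bases →
GC-coordinated; all-A or all-T → AT-coordinated; mixed → non-coordinated.

The enrichment machinery is then applied per mutation category — all
GC-coordinated clusters, size strata {2, 3, ≥4} (the published stratified
analyses do not print their bins; ours are configurable), scattered
mutations, genome-wide — and APOBEC3A-like (`ytCa`) vs APOBEC3B-like
(`rtCa`) enrichment is compared with the classic Breslow–Day chi-square
test of odds-ratio homogeneity against the Mantel–Haenszel common odds
ratio (Tarone's adjustment available by flag, off by default). The
comparison row is emitted when both motifs are individually significant
by one-sided Fisher; the two count tables are always reported so the
homogeneity test can be run unconditionally where appropriate.

APOBEC candidacy is a *report*, not a hard filter: significant combined
`tCw` MEML, the balance of `tCw→tTw` vs `tCw→tGw` inside GC-coordinated
clusters, and GC-coordinated cluster prevalence are tabulated per sample
with thresholds left to the analyst.

## Cohort statistics

MEML values are averaged per donor (means including and excluding zeros
are both reported; age correlations use the zero-inclusive mean). Donors
are binned into fixed age terciles [0, 33.3], (33.3, 66.7], (66.7, 100]
years — printed boundaries, not data-driven quantiles; ages above 100 go
to T3 with a warning. Healthy vs diseased donors are compared per study ×
tercile × disease × motif with a two-sided Wilcoxon rank-sum test
(`scipy.stats.mannwhitneyu(method="auto")`, matching R `wilcox.test`
defaults: exact distribution for small tie-free groups, otherwise the
normal approximation with tie correction), BH-corrected across the
emitted rows. Two-sidedness is deliberate: disease effects in both
directions are of interest, and the direction is read off the group
medians. Clock-like behaviour is assessed by Spearman correlation
(average ranks, two-sided p) of donor-mean MEML with age, and jointly by
OLS of motif MEML on age plus one indicator per disease against the
healthy baseline. Single-cell MEML counts are prorated to genome-wide
estimates by the sample-specific multiplier `estimated_snvs /
identified_mutations`.

96-channel pyrimidine-canonical trinucleotide profiles and cosine
similarity are provided as QC plumbing (COSMIC-signature refitting itself
is out of scope).

## The synthetic-data generator

`make_genome` draws an i.i.d. sequence from a chosen base composition;
`cpg_factor` rescales P(G | previous C) through a first-order Markov
adjustment (0 removes CpG entirely). `make_catalog` mixes uniform
background substitutions with motif-targeted processes: sites matching
the motif's reference pattern on either strand are sampled without
replacement (matching the enrichment model's null of position
exchangeability within context), and the motif's substitution is applied
on the matched strand. Processes run in fixed-count or per-year-rate mode
(rate × age × disease multiplier, Poisson-sampled), and a configurable
fraction of a process's mutations is laid down as same-strand runs within
a bounded span, with members spaced ≥ 11 bp so injected clusters survive
complex exclusion. `make_cohort` derives per-sample seeds from the master
seed deterministically; identical seeds give byte-identical FASTA, MAF,
metadata and truth outputs.

What the generator does **not** emulate: chromatin / replication-timing
covariates, sequencing error, copy number, indels, and regional coverage
bias. Passing tests therefore demonstrate the correctness and calibration
of the statistics under their own model assumptions, not robustness to
every artefact of real catalogues.

## Validation designs and their rationale

The validation suite (and `scripts/acceptance.py`) uses deliberately
sized simulations; all run on one CPU in a few minutes.

* **Fisher oracle.** The one-sided p (implemented as the hypergeometric
  survival function) is compared against exact integer-arithmetic tail
  enumeration for every 2×2 table with grand total ≤ 60 (635,376 tables);
  agreement is ~4×10⁻¹⁶.
* **Null FDR.** 200 background-only samples (500 SNVs each, 2 Mb genome)
  across all 18 registry motifs: the fraction of sample × motif rows with
  MEML > 0 stays below 7% (observed: ~0%) — the BH gate controls false
  MEML under the global null.
* **Parameter recovery.** 50 replicate samples with a 40-mutation `aTn`
  excess over a 300-SNV background, enrichment ≈ 3. Because the expected
  recovery is (1 − ρ)·n (see above), the benchmark genome uses gene-rich,
  GC-rich composition (A=T=0.20, C=G=0.30, ρ = 0.20) so that the
  estimator's intrinsic bias (−20%) is separated from estimation error;
  median recovery is ~0.78 of the injected excess.
* **Strand symmetry.** Reverse-complementing the genome while flipping
  every record to the other strand leaves all counts, statistics,
  coordination labels and the 96-profile exactly unchanged.
* **Clock-like recovery.** 20 donors aged 20–80 with a 2/year CpG-like
  process: Spearman ρ ≈ 0.95, q ≈ 10⁻¹⁰.
* **Cohort comparison.** Power: a 3× disease multiplier in 8 vs 8
  age-matched tercile-3 donors is detected at q ≈ 10⁻³. Calibration: 200
  null replicates with all 24 donor ages drawn i.i.d.; the p-values are
  approximately uniform (KS ≈ 0.07–0.11). Two design notes matter here:
  groups of 12 keep the exact rank-sum test's discreteness (intrinsic KS
  deviation 0.045 at 12v12, 0.081 at 8v8) below the sanity band, and the
  ages must be i.i.d. because an age-*matched* grid combined with a
  clock-like process makes the rank-sum test conservative (the pooled
  values are exchangeable only within age pairs, which narrows the null
  distribution of the rank sum — a caveat that applies equally to real
  age-matched cohorts).
* **Cluster recall.** 50 injected same-strand runs (span ≤ 2 kb, two
  motifs giving GC- and AT-coordinated truth) across 25 replicate 4 Mb
  genomes: 100% recalled with correct labels. The genome is sized so that
  chance adjacency between independent runs (which merges clusters and
  scrambles labels) is rare.
* **Breslow–Day calibration.** 2000 replicates of two strata with a
  common odds ratio of 2 (n = 200 per arm): rejection rate 4.6% at
  α = 0.05. A `ytCa`-restricted deamination simulation yields `ytCa`
  enrichment ≫ `rtCa` with Breslow–Day p ≈ 10⁻⁶¹; placing `tCa` mutations
  irrespective of the −2 base gives non-concentrated Breslow–Day p.

## Numerical and engineering choices

* Coordinates are 0-based internally only at the string-slicing boundary;
  every public surface is 1-based (MAF/VCF convention).
* Degenerate Fisher margins give p = 1; a zero enrichment denominator
  yields an `undefined_enrichment` status with MEML 0 rather than an
  error (sparse classes are legitimate in WES catalogues).
* BH families: per motif across samples by default, `global` available;
  α = 0.05 by default, exposed as a parameter.
* Duplicate calls within a sample are collapsed on load; cross-sample
  overlap removal within a donor (highest-VAF wins, stable first-sample
  fallback with a warning) is an explicit I/O-stage step, never applied
  silently.
* Every filtering rule (non-SNV, duplicate, reference mismatch, complex
  exclusion, cross-sample duplicate) increments a named counter on the
  catalogue for auditability.
* All randomness flows through explicit integer seeds; per-entity seeds
  are derived by seeding a `SeedSequence` with (master, entity indices).

## Known limitations

* Cluster calling is a simple maximal-run rule; it does not model local
  mutation rate and will merge independent events in extreme hypermutated
  samples.
* The rank-sum comparison is conservative for age-matched groups when the
  motif process is clock-like (see above); the regression interface
  (`regress_age_disease`) is the appropriate tool in that setting.
* MEML is a minimum estimate by construction (bias ≈ −ρ·n for a true
  excess n); comparisons of MEML across motifs with very different
  context fractions should account for this.
* WES-scale catalogues (tens of mutations) often leave enrichment
  undefined or unpowered for rare motifs; rows are flagged, not dropped.
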