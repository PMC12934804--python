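# motifload

Motif-centered analysis of somatic mutagenesis in normal tissues:
per-sample enrichment of knowledge-based mutational motifs, a
statistically gated **Minimal Estimate of Mutation Load (MEML)**,
sub-motif disambiguation of overlapping mechanisms, strand-coordinated
mutation-cluster (kataegis) and APOBEC3A/3B dissection, and cohort-level
age/disease statistics — plus a fully deterministic synthetic mutation
catalogue generator so everything is testable without any data download.

## Who this is for

Researchers with per-sample somatic SNV catalogues (MAF or VCF) from
whole-genome or whole-exome sequencing of normal or diseased tissue who
want to ask: *which known mutagenic processes are active in each sample,
how many mutations does each process account for, and how does that load
vary with donor age and disease?*

## The statistic

A mutational motif is a short IUPAC pattern with one designated mutated
base, written pyrimidine-canonical (e.g. `aTn→aCn` for small-epoxide
mutagenesis, `nCg→nTg` for spontaneous meCpG deamination, `tCw→tTw|tGw`
for APOBEC). For a sample × motif pair:

```
enrichment(aTn→aCn) = [Mutations(aTn→aCn) × Context(t)] / [Mutations(T→C) × Context(atn)]
```

where the Context terms count the motif pattern and the mutated base in
the ±20 bp around each of the sample's mutations, on both strands.
Over-representation is assessed by a one-sided Fisher exact test with
Benjamini–Hochberg correction across samples; significant samples
(enrichment > 1, q ≤ 0.05) get

```
MEML(aTn→aCn) = Mutations(aTn→aCn) × (enrichment − 1) / enrichment
```

and every other sample gets MEML = 0. Mutations ≤ 10 bp apart ("complex")
are excluded first. See `docs/methods.md` for the full model, the cluster
and Breslow–Day machinery, and the validation designs.

## Worked example

Simulate a small cohort carrying a clock-like CpG-deamination-like
process, run the enrichment pipeline, and correlate donor-mean MEML with
age:

```python
import numpy as np
from motifload import (DonorSpec, ProcessSpec, builtin_registry,
                       donor_aggregate, make_cohort, make_genome,
                       run_enrichment, spearman)

genome = make_genome(length=500_000, seed=61)
ages = np.linspace(20, 80, 20)
design = [DonorSpec(donor_id=f"D{i:02d}", age=float(a)) for i, a in enumerate(ages)]
processes = [ProcessSpec(motif="nCg", mode="per_year_rate", intensity=2.0)]
catalogs, metadata, truth = make_cohort(design, processes, genome,
                                        seed=71, n_background=150)

results = run_enrichment(catalogs, builtin_registry().subset(["nCg"]), genome)
print(results[["sample_id", "mut_in_motif", "enrichment", "q", "meml"]].head(3))

summaries = donor_aggregate(results, metadata)
rho, p = spearman(summaries["age"], summaries["meml_mean"])
print(f"Spearman rho = {rho:.3f}, p = {p:.2e}")
```

Output:

```
  sample_id  mut_in_motif  enrichment             q       meml
0    D00_s1            40    3.068800  1.739660e-14  26.965591
1    D01_s1            50    2.727585  1.317518e-14  31.668767
2    D02_s1            52    3.018898  2.256433e-18  34.775171
Spearman rho = 0.955, p = 6.24e-11
```

Each row is one sample × motif: `mut_in_motif` CpG-context C→T calls, an
enrichment of ~2.7–3.1 over the local-context expectation, a BH-corrected
q far below 0.05, and a MEML of ~27–35 mutations attributable to CpG
deamination. Donor-mean MEML rises with age (ρ = 0.95), recovering the
injected 2-mutations-per-year clock.

The same pipeline is available from the shell:

```bash
motifload simulate --config design.json --seed 71 --out-prefix sim
motifload enrich --maf sim.maf --fasta sim.fasta --metadata sim.metadata.tsv \
         --motifs all --out enrich.tsv
motifload aggregate --results enrich.tsv --out donors.tsv
motifload age-corr --summaries donors.tsv --out age.tsv
```

Other subcommands: `motifs` (registry listing), `clusters`
(strand-coordinated cluster calling), `apobec` (ytCa/rtCa APOBEC3A/3B
dissection with Breslow–Day), `compare` (healthy-vs-disease Wilcoxon per
study × age tercile), `regress` (MEML ~ age + disease OLS).

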