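# ribophase

Analysis toolkit for **paired rDNA/rRNA 18S metabarcoding time series** of
planktonic microbial eukaryotes. Amplicon libraries built from genomic
ribosomal genes (rDNA) index which organisms are present and in what
relative abundance; libraries built from reverse-transcribed ribosomal RNA
(rRNA) index ribosome content, a proxy for relative cell activity. Reading
the two together over a seasonal cycle lets you ask not just *who is
there* but *who is gearing up* — including bloom-forming taxa such as
*Phaeocystis globosa*, whose activity signal can rise weeks before its
abundance does.

The package is aimed at microbial ecologists working with OTU count
tables from coastal or open-ocean surveys. It covers:

- **I/O** — TSV and mothur `.shared` OTU tables, taxonomy tables, sample
  manifests linking each library to its date, molecule and date-pair,
  and environmental tables (`ribophase.io_tables`).
- **Preprocessing** — dataset-singleton removal, metazoan-OTU removal,
  rarefaction without replacement, relative abundance
  (`ribophase.preprocess`).
- **Alpha diversity** — bias-corrected Chao-1
  `S_chao1 = S_obs + F1(F1−1)/(2(F2+1))`, Simpson dominance `D = Σ p_i²`,
  Shannon `H'` and equitability `J = H'/ln S_obs`, plus a pooled-resplit
  permutation comparison between samples (`ribophase.diversity`).
- **Environmental seasons** — depth-averaged sub-surface light
  `I = I0(1−e^{−kd·z})/(kd·z)`, BoxCox transforms, correlation-matrix PCA
  with per-variable contribution %, and Ward clustering of the first
  factorial plane into season groups (`ribophase.envstats`).
- **Community structure** — Bray-Curtis `d = Σ|x−y| / Σ(x+y)`, UPGMA
  dendrograms with top-down SIMPROF significance testing, similarity-level
  cuts, rDNA/rRNA pair coupling, cluster-vs-season agreement, three-way
  Venn partitions of shared richness, Kolmogorov-Smirnov group
  comparisons, and rDNA/rRNA inventory overlap (`ribophase.community`).
- **Activity** — the signed rRNA:rDNA ratio (+r for r ≥ 1, −1/r
  otherwise, so −40 means a 40-fold rDNA excess), reduced-major-axis
  regression of log₁₀ rRNA on log₁₀ rDNA abundance with bootstrap errors
  and RNA-/DNA-prevalence calls, four-quadrant life-cycle phases
  (rare/abundant × low/active at the 0.01 % and 0.1 % relative-abundance
  thresholds), bloom intervals and early-warning dates
  (`ribophase.activity`).
- **Synthetic data** — a seasonal community generator with known ground
  truth (guild profiles, rDNA copy-number multipliers, an activity lead
  for bloom taxa, multinomial read sampling), used throughout the test
  suite (`ribophase.synthetic_data`).

## Worked example

Simulate a three-guild seasonal community (30 paired dates, 150 OTUs,
20 000 rDNA / 10 000 rRNA reads per library), then cluster all 60
libraries on Bray-Curtis with SIMPROF:

```python
import pandas as pd
import ribophase as rp
from ribophase.synthetic_data import three_guild_truth, simulate_community, season_of_dates

truth = three_guild_truth(seed=7)
dna, rna, manifest, tax = simulate_community(truth)

print(rp.diversity_table(dna)[["S_obs", "S_chao1", "simpson_D"]].head(3).round(3))
#            S_obs  S_chao1  simpson_D
# sample_id
# D001         128  147.250      0.041
# D002         134  140.600      0.068
# D003         149  151.143      0.060

both = rp.OtuTable(pd.concat([dna.counts, rna.counts]),
                   pd.concat([dna.dates, rna.dates]),
                   pd.concat([dna.molecule, rna.molecule]))
result = rp.cluster_samples(both, seed=7)
labels = result.labels_at(25)
seasons = season_of_dates(both.dates.values)
seasons.index = labels.index
print(labels.nunique(), round(rp.season_agreement(labels, seasons), 3))
# 3 0.95
```

Three clusters emerge at the 25 % similarity cut and 95 % of libraries
sit in the cluster matching their planted season. A bloom taxon whose
activity leads its abundance by 21 days is flagged three weekly sampling
dates ahead of its bloom:

```python
from ribophase.synthetic_data import bloom_truth

bt = bloom_truth(lead_days=21.0, seed=7)
bdna, brna, _, _ = simulate_community(bt)
d = rp.relative_abundance(bdna).values["BLOOM"]
r = rp.relative_abundance(brna).values["BLOOM"]
tl = rp.phase_timeline("BLOOM", bdna.dates.values, d.to_numpy(), r.to_numpy())
print(tl.warnings[["date", "bloom_start", "lead_intervals", "lead_days"]])
#         date bloom_start  lead_intervals  lead_days
# 0 2013-03-17  2013-04-07               3         21
# 1 2013-03-24  2013-04-07               2         14
# 2 2013-03-31  2013-04-07               1          7

print(rp.signed_ratio(0.020, 0.0005))
# -40.0
```

The first warning fires 21 days before the bloom interval — the planted
lead — because the rRNA signal crosses the 0.1 % abundant threshold while
the rDNA signal is still below it.

A CLI wraps the same functions: `ribophase simulate`, `ribophase
diversity`, `ribophase cluster`, `ribophase activity` and `ribophase run`
(see `ribophase --help`).

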