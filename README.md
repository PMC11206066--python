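# ecoassembly

Community-assembly analysis of OTU count tables along environmental
gradients, with a synthetic-data generator that provides known ground
truth for every stage:

- **Niche classification** — Levins niche breadth per OTU with
  generalist / neutral / specialist calls against a count-quasiswap
  permutation null (row sums, column sums, total and fill all preserved).
- **Neutral community model** — Sloan-type fit of occurrence frequency vs
  mean relative abundance; estimates the migration rate *m*, reports the
  goodness of fit (1 − SSE/SST) and partitions OTUs against 95% Wilson
  prediction bands. Two detection models: exact beta-binomial occurrence
  (default, unbiased on read-sampled data) and the classical
  `1 − BetaCDF(1/N)` threshold form.
- **C-score / SES** — checkerboard co-occurrence statistic against a
  binary fixed-margin trial-swap null; negative SES = aggregation,
  positive = segregation.
- **Elevation MRT** — multivariate regression tree of the
  Hellinger-transformed community on elevation, cross-validated with the
  1-SE rule; leaves become LEG/MEG/HEG elevation bands.
- **RDA / envfit / VPA** — redundancy analysis on environmental
  covariates, permutation significance per variable, and Ezekiel-adjusted
  variance partitioning among topography / light / soil blocks.
- **Diversity statistics** — Shannon index, Kruskal–Wallis comparisons
  across bands, Venn shared/unique OTU summaries.
- **Synthetic data** — Dirichlet-multinomial neutral backbone with a known
  migration rate (marginally Beta, matching the neutral-model assumption),
  planted specialists/generalists, and elevation-structured covariates.

## Command line

```sh
# synthetic dataset with ground truth
ecoassembly simulate --n-otus 2000 --seed 1 --outdir synthetic

# individual stages
ecoassembly classify-niche synthetic/otu_table.tsv --permutations 1000 --seed 1
ecoassembly fit-ncm synthetic/otu_table.tsv
ecoassembly mrt synthetic/otu_table.tsv synthetic/metadata.tsv --seed 1
ecoassembly cscore synthetic/otu_table.tsv --band-file mrt_bands.tsv --seed 1
ecoassembly rda synthetic/otu_table.tsv synthetic/metadata.tsv --seed 1
ecoassembly stats synthetic/otu_table.tsv --band-file mrt_bands.tsv

# everything at once (simulates if no input table is configured)
ecoassembly run-all --seed 1 --permutations 1000 --outdir run1
```

`run-all` writes every stage output as TSV plus `manifest.json` (seed,
config echo, stage timings, sha256 of every output). Stage outputs are
byte-reproducible for a fixed seed.

Input formats: tab-separated OTU table (rows = OTUs, columns = samples;
the reader also accepts the transpose) and a sample metadata TSV with
topography (MEA, CON, SLO, ASP), light (ALA, CC, TR, SR, DR, LT, LAI) and
soil (soil_pH, organic_matter, alkaline_N, available_P, water_content)
columns plus optional `band`.

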