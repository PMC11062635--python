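# evokit

Analyses for bacterial experimental-evolution studies on a genome-reduced
*E. coli*-like chromosome, with a synthetic-data generator so the whole
pipeline runs and tests without any external data:

- **growth** — per-interval rates `r_i = ln(C_{i+1}/C_i)/Δt` from plate-reader
  OD600 curves, best-window-of-three rate selection (CV-filtered, largest
  mean), robust carrying capacity, serial-transfer generation counting
  `G = log2(Nt/N0)` with companion rates `μ = ln(Nt/N0)/Δt`, Mann–Whitney /
  Spearman group comparisons.
- **mutbias** — per-lineage mutation summaries (all / intergenic / genic
  indel / genic SNP / N / S), circular distance to the nearest
  genome-reduction scar, and a 1000-replicate randomization test (uniform
  random placements vs observed, two-sided Welch's t per replicate, decision
  statistic μ_p = mean replicate p-value with a 95% interval), plus a 2×2
  chi-square for essential-gene enrichment among mutated genes.
- **periodicity** — FPKM conversion and global log-mean normalization, 1-kb
  genomic binning by gene midpoint with circular interpolation of empty
  bins, 100-kb circular moving average, Fourier periodogram, Fisher's exact
  g test, and a fixed-wavelength sinusoid fit
  `a·sin(2π(x+b)/T) + c` at the dominant period.
- **enrichment** — one-sided binomial enrichment of gene sets against
  annotation backgrounds (labels with > 15 members), Bonferroni (or BH)
  corrected, with hypergeometric tails behind a flag; set-overlap tables.
- **simulate** — deterministic generators for genome layouts (scars +
  non-overlapping genes), null / scar-biased mutation sets, logistic OD
  curves, daily serial-transfer logs, and sinusoidal expression profiles.

## CLI

Every stage is a subcommand; `replay` chains them end-to-end on synthetic
inputs and writes a hash manifest:

```sh
evokit simulate --outdir run/ --seed 7
evokit growth --od run/plate.csv --map run/wells.tsv --out run/rates.tsv
evokit generations --log run/transfers.tsv
evokit mutbias --mutations run/mutations.tsv --genome run/layout \
    --reps 1000 --seed 42 --out run/randomization.json
evokit periodicity --expr run/expression.tsv --genome run/layout \
    --bin 1000 --smooth 100000 --out run/periodicity.json
evokit enrich --query run/mutated_genes.txt --annot run/annotations.tsv \
    --scheme category --out run/enrichment.tsv
evokit replay --outdir run/ --seed 7
```

Config can also come from a YAML file (`--config cfg.yaml` with a `sim:`
block of `SimConfig` fields); CLI flags override it. Logs go to stderr
(`--quiet` silences them), machine output only to files.

## Layout

```
src/evokit/         simulate, growth, mutbias, periodicity, enrichment, io, cli
tests/              unit + property tests, test_acceptance.py
scripts/acceptance.py
```

Coordinates are 1-based inclusive on a circular chromosome; scar files are
written as BED-like 0-based half-open width-1 intervals at the junction
points.
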