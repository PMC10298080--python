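# rohscan

Runs-of-homozygosity (ROH) analysis for diploid genotype panels: a
windowed ROH caller, genomic inbreeding coefficients (F_ROH) stratified by
segment length, population ROH-island detection with gene annotation, and
a synthetic-panel generator that makes the whole chain testable against
planted truth.  Built for population geneticists working with multi-sample
VCFs from livestock or wildlife resequencing/chip panels who want a
transparent, fully scripted alternative to ad-hoc PLINK pipelines.

## What it computes

**ROH calling.**  A sliding window (default 50 consecutive SNPs; a
base-pair-span mode is available) passes if it has ≤ 1 heterozygous and
≤ 4 missing calls.  Each SNP's *hit fraction* is the share of windows
containing it that pass; SNPs with hit fraction ≥ 0.05 form runs, split at
inter-SNP gaps > 1 Mb, and runs become segments if they span ≥ 500 kb,
contain ≥ 25 SNPs, and average ≤ 50 kb per SNP.  An exhaustive brute-force
oracle ships alongside the production caller and the two are required to
agree exactly on randomized instances.

**Inbreeding.**  Segments are classed as <1, 1–5, 5–10, >10 Mb
(lower-inclusive bounds) — a rough clock from ancient to recent
inbreeding — and per individual

    F_ROH = L_ROH / L_AUTO

is computed per class and overall (L_AUTO = total autosome length).
Breed-level summaries report counts, lengths, class-wise mean F_ROH and
the SD of F_ROH-all (only for n > 3).

**ROH islands.**  Per population, each SNP's incidence is the fraction of
individuals whose ROH cover it; SNPs in the top 1% of the empirical
incidence distribution (ties included) are merged into islands and
annotated with overlapping genes (GFF3 or BED).

**Simulation.**  Hardy–Weinberg background at Poisson-spaced sites,
per-sample planted autozygous tracts (truncated-exponential lengths,
controllable total fraction φ, residual het error, missingness), optional
shared autozygous interval planting a population island; byte-identical
output from identical seeds.

## Worked example

The numbered scripts under `analysis/` run a complete small study into
`results/`:

```sh
python analysis/01_simulate_panel.py    # 3 simulated breeds, 24 samples, 50 Mb
python analysis/02_call_roh.py          # windowed ROH calling
python analysis/03_inbreeding_stats.py  # F_ROH and breed summaries
python analysis/04_island_scan.py       # island case study with planted sweep
python analysis/05_published_table_checks.py
```

`03_inbreeding_stats.py` prints the breed summary and the planted-truth
comparison:

```
population  n_samples  total_n_roh  mean_n_roh  mean_length_mb  mean_f_roh_all
     Sport          8           46           6       12.780531        0.255611
      Warm          8           22           3        5.952699        0.119054
Indigenous          8           12           2        2.162836        0.043257

F_ROH-all versus planted autozygous fraction:
  Sport: planted 0.2552, estimated 0.2556, bias +0.0005
  Warm: planted 0.1213, estimated 0.1191, bias -0.0023
  Indigenous: planted 0.0431, estimated 0.0433, bias +0.0002
```

The "Sport" breed was simulated with a quarter of its genome autozygous,
the "Indigenous" breed with 4%; the caller's F_ROH-all recovers each
planted fraction to within a few thousandths.  `04_island_scan.py` plants
a 2 Mb sweep in 90% of a 20-sample population over 8% background and
recovers it as the single top-1% island:

```
top-1% incidence cutoff: 0.9000 (n = 49867 SNPs, 20 individuals)
islands called: 1
  chr1:20001669-21997452  1937 SNPs, peak incidence 0.90, genes: SYNGENE0101, ... overlaps planted sweep
```

The same stages are available as a CLI for real data:

```sh
rohscan call    --vcf cohort.vcf --out out/
rohscan stats   --roh out/roh.tsv --samples breeds.tsv --autosomes autosomes.tsv --out out/
rohscan islands --roh out/roh.tsv --vcf cohort.vcf --samples breeds.tsv \
                --population Thoroughbred --top 0.01 --genes genes.gff3 --out out/
rohscan all     --config run.toml
```

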