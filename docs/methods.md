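# Methods

## The problem

Runs of homozygosity (ROH) are contiguous stretches of a diploid genome in
which every assayed site is homozygous, arising when both parental
haplotypes descend from a recent common ancestor.  Their summed length,
relative to the autosome length, is the genomic inbreeding coefficient
F_ROH = L_ROH / L_AUTO — a pedigree-free estimate of autozygosity — and
regions where ROH pile up across a population ("ROH islands") mark
candidate targets of selection.  This package implements the full chain:
windowed ROH calling from multi-sample VCF, length-class stratification and
F_ROH, breed-level summaries, and the top-percentile incidence scan for
islands, together with a synthetic-panel generator that makes every stage
testable against planted truth.

## The windowed caller

The scan is the sliding-window screen popularised by PLINK's `--homozyg`.
A window slides along each chromosome of each individual; a window *passes*
if it contains at most `het_allowed_per_window` heterozygous calls
(default 1) and at most `missing_allowed_per_window` missing calls
(default 4).  Each SNP's **hit fraction** is the share of windows
containing it that pass; SNPs with hit fraction ≥ `hit_fraction_threshold`
(default 0.05, PLINK's documented default) are run-eligible.  Maximal runs
of eligible SNPs — split wherever adjacent SNPs are more than `max_gap_bp`
(1 Mb) apart — become segments if they span ≥ `min_segment_length_bp`
(500 kb), contain ≥ `min_segment_snps` (25), and have at most
`min_density_bp_per_snp` (50 kb) per SNP.  Segment bounds are the first and
last SNP of the run (no extrapolation beyond assayed sites);
`length_bp = end − start + 1`.  Runs separated by a single ineligible SNP
are not merged.

Two interpretation choices deserve explanation, because the windowed-scan
literature states its criteria loosely:

**Window unit.**  `window_mode="snp"` (default) slides a window of
`window_snps` = 50 consecutive SNPs, PLINK v1.9's native unit; a
chromosome shorter than one window is itself the single window.
`window_mode="span"` instead anchors a window of `window_span_bp` = 500 kb
at every SNP position.  The span reading looks closer to how such screens
are often described, but it couples the het allowance to SNP density: at
1 SNP/kb a 500 kb window holds ~500 SNPs, so a 1-het allowance tolerates a
heterozygote rate of only 0.2%, and at whole-genome-sequencing densities
(~10 SNPs/kb) essentially no window with any residual heterozygosity can
pass — under that reading a screen with these allowances could call almost
nothing on real sequencing data.  The SNP-count reading keeps the tolerated
het rate fixed (1/50 = 2%) regardless of density, which is both PLINK's
actual mechanism and the only reading under which the caller's recall
survives realistic genotyping error; the 500 kb figure then lives on as the
minimum segment length (PLINK's `--homozyg-kb 500`), which is this
package's default floor.  Both modes are implemented and both are verified
against the exhaustive oracle.

**Heterozygous sites inside runs.**  By default a heterozygous SNP may sit
inside a run when its hit fraction passes — the per-window allowance has
already vouched for its neighbourhood, and PLINK's ROH likewise contain
tolerated hets (its report counts them per segment).  `exclude_het_sites=
True` makes het SNPs categorically ineligible, so a single het splits a
run; that is the stricter variant sometimes wanted for chip data.  With
exclusion on, any realistic residual het rate fragments long tracts below
the 500 kb floor (a 1% error rate breaks a tract roughly every 100 kb at
1 SNP/kb), which is why tolerance is the default.  Missing genotypes are
run-eligible when their hit fraction passes; missingness is already bounded
per window.

**The oracle.**  `oracle_call_segments` recomputes the identical contract
by direct enumeration — every window materialised as an explicit index
list, het/missing counted by scanning, hit fractions by listing every
containing window — with no prefix sums or incremental state, and refuses
instances over 500 SNPs.  The caller is required to agree with it exactly
on a thousand randomized instances (positions, genotypes and all parameters
randomized, both window modes, both het policies).

**A note on monotonicity.**  Raising the per-window allowances enlarges the
set of passing windows, hence hit fractions and the run-eligible set, and
ordinarily the total called length.  It is not a theorem under the density
filter: an enlarged eligible set can extend a run with sparse flanking SNPs
until bp-per-SNP exceeds the cap and the whole run is discarded.  The
monotone sub-quantities are property-tested as such; total-length
monotonicity is tested on dense instances where the density cap is slack.

## Length classes and F_ROH

Segments are stratified into <1 Mb, 1–5 Mb, 5–10 Mb and >10 Mb.  The
boundaries are half-open and lower-inclusive — [min, 1), [1, 5), [5, 10),
[10, ∞) Mb — so every segment maps to exactly one class (the published
labels share endpoints; a deterministic convention is required).  The class
is a rough clock: long ROH reflect recent inbreeding, short ROH ancient
inbreeding.

F_ROH is computed per class and overall as the class-wise sum of segment
lengths over the total autosome length from the supplied autosome table;
by construction the overall coefficient equals the sum of the four class
coefficients.  The packaged autosome table is a synthetic 31-chromosome
apportionment whose total is exactly 2,280,940,000 bp — the equine
autosome total used by the published horse panel this package validates
against; only the total enters any F_ROH computation.

Breed summaries report total/mean/max segment statistics, per-class counts,
and class-wise mean F_ROH.  The mean segment count is rounded half-up to an
integer (so 3183/5 = 636.6 reports as 637).  The standard deviation of
F_ROH-all uses the n−1 denominator and is reported only for populations
with more than 3 samples, NaN otherwise.  Per-chromosome ROH coverage
defaults to the mean over samples of each sample's covered fraction; a
union-across-samples variant is available (`method="union"`) since
published "percentage of ROH coverage" figures rarely state which was
meant.

## Island scan

For one population, each SNP's incidence is the fraction of individuals
with at least one called segment containing it (an individual counts once
regardless of how many of its segments cover the SNP).  The cutoff is the
empirical (1 − p) quantile of the genome-wide incidence distribution with
p = 0.01, computed with the "higher" order statistic, and every SNP at or
above the cutoff is flagged — ties can only add SNPs, never drop below the
nominal top fraction.  Flagged SNPs are merged into islands, splitting at
chromosome boundaries or where adjacent flagged SNPs are more than
`merge_gap_bp` (default 1 Mb, matching the caller's gap rule) apart.  The
quantile is genome-wide, not per chromosome.  Genes overlap an island under
a ≥1 bp closed-interval rule; full containment is available behind
`require_containment`.

## The synthetic generator

`simulate_panel` draws, per chromosome, SNP positions from a Poisson
process at `snp_spacing_bp` mean spacing; per-site alternate-allele
frequencies from Uniform(0.05, 0.5) by default (avoiding monomorphic
sites); background genotypes from Hardy–Weinberg proportions; and, per
sample, non-overlapping autozygous tracts until their total reaches
φ × genome length.  Tract lengths are a truncated exponential
(`seg_min_len_bp` + Exp(mean − min)): IBD tract length decays roughly
exponentially in generations to the common ancestor, making the mean the
"recent vs ancient inbreeding" knob.  The final tract is clipped toward
the exact φ target (never below the minimum length), so the realized
fraction overshoots φ by at most min_len/genome.  Inside a tract, each
site is homozygous with the ancestral allele drawn by its frequency,
except heterozygous with probability `het_error_rate`; every call is
independently set missing with probability `missing_rate`.  An optional
shared interval is forced autozygous in a chosen fraction of samples,
planting a population island.  Everything is reproducible from the seed;
identical seeds give byte-identical VCFs.

What the generator does **not** emulate: linkage disequilibrium between
background sites (sites are independent given their frequencies), allele
frequency spectra of real populations, mutation/genotyping-error structure
outside tracts, and recombination-map heterogeneity.  Passing recovery
tests therefore show the caller's window logic, gap handling and length
accounting are correct under the model's assumptions — not that the five
screening criteria are optimally tuned for any particular real organism or
marker density.

## Validation experiment sizes

The recovery experiments run 20 individuals on a 50 Mb single-chromosome
genome at 1 SNP/kb (50k sites) with tracts ≥ 1 Mb (mean 2.5 Mb): large
enough that a 2 Mb planted sweep spans ~2000 SNPs and each genome carries
dozens of tracts, small enough that the full suite runs in seconds.
Measured under these conditions (seeded): caller–oracle agreement 1000/1000
random instances; |mean F_ROH-all − φ| below 0.01 for φ ∈ {0.05, 0.15,
0.30} (bound asserted: 0.02); base-pair recall of ≥1 Mb tracts ≈ 0.85–0.89
under 1% het error (bound asserted: 0.8); a sweep planted in 90% of
individuals over 8% background recovered as exactly one overlapping
top-1% island.

## Published-table arithmetic

The published 16-breed tables are internally linked by exact arithmetic
that this package also performs on its own output: mean total ROH length /
2280.94 Mb = mean F_ROH-all (reproduced to 3 significant figures for 14 of
16 breeds; the two failures, Thoroughbred and Franches-Montagnes, are the
two breeds whose sample counts disagree between the published tables
themselves); pooled class counts give the printed 69.55% / 29.83% class
shares exactly; rounded mean counts match for all 16 breeds.

## Known limitations

- No LD pruning, phasing, or model-based (HMM) ROH calling; only the
  windowed screen.
- No genotype-quality or per-site QC filters (MAF, call rate) — input is
  assumed pre-filtered.
- Chromosome name matching is exact (optional "chr"-prefix stripping is
  off by default).
- The simulator's independence assumptions understate the short-ROH
  background real LD produces, so absolute false-positive rates on real
  data will differ from the simulated ones.
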