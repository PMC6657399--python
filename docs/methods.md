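# Methods

## The scan model

The package detects recent positive selection from two-group pooled
sequencing. Both statistics operate on per-site allele read counts summed
to group level; individual pools are not tracked because both statistics
depend only on group totals.

**Pooled heterozygosity.** For a window and group,
H_P = 2ab/(a+b)² with a = Σ major and b = Σ minor allele reads over the
window's SNPs. H_P ∈ [0, 0.5], reaching 0.5 only when a = b, and 0 when the
group's reads all fall on one side of the pooled major/minor orientation.
Because the orientation is fixed once from the pooled counts of both
groups, a group that is *fixed at every site* can still show a small
nonzero window H_P when it is fixed for the pooled-minor allele at some
sites (e.g. complete oppositely-fixed differences between groups). This is
a property of the statistic, not an artifact.

**Window F_ST.** Per SNP, a Hudson-type two-population estimator on
read-count allele frequencies, with the finite-sample correction terms
p̂ᵢ(1−p̂ᵢ)/(nᵢ−1) using the number of distinct chromosomes sequenced per
group (defaults 800 and 400: 40 and 20 pools of 10 diploids). Windows
aggregate as ratio of sums (Σ numerators / Σ denominators), the recommended
aggregation for window scans; per-site values may be negative. A
variance-standardised estimator without the sampling correction
(`wright_mean`) is available for comparison. The estimator identity behind
the original analysis could not be pinned down, so it is pluggable; Hudson
ratio-of-sums is the default on standard-practice grounds.

**Z-scores and calling.** ln(H_P,B/H_P,A) (control over selected, so
positive = heterozygosity loss in the selected group) and window F_ST are
standardised genome-wide over retained windows (sample SD, n−1). Candidate
windows need Z > 5 in both statistics (strict inequality); overlapping or
abutting candidates merge into regions carrying member maxima. The log
ratio is computed as log(x) − log(y) rather than log(x/y) so that swapping
the group labels negates it exactly in floating point.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| window_size / step | 50 kb / 10 kb | scan granularity; contiguous signal always overlaps at this step |
| min_sites | 10 | windows with fewer informative SNPs are discarded, not scored |
| z_cutoff | 5.0 | per-statistic outlier threshold (applied to both) |
| hp_floor | 1e-4 | floor inside the log ratio; keeps complete sweeps (H_P = 0) as large finite signals instead of ±∞ |
| haploids_a/b | 800 / 400 | chromosomes per group for the F_ST correction |
| QC: max_error_rate | 0.01 | site quality ≥ 20 on the Phred scale |
| QC: min_spacing | 5 bp | SNP clusters closer than this are removed entirely (clustered calls indicate misalignment); `keep_first` mode available |
| QC: depth bounds | [⅓×, 2×] group mean | inclusive; mean computed per group on the post-spacing set so dropped clusters cannot shift it |
| max_gap | 0 | region merging bridges gaps ≤ max_gap (0 = overlap-or-abut) |
| min_region_length | 0 | optional minimum region length; exposed because a fixed-length cutoff is a study-level choice, not part of the statistic |

QC order is quality → spacing → depth, and the report attributes each
dropped site to the first filter it fails. "Support values" are read as
total per-group site depth (the conventional depth-filter meaning).

## The simulator

`simulate_sites` emulates what the scan assumes about real pool-seq data:
SNP positions from a Poisson process (default 1/500 bp); ancestral
frequencies from a symmetric Beta(0.2, 0.2) spectrum (most sites near
fixation, as in a folded allele-frequency spectrum); group frequencies as
independent logit-normal jitters (SD 0.2) of the ancestral value, giving
shared-drift correlation between groups; then a two-level sampling scheme —
pool frequency ~ Binomial(haploids, group frequency)/haploids, read depth ~
Poisson(25), allele reads ~ Binomial(depth, pool frequency). The two-level
scheme reproduces the extra count variance a finite pool imposes; direct
binomial sampling from the population frequency would understate it.

Inside a planted sweep the selected group's frequency is moved toward its
nearer boundary so that p(1−p) is scaled by `het_reduction` (the quadratic
solved exactly), and the control frequency is displaced by
`divergence_shift` toward the opposite boundary. Displacing the control —
which retains the non-swept allele — raises differentiation while leaving
the selected group's calibrated heterozygosity loss intact; displacing the
already near-fixed selected frequency instead would clip at the boundary
and destroy the het_reduction calibration. Sites monomorphic in the sampled
reads, or with zero depth in a group, are not emitted (a caller would not
report them).

What the simulator does **not** model: linkage disequilibrium and local
genealogies (frequencies are independent across sites), mapping and
reference bias, indels/structural variation, base-calling error in the
counts, and depth autocorrelation along the genome. Passing tests therefore
show that the scan recovers frequency-signature sweeps at realistic depth
and pool sizes, not that it is robust to alignment artifacts; the QC
filters address those on real data but are exercised here on simulated
qualities and spacings.

The qPCR simulator draws, per sample, a target Ct =
24 + 0.02·stage_mm − effect·[selected] + N(0, 0.2) and triplicate replicate
Cts with SD 0.15 around it, reference gene flat at 18 Ct: typical SYBR
qPCR magnitudes, with five stages spanning 45–210 mm fetal length and three
samples per group and stage.

## ΔΔCt analysis

ΔCt = mean(target Ct) − mean(reference Ct) per sample (arithmetic mean of
replicates); ΔΔCt is taken against the mean ΔCt of control samples at the
earliest stage, and fold = 2^−ΔΔCt. The calibrator choice is a convention
only: all between-group fold *ratios* are calibrator-invariant, and the
reported log2 fold ratio is computed directly as the difference of group
mean ΔCt (never touching the calibrator). The group test is a two-sided
Welch t-test on ΔCt (the approximately normal scale); the stage trend is a
Spearman correlation of fold against fetal length. Stages present in only
one group are excluded with a warning.

## Numerical and convention choices

- Coordinates are 1-based inclusive internally (matching VCF and the
  conventional region-table format); BED/bedGraph output converts to
  0-based half-open at the boundary only.
- Major/minor orientation is decided once on pooled (A+B) counts, ties to
  the reference allele, so the H_P ratio of the two groups always refers to
  the same allele partition.
- Windows start at position 1 and are emitted only if they fit entirely
  within the contig: floor((L − W)/S) + 1 windows per contig.
- The F_ST numerator groups its two correction terms before subtracting so
  group relabelling is exactly symmetric in floating point.
- Window sums use prefix sums over sorted sites; this is bit-identical to
  naive per-window recomputation (integer sums) and is tested against it.
- Z-transformation refuses < 2 values or zero dispersion rather than
  returning NaNs.
- Sites with zero total reads in either group are dropped at ingestion;
  both statistics are undefined there.
- Sync-format input carries no site quality, so ingested sync sites get a
  configurable default (60); the quality filter is only informative on VCF
  or simulated in-memory input.

## Problem sizes

Simulation-based tests and the acceptance script use a 10-Mb genome
(≈ 996 windows, ≈ 11–12k sampled SNPs after monomorphic dropout at the
1/500 nominal rate) with a 300-kb planted sweep, 20 seeds for
recovery/null calibration and 20–50 seeds for ΔΔCt recovery. These sizes
give stable genome-wide Z references (the sweep occupies ≈ 3% of windows)
while keeping the whole suite in the tens of seconds.

## Known limitations

- The dual Z > 5 intersection is an outlier criterion, not a calibrated
  test; no p-values are attached to regions.
- Genome-wide Z-scores assume sweeps occupy a small fraction of windows; on
  short test genomes where a sweep covers ≳10% of windows it inflates the
  SD and suppresses its own signal.
- The H_P ratio floor makes complete sweeps comparable but compresses
  differences among them.
- Region boundaries are window outer edges (multiples of the step), not
  breakpoint estimates.
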