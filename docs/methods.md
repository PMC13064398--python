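# Methods

This note records the model behind `tetrasweep`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical and design decisions a maintainer should know about.

## Diversity metrics from dosages

All statistics are computed from unphased integer allele dosages
d ∈ {0..k} (k = ploidy, default 4) with missing calls excluded per locus.
The alternative-allele frequency is estimated as the mean dosage divided by
the ploidy, p = Σd/(k·n). Observed heterozygosity Ho is the fraction of
non-homozygous dosage genotypes (classes 1..k−1); expected heterozygosity
He = 1 − (p² + q²); per-site nucleotide diversity uses the small-sample
correction π = n/(n−1)·2p(1−p), so π = He·n/(n−1) identically — an identity
the test suite checks to 1e−12 as a cross-metric self-check. Undefined
values (n = 0; π at n = 1) are stored as NaN and *excluded* from window
means and quantiles, never imputed as 0: imputing 0 would fabricate extreme
π-ratios and deviations.

Between two groups A and B the comparative metrics are ΔHo = Ho_A − Ho_B
(ΔHe likewise), the π-ratio π_A/π_B (NaN when π_B = 0), and
FST = (H_T − H_S)/H_T with H_T = 2p̄(1−p̄) from the unweighted mean
frequency p̄ = (p_A + p_B)/2 and H_S the unweighted mean of the group He
values; a sample-size-weighted variant sits behind `weighted=True`. The
numerator is evaluated as 2·w_A·w_B·(p_A − p_B)², which is algebraically
equal to H_T − H_S but cannot go negative by floating cancellation when
p_A ≈ p_B, keeping FST in [0, 1] exactly. Between ΔHe and ΔHo, the
observed-heterozygosity difference drives comparative calling by default
(ΔHe is computed and can be scanned via the `tails` argument); with unphased
tetraploid dosages Ho is the more direct group contrast and matches how the
contrast is usually plotted.

## Windows and deviation tracks

Two window schemes run per chromosome: a fixed count of 100 consecutive
SNPs stepped by 10 (trailing partial windows are dropped so per-window
variance stays comparable, which the rank bands implicitly assume), and a
fixed 1 Mb width stepped by 500 kb anchored at bp 1, dropping windows with
fewer than `min_loci = 10` SNPs to guard against wild means in sparse
windows. A track stores each window's mean of a per-locus metric and its
deviation from the genome-wide mean over *loci* (not over windows —
overlapping windows would otherwise multiply-count loci in the baseline).
Window positions for region arithmetic are mid-points, giving the 1 Mb
extension a point anchor. Window sums use one `reduceat` pass; they agree
with a naive per-window loop to summation-order rounding (~1e−14), and
`deviation + genome_mean == window_mean` holds exactly.

LD decay — the summary that motivates window sizes — is the mean squared
Pearson correlation of dosage vectors over pairwise-complete samples,
binned by physical distance (10 kb bins by default); pairs with fewer than
3 shared samples or zero variance are skipped.

## Bootstrap and simultaneous rank bands

Uncertainty in the deviation tracks is quantified by resampling accessions
(matrix rows) with replacement — loci are never resampled, which preserves
LD and the dependence between overlapping windows — and recomputing the
per-locus metric, window means, genome mean and deviations in every
replicate (B = 1000 default; each replicate is recentred by its own genome
mean, with `recenter='point'` available). Per chromosome, the band at
window w is the closed interval [t₍ₖ₎,w, t₍B+1−k₎,w] of bootstrap order
statistics, with one shared depth k = the largest integer such that the
fraction of replicates lying inside the band at **all** windows
simultaneously is ≥ 1 − α. The exhaustive k-scan is the normative
definition; ties are resolved by ≤/≥ comparisons, which can only raise
coverage, and k is capped at ⌊(B+1)/2⌋ so degenerate (zero-variance) tracks
return a zero-width band with coverage 1. For a single window and
continuous values the construction reduces to the familiar percentile
interval: B = 1000, α = 0.05 gives k = 26 and coverage exactly
(B − 2k + 2)/B = 0.95. If even k = 1 misses the target the band is returned
with a warning to increase B. Bands are per chromosome and per metric; a
genome-wide joint band is deliberately out of scope.

The calibration check in the test suite scans a fresh data half against the
band bootstrapped from that same half and requires the family-wise exit
rate to stay far below the pointwise W·α rate. A cross-half variant (band
from one half, track from the other) is *not* a calibration check: the
difference of two independent estimates has twice the variance the band is
calibrated for, and its exit rate is correspondingly high (~0.6 at these
sizes) for any sample size.

## Within-group sweep caller

Per chromosome and metric, only negative deviations are candidates. Local
minima are found in a ±2-window neighborhood under a leftmost-of-tied-run
rule (strictly below everything to the left, at most everything to the
right; NaNs are transparent), minima at or below the 5% quantile of that
chromosome's negative deviations are retained — the quantile is over all
negative deviations, the literal reading of "the empirical distribution of
negative deviations", not over minima only — and each becomes a region
±1 Mb around the window mid-point, clipped to the chromosome. Overlapping
regions merge (union of span, metrics and peaks; the deepest peak is kept
as the representative). Consensus keeps merged regions supported by ≥ 2 of
{Ho, He, π} ("multiple metrics" read as two, configurable to three). When a
band is supplied, each region records whether the simultaneous upper limit
at its peak is below zero (`band_significant`); `require_band=True` turns
that annotation into a filter. The quantile rule is the operative selection
by default because the 5%-of-negative-deviations criterion, not the band,
is what defines the candidate set; the band is the significance annotation.

Note the per-chromosome quantile *always* nominates each chromosome's
deepest trough, sweep or not — the worked example shows two such background
calls. Consensus, the band annotation, and inspection of deviation depth
are the guards; users scanning genomes with few true sweeps should lean on
`require_band`.

## Comparative (two-group) caller

Extreme windows are those in the 1% tails of each metric's window-value
distribution: FST upper tail only; ΔHo and π-ratio both tails (a low tail
marks diversity lost in group A, a high tail in group B). Thresholds are
taken from the **genome-wide** distribution of a metric's window values by
default. The chromosome-specific variant (`per_chromosome_tails=True`) is
provided, but with ~80 windows per chromosome a per-chromosome 1% quantile
flags every chromosome's extremum by construction, and because ΔHo,
π-ratio and FST are all driven by the same underlying frequency
differences their extremes co-locate: on sweep-free simulated genomes the
per-chromosome rule produced ~10 spurious regions per genome versus 0.7
for the genome-wide rule, with no loss of true-sweep recovery.

Runs of adjacent extreme windows (window-index distance ≤ 1, events from
all metrics pooled) form clusters. A cluster becomes a region when at least
`min_metrics = 2` distinct metrics each contribute at least
`min_windows_per_metric = 2` extreme windows — reading "clusters of
adjacent extreme windows" as genuinely plural. This per-metric depth
requirement is what separates true group-specific sweeps (which put long
runs of windows of every affected metric into the tail) from chance
co-locations of single extreme windows; under the study-scale conditions it
measured 0.70 false regions per null genome with 40/40 recovery of an
intensity-0.8 group-specific sweep, versus 1.3 false regions when a single
shared window sufficed. Local extrema (±1 window, mirrored tie rule) inside
the cluster are kept as peak anchors; the region is ±1 Mb around the mean
member mid-point (mean chosen over median/most-extreme; the difference is
well under a window width in simulation). Direction is a vote over member
tails: low ΔHo / low π-ratio → reduced in A, the high tails → reduced in
B, FST abstains; a tie reports elevated differentiation.

## Annotation

Genes overlap a region when their 1-based inclusive intervals share ≥ 1 bp
(an interval tree per chromosome). Term enrichment of a region's genes
against the genome-wide background (all genes in the supplied table) is the
one-sided Fisher exact / hypergeometric upper tail, BH-corrected across the
terms tested within that region; terms absent from the region are skipped.
Depletion tests and term-hierarchy handling (GO levels, DAG propagation)
are out of scope — the term universe is whatever the gene→term map
supplies.

## Synthetic data generator

The generator emulates the structure of an array-genotyped cultivated-rose
panel: 7 chromosomes, 87 SNPs/Mb, two groups of 95 ("cut") and 190
("garden") accessions, tetraploid dosages, 8% missing calls, ancestral
frequencies uniform on [0.05, 0.95]. Chromosomes default to 10 Mb — the
desk-scale genome used across tests and the acceptance script; real rose
chromosomes are ~50–70 Mb, so per-chromosome window counts here are ~81
rather than several hundred, which makes the per-chromosome-quantile
caveats above *milder* on real data, not worse. Dosages are binomial
(ploidy, p) per sample — the random-bivalent-pairing idealisation of an
autotetraploid; per-locus group frequencies add clipped-normal jitter
(sd = 0.05, clipped to [0.01, 0.99]), yielding a background per-locus FST
of roughly 0.01, on the conservative side of real cut-vs-garden panels.
Sweeps act on the generating frequency, not post-hoc on dosages, so the
truth diversity reduction is analytically known; every affected group moves
toward the boundary nearer the ancestral frequency (one swept haplotype per
locus), so an intensity-1 shared sweep is monomorphic panel-wide. Missing
entries are i.i.d.; positions are uniform draws, sorted, with +1 bp
collision shifts.

What the generator does **not** emulate: linkage disequilibrium between
loci (dosages are independent given frequencies), ascertainment bias of
array SNP selection, population structure beyond the two-group split,
segmental allopolyploidy / preferential pairing, recombination-rate
variation (centromeric diversity troughs), and genotype-calling error.
Passing recovery tests therefore demonstrate that the callers find
frequency-level diversity troughs of the stated size and intensity at the
stated sample sizes — not that real-data artefacts (low-recombination
regions, array bias) cannot mimic them.

## Numerical choices and degenerate inputs

- Missing is NaN internally and `NA` on disk; dosage 0 is never conflated
  with missing. The 10% missingness filter is strict (`> max_missing`,
  compared on counts): a locus missing in exactly 10% of samples is kept.
- Quantiles use NumPy's default linear interpolation.
- The minima tie rule (leftmost of a run) makes a constant sequence yield
  exactly one minimum at index 0; strictly increasing sequences yield the
  edge minimum.
- Merging treats intervals as 1-based inclusive; regions touching at a
  single bp merge. BED output converts to 0-based half-open at the write
  boundary only.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; pipeline outputs contain no timestamps, so identical config +
  seed reproduces byte-identical files.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at 7 chromosomes × 10 Mb, ~90 SNPs/Mb,
95 + 190 accessions, with 20 replicate genomes per condition and B = 200
bootstrap replicates where bands are exercised; these sizes make the full
suite and the acceptance script complete in well under a minute each on one
CPU while keeping every window, caller and band code path at realistic
density and sample size.

## Known limitations

- He from pooled dosage frequencies assumes a biallelic locus and
  Hardy-Weinberg-like dosage composition within groups; strong inbreeding
  shifts Ho against He in ways the scan reports but does not model.
- The rank band is one concrete member of the rank-based simultaneous-band
  family; its k-scan definition is normative here.
- The comparative caller's genome-wide tail thresholds assume most of the
  genome is not differentiated; panels where one group is globally depleted
  of diversity will concentrate all tail windows in few regions.
- VCF ingest trusts `FORMAT/DS` rounding (or GT allele counts); no
  genotype-likelihood handling.
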