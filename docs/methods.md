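# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open, BED-native. The only
conversions happen at format boundaries: RepeatMasker `.out` rows (1-based
inclusive, strand `C` = minus) are normalized on read, which preserves
element length by construction. Zero-length intervals are rejected at read
time. An interval's midpoint is `floor((start+end)/2)`. A repeat's *head* is
its 5' end in its own orientation: `start` on the plus strand, `end − 1` on
the minus strand. narrowPeak summits are `start + offset` from column 10; a
`-1` offset (summit not called) and plain BED fall back to the interval
midpoint. RepeatMasker carries two labels per row (repeat name and
class/family); we map the class part to `family` and the family part (or,
failing that, the repeat name) to `subfamily`, since analyses here operate
at both the SINE and the B1 level.

## TE-family enrichment

A hypergeometric test needs a finite universe of exchangeable draws, which
raw intervals do not provide. We tile the genome into fixed-length bins
(default 500 bp — the same scale as the ±500 bp summit windows used in the
positional analyses; the last bin per chromosome may be short, and bins
never span chromosomes). The universe size `N` is the bin count, the sample
`n` the bins touched by ≥1 peak, successes `K` the bins touched by ≥1
element of the family, and `k` the bins touched by both. Then
`p = P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` (scipy's survival function) and
`fold = (k/n)/(K/N)`. Benjamini–Hochberg correction runs across all
families tested in one call. Families absent from the binned genome
(`K = 0`) report fold `NaN` rather than 0, to avoid implying depletion.
Because the binning is one interpretation among several (instances or
base-pair fractions would also do), a shuffle-based empirical mode
(`empirical_family_enrichment`, add-one estimator over uniform re-placements
of the peaks) is provided as an independent cross-check. Enrichment is
computed at subfamily resolution with a family-level rollup, as both levels
are scientifically meaningful.

Peak-level summaries (`count_peaks_with_family`) count a peak once no
matter how many instances it overlaps; overlap means ≥1 shared base, with
no minimum-fraction option. Percentages carry an explicit rounding mode
(nearest / floor / ceil / raw, with configurable decimals); nearest at zero
decimals is the default since that is how such ratios are customarily
printed.

## Summit anatomy and the orientation test

Elements are assigned to a summit window `[summit − w, summit + w + 1)`
(default `w` = 500) and classified by (strand, side of summit), side being
decided by the element *midpoint* — the natural reference given that the
downstream motif and dyad analyses are midpoint-anchored. Midpoints exactly
on the summit are excluded from the test and reported separately. On the
plus strand the head is the low-coordinate end, so minus/upstream and
plus/downstream are the head-inward configurations. The orientation test is
a two-sided exact binomial against 0.5 on head-inward counts, doubling the
smaller tail and capping at 1 — the simplest exact two-sided convention,
and exactly symmetric under swapping head- and tail-inward counts. An
element inside two overlapping peaks' windows counts once per (peak,
element) pair, matching the window-count semantics.

Positional profiles histogram integer offsets on `[−w, +w]`, divide by the
number of contributing regions, and smooth with a centered uniform moving
average (default 11 bp; 21 bp for dyad profiles, which are broader). The
kernel sums to one, so smoothing conserves total mass except at window
boundaries; the unsmoothed counts are kept alongside for mass audits and
spread estimates. Mode lookup resolves smoothing-induced plateaus of tied
maxima to the plateau center.

## Motif scanning and anchored profiles

JASPAR count matrices are normalized with a 0.01 per-cell pseudocount.
Scores are `Σ log2(p_ij / background_j)` under a uniform background by
default; the relative score rescales by the PWM's attainable min/max so the
default threshold (0.8) means the same thing across motifs. Both strands
are scanned; windows containing N are skipped; a minus-strand hit at `i`
means the reverse complement of the window matches. Hit positions are
recorded at the motif center, so anchor offsets are length-independent.
Anchored profiles fetch `±(w + L)` of sequence around each anchor (clipped
at chromosome ends) so hits whose windows straddle the profile edge are not
lost, then keep hit centers within `±w`. Per-quadrant profiles default to
genomic coordinates; `flip_minus` negates offsets at minus-strand anchors
to merge strands into element-oriented coordinates.

The packaged KLF-like and SOX-like PWMs are synthetic stand-ins built
around the G-rich KLF and A/T-rich SOX consensus cores (the matrices a
motif database would supply are not identified unambiguously anywhere we
can cite, and the analyses only need a sharp, correctly-shaped PWM).
De novo motif discovery is out of scope by design.

## Nucleosome dyads

MNase BED records are treated as protected fragments; the dyad is the
fragment midpoint (floor). No fragment-length filter is applied by default,
but a configurable closed-range filter (e.g. 120–180 bp for
mononucleosomes) is available, as is a mode for pre-called single-bp dyad
records. Profiles are per-region normalized by default so anchor sets of
different sizes are comparable, and minus-strand anchors are flipped by
default (flipping twice is the identity; with strand-balanced planting the
flipped and unflipped profiles agree within sampling error).

## Region classes

Each region contributes a summit-centered window (default 2000 bp, 50 bins
per sample) of mean per-bin coverage per sample; sample blocks are
concatenated and log1p-transformed, with no row standardization — the
default behavior of the common heatmap tooling this mirrors. K-means uses
k-means++ initialization, Lloyd iterations (max 300), and the best of
`n_init` = 10 seeded restarts; the seed is mandatory, making the partition
deterministic. With k = 2 the cluster with the higher mean signal over the
MEF (fibroblast) sample columns is labeled `cluster1_open_in_MEF`, the
other `cluster2_closed_in_MEF_opening`; labels follow content, not sample
order, and an exact tie raises rather than guessing. A coverage track
missing a chromosome contributes zeros with a logged warning, so one
truncated track degrades gracefully instead of aborting a run.

## Synthetic data: what it emulates, and what it does not

The generator plants, per element-bearing peak: a 140 bp element at a site
center, strand Bernoulli(0.5); a summit displaced from the element midpoint
by `|Normal(70, 15)|` bp on the side that makes the head face the summit
with probability 0.75; KLF-like/SOX-like motifs overwriting the element's
head/tail before per-base mutation (rate 0.05); 20 MNase fragments per
element with dyads `Normal(midpoint, 20)`; and four coverage tracks
(WT/KO × MEF/72 h, Poisson noise around a stepped profile) realizing two
classes at 121:1401-like proportions — a minority open in both MEFs that
closes on reprogramming except where the knockout resists, and a majority
closed in MEFs that opens at 72 h, more strongly in the knockout. Defaults
(479 peaks, element fraction 0.92, 700 elements) are the study conditions
the statistics are calibrated against. A background-only decoy subfamily
(B2, 150 copies) makes enrichment ranking a real comparison. Sites are
placed by rejection sampling with a retry cap, with a 1300 bp minimum
separation chosen so each summit's ±500 bp window contains only its own
element — orientation and position statistics then measure planting, not
crowding. The default 2 Mb two-chromosome genome keeps generation around a
second; the synthetic consensus sequence is constructed to contain no
near-match to either packaged motif, so motif profiles measure planting
alone.

What the toy data does *not* emulate: mappability and GC structure, repeat
nesting and fragmentary copies, element families with internally divergent
subfamilies, read-level noise (coverage is emitted as clean 10 bp-step
Poisson draws), or peaks containing multiple elements. Passing recovery
tests therefore demonstrates correctness of the statistics under the
planted model, not robustness to every pathology of real annotation.

Screen-design arithmetic: the fraction of cells with at least one viral
integration at multiplicity of infection `m` is the Poisson complement
`1 − e^(−m)` (≈ 0.8647 at `m` = 2, i.e. 86% to the nearest integer).

## Numerical and degenerate-input choices

Exact binomial tails and hypergeometric survival functions come from scipy
and are verified in the tests against direct pmf enumeration (all universes
with `N` ≤ 30, and seeded Monte-Carlo agreement within 3 standard errors).
BH adjustment is the vectorized step-up with monotonicity enforced from the
largest rank down. Empty peak sets, all-zero orientation counts, zero-length
intervals, non-positive windows, out-of-range probabilities, and k-means
with more clusters than regions all raise with specific messages. Log-odds
use a 1e-9 probability floor only for PWMs constructed directly from
probabilities containing zeros; matrices built from counts never hit it.

## Problem sizes in the shipped tests

The suite generates datasets at 60–479 peaks and calibration simulations at
500–4000 regions (200 replicates for the null-uniformity check, 10,000
dyads for spread recovery), which resolve all planted effects at the stated
tolerances while keeping a full run around ten seconds on one CPU.

## Known limitations

The hypergeometric universe is a modeling choice; bin length changes `N`,
`K`, `n`, `k` jointly, and while the ranking of families is stable in our
tests, absolute p-values are interpretation-dependent (the empirical
shuffle mode exists for exactly this reason). The positional profiles
report densities, not significance; no bimodality test is attempted.
bigWig is not read (bedGraph only), and BAM/SAM parsing, peak calling,
differential accessibility, and de novo motif discovery are explicitly
upstream of this package.
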