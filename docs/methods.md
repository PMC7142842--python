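# Methods

This note documents the models and procedures `cnatree` implements,
the defaults and why they were chosen, what the synthetic data do and
do not emulate, and the numerical conventions that matter when
reproducing results.

## Data model and coordinates

Everything is indexed against ordered fixed-width genomic bins
(default 500 kb).  Coordinates are 0-based half-open internally; the
SEG writer converts to 1-based inclusive at the boundary.  A bin
carries a GC fraction and a usability flag; sex chromosomes are
flagged per chromosome and excluded from event matrices (a
sex-mismatched transplant design makes X/Y coverage uninformative
about somatic copy number, and single-copy X in males would otherwise
masquerade as deletion).  Copy-number ratio 1.0 means diploid; copy
number = 2 x ratio throughout.

## Synthetic data generator

The generator emulates binned counts from MALBAC-amplified, ~0.3x
single-cell WGS of a tumor with clonal structure:

- **Genome**: 11 autosomes + 1 sex chromosome x 150 bins of 500 kb — a
  deliberately scaled-down mouse-like genome (real mouse: 19 autosomes,
  ~5,300 x 500 kb bins) sized so a full pipeline run takes seconds while
  leaving CNA events a minority of the genome.
- **GC content**: stationary AR(1) process along each chromosome
  (rho = 0.9, sd 0.06 around 0.45, clipped to [0.30, 0.62]) — smooth
  enough for LOESS to model, variable enough to matter.
- **Clonal truth**: a random rooted binary tree over `n_clones` (4)
  below a single trunk branch.  Events are contiguous bin intervals
  (20-30 bins) with integer copy change in {-2, -1, +1, +2}, floored at
  copy 0, placed without overlap and separated by at least
  `event_guard_bins` (20) neutral bins.  The guard has a power
  rationale: for the joint segmentation to keep an event boundary, the
  SSE gain `n_carriers * (n_event * n_flank / (n_event + n_flank)) * delta^2`
  must exceed gamma = 20; with 10 cells per clone, >= 20-bin events,
  >= 20-bin flanks and the smallest ratio change (0.5), the gain is
  ~25-50, safely above the penalty.  Tighter event packing or fewer
  cells per clone genuinely starves the breakpoint test — that is a
  property of the method, not of this implementation.
- **Event budget**: `events_per_branch` (3) x number of branches, then
  redistributed by mode: *punctuated* places `ceil(trunk_fraction *
  total)` events on the trunk (every other branch still gets at least
  one, so clones remain distinguishable); *gradual* spreads evenly over
  all branches.
- **Counts**: expected count = `mean_reads_per_bin * (cn/2) * g(gc)`,
  with g a quadratic in GC normalized to unit mean, drawn gamma-Poisson
  with variance `mu + overdispersion * mu^2` (exactly Poisson at 0).
  Defaults `mean_reads_per_bin = 200`, `overdispersion = 0.005` give a
  per-bin ratio CV of ~0.1 at diploid coverage.  No published per-bin
  depth was available to copy; these are the package's own choices for
  a realistic low-pass regime and are ordinary config knobs.
- **Labels**: a configurable fraction (0.3) of tumor cells is marked
  "non-green" independent of clone, emulating reporter (GFP) loss, so
  the shared-origin analysis has a non-trivial mixed-label answer.
  Normal cells are labelled "blood" and are the rooting outgroup.

What the generator does **not** emulate: locus dropout and
allele-level amplification artifacts of real MALBAC chemistry,
mappability structure, chromosome-length heterogeneity, subclonal
(non-integer) mixtures within a cell, and sex-chromosome copy
differences (sex-chromosome copy number stays at baseline 2; the
pipeline drops those bins from event matrices anyway).  Passing tests
therefore demonstrate correctness of the algorithms under controlled
noise, not robustness to every artifact of real amplification
chemistry.

## Read counting and normalization

Reads are assigned to exactly one bin by leftmost aligned position;
unmapped, duplicate-flagged and mapping-quality < 40 records are
dropped.  Aberrant bins are masked per chromosome using the normal
reference cells: after scaling each reference cell to mean coverage 1,
a bin is masked when its median scaled coverage is zero or deviates
from the chromosome median by more than 5 scaled MADs (the filter rule
is a documented package choice; only the existence of the filter, not
its criterion, is standard).

GC normalization fits a locally weighted regression (LOESS) of count
on GC over usable autosomal bins, span 0.3, and divides by the fitted
curve; sex-chromosome bins use the interpolated curve.  The smoother
is statsmodels' local-*linear* lowess — no installed library exposes a
degree-2 local fit, and at span 0.3 the local-linear fit tracks a
smooth quadratic bias to well below the acceptance threshold on
residual GC correlation (|r| < 0.05).  Each cell is finally rescaled
so its median usable autosomal ratio is exactly 1.  This median-diploid
assumption is the same one behind mapping ratio cutoffs to copy
numbers (1.4 -> 2.8 etc.); it fails for genomes that are mostly
aneuploid.  The whole normalization is exactly invariant to scaling a
cell's counts by any positive constant.

## Per-cell segmentation (CBS + MergeLevels)

CBS runs on **linear** ratios, not log2, so segment means compare
directly against the published 1.4/0.6 cutoffs (log2 is used for
display and SEG output only; whether the original analysis segmented
linear or log2 ratios is not documented — linear was chosen and is
flagged here).  On each chromosome the best circular arc (i, j]
maximizes |mean(arc) - mean(rest)| / sqrt(1/k + 1/(n-k)); the common
noise SD is omitted because the permutation null makes the test
scale-free.  A split is accepted when its permutation p-value (up to
1,000 label shuffles, early-stopped once p >= alpha is certain) is
below alpha = 0.01, then recursion continues on the arms; minimum arm
width 2.  After recursion, boundaries are undone while the smallest
between-segment mean difference is below `undo_prune_sd` (0.05) times
the profile noise SD, estimated robustly as
`1.4826 * median|first difference| / sqrt(2)` — the published
parameter names the threshold but not the estimator, so the estimator
is fixed and documented here.

MergeLevels visits adjacent segment pairs in order of increasing mean
difference and merges a pair whenever a two-sided rank-sum
(Mann-Whitney) test on the member-bin ratios is non-significant
(p >= 1e-4), restarting until every remaining adjacent pair differs.
It never increases the segment count and is idempotent.

## Joint (population) segmentation and event calling

All cells share one breakpoint set per chromosome, minimizing total
per-cell SSE + gamma x (number of breakpoints), gamma = 20.  The DP is
exact up to 1,000 bins per chromosome (O(n^2 x cells), vectorized);
longer chromosomes fall back to a coarse-to-fine heuristic (DP on
block means, then local exact refinement of each breakpoint).  Exact
ties in the DP are broken toward the later predecessor, so gamma = 0
reproduces the interpolating fit (a breakpoint at every boundary,
SSE = 0), and breakpoint count is non-increasing in gamma.

Shared segments under 10 bins are removed *before* state calling (the
published order) and their bins take no part in event calls.  State
calling uses closed outer cutoffs and an open neutral band:
ratio >= 1.4 -> +1, <= 0.6 -> -1, strictly inside (0.7, 1.3) -> 0; the
closed bands [0.6, 0.7] and [1.3, 1.4] are ambiguous.  The published
prose mixes "less/greater than" with "cutoffs", so the inclusivity
convention is fixed here: outer cutoffs inclusive, neutral band open.

Ambiguous calls are resolved by a 3-component Gaussian Bayes
classifier: posterior ∝ prior(state) x N(mean ratio; state mean,
SD / sqrt(n_bins)), state means (0.5, 1.0, 1.5) = ratios of copy
numbers 1/2/3.  The SD is estimated from the bin ratios of
unambiguously neutral segments of the same dataset; priors are the
add-one-smoothed frequencies of the unambiguous calls.  Exact
posterior ties prefer neutral, then the larger prior.  The underlying
probabilistic model was not published; this one is deliberately
minimal and every piece of it is a config field.

## Tree building

Characters are the autosomal shared segments with unordered states
{-1, 0, +1} and unit change cost (a -1 -> +1 change costs 1; an
ordered Wagner-style alternative would cost 2 — unordered was chosen
as the default because a single segmental event can in principle move
between any two states).  Cells with identical rows are collapsed to
one search leaf; the search therefore runs over distinct event
patterns (typically < 10), and zero-event cells — blood and
early-stage tumor cells — end up in one pattern that re-expands as a
polytomy at the root, where they cannot destabilize branch swapping.

The ratchet starts from a neighbor-joining tree on Hamming distances
and alternates hill climbing (first-improvement NNI, then SPR) on
character-reweighted data (25 % of characters doubled) with climbing
on the original weights, keeping any tree at least as good as the
incumbent; 200 iterations by default.  All distinct best topologies
are returned (canonical split sets); the first is used for rooting.
On matrices with <= 7 distinct patterns the search provably reaches
the global optimum in the test suite (exhaustive enumeration of all
<= 945 unrooted topologies).

Rooting places the root on the branch separating the outgroup (blood)
cells; when the outgroup shares its all-zero pattern with other cells
the pattern's polytomy node becomes the root.  ACCTRAN assigns
ancestral states root-down: the root is forced all-neutral, each child
keeps the parent state when its Fitch downpass set allows it and
otherwise changes immediately — placing every change as close to the
root as a minimum-change reconstruction allows.  Branch length = number
of characters changing on the branch; lengths always sum to the Fitch
parsimony score.  Remaining ties are reported as state sets per node
(preference order for the single reported state: neutral, deletion,
amplification).

## Origin report and burden summary

A *clonal clade* is a maximal clade whose stem carries >= 1 event and
whose leaves are all CNA-bearing cells; the number of such clades is
the number of independent inferred origins.  The report gives the
label composition of the largest clade and a mixing statistic (the
fraction of its internal branches whose descendants include both green
and non-green cells).  The burden summary reports mean events per cell
and the trunk fraction — stem length of the largest clonal clade over
total tree length — with >= 0.5 flagged "punctuated-like" (the
threshold is a config knob; the punctuated/gradual distinction is
qualitative in the literature).

## Cohort analyses

Cross-sample clustering is hierarchical (average linkage, Euclidean)
on bin-level log2 ratios over the intersection of usable bins —
bin-level rather than event-level, to mirror continuous CNA heatmaps —
with a per-cell purity score (fraction of k = 5 nearest neighbors from
the same mouse).  Gene copy number is read off the segment model:
2 x length-weighted mean segment ratio over the gene interval, NaN for
genes touching no usable bin.  `synthetic_gene_table` provides a
clearly-synthetic stand-in gene list (real gene coordinates are user
input).

## Numerical and testing conventions

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; equal seeds give byte-identical outputs,
  including pipeline reruns.
- Acceptance-grade checks use independent oracles implemented
  separately from the library code: brute-force changepoint search for
  CBS, full breakpoint-subset enumeration for the joint DP (complete up
  to 16 bins, bounded to <= 4 breakpoints for 20-30 bins, where full
  enumeration is combinatorially out of reach), and exhaustive topology
  enumeration with set-based Fitch for the ratchet.
- End-to-end validation runs 20 simulated tumors at the generator
  defaults above (the problem size keeps the full suite to a few
  minutes); the acceptance script reports pooled event recovery,
  false-segment rate, clone-topology recovery (Robinson-Foulds 0) and
  the single-origin-with-both-labels rate.

## Known limitations

- The joint-DP heuristic above 1,000 bins per chromosome is not
  guaranteed optimal (exact refinement is local).
- Fitch scoring at polytomies combines children pairwise, which is
  exact for the polytomies this pipeline produces (identical-state
  groups) but an upper bound for arbitrary multifurcations.
- The Bayes resolver assumes Gaussian segment means with a single
  shared SD; strongly overdispersed or bimodal segments violate it.
- Integer copy-number inference beyond cn = 2 x ratio annotation,
  allele-specific states, purity/ploidy modelling, and likelihood or
  Bayesian tree inference are out of scope.
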