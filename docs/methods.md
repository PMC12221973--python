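# Methods

This note documents the models behind each pipeline stage, the defaults
that matter, the design choices made where the design was genuinely open,
and what the synthetic-data experiments do and do not demonstrate.

## Synthetic contact maps

The generator produces the expected contact frequency of a binned map as a
multiplicative model on 0-based, half-open coordinates with fixed-width bins
(a possibly short terminal bin):

    E[i, j] = (d_ij)^-alpha x comp(i, j) x ins(i, j) x loop(i, j) x dom(i, j)

with `d_ij` the genomic distance in bp between bins, clamped to one bin on
the diagonal.

- **Decay** `alpha` (default 1.0, dimensionless): contact frequency falls as
  a power law of distance, the leading-order behaviour of real maps.
- **Compartments**: intervals labelled A/I/B; pairs of bins in the same A or
  B interval class are boosted by `f >= 1` (I is neutral). The
  `checkerboard_compartments` helper draws alternating blocks with
  *randomised* lengths (20-80 bins). Regular equal-width blocks are
  deliberately avoided: with a periodic layout, whether a pair is homotypic
  becomes a deterministic function of its distance, so the per-distance
  expected absorbs the entire compartment signal and the O/E checkerboard
  cancels. Real compartment domains vary in size; the variable-block layout
  reproduces that and keeps the planted signal recoverable.
- **Boundaries**: positions in bp; a pair straddling k boundaries is
  attenuated by `b^k`, `b in (0, 1]` (default experiments use b = 0.4).
- **Loops**: anchor bin pairs with focal enrichment `e >= 1` at the centre
  pixel and 0.9e on the eight neighbouring pixels. The halo makes pile-ups
  realistic while the centre remains the unique maximum, so the caller can
  localise the anchor to within one bin; the local 3x3 mean stays close to
  e, matching the APA convention below.
- **Domains**: intervals whose internal pairs are boosted (self-interacting
  contact domains).
- **Counts** are independent Poisson draws per upper-triangle pixel with
  means scaled to a total depth, then mirrored. Overdispersion (negative
  binomial) is not modelled; none of the validated guarantees depend on it.
- **Tracks and genes**: genes are placed evenly (or at random) and assigned
  classes GP1/GP2/GP3 with realistic proportions (0.30/0.35/0.35 by
  default, matching the observed ordering of group sizes in gene-dense
  animal genomes). GP1/GP2 TSSs receive Gaussian ATAC/H3K4me3/H3K4me2 peaks
  (height 10, width 600 bp over a gamma-noise background); enhancers midway
  between genes receive H3K4me1/me2/ATAC peaks without H3K4me3; GP3 TSSs
  receive nothing. GP1 genes are wired into loops: each loops to the
  nearest enhancer within 150 bins, and consecutive GP1 genes are chained
  into promoter-promoter hub groups of 2-5, mirroring observed hub sizes.
  A GP1 gene that ends up with no loop partner is demoted to GP2 so labels
  stay consistent with the planted map.
- **Paired genomes**: genome B is genome A with a stated fraction of the
  genes outside designated conserved blocks relocated (a random permutation
  of their positions); orthology is one-to-one on retained genes.

All randomness flows through one seeded `numpy` generator; identical
configuration and seed reproduce every output byte-for-byte.

What the simulations do **not** emulate: restriction/MNase fragment
structure, mappability-correlated coverage bias, overdispersed counts,
trans contacts, stripes/fountains, and realistic ChIP peak shapes. Passing
recovery tests therefore demonstrates algorithmic correctness under the
generative model, not performance on any particular real dataset.

## Balancing, decay, O/E, SCC

**ICE balancing** iterates marginal equalisation on the valid-bin submatrix
until the marginal coefficient of variation falls below `tol` (1e-9,
max 200 iterations; non-convergence raises with the residual). Bins whose
raw marginal is below 2% of the median non-zero marginal are flagged
invalid first — a concrete, reproducible stand-in for the coverage filters
real pipelines apply. Weights are scaled so valid-bin marginals of the
balanced matrix equal 1.

**Distance decay** is the per-diagonal mean of the balanced matrix over
valid pairs, reported on a geometric grid (ratio 1.12 per step, 1 kb-100 Mb
clipped to the chromosome) and averaged across chromosomes with equal
weight.

**O/E** divides the balanced matrix by its per-diagonal means, so every
retained diagonal has mean exactly 1 (to float precision). For saddle and
pile-up analyses `observed_over_expected(..., smooth=True)` first smooths
the per-diagonal means over a geometric window (+-25% of the distance,
pair-count weighted). The smoothed expected matters: planted (and real)
segmental structure aliases into the raw per-diagonal means — at distances
that resonate with the segment layout most pairs are homotypic, inflating
the expected and cancelling the very signal the saddle measures. Smoothing
across the oscillation removes the aliasing; the exact (unsmoothed) form is
kept as the default because its unit-diagonal property is what downstream
normalisation contracts rely on.

**SCC** smooths both maps with a 3x3 mean filter, computes the Pearson
correlation per diagonal (stratum) up to 5 Mb, and combines strata with
weights `N_d * sd_a * sd_d` (variance-stabilised stratum weighting).
Self-comparison gives exactly 1; the score is symmetric and invariant to
positive rescaling. The smoothing span and stratum cap are declared
defaults, not fitted quantities.

## Compartments

Per chromosome, the Pearson-correlation matrix of the O/E map (pairwise-
complete over missing pixels) is eigendecomposed. Instead of manual visual
inspection, the compartment eigenvector is chosen automatically among the
top three by maximal |Spearman correlation| with an orientation reference
(GC fraction or an active mark), then sign-oriented so A = high values; the
chosen index is recorded on the profile. Degenerate leading eigenvalues set
an ambiguity flag.

Saddle analysis ranks valid bins genome-wide by eigenvalue (stable sort, so
exact ties break positionally and the result is permutation-invariant),
splits them into 40 equal-count groups, drops the extreme 2.5% groups at
each end, and averages O/E per group pair across chromosomes. Compartment
strength is `(mean AA + mean BB) / (mean AB + mean BA)` over the extreme
`ceil(0.2 x retained)` groups per side. The alternative reading — top 20%
of O/E *values* within the homotypic and heterotypic halves — is available
via `mode="values"`; the ranked-group reading is the default because it is
the one consistent with eigenvector-ranked saddle construction.

The intermediate I state: the genome-wide eigenvalue distribution is fitted
with a three-component univariate Gaussian mixture by EM with deterministic
initialisation (means at the 10th/50th/90th percentiles, shared initial
variance, equal weights) and component-specific variances. EM is
implemented directly rather than through a library: the fit must be exactly
affine-equivariant (thresholds(a x + b) = a thresholds(x) + b), and library
implementations add covariance regularisation floors that break this;
`sklearn.mixture.GaussianMixture` is used as an independent cross-check in
the tests. The B-I and I-A thresholds are the density intersections between
adjacent components inside the inter-mean interval; if no real intersection
lies there the midpoint of means is used and flagged. For the planted
equal-variance mixture the intersections are the midpoints, which the fit
recovers within +-0.05 at n = 10,000.

The feature-enrichment normalisation is `-log2(1 - q)` with mid-rank-tie
quantiles `q = (rank - 0.5) / n`, so the maximum maps to `(n - 0.5)/n` and
the score stays finite; the median scores exactly 1 and a value in the top
1/64th scores 6.

## Insulation and boundaries

The insulation score of bin i at window w is
`log2(mean of the w x w diamond crossing i / chromosome mean of diamonds)`,
defined only where at least half the diamond is valid and the full window
fits. Scores are invariant to global count scaling.

Boundaries are local minima of the score; strength is the topographic
prominence of the inverted score (prominence against the lower flanking
maximum), computed with `scipy.signal.find_peaks`. Minima within two bins
of an unmappable interval are removed. The strong/weak split uses the Li
minimum cross-entropy threshold of the strength distribution, computed by
exhaustive minimisation of the Li-Lee objective over a 256-bin histogram —
exhaustive rather than fixed-point iteration because it is deterministic,
cannot stall, and is O(bins); `skimage.filters.threshold_li` (the iterative
form) serves as the independent reference in the tests. On well-separated
bimodal strengths both thresholds land in the inter-mode gap and classify
identically.

The resolution/window scan coarsens the raw counts to each candidate
resolution, re-balances, computes profiles at x5/x10/x25 windows, and
scores each grid point by mean boundary prominence (the strongest
partitioning); mean |score| is available via `criterion="absolute"`. Ties
break to the smallest resolution, then smallest windows. When two optimal
windows are used jointly, a boundary must appear in both profiles within
one bin.

Classification follows strict precedence — loop anchor > TSS (of genes not
at loop anchors) > accessible region > compartment limit > unassigned —
with a feature matching when its interval comes within one bin of the
boundary. The implementation is vectorised interval arithmetic, checked
exactly against a full-scan oracle on random fixtures.

Rescaled pile-ups take each inter-boundary domain no longer than 100 kb
between consecutive strong boundaries, extend it by one domain length on
each side, area-resample the O/E submatrix onto a fixed 3G x 3G grid
(NaN-aware area weighting), and average element-wise.

## Loops, anchors, hubs, gene groups

The focal caller marks a pixel as a candidate when (1) its O/E exceeds
`fold_threshold` (default 2) times the mean of the surrounding ring (an
11 x 11 square minus the central 3 x 3), (2) its raw count reaches
`min_count` (default 5), and (3) its raw count is Poisson-significant
against the ring's mean raw count at `pixel_alpha = 1e-6`. The third
condition is essential at realistic depths: in the sparse long-distance
band, per-pixel counts are small and chance O/E spikes alone would swamp
the calls (precision collapses to ~0.002 without it). 8-connected
candidates merge and the peak O/E pixel is reported; anchors are expanded
to two bins. External loop lists enter through the BEDPE reader and flow
through APA and annotation unchanged.

APA centres a (2h+1)-square of O/E on each loop pixel (h = 10 bins);
the score is the mean of the central 3 x 3 over the mean of the lower-left
corner quadrant (h/2 x h/2) — the short-distance background. The aggregate
APA applies the same ratio to the element-wise mean submatrix. The
centre/corner convention is a documented choice; no published formula
exists for the quantity it stands in for. Outlier filtering removes loops
with |z| > 3 on log APA (both tails: extreme high-intensity signals
typically mark rearrangements or assembly artefacts).

Anchor identity: CPM coverage of H3K4me3 and the configured enhancer mark
(H3K4me1 by default, H3K4me2 selectable — usage differs between species)
in a window around each anchor centre (window sizes of 1/2/10 kb mirror
per-species resolution choices), quantile-normalised across marks against
genome-wide tiling windows (mean-of-sorted reference, mid-rank ties). The
activity threshold is the Li threshold of the pooled window-coverage
distribution rather than a fixed coverage quantile: a fixed 70th percentile
sits inside the background bulk whenever less than ~30% of the genome
carries signal, so by construction ~30% of background windows would
classify as active; the Li threshold finds the gap between background and
signal regardless of the signal fraction. A plain quantile rule remains
available via `activity_quantile`.

Promoter hubs are connected components (>= 2 promoters) of the graph whose
nodes are P-classified anchors and edges are P-P loops, computed with
`scipy.sparse.csgraph` and checked exactly against a plain union-find
oracle. GP groups: GP1 = ATAC + H3K4me3 peaks at the TSS (+-1 kb default)
and TSS at a loop anchor; GP2 = peaks without a loop (one mark only gives
GP2 with a `partial` flag); GP3 = no peaks. Per-group APA pairs consecutive
same-group TSSs and scores them with the same APA routine; planted GP1
loops score well above 1 while GP2/GP3 pairs sit at background.

## Synteny conservation

Foreground regions (loop anchor pairs) and 3x length-matched background
regions (lengths resampled from the foreground multiset, uniform placement
rejected on foreground overlap) are mapped to flanking anchor genes
(closest overlapping gene per end; overlap first, then distance, ties to
the smaller start). The per-region conservation count is the number of
orthogroups shared between the inter-anchor gene sets of the two species,
at most one count per orthogroup per region ("between the flanking genes"
is read as the inter-anchor span; a flanking-genes-only reading is the
obvious alternative and the inter-anchor reading is the default because it
is the one that scales with region content). Global fractions are compared
with a chi-squared goodness-of-fit test using background-derived
probabilities; per-region distributions with a one-sided Wilcoxon rank-sum
test with continuity correction (`scipy.stats.mannwhitneyu`, asymptotic,
matching R's `wilcox.test`).

Calibration is assessed on the Wilcoxon test: under a uniform-shuffle null
with disjoint foreground regions its rejection rate at alpha = 0.05 is
~0.05 over 1000 replicates. The chi-squared count test is reported but is
not expected to be nominally calibrated under the permutation null — the
per-region counts it aggregates share genes and orthogroups within a
genome pair, violating the independence its null distribution assumes; it
is anticonservative there and should be read as an effect summary, as in
the original analysis setting where it accompanies the rank test.

## Problem sizes and tolerances

The validation experiments (also run by `scripts/acceptance.py`) use:
500-bin matrices for balancing (marginal CV < 1e-6 against a 10k-iteration
Sinkhorn fixed point), 1000 bins x 1e7 contacts for compartment recovery
(>= 95% sign agreement; strength within 15% of the noise-free-matrix
oracle), 2000 bins x 1e7 for boundary recovery (F1 >= 0.9 at +-1 bin),
flat-decay 1000-bin maps with 30 planted e=3 loops for the caller
(precision/recall >= 0.9; aggregate APA in [2.5, 3.5] planted, [0.9, 1.1]
loop-free), a 60-gene 3-Mb chromosome for hub/GP recovery, and 1000 null
plus 50 alternative replicates (800-2000 genes) for the synteny test.
These sizes make each experiment complete in seconds while leaving the
measured quantities far from their thresholds; depth-scaling behaviour is
monotone (error shrinks as depth grows), so larger simulations only tighten
the margins.

## Known limitations

- Dense in-memory matrices: chromosomes are processed as dense arrays, fine
  for the small genomes this targets (up to a few thousand bins per
  chromosome per resolution), not for mammalian-scale maps at fine binning.
- Cis only: no trans-contact analysis.
- The focal loop caller is a transparent stand-in, not a re-implementation
  of any published caller; for production calls on real data, import
  external BEDPE and use the APA/annotation stages.
- Poisson counts in the generator mean recovery results are optimistic
  relative to overdispersed real libraries.
- The GMM threshold fallback (midpoint of means) triggers when adjacent
  components have no density intersection between their means — e.g. when
  one component collapses; such fits should be inspected.
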