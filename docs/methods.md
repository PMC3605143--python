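# Methods

## Model of discordance

A mapped mate pair is summarised by the positions, strands and mapping
qualities of its two ends, placed in canonical (chromosome order,
position) order; chromosome order is the order of the alignment file's
sequence dictionary, which makes all downstream keys deterministic without
imposing a naming scheme. Internally all coordinates are 0-based,
half-open; SAM's 1-based positions are converted at the I/O boundary and
nowhere else.

Classification is a total function with fixed precedence:

1. mates on different chromosomes → `INTERCHROM` (there is no meaningful
   one-axis distance for such a pair);
2. orientation differing from the library's expectation (FR-inward for
   standard paired-end chemistry; RF-outward selectable for mate-pair
   libraries) → `ORIENTATION`, regardless of distance;
3. otherwise the leftmost-to-leftmost separation d = posB − posA decides:
   `WINDOW_DISTANCE` for window_min < d ≤ window_max (defaults
   1000–7000 bp), `BEYOND_WINDOW` for d > window_max, `NORMAL` below.

The boundary convention is half-open on the left: d = 1000 is normal
(a separation is abnormal only when *more than* 1000 bp), d = 7000 is
in-window. `BEYOND_WINDOW` pairs are tallied — they are useful
diagnostics — but excluded from calling by default, because separations
beyond the window are dominated by noise and by germline variation
relative to the reference rather than by somatic events; the
`count_beyond_window` switch includes them.

## Binned accumulators and the merge contract

The bin width defaults to 1000 bp so that nearly all concordant pairs fall
in one bin; two reads less than a bin apart always land in the same or
adjacent bins, which is the resolution the caller guarantees. Pass 1
tallies, per 1-D bin, (a) pair coverage counted at both ends' bins (once
per bin per pair) and (b) a leftmost-end-only coverage used by the local
coverage rule, plus per-class discordance counts; per 2-D cell
(bin × bin, canonically ordered), the per-class supporting read names and
the per-pair min(mapqA, mapqB) — a feature is only as reliable as its
worse-mapped end.

Per-pair quality is stored keyed by read name with elementwise `min` on
merge. This has three consequences at once: a pair observed twice (e.g.,
via duplicated records) is deduplicated; merging partial accumulators is
associative and commutative; and partitioning a stream arbitrarily,
counting the parts and merging reproduces the single-pass accumulator
bit-exactly. The tests verify that contract all the way to byte-identical
BEDPE output. Accumulators also serialize to a sorted line-oriented TSV
dump that round-trips exactly, so partial results from separate processes
can be reduced externally; no cluster-framework bindings are provided,
only the contract.

Unknown chromosomes are never fatal: such records are skipped and counted,
and total pairs in = pairs accumulated + pairs skipped.

## Calling

Pass 2 clusters same-class 2-D cells whose bin indices differ by at most
`adjacency_radius` (default 1) on both axes, by single linkage; the radius
exists solely to heal clusters straddling bin boundaries. A candidate
becomes a call when it has ≥ `min_support` (default 3, i.e. *more than
two*) distinct supporting pairs and those exceed `min_support_fraction`
(default 0.05) of the local coverage. Local coverage is the number of
pairs, of any class, whose leftmost end lies in the union of the
candidate's A-axis and B-axis bins — the union deduplicates a bin shared
by both axes, and counting leftmost ends only means no pair is counted
twice. A region supported by two different discordance classes yields two
calls; classes are never mixed, since they are evidence for different
rearrangement geometries.

The support-count default follows the stricter of two plausible readings
(a diagnostic cluster-size histogram, `cluster_size_distribution`, is
exported precisely so users can choose their own threshold by contrasting
matched samples); `--min-support 2` reproduces the laxer variant and both
are covered by tests. MAPQ 255 ("unavailable") enters scoring as a
configurable conservative default (20) but never affects classification.

The depth-first `local_topology_tree` export walks the call graph from an
anchor region, spawning a child for each call overlapping the current
region; each call edge is used at most once, so cycles terminate, and
traversal is depth-bounded. Output is nested JSON-serializable records;
no rendering is included.

## Quality assurance

The insert-size distribution is estimated nonparametrically: Gaussian KDE
with Silverman bandwidth on a 512-point grid over [0, max distance]
(distances above a configurable cap, default 10⁶, are excluded from the
grid), while quantiles and tail fractions are empirical so the heavy right
tail is represented exactly. A degenerate (zero-variance) sample is
represented as a point mass on the nearest grid point rather than an
error.

Read groups are screened against the pooled distances of the *other*
groups in the same sample with the two-sample KS statistic (flag above
0.1) and by the ratio of discordant-pair rates (flag above 2.0); groups
with fewer than 500 pairs are listed as "insufficient" and exempt. KS was
chosen because it is distribution-free, consistent with the nonparametric
treatment of the insert distribution; the thresholds are package
decisions, exposed as parameters, since no canonical values exist. Usable
regions are maximal runs of bins with ≥ `min_cov` pairs (default 8) in at
least `min_fraction_samples` of samples (default 0.9) — again declared,
overridable defaults. A matched tumor/blood pair passes QA iff both
samples have no flagged read group and a non-empty usable-region set.

## Cross-sample statistics

Disruption matrices count, per gene and sample, the calls with either end
region overlapping the gene (interval-tree lookup; a call touching two
genes increments both, a call inside one gene counts once). Sample
profiles are compared with the normalized mutual-information distance
D = 1 − I(X;Y)/H(X,Y), computed from plug-in (maximum-likelihood)
entropies of the joint histogram with 0·log 0 = 0 and no small-sample
bias correction; D is defined as 0 when H(X,Y) = 0 (two constant
profiles). This normalization was chosen because it is a genuine metric
on [0, 1] — identity, symmetry and the triangle inequality are all
property-tested. Profiles are binarized (disrupted / not) by default;
four-level quantile binning of counts is available for count profiles.

Embedding uses classical (Torgerson) MDS: double-center −D²/2, take the
leading eigenpair, scale the eigenvector by the square root of its
eigenvalue, and fix the sign so the largest-magnitude coordinate is
positive. A non-positive leading eigenvalue (geometry with no 1-D
Euclidean structure) raises a degenerate-geometry error rather than
returning noise.

Cluster quality is reported as 1 − C, where C is the Hubert–Levin
statistic: with S the sum of the m within-cluster distances and
S_min/S_max the sums of the m smallest/largest distances in the whole
matrix, the index is 1 − (S − S_min)/(S_max − S_min). The orientation is
flipped from the classical low-is-good C so that 1 means maximally
compact, matching how the index is conventionally quoted for good
clusters. If every pairwise distance is equal the index is returned as 1
with a warning.

Coverage bias is diagnosed two ways: the Pearson correlation between
per-gene coverage and per-gene disruptions (near zero is desirable; zero
variance yields a flagged NaN, not an exception), and a greedy
node-deletion biclustering that repeatedly removes the row or column whose
removal most lowers the Cheng–Church mean squared residue until it falls
below a threshold (ties break toward rows, then earlier indices; if the
matrix would shrink below 2×2 first, the best submatrix found is returned
with a warning). The greedy variance-deletion procedure is this package's
own concrete choice of biclustering; it recovers a planted constant block
reliably in tests, which is all that is asked of it here.

## Simulator: what it does and does not emulate

The generator draws background pairs with leftmost positions uniform over
chromosomes, FR-inward orientation, insert sizes N(400, 50²) truncated
positive, and MAPQ 60; a `mismap_noise_rate` fraction (default 0.001 —
the long-distance tail rate of a well-behaved germline library) has its
mate re-assigned a uniformly random chromosome/position/strand at MAPQ 15.
Planted deletions emit pairs whose separation is insert + size (sizes
default inside the 1000–7000 bp window, so the signal lands in the
calling band; larger sizes exercise the beyond-window exclusion),
inversions emit same-strand pairs straddling the locus, translocations
emit pairs joining the two partner loci; support positions are jittered
within one bin of the breakpoints. One seeded generator drives a
scenario, with a fixed draw order (background, then each planted event in
declaration order), so identical seeds give byte-identical SAM output.

Deliberately not modelled: sequence bases, read errors, alignment itself
(only its output), copy number, chimeric artifact structure, GC or
mappability bias, and correlated (non-uniform) mismapping. Consequently,
a passing planted-recovery test demonstrates the caller's geometry,
thresholds and score behave as specified at realistic densities — it does
not certify sensitivity or specificity on real libraries, where mismapping
clusters in repetitive regions rather than scattering uniformly.

## Problem sizes and numerical choices

Tests and the acceptance script run matched-pair scenarios on a 10-Mb
two-chromosome genome at one pair per kilobase (≈10⁴ pairs per sample;
100 replicates in the test suite, 20 in the reporting script) — enough
for every property under test to be measured far from its thresholds
while keeping a full run to tens of seconds. Scores are exact products of
powers of ten; BEDPE scores are written at 4 decimals and support
fractions at 6, with stable sorts everywhere, so all writers are
deterministic. KDE integration is checked by trapezoidal quadrature to
±0.01. MDS accepts matrices symmetric to 10⁻¹² and reconstructs exact
1-D geometries to better than 10⁻⁸.

## Known limitations

Breakpoints are reported at bin resolution (regions, not base pairs), and
the caller does not reconstruct what rearrangement produced a feature
beyond its discordance class. Two tight clusters in adjacent bins
(separation between one and two bin widths) merge into one candidate;
that is the price of the linear-time bin geometry and is bounded by the
adjacency radius. Read-group screening assumes groups share a library
design; a sample whose groups are *all* shifted the same way has nothing
to flag. The biclustering is greedy and makes no optimality claim. CRAM
input and split-read/soft-clip evidence are out of scope.
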