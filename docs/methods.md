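# Methods

`ceda` treats every continuous feature as carrying an authentic
categorical structure, reads associations and classifications off
contingency tables built from those categories, and analyzes multivariate
responses locality by locality on a covariate bin lattice.  This note
records the models, the estimators, the defaults, and the choices made
where the design was genuinely open.

## Possibly-gapped histograms

A feature's categorization is a piecewise-linear (PL) approximation of
its empirical CDF.  Bin edges are chosen by recursive maximum-deviation
bisection (Ramer–Douglas–Peucker) of the ECDF, then refined until the PL
interpolant through the edges deviates from the ECDF by at most `tol`
(default 0.02, i.e. 2% of the sample) everywhere on the observed
support.  Deviations are measured against the *jump-midpoint* version of
the ECDF: a step of mass `m` cannot be tracked closer than `m/2` by any
continuous function, while its midpoint can be matched exactly, so the
midpoint convention is the only target for which the tolerance contract
is satisfiable on data with ties.

Gap detection runs first: a spacing between consecutive distinct values
is declared a gap when it exceeds `max(gap_factor, log2(u)) × (median
spacing)`, with `gap_factor = 3` and `u` the number of distinct values.
The `log2(u)` floor is essential: spacings of a continuous sample behave
like exponentials, whose maximum is routinely `~log2(u)` times the
median, so a fixed multiple alone misclassifies ordinary sampling
fluctuations as structure (measured on smooth data: roughly one spacing
in eight exceeds three times the median).  Detected gaps split the
sample into clusters segmented independently, bridged by a single edge
at each gap midpoint; bins therefore tile the support and a query in a
gap is assigned to the nearest bin by boundary distance (exact midpoints
break toward the lower-indexed bin).

Features with at most `discrete_max = 12` distinct values are treated as
discrete — one bin per value, edges at both the values and their
midpoints, making the PL error exactly zero.  Without this, a k-level
feature can never occupy k bins (edges at data values yield k−1), and a
label-like feature would be merged with itself shifted by one level.
Uniform and equal-frequency binnings are available as explicit fallbacks.

## Conditional-entropy associations

For a contingency table, the directed association row→col is the
occupancy-weighted mean of row-conditional Shannon entropies of the
column variable, rescaled by the column-marginal entropy:
`CE(row→col) = Σ_i (n_i·/N) H(p_·|i) / H(p_·)`, a number in [0, 1]
(0 = the rows determine the columns, 1 = independence), invariant under
row and column permutations and hence sensitive to arbitrary nonlinear
association.  The mutual conditional entropy (MCE) is the plain mean of
the two directions; whether the average should be entropy-weighted is
open in principle, and the simple mean was adopted.  Degenerate
marginals define the measure as 0; empty rows and columns are ignored
(both properties are tested).

The K×K MCE matrix is clustered hierarchically *using the matrix itself
as the distance* (average linkage by default; the linkage method is
configurable since nothing deeper than "a hierarchical clustering" is
required).  Feature-groups are the flat clusters at a cut height
defaulting to 0.7 × the median off-diagonal MCE — a heuristic standing
in for reading blocks off a heatmap by eye, and always overridable.

## Label-embedding trees from triplet dominance

Direct cloud-to-cloud distances (optimal transport, Gromov-type) are
dominated by the clouds' edges and tails.  The rank-based alternative:
each round samples a label triple uniformly, one point per cloud (with
replacement), computes the three pairwise Euclidean distances, and
records the two larger pairs as *dominating* the minimal pair.  Row sums
of the resulting pair-by-pair dominance matrix, divided by the number of
rounds the pair participated in, give each label-pair's relative
distance; the participation normalization matters for more than three
labels, where pairs enter unequal numbers of triples.  Exact distance
ties are discarded and resampled (measure zero for continuous features;
a resampling cap keeps degenerate inputs terminating).  Average-linkage
clustering of the relative-distance matrix yields the label-embedding
tree (LET).  Defaults: `n_rounds = 1000 × C(L,3)` capped at 10⁶;
distances on raw feature scales, with optional per-feature z-scoring.
On the Iris petal pair the exhaustive expectation over all 50³ triplets
is (0.894, 0.000, 0.106) for the minimal-pair probabilities of
(virginica-versicolor, virginica-setosa, versicolor-setosa); Monte-Carlo
runs are tested against that enumeration within 3 binomial σ.

## Set-valued prediction

A query descends the LET playing one Left-vs-Right competition per
internal node using its `k* = 20` nearest training neighbors among the
node's labels.  If the minority branch holds less than `dominance_share
= 0.10` of the pooled neighbors, the majority wins outright.  Otherwise
each branch contributes the distances from the query to its own k*
nearest members, each sample becomes a Gaussian-KDE pseudo-likelihood
(Silverman bandwidth), both densities are evaluated at the median of the
pooled 2k* distances, and the ratio is compared with the band
`[cl, cu] = [0.65, 100/65]`: above → Left, below → Right, inside → no
winner, and the node's member set is the prediction.  This
common-reference construction — "which branch's distance distribution
puts more mass at the typical neighborhood radius" — is the package's
resolution of the least constrained part of the scheme; the variant
evaluating each density at its own branch median, and pooling over all
branch members instead of neighbors, are available behind
`CompetitionConfig` switches.  `cl = cu = 1` forces a singleton
prediction at every node (and forfeits the reject and outlier options).

Outliers are rejected before descending: a query whose nearest training
point is farther than the 0.99 quantile of the training set's
leave-one-out nearest-neighbor distances returns the empty set.  The
quantile rule quantifies a capability the scheme names but does not
specify; on duplicate-heavy data the LOO distances concentrate at zero
and the rule is deliberately strict.

## Chains, pattern-categories, and dissecting external classifiers

A chain re-examines, through a second (and optionally third)
feature-group's LET, exactly those queries whose current
pattern-category — the ordered tuple of predicted label-sets so far — is
*uncertain*, i.e. was reached by calibration points of more than one
true label.  The registry of observed categories is built on the 20%
held-out calibration split; categories never seen in calibration are
flagged `novel` (supported set = the first stage's members) rather than
guessed.  Chains are capped at three stages.  An external classifier's
single-label decision is dissected into
certainty/uncertainty × coherent/incoherent by locating its
pattern-category in the registry.

One structural fact deserves emphasis: for deterministic per-point stage
predictions, a fully refined two-stage chain produces the *same*
multiset of uncertain terminal categories in either stage order — a
terminal tuple (σ, τ) contains exactly the points with stage sets τ and
σ regardless of which came first.  What the order genuinely controls is
how much is settled at the first stage (points in first-stage-certain
categories, number of categories needed), which is the sense in which a
major factor should lead the chain; the tests assert both the invariance
and the first-stage dominance on a planted fixture.

## Response manifold analytics

With responses (Y1, Y2) and major covariates (X1, X2), the major
covariates' bins frame a lattice of rectangular localities; every
training point lies in exactly one.  For real manifolds a handful of
strips per major covariate is the working resolution; `locality_lattice`
accepts `n_bins` to force k equal-frequency strips (the analyses here
use 3×3, matching the synthetic generator's planted grid).

**Major-factor score.**  "Bins of a major covariate mark clear-cut
strips on the manifold" is operationalized as the relative conditional
entropy improvement: within each anchor bin (or the whole sample when no
anchor is given), `1 − H(binned responses | candidate bins) / H(binned
responses)`, occupancy-weighted.  Responses are jointly binned
equal-frequency at 4 bins each and covariates at 8 — a common fixed
resolution so scores are comparable across candidates, chosen so the
doubly-conditioned cells stay populated at the sample sizes used
(n ≈ 1500–2000); entropies carry the Miller–Madow small-sample bias
correction.  The ECDF-approximation histogram is *not* used here: it
legitimately collapses a smooth covariate to one or two bins, which has
no conditioning power.  A sequential search (best unconditional
candidate, then best candidate conditional on it) recovers the planted
majors of the spiral fixture in 40/40 seeded runs; a default flag
threshold of 0.3 is provided but ranking is the primary use.

**Minor factors.**  Within each locality, the Shannon entropy of a
candidate's level distribution and the normalized localization score
`1 − H_locality / H_global` (0 = no localization, → 1 = one level
dominates).  A candidate is flagged minor when its maximum score over
localities with at least 20 members exceeds 0.5; the size floor exists
because the entropy of a few points is spuriously zero.

**Prediction.**  Locate the query's locality by nearest-bin assignment
(nearest non-empty locality, flagged, if the cell is unoccupied); take
the `k* = 20` nearest locality members in raw major-covariate space;
filter them to the query's minor level, falling back (flagged) to the
unfiltered neighbors if the filter empties the set; predict the mean
response vector.  With one global locality and no filter this is exactly
k-NN regression, and is tested for equality against an independent
implementation.

**Errors.**  Besides per-response SSE, the covariance-rescaled error
`Σ e_iᵀ Σ̂⁻¹ e_i` with Σ̂ the sample covariance (divisor n−1) of training
responses, either overall or locality-specific (localities under 10
members fall back to the overall matrix; singular matrices fall back to
the pseudo-inverse with a warning).  The quadratic form is invariant
under joint linear reparameterization of responses and covariance,
which is tested numerically.

## Synthetic generators

`generate_clouds` draws exact-size Gaussian clouds; the `engulfed_by`
construction places a small cloud on a larger one's flank, producing the
asymmetric mixing the set-valued classifier is designed to expose
(mixed sets concentrate in the engulfed label's column).
`generate_manifold` draws the spiral `(Y1, Y2) = A(θ, ρ)(cos θ, sin θ)`
with `A(θ, ρ) = (c0 + c1 ρ) θ`, defaults `c0 = 1, c1 = 1.5`,
`θ ∈ (0.6, 4.7)`, `ρ ∈ (0, 1)`, Gaussian response noise σ = 0.05 —
noise small against the tercile amplitude separation (≈ 0.5·θ) so the
modulator's bins form visible strips, which is the regime the method
targets.  A three-level minor factor dominates three declared cells of
the 3×3 (θ, ρ) grid at probability 0.9 and shifts responses by ±0.3
there; one continuous and one uniform categorical nuisance are
independent of everything.  `generate_complementary_clouds` builds four
labels whose separability is split across two feature pairs so that a
chain led by G1 settles half the labels at stage one.  All generators
are bit-reproducible under a seed and emit ground-truth sidecars.

What the generators do not emulate: heavy tails, measurement
quantization, covariate-dependent noise, label imbalance, and drifting
class geometries.  Passing recovery tests on these fixtures shows the
estimators find the structure they define, not that real tracking data
would be as clean.

The vendored 150×4 Iris table (checksum-pinned) is the worked example
throughout; its known quirk — a few versicolor individuals deep inside
the virginica petal cloud — is precisely what makes set-valued
prediction informative there, and also why "every versicolor point gets
a correct singleton" holds only for favorable train/test splits.

## Numerical and degenerate-input conventions

Ties in neighbor sorts are broken by stable index order; dominance-round
distance ties are discarded and resampled; KDE on a zero-variance
distance sample degenerates to a point mass; a feature whose histogram
collapses to one bin is reported as unassociated (MCE 1) with a warning;
empty contingency tables, single-label rankings, sub-3-label triplet
runs, and non-finite inputs raise `ValueError`.  Problem sizes in the
test and acceptance runs — 1000 dominance rounds on Iris, 20 seeded
splits, 40 seeded manifold runs at n = 1500 — are the package's standard
demonstration scale and complete in seconds.
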