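# Methods

This note records the model, the conventions that could plausibly have been
chosen otherwise, and what the synthetic benchmark does and does not show.
Every convention listed here is also emitted in the CLI's run manifests.

## Data model

An ensemble is a set of trajectories sharing one strictly increasing,
uniform time grid (fs), with fixed atom count and ordering (coordinates in
Å).  Trajectories of unequal length are truncated to the shortest common
frame count at assembly (`on_length_mismatch="truncate"`, the default, with
an `"error"` mode to refuse).  We deliberately did not introduce a second,
ragged ensemble type: the L₂ metric requires equal lengths anyway, and for
DTW-only analyses of unequal-length data `pairwise_dtw_ragged` accepts a
plain list of per-trajectory (time × feature) arrays instead.  One
invariant-rich container beats two.

Electronic-state populations are optional, validated entry-wise to [0, 1]
only; per-trajectory sums are *not* required to be 1, since semiclassical
weights can legitimately deviate.

## Features

Internal coordinates only: bond lengths (Å), bend angles and signed
dihedrals (degrees).  Atom indices are one-based everywhere a user sees
them (chemical numbering).  The dihedral uses the two-argument arctangent
form (stable near 0°/180°) with the convention that, looking from the
second to the third atom, clockwise rotation of the far bond is positive;
under this convention the torsion is invariant under reversal of the atom
order and changes sign under mirror reflection.

Dihedral time series are unwrapped per trajectory by default (consecutive
steps forced to |Δ| ≤ 180°).  This matters twice: channel-center torsions
can genuinely exceed 200°, which is unrepresentable in the principal range,
and a ±360° seam crossing would inject a huge spurious jump into both L₂
and DTW distances.

Min–max normalization uses *global* extrema per feature (over all
trajectories and times), so one affine map applies ensemble-wide and
normalized distances remain comparable across trajectories.  Constant
features map to 0 (not NaN, not dropped — shapes stay stable) with a logged
warning; they have zero variance and are never selected.  Feature ranking
uses population variance on normalized values; ranking raw values is
available behind a flag for diagnostics only.  The number of retained
features *k* is a user parameter (typically 4); no variance threshold is
hard-coded.

## Distances

**L₂ (p = 2).** d = (Σ_t Σ_f |x_tf − y_tf|^p)^(1/p), a strict 1:1 time
mapping.  Exact metric axioms hold (tested on random triples).

**MD-DTW (dependent variant).** One shared warping path over all features;
local cost = plain Euclidean distance across features at a pair of time
points (not squared — the total cost is the literal sum of path elements,
so the band-width-0 limit coincides with an L1-over-time aggregation of the
local costs).  Dynamic program with the symmetric step pattern
{(−1,0), (0,−1), (−1,−1)}, unit weights.  The accumulated cost is *not*
normalized by path length; DTW and L₂ values therefore live on different
scales and need different ε ranges downstream.

Frequency invariance is limited by a Sakoe–Chiba band of half-width *w*
(time steps) around the diagonal; default w = max(1, 5% of the series
length).  DTW is intended here to absorb *small* temporal offsets between
otherwise similar trajectories, not to identify different vibrational
frequencies with each other.  Back-tracing ties are broken
deterministically (diagonal, then advance-first-series, then
advance-second-series); tie-breaking never changes the distance, only which
optimal path is reported.

The pairwise stage is a numba-compiled kernel; a 90-trajectory,
150-frame, 4-feature DTW matrix takes on the order of a second.

## DBSCAN

Classic semantics on the precomputed matrix: MinPts counts the point
itself; neighbourhoods are closed balls (≤ ε); clusters grow from core
points in ascending trajectory index, which also resolves the classic
order-dependence of border points reachable from two clusters (first
discovered cluster wins) — every run is bit-reproducible.  Cluster ids are
consecutive integers in discovery order; noise is −1.

**Parameter scan.** One distance matrix is reused across the whole
(ε, MinPts) grid.  Cells with fewer than two clusters carry NaN for S_avg
(a silhouette needs a nearest *other* cluster) and never rank.  Ranking of
cells: S_avg descending, ties by lower noise count, then lower ε —
preferring solutions that explain more of the ensemble.

**Default ε range.**  When no range is given, it is derived from the
k-distance distribution (k = largest MinPts scanned): from the 95th
percentile of per-point k-distances up to 2.5× that value, 20 values.
Below the top of the k-distance bulk DBSCAN shreds genuine clusters into
tight cores plus bulk noise — a regime where the silhouette (computed over
the surviving clustered points only) can *reward* discarding most of the
data; above it, results are stable until clusters merge.  Restricting the
scan to this range is the standard k-distance-plot reading of DBSCAN
parameter choice, expressed as an automatic rule.

## Silhouette

a_i = mean distance to the *other* members of the own cluster (denominator
|C_I| − 1; a literal-|C_I| option exists for sensitivity checks), b_i = the
smallest mean distance to another cluster, s_i = (b_i − a_i)/max(a_i, b_i).
Noise trajectories are excluded from every mean and from S_avg; singleton
clusters get s_i = 0 by convention (they cannot arise with MinPts ≥ 2).
Silhouettes always reuse the same matrix that produced the clustering —
mixing metrics between clustering and validation is refused by
construction.

Cluster centers and spread envelopes are computed on *unnormalized*
features so plots carry physical units; the envelope is the member standard
deviation by default (percentile and min–max bands available — the choice
is cosmetic and does not affect any statistic).  Representatives are
medoids (smallest total intra-cluster distance, ties by index).  The
population split classifies a trajectory as dominant in state *a* iff
P_a > P_b strictly at the analysis time (a point exactly on the x = y line
counts as not dominant-a).

## Synthetic benchmark

The generator emulates the statistical structure of a branching
photochemical ensemble, not its physics: no forces, surfaces or hopping.
Each trajectory follows a shared damped-oscillatory transient
(period 20 fs, decay 25 fs) from a common starting geometry, then branches
at its channel's onset (40–50 fs) and relaxes exponentially toward
channel-specific targets in four features (one C–C bond, three torsions),
with channel oscillations, i.i.d. Gaussian noise per frame, and an integer
temporal jitter drawn uniformly in ±2 steps.  Populations (two states)
ramp sigmoidally toward each channel's dominant state.  Defaults: 90
trajectories over 150 fs at 1 fs, channel fractions 0.40/0.35/0.25
(hot-reactant return / ring-opened ground-state product / excited
high-torsion channel whose central torsion runs to ~215°, exercising
unwrapping).  An optional fourth minor channel (fraction 0.15, fractions
renormalized) carries a 2.5× dispersion multiplier — a deliberately broad,
sparse cluster probing DBSCAN's known weakness with variable density.

Deterministic details chosen for testability: trajectories are allocated
to channels by largest remainder (exact, reproducible counts); all random
draws come from a single seeded generator in canonical order (trajectory
index, then time), so equal seeds give bit-identical ensembles; the
between-channel final-time feature gap exceeds 6× the per-feature noise SD
(`channel_separability`), which is what guarantees recoverability.

Cartesian embedding places each feature on an independent atom unit of a
synthetic probe molecule (bond units along z; torsion units rotating the
far atom about the central axis), spaced 10 Å apart.  Feature
re-extraction from the embedded XYZ recovers the generated series to
1e−6, so file-level fixtures are indistinguishable from real inputs.

What passing on this benchmark does **not** show: robustness to
non-Gaussian or correlated noise, to channels connected by intermediate
trajectories (density bridges), to strongly unequal channel time scales,
or to feature sets where the discriminating coordinates are unknown.  The
generator's channels are well separated by construction; real ensembles
need the parameter scan and silhouette/noise diagnostics precisely because
that separation is not guaranteed.

## Problem sizes and runtime

Unit tests run scaled-down ensembles (typically 24×60) where the tested
property does not depend on size; end-to-end recovery checks use the full
default 90×150×4 conditions across 10 seeds, and oracle-equivalence checks
use exhaustive enumeration (series ≤ 6 points) and brute-force
density-reachability (n ≤ 40) at instance counts in the low hundreds.  The
whole suite completes in well under a minute on one CPU; the acceptance
script in a few seconds plus one-off numba compilation.

## Known limitations

- DBSCAN uses one global ε: channels of very different density may not be
  resolvable at any single cell (the broad-channel fixture demonstrates
  the regime, not a fix); OPTICS/HDBSCAN-style variable-density methods
  are out of scope.
- DTW here is the dependent multidimensional variant only; there is no
  per-feature (independent) warping, no subsequence DTW, and no
  lower-bounding acceleration — ensembles of a few hundred trajectories
  are well within reach without it.
- No periodic-boundary handling and no binary MD formats (gas-phase
  multi-frame XYZ is the interchange format).
- Cluster significance is not reweighted by quantum amplitudes; cluster
  size is the only weight reported.
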