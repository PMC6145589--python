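# Methods

`planarnets` analyses planar spatial networks — undirected simple graphs whose
nodes carry 2D coordinates — with the measures and null models used to compare
biological distribution systems such as mycelial fungi and the pial
vasculature on the rodent cortical surface.  This note records the models, the
parameters that matter, the numerical choices, and the limits of what the
synthetic experiments can show.

## Network model

A network is a binary adjacency structure `A_ij` plus coordinates
`{x_i, y_i}`.  Coordinates are unitless; all derived lengths inherit the input
unit, and every headline quantity is either dimensionless or a ratio, so the
unit never matters.  Edges are straight segments (vessel/cord tortuosity is
neglected) and flow is assumed bidirectional.  Connectivity is enforced at
load time because every path-based measure assumes it; an override exists for
deliberately damaged networks.  Duplicate node coordinates only warn (they
break nothing unless an edge has zero length, which is an error).

The vasculature-specific *reduced* form removes degree-1 nodes labelled
`penetrating_arteriole` together with their incident edge, in a single pass:
the reduction models dropping arteriole offshoots, not iterated leaf pruning,
so nodes that become degree 1 afterwards stay.

## Measures

* **Mean degree** `<k> = 2M/N` and average clustering `C` (degree-<2 nodes
  count as zero; the alternative of excluding them shifts `C` but not the sign
  of any group difference on synthetic cohorts).
* **Alpha index (meshedness)** `alpha = (M - N + 1) / (2N - 5)`: the number of
  independent cycles relative to the maximum possible in a planar graph; 0 for
  trees, 1 for maximal planar networks.
* **Topological efficiency** `E^t`: mean inverse hop-count shortest-path
  length over ordered pairs; unreachable pairs contribute 0, which keeps the
  measure defined on damaged networks.
* **Wiring length** `W = sum_{i>j} A_ij D_ij` with `D` the Euclidean distance
  matrix: the material-cost proxy.
* **Physical efficiency**: `E^p_avg` is the mean inverse shortest
  *summed-edge-length* path; `E^p` divides by the same quantity for the
  complete graph on the identical node positions (inverse straight-line
  distances), giving a [0, 1] routing-capability score.  We read "fully
  connected network with the same number of nodes" as the complete graph on
  the same positions; an idealised-position alternative is undefined.
* **Edge betweenness**, topological and physical: per edge, the sum over
  unordered node pairs of the fraction of shortest (hop-count, respectively
  Euclidean-length) paths through that edge.  Tied path lengths split the
  contribution fractionally; for geometric weights two lengths tie when they
  agree to 1e-9 relative, which makes lattice fixtures (where alternative
  routes are exactly equal) behave like their exact rational counterparts.
  Only the *rank* correlation between the two variants (Spearman rho) is used
  downstream, so the unordered-pair convention is immaterial there.

## Null models

* **Euclidean MST** — minimal total edge length over all spanning trees of
  the node positions; computed on the Delaunay edge set (a strict superset of
  the Euclidean MST) so it scales near-linearly; collinear degenerate inputs
  fall back to the complete pair list.  The MST is the lower anchor for cost,
  efficiency and robustness.
* **Greedy triangulation (GT)** — node pairs are connected in ascending order
  of distance whenever the new straight edge crosses no accepted edge (ties
  broken by smaller then larger node id; a shared endpoint is not a crossing,
  collinear overlap is).  The result is a maximal planar straight-line graph:
  for points in general position exactly `3N - 3 - h` edges (`h` = hull
  vertices), which doubles as the termination test.  The implementation walks
  the full distance-sorted pair list with a uniform-grid spatial index so only
  nearby edges are crossing-tested; it is validated against a quadratic
  reference implementation and brute-force maximality checks.
* **Connected degree-preserving rewiring** — double-edge swaps that reject
  self-loops, multi-edges and disconnection, targeting 15 accepted swaps per
  edge (attempt cap 100 per edge), applied in windows with rollback so the
  connectivity check amortises.  Sources with no valid swap (stars) return
  flagged copies.  Rewired members keep the source coordinates, which is what
  makes their physical Rent exponents and "same-positions" comparisons
  meaningful.  Ensemble normalisation `X / <X_rewire>` reports NaN with a
  diagnostic when the ensemble mean is zero (typical for clustering).

Relative measures anchor an empirical value between MST (0) and GT (1):
`W_rel = (W - W_MST) / (W_GT - W_MST)` and likewise for `E^p` and `R`.
Values slightly outside [0, 1] are possible (robustness is stochastic; a
badly embedded network can be less efficient than its MST) and are reported,
not clipped.

## Rentian scaling

Rent's relation `m ∝ n^r` links the nodes `n` inside a partition to the
edges `m` crossing its boundary.

*Topological* partitions come from recursive balanced min-cut bisection:
a spectral split (median of the Fiedler vector, scanning rotations within the
span of the two lowest nontrivial Laplacian modes — square meshes have a
degenerate pair whose arbitrary mixture would give diagonal cuts) followed by
a greedy boundary-refinement pass under a 10% balance tolerance.  Five runs
with jittered tie-breaks are averaged.  Partitions recurse while they hold at
least `min_partition = 8` nodes, and every partition at every level emits a
sample.  Two boundary measures are provided:

* `crossing` (default) — `m` counts whole-network edges with exactly one
  endpoint inside.  On finite meshes this measure is *intrinsically* biased
  low: partitions abutting the free outer boundary lose crossing edges, and
  exact enumeration of ideal recursive bisection of a 16x16 / 32x32 grid
  gives all-level slopes of 0.33 / 0.41, not the interior mesh value 1/2.
  Our estimator reproduces those enumeration values to ~0.01, which is the
  real calibration of partition quality.
* `cut` — `m` is the bisection cut that created the partition; for a mesh
  the balanced min cut is `~ sqrt(n)` at every scale, so this measure tracks
  the interior exponent, though the ordinary-least-squares fit over the
  cut "stairstep" overshoots on small meshes (ideal value 0.578 at L=16,
  which the estimator again reproduces).

Empirical-network summaries use the `crossing` default; since the reported
quantities are ratios against rewired ensembles partitioned the same way, the
finite-size bias divides out to first order.

*Physical* partitions are 5000 axis-aligned squares with side uniform in
`[s_min, s_max]` and uniform centre, rejection-sampled until all four corners
lie inside the node cloud's convex hull.  `s_min` is the side holding two
nodes in expectation at the global density; `s_max` is the largest side with
at least 1% containment acceptance (calibrated on 1000 trials) — a concrete
"random side" distribution that spans scales while keeping rejection
sampling usable.
Boxes are half-open to avoid double counting; `n` counts nodes strictly
inside and `m` edges with exactly one endpoint inside (an edge whose segment
geometrically clips the box but has both endpoints outside is *not* counted —
Rent's rule is about node partitions).  Samples with `n = 0` or `m = 0` are
excluded before the log-log fit.  On meshes this estimator lands on
0.5 ± 0.01.

Exponents are ordinary least squares of `log10 m` on `log10 n`; fits report
Pearson r and r².  The theoretical minimum physical exponent is
`p_min = max(1 - 1/d_E, t)` with `d_E = 2`, and `t >= 1 - 1/d_T` bounds the
topological dimension.

## Robustness

`R` is the percentage of edges removed, along a uniformly random order, at
which the largest connected component first drops *strictly* below `N/2`
(the strictness choice matters only at parity ties and is configurable in
spirit: group-level conclusions on synthetic cohorts are insensitive, single
networks can differ by one removal).  Each trial is one permutation; the
crossing point is found backwards with a union-find over edge re-additions,
so a 20-trial estimate costs `O(20 M α)`.  20 trials is the default
throughout.

The efficiency-decline experiment removes `floor(f M)` random edges for each
`f` on a grid from 0 to 0.6 in steps of 0.004 (independently per `f` and
trial; a nested single-permutation mode exists), recomputes `E^p` with
unreachable pairs contributing zero, and averages the ratio `E^p(f)/E^p(0)`
over 20 trials.  The initial damage sensitivity is the OLS slope on
`f ∈ [0, 0.1]`.  For large cohorts the inverse-path-length sums can use a
fixed random subset of source nodes (`n_sources`); this is an unbiased
estimator of the ordered-pair mean, the `f = 0` denominator uses the same
subset so the ratio anchors at exactly 1, and the cohort analyses use 128
sources (exact all-pairs sums remain the default and are what unit tests
exercise).

## Synthetic generators

The generators produce connected planar networks in the two empirical
regimes; they define the study conditions for every cohort-level result.

Mechanism: sample points in a square region; build the Delaunay
triangulation (guaranteeing a planar embedding and a sane degree range);
remove edges in random order under a length-bias `P(remove e) ∝ |e|^beta`,
skipping bridges so connectivity is never broken, until the target alpha
index is hit (the achievable alpha granularity is `1/(2N-5)`, so targets are
met within ±0.01 for N ≥ 55 and far tighter at study sizes).

* *Mycelium-like*: radial Gaussian point density around a central `inoculum`
  node (no empirical density profile is published; this models outward growth
  from the food source and is a modelling convenience), default target alpha
  0.14,
  and `beta = 0` — cross-cords fuse wherever hyphae happen to meet, roughly
  independent of cord length, so the surviving loops carry genuine extra
  wiring.  This lands the regime at `W_rel ≈ 0.3`, the empirical fungal
  value.
* *Vasculature-like*: uniform backbone points pruned with `beta = 2`
  (vessel layouts shed long redundant segments under cost pressure, keeping
  wiring minimal, `W_rel ≈ 0.06`), default target alpha 0.02, plus
  `ceil(stub_fraction × N)` degree-1 `penetrating_arteriole` nodes (default
  fraction 0.4) attached by short edges placed in the widest free angular gap
  at the attachment node, which preserves planarity by construction and is
  re-checked against nearby edges.

A single integer seed drives one PCG64 stream per generator call, so equal
configurations give bitwise-equal networks.

What the generators do *not* emulate: real vessel/cord radii and conductances
(no weights anywhere in this package), flow-adapted loop placement (real
vessel networks place loops where they shorten routes, which no random
pruning of a Delaunay graph does — synthetic `E^p_rel` sits near 0 for both
regimes, so only the *non-dominance* of the efficiency contrast, not its
absolute level, carries over to real data), tortuosity, and growth dynamics.
Cohort-level conclusions should therefore be read as statements about the
size/loop-density/cost structure of the regimes, not about vascular
optimisation.

## The matched cohort

The cohort reproduces the empirical study design: 13 mycelium-like and 9
vasculature-like networks whose node counts and per-network alpha targets are
copied from the published size table (so the mean degree and alpha group
statistics are the empirical ones by construction), analysed with 20-trial
robustness, MST/GT relative measures, and decline slopes (26 grid points on
[0, 0.1], 20 trials, 128 source samples).  The full cohort runs in about
three minutes on one core.  A pooled-variance two-sample t-test compares the
regimes per metric (the pooled variant reproduces the published p-values on
the size-derived rows; Welch is available and reported alongside in the
analysis output); SEM is the sample standard deviation over `sqrt(n)`.  No
multiple-testing correction is applied across rows, matching the original
analysis.

## Known limitations

* Min-cut bisection is heuristic (spectral + refinement); it matches exact
  enumeration on meshes but carries no optimality guarantee on irregular
  graphs.
* The greedy triangulation accepts up to ~4000 nodes (quadratic candidate
  list); larger inputs need a different candidate generator.
* Physical edge betweenness is exact but pure-Python Brandes,
  `O(N M log N)`; practical to a few thousand nodes, so the cohort pipeline
  computes the betweenness rank correlation only on request.
* `R` is undefined for `N = 2` under the strict halving rule (a singleton is
  exactly half); the implementation reports full removal there.
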