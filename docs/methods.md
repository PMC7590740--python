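# Methods

## Data model

A gated cytometry admits three equivalent descriptions: the labelled point
set `{(x_j, y_j)}`, the partition of events into per-cell-type clusters with
weights, and a mixture of location-scatter distributions
`{(m_k, S_k, p_k)}` whose parameters are the empirical moments of each
cluster.  `flowot` operates on the third view.  `summarize` builds it with
one component per cell-type label: the mean is the label's empirical mean,
the covariance the unbiased (`n_k − 1`) empirical covariance, and the weight
the empirical proportion `n_k / n`.  Proportions-as-weights is a design
choice: it makes the summary a proper mixture so transport masses have a
population interpretation.

Tiny clusters break the symmetric-positive-definite (SPD) invariant, so a
scaled ridge `ridge · (trace/d) · I` (default `ridge = 1e-6`) is added
whenever a label has at most `min_points` events (default `d + 1`) or the
raw covariance is not positive definite.  Markers are matched across a
database by name, never by column position; mismatches are errors.

FCS support is read-only (versions 3.0/3.1, events segment, list mode,
float/double/integer data) and returns raw values: spillover compensation
and variance-stabilising transforms are deliberately upstream choices — the
more the transformed data resemble a location-scatter mixture, the better
every step below behaves.

## Distances

* **Between clusters** the default cost is the closed-form 2-Wasserstein
  distance between Gaussians,
  `W2² = ‖Δm‖² + tr(S_a + S_b − 2(S_a^{1/2} S_b S_a^{1/2})^{1/2})`.
  Matrix square roots use symmetric eigendecomposition with eigenvalues
  floored at 1e-12 and re-symmetrisation; the Bures term is clamped at zero;
  bitwise-identical parameters short-circuit to exactly 0 so "zero iff
  identical" holds without floating-point dust.  Alternatives: the
  symmetrised Kullback–Leibler divergence (closed form), an
  entropy-regularised empirical OT cost (log-domain Sinkhorn, squared
  Euclidean ground cost, penalty `γ·KL(plan ‖ product)`, reporting the
  transport part, tolerance 1e-9 on the marginals with a 10,000-iteration
  cap), and the mean pairwise squared distance
  `(1/|A||B|) Σ Σ ‖x − y‖²`, computed through the exact moment rewrite and
  preceded by a seeded uniform subsample when a cluster exceeds 10,000
  points.

* **Between cytometries** the similarity distance is `d_S = d_OT / d_NT`,
  where `d_OT` is the optimal value of the transportation linear program
  moving the weights of one component set onto the other at the chosen
  cluster cost, and `d_NT` the product-coupling cost.  The LP is solved
  exactly (HiGHS simplex, deterministic pivoting), not by entropic
  approximation, so `d_S` stays parameter-free; the unsquared W2 enters the
  cost by default, with a squared variant behind a flag.  `d_S ∈ [0, 1]`;
  the degenerate case `d_NT = 0` (every cluster identical across both
  cytometries) is defined as 0 with a warning, since the two mixtures are
  then indistinguishable.  The averaged pairwise KL / Mahalanobis
  dissimilarities used by flowMatch-style matching are provided as
  baselines; the Mahalanobis convention between two Gaussians is the
  pooled-covariance form `d² = Δmᵀ((S_a+S_b)/2)⁻¹Δm` (the literature leaves
  this open; the choice is documented and swappable).

## Barycenters and k-barycenters

The W2 barycenter of Gaussians with weights `λ_i` has mean `Σ λ_i m_i` and
covariance the fixed point of
`S ↦ S^{−1/2}(Σ λ_i (S^{1/2} S_i S^{1/2})^{1/2})² S^{−1/2}`, iterated from
the Euclidean average `Σ λ_i S_i` until successive iterates differ by less
than 1e-8 in Frobenius norm (cap 1000 iterations; non-convergence is an
error carrying the last residual).  Within a consensus group `λ` is
proportional to component mass by default — a heavily populated cell type
should pull the consensus harder — with uniform weighting available.

Trimmed k-barycenters run Lloyd alternation in Wasserstein space: assign
each component to its nearest barycenter by squared W2, trim the `⌈N·trim⌉`
components farthest from their assigned center, recompute each group's
barycenter, stop at an assignment fixed point.  The best of 10 seeded
restarts (random K-subsets as initial centers) by final objective is kept;
an emptied group respawns at the farthest untrimmed component and the event
is logged.  Trimming operates on components (clusters), not events: at the
template level the outlying object is an aberrant cluster shape.

## Templates

`optimal_flow_templates` summarises the database, fills the pairwise `d_S`
matrix (computed once per pair), meta-clusters it, and builds one template
per group:

* **pooling** (labelled members): one barycenter per cell-type label across
  the members carrying it; the template proportion of a label is the mean of
  the member proportions, renormalised.  Labels ride along, which is what
  later enables label transfer and template QDA.
* **density** (no labels needed): pool all member components, cluster them
  by pairwise W2 with HDBSCAN (or a linkage cut), one barycenter per
  component-cluster, weights proportional to summed member mass.  HDBSCAN
  runs with `min_samples = 1` and `min_cluster_size` defaulting to about
  half the group size: a genuine cell type recurs in most members, so
  smaller agglomerations are substructure, not separate types.  Components
  labelled noise are excluded; everything-noise is an error ("no consensus
  structure").  A singleton group is copied through unchanged.
* **kbarycenter**: pool all components and run trimmed k-barycenters with a
  chosen K.  Under contaminated data it pays to add one component for the
  background population and a trim fraction of roughly the contamination
  rate, so aberrant background shapes are trimmed rather than polluting
  cell-type barycenters.

Meta-clustering accepts single/average/complete linkage on the precomputed
matrix (cut by group count or height; the merge list is exported for
dendrogram inspection) and DBSCAN/HDBSCAN, which may emit noise cytometries;
those become singleton templates rather than being dropped, so a later
classification can still match them.  Templates are built only at the chosen
cut, not at every dendrogram stage.

## Gating a new cytometry

tclust searches for a partition `{C_0, …, C_k}` with `|C_0| = ⌈nα⌉` trimmed
events maximising the pseudo-likelihood
`Σ_j Σ_{i∈C_j} log(p_j φ(x_i; m_j, S_j))` under the eigenvalue-ratio
restriction `max eig / min eig ≤ c` across all cluster covariances.  The
implementation is classification-EM: score every event under every
component (`log p_j + log φ`), trim the `⌈nα⌉` events with the lowest best
score, assign the rest to their argmax (ties to the lower index), update
weights over the untrimmed count, means, and maximum-likelihood covariances,
then enforce the restriction by the finite-candidate-set truncation: the
common truncation interval `[t, c·t]` is chosen over the eigenvalues, their
values divided by `c`, and the per-interval stationary points, to maximise
the restricted objective.  The recorded objective is non-decreasing across
iterations and the post-M-step eigenvalue ratio never exceeds `c` (both are
asserted in the test suite).  Emptied clusters re-seed at the worst-fit
untrimmed event.

`best_unsupervised_partition` runs one tclust per template, initialised at
the template's own weights/means/covariances with `k` equal to its component
count, and keeps the fit with the highest pseudo-likelihood — the selection
criterion is a design choice; initialising from the database is what makes
its information usable.  Any externally produced partition can be injected
instead.  The untrimmed events are then re-summarised into the mixture
`C^u`, which is assigned to the template minimising `d_S` (ties to the
lower index; the full distance vector is reported).

Event labelling strategies:

* **label transfer**: solve the OT program between the labelled template
  (source) and `C^u` (target); the fuzzy score `s^l_k = w*_kl / p^j_l` is
  the share of target cluster `l`'s mass arriving from source cluster `k`
  (columns of `s` sum to 1), and `s̃^l_k = s^l_k · w*_kl / p^i_k`
  down-weights small spillover from large clusters.  Hardening uses the
  Hungarian method on `−s̃` by default (argmax variants available; ties
  break by larger `s̃`, then lower source index; with more target than
  source clusters the unmatched columns fall back to their argmax).  Trimmed
  events still receive the label of their nearest `C^u` component in
  Mahalanobis distance and carry a trimmed flag, because downstream
  evaluation needs a total labelling.
* **template QDA**: per-event `argmax_j log p_j + log φ(x; m_j, S_j)` over
  the labelled template components — quadratic gating regions derived from
  the template.
* **nearest-cytometry learning**: pick the group member minimising
  `d_S(C^u, member)` and train QDA or any injected backend
  (`fit(X, y)` / `predict(X)`) on its events; a random forest is the usual
  non-parametric default.

## Evaluation

The F-measure of a predicted against a reference partition is
`Σ_k (|C_k|/M) max_l F(C_k, C'_l)` with `F` the harmonic mean of recall
`|∩|/|C_k|` and precision `|∩|/|C'_l|`, and the conventions
`R(∅,·) = P(·,∅) = 1`, `R(·,∅) = P(∅,·) = 0`.  The median F-measure pairs
clusters by equal label, appends one zero per label present on only one
side (the symmetric difference of the label sets), and takes the median
(mean of the two central values at even counts), so small but diagnostic
cell types weigh as much as dominant ones.  Per-label reports expose F,
precision and recall for each shared label, zeros otherwise.

## Synthetic data: what it emulates and what it does not

The generator mimics a multi-centre collection: `G` generative conditions,
each a mixture of `K` cell types whose base means sit on a jittered lattice
with pairwise separation ≥ 8 under unit-order random SPD covariances
(eigenvalues in [0.5, 2]), centred at the origin so the multiplicative
technical distortion acts evenly across cell types.  Per condition, each
cell-type mean is displaced by `between_group_shift = 6` in a random
direction; per cytometry, means get an individual Gaussian shift
(`within_group_jitter = 0.3`, biological variability), all events get a
diagonal axis scaling of sd `tech_scale_jitter = 0.02` around 1 (technical
variability), proportions are Dirichlet-resampled around the condition's
base (concentration 50), a cell type can be dropped with probability
`missing_type_prob`, and `outlier_frac = 0.05` of events are uniform
background labelled `outlier`.  Defaults: 3 conditions × 5 cytometries,
4 cell types, 2 markers, 1000 events.  Everything derives from one seed,
bit-for-bit reproducible; a separation below 3× the jitter warns that
groups may be unrecoverable.

Under these defaults the within-group similarity distances sit strictly
below the between-group ones, so group recovery is unambiguous — passing
tests show the machinery is correct under location-scatter mixtures with
well-separated populations, **not** that real, untransformed FC data (heavy
tails, doublets, spillover, time drift, overlapping rare populations) would
be gated at the same accuracy.  Those artifacts are deliberately not
emulated.

## Numerical choices and problem sizes

* OT linear programs: exact HiGHS simplex; weights validated to sum to 1
  within 1e-6 and renormalised; coupling marginals verified to 1e-9.
* Degenerate inputs: `d_NT = 0` → `d_S = 0` with a warning; empty tclust
  cluster → re-seed and log; all-noise density consensus → error.
* Tie-breaks are deterministic everywhere (argmax to the lower index,
  k-barycenter restarts and trimming order seeded and stable), so a fixed
  seed reproduces labels byte-for-byte.
* The CLI derives per-stage substreams from the single `--seed` by a fixed
  affine map, so adding a stage never perturbs another stage's randomness.
* The test suite runs the full pipeline at 15 cytometries × 1000 events in
  2 markers and tclust at n = 3000 — sizes chosen so the whole suite
  exercises every path in a few minutes on one core; the method itself has
  no such limits (the LP is over components, not events, so cost grows with
  the number of cell types, not the number of cells).

## Known limitations

* Clusters are summarised as Gaussians; strongly non-elliptical populations
  are represented only through their first two moments (the location-scatter
  assumption the whole pipeline shares).
* Pooling requires a shared label vocabulary across members; harmonising
  synonyms is out of scope.
* The density template's component count is as good as HDBSCAN's cut on a
  handful of points; with very small groups the k-barycenter route with an
  explicit K is more predictable.
* FCS writing, spillover compensation and transforms are out of scope by
  design.
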