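# Methods

## Model and procedure

The package treats surface-sampled resting fMRI as a field d(s, τ) over
the vertices s of a triangulated cortical surface, with T time samples per
vertex. Three stages are implemented: denoising (non-local or linear),
graph construction and normalized-cuts partitioning, and evaluation.

### Standardization

Each vertex series is normalized to zero mean and unit variance with the
*population* denominator T, not T − 1. This choice is forced by
consistency: only with population normalization does the identity

    (1/T) ‖d(s) − d(r)‖² = 2 − 2 · corr(d(s), d(r))

hold exactly, and both the tNLM weight and the affinity-graph edge
strength rely on it. Vertices with (numerically) zero variance — the
cutoff is sd < 1e−12 · (|mean| + 1), the scale of accumulated round-off
for a constant series — are set to all-zero series and flagged; they pass
through the tNLM filter unchanged and are excluded from serving as
neighbors, because their formal weight exp(−2/h²) would pull every
average toward zero without carrying signal.

### Temporal non-local means

The filter averages each vertex over its linked-distance neighborhood
N(s) = {r : hop distance(s, r) ≤ D} with weights
w(s, r) = exp(−(2 − 2·corr)/h²) computed once from the full standardized
series. Linked distance is combinatorial (mesh-edge hops, breadth-first
expansion), not geodesic millimetres: "linked" is a property of the
tessellation, and hop neighborhoods are cheap and parameter-free. The
self-weight is always 1, so the normalizing sum never vanishes. Weights
for strongly anti-correlated pairs underflow toward (but analytically
never reach) exp(−4/h²); float underflow to zero is harmless.

Parameters, units and defaults:

- `h` (dimensionless, default 0.72) — weight decay per unit of
  standardized squared distance. Smaller h sharpens edge preservation;
  h → ∞ degenerates to the unweighted neighborhood mean, h → 0⁺ to the
  identity. 0.72 is the setting used for the main qualitative cortical
  results; 0.60 and 1.73 bracket it in the quantitative sweeps.
- `D` (hops, default 11) — neighborhood radius. 11 is the full-cortex
  default on ~32k-vertex meshes; the desk-scale simulation study uses
  D = 5 on a 20×20 patch, where 11 hops would cover most of the patch and
  blur the distinction between local and non-local.

Windowed (time-varying) similarity and volumetric variants are out of
scope.

### Laplace–Beltrami baseline

Linear smoothing is implemented as heat-kernel filtering through a
truncated eigenbasis of the discrete Laplace–Beltrami operator:
cotangent-weighted stiffness matrix S with lumped (diagonal barycentric)
mass M, the standard first-order discretization, solved as the
generalized symmetric problem S φ = λ M φ. Each time frame is expanded in
the M-orthonormal basis, mode i attenuated by exp(−λᵢ t), and
resynthesized. `t` (mm², default 4) is the diffusion time; the smoothing
length is ≈ √(2t). Default truncation is min(500, n_vertices) modes;
on desk-scale meshes the basis is computed densely, and correctness is
checked against the dense matrix exponential expm(−t M⁻¹S) and against
the closed-form Neumann spectrum π²(m² + n²)/L² of a flat square patch.
The exact discretization and truncation used for the published cortical
figures are not fully specified, so numerical equivalence with them is
not claimed; agreement with the flat-domain closed forms is the
correctness standard here.

### Affinity graph and N-cuts

The graph is fully connected with A(u, v) = exp(corr(u, v)) and no
spatial edges — spatial structure enters only through filtering, which is
exactly what makes the linear-vs-non-local comparison informative.
Self-loops are kept (diagonal e¹); the normalized-association objective
sums over all ordered pairs within each class. Storage is dense; a guard
warns above 15k vertices (32k² doubles ≈ 8 GB).

Partitioning follows the multiclass spectral relaxation: top-K
eigenvectors of D^{−1/2} A D^{−1/2}, row-normalized, then rotation-based
discretization (alternating argmax assignment and orthogonal Procrustes
updates). The discretization is run from 4 seeded starts and the labeling
with the highest normalized association is kept; a seeded k-means on the
same embedding is the fallback if every start leaves an empty class. All
randomness flows through one seed, so identical graph + seed gives
identical labels. A constant-affinity graph has no identifiable
partition; the implementation returns contiguous index blocks with a
warning rather than failing. On small graphs (≤ 12 nodes, K = 2) the
discretized solution is checked against exhaustive enumeration of the
objective; any relaxation gap would be reported by that check (none is
observed on planted-block graphs).

### Evaluation metrics

Label correspondence uses Gale–Shapley stable matching with both sides
ranking counterpart labels by overlap vertex count, ties broken toward
the smaller label ID, and side A proposing. The exact preference
construction is a declared convention (overlap count is the natural
choice); the resulting matching is deterministic and admits no blocking
pair under those lists. Concordance is the fraction of vertices agreeing
after the matched relabeling, with the first-listed parcellation
proposing; vertices under unmatched labels (when K differs) count as
disagreements, and the reverse direction is available for symmetry
checks. Task label maps threshold per-contrast Z maps at 3.0 (one-tailed
p ≤ 0.00135), resolve multi-task vertices by the most significant
activation, and drop same-label connected components of ≤ 40 vertices
(connectivity via mesh edges restricted to same-label vertices); "≤"
semantics are asserted at exactly 40 vs 41. Agreement fraction divides by
the task-label size, not the parcel size, so a task region wholly inside
a larger parcel scores 1. Boundary maps flag triangles whose three
vertices carry ≥ 2 labels and are summed across parcellations (typically
K = 2…10, 15, 30, 40, 50, 60, 80). Population-level significance testing
of metric differences is deliberately left to standard statistics
libraries.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *correlation block structure* of the
four-quadrant boundary study: an n×n flat patch (unit spacing, fixed
lower-left→upper-right cell diagonals so neighbor counts are
deterministic) whose quadrants carry unit-variance AR(1) latents
(φ = 0.9, mimicking slow BOLD autocorrelation) with a configurable
cross-quadrant correlation, plus i.i.d. Gaussian vertex noise, then
standardization. Optional sub-blocks split a quadrant along x, each with
its own latent sharing the quadrant signal at correlation `within_corr`
(default 0.4, set by a design-time pilot so that sub-blocks are
separable by the pipeline at K = 8 while quadrant-level coherence is
preserved at K = 4). In the original study the quadrants were seeded with
recorded time series from four real networks (visual, motor, default
mode, task positive); here a parametric latent model stands in, because
only the between-region correlation structure drives the boundary
effects under study. The generator does not emulate scanner or
physiological artifacts, spatial autocorrelation of the noise, residual
ICA structure, or cortical geometry (curvature, irregular tessellation) —
so passing simulation tests demonstrates the filtering/parcellation
mechanics and boundary behavior, not performance on real cortical data.

Study conditions used by the simulation tests and the acceptance script:
n = 20 (400 vertices), T = 300, noise_sd = 1 (0 dB SNR against the
latents), cross-quadrant correlation cycled over ±0.2, ±0.1, 0 across 10
seeds; tNLM at h = 0.72, D = 5; LB at t = 4; the sub-block configuration
splits the upper-right quadrant in 2 and the lower-right in 4 (8 regions
for K = 8, mirroring the 2-way/4-way sub-parcellation seen in the
original simulation). These sizes keep the full study in the order of
seconds on one CPU while leaving the qualitative contrasts
(edge-preserving vs boundary-mixing) unambiguous.

## Numerical choices and degenerate inputs

- Eigen-solvers: dense generalized `eigh` when n_modes > n/4 or
  n ≤ 2000, shift-inverted sparse `eigsh` otherwise; tiny negative LB
  eigenvalues from round-off are clipped to 0.
- Isolated mesh vertices receive a 1e−12 lumped mass to keep the mass
  matrix definite; disconnected meshes are accepted with a warning and
  handled per component.
- Discretization convergence: iteration stops when the Procrustes
  objective changes by < 1e−10 (max 100 iterations).
- Gale–Shapley tie-break (smaller label ID) makes matching, concordance
  and agreement exactly reproducible.
- The HDF5 container is written with object timestamps disabled so that
  write∘read∘write is byte-identical.

## Known limitations

- Dense affinity limits the parcellation path to desk-scale meshes
  (~15k vertices) without out-of-core handling.
- The tNLM loop is O(Σ|N(s)|·T) in Python/NumPy; full 32k-vertex,
  D = 11 cortical runs are feasible but slow compared to a compiled
  implementation.
- Bit-exact replication of published cortical label maps is not a goal:
  the reference N-cuts code's internal tie-breaking and the published LB
  discretization details are unspecified.
- At noise_sd = 1 a single seam vertex can occasionally join a
  neighboring quadrant's parcel under tNLM at K = 8 without planted
  sub-blocks (residual mixing: cross-boundary weights are ≈ 1/7 of
  within-region weights rather than 0); the qualitative contrast with
  linear smoothing — which produces whole spanning parcels hugging the
  seams — is unaffected.
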