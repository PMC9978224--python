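# Methods

## Problem and model

A multi-organ shape complex is a set of K triangulated surfaces (one per
organ) per subject, in a common coordinate frame. Two kinds of variation
coexist in such an ensemble: the morphology of each organ, and the relative
pose of the organs within the complex. Correspondence particles — M ordered
points placed consistently on every subject's surfaces — turn the ensemble
into a point-distribution model: subject n becomes a vector
z_n ∈ R^{3M}, organ k contributing M_k particles.

Every particle decomposes exactly as

    x = z̄_n  +  (x − z̄_{n,k})  +  (z̄_{n,k} − z̄_n)
        offset    within-organ       between-organs

with z̄_{n,k} the particle centroid of organ k and z̄_n the global particle
centroid. The within terms are pure morphology (each organ about its own
centroid); the between terms are pure pose (organ centroids about the
global centroid). For every sample the within vector and the per-particle
expansion of the between vector are orthogonal by construction, and the
ANOVA identity holds exactly:

    SSQ_total = SSQ_within + SSQ_between,

where SSQ_total sums squared deviations about the per-subject offset and
the between sum weights each organ's centroid deviation by M_k
(equivalently, counts it once per particle). Note that writing the between
term unweighted, or measuring the total about the origin instead of the
offset, breaks the identity for unequal particle counts; the implementation
uses the exact form and the test suite asserts conservation to 1e-9
relative on arbitrary random systems.

## Correspondence objectives

All optimization modes combine a per-surface *sampling* (configuration
space) entropy, which spreads particles uniformly, with *shape-space*
entropies, which make the statistical model compact:

* **single** — per-organ: Q = α Σ_k H(Z_k) − Σ_{n,k} H(X_{n,k});
* **global** — one shared 3M-dimensional shape space:
  Q = α H(Z) − Σ_{n,k} H(X_{n,k});
* **mlmo** — disentangled:
  Q = α_W Σ_k H(Z_k^W) + α_B H(Z^B) − Σ_{n,k} H(X_{n,k}),
  with Z_k^W the within variables (covariance 3M_k × 3M_k) and Z^B the
  between variable (covariance 3K × 3K, *independent of the particle
  counts* — the structural reason this mode scales to dense models).

Sampling entropy uses a Parzen estimate with isotropic Gaussian kernels,
H(X) ≈ −(1/M) Σ_m log p(x_m), p(x_m) = (1/(M−1)) Σ_{j≠m} N(x_m; x_j, σ_j²I).
Kernel widths σ_j are the median distance to the 6 nearest same-organ
particles, floored at 1e−3 of the organ bounding-box diagonal, and are
treated as lagged constants during gradient steps. The kernel is **not**
truncated: particle counts per organ are modest (≤ a few thousand), the
full pairwise sum is cheap, and an untruncated estimate has an exact,
finite-difference-verifiable gradient.

Shape-space entropies are Gaussian: H = ½ Σ_i log(λ_i + α_reg) over *all*
eigenvalues of the subspace's sample covariance (1/(N−1) convention),
including the structural zeros, each contributing ½ log α_reg. They are
evaluated through the N × N Gram matrix, never materializing a 3M × 3M
covariance. The gradient used for particle updates is the exact derivative
of this estimate, Y (YᵀY + α_reg (N−1) I)^{-1} in dual form — the familiar
regularized-covariance update with the regularizer rescaled by the
covariance normalization. Gradients are mapped to raw particle coordinates
through the full centering Jacobians:

* within, organ k: ∂(x_m − z̄_k)/∂x_j = δ_{mj} I − (1/M_k) I
  (subtract the per-organ mean of the per-particle gradients);
* between, particle of organ k: ∂(z̄_{k'} − z̄)/∂x = δ_{kk'} (1/M_k) I − (1/M) I
  (organ-block gradient divided by M_k minus the global coupling term).

The across-subject mean-centering Jacobian is handled automatically: the
dual-form gradient of a column-centered matrix already has zero row mean.
All analytic gradients match central finite differences to < 1e−4 relative
(most to ~1e−7) on small systems; this is asserted in the tests.

## Optimization loop

Particles are initialized coarse-to-fine: one particle per organ, then
repeated splitting (each particle spawns a child at a small tangential
offset, 2% of the organ bounding-box diagonal, re-snapped to the surface)
until the target counts — powers of two — are reached, with a relaxation
phase at every level. Split directions are drawn once per (organ, particle)
and shared across subjects so children inherit their parents'
correspondence.

Each iteration computes the statistics (kernel widths, subspace gradients)
once and lags them through the update, then takes backtracking steps: the
update direction is tangent-projected at each particle's current face,
scaled so the largest displacement equals the current step length,
applied, and every moved particle is snapped back to its surface by an
exact closest-point query. If the (frozen-statistics) energy rises, the
step halves (up to 10 times, else the phase is a no-op); on success it
grows by 1.1× up to 4× the level's initial step (half the mean kernel
width).

In mlmo mode one iteration runs K within phases followed by one between
phase, all sharing the iteration's statistics. Each organ's within phase
steps **independently**, with its own adaptive step length, judged by the
energy terms only that organ's particles affect (its within entropy plus
its sampling entropies). This separation matters in practice: the within
objective is exactly separable per organ, and a single globally normalized
step lets the organ with the largest gradient scale starve the others —
residual correspondence noise in a quiet organ then decays orders of
magnitude too slowly. The between phase moves all particles (each organ's
update is a single 3-vector spread over its particles) and is judged by
the full objective. The energy trace records Q before and after every
phase; Q_post ≤ Q_pre holds per phase by construction.

Two deterministic *consensus repair* passes run at the end of every split
level while organs have ≤ 64 particles, each followed by a re-relaxation
if anything changed. They address label switching on nearly symmetric
surfaces (an m-lobed shape has ~2m equivalent positions; a subject whose
coarse particles settle on the wrong one is a deep local minimum the
gradient cannot escape). Configuration-level repair computes pairwise
distances between the subjects' centered particle configurations, splits
them at their largest multiplicative gap (requiring a ratio ≥ 20, so
legitimately extreme shapes — typically a few-fold from the median, not
orders of magnitude — are never touched), takes the largest mutually
consistent cluster as the reference labeling, and re-snaps the cluster
consensus onto each outlier's surface, keeping it only if the deviation
shrinks. Particle-level repair applies the same gap rule to individual
particle deviations from the ensemble-mean position of their
correspondence index, catching single mislabeled particles. With no gap in
the distributions both passes are no-ops, which is the common case.

The covariance regularization α_reg decays geometrically across split
levels from 10× to 0.01× the mean positive covariance eigenvalue of the
corresponding subspace, recomputed at each level: heavy regularization
while M ≫ N keeps early gradients sensible, light regularization at the
final level lets the model tighten. A level ends after
`iterations_per_split_level` (default 30) or when the relative energy
change over a 10-iteration window falls below 1e−6. All randomness
(split directions) derives from one seed; runs are bit-reproducible.

Default weights are α = α_W = α_B = 1; they are exposed in
`OptimizerConfig`. The closest-point query is exact: candidate faces come
from a KD-tree over face centroids and any point whose candidate set
cannot be certified (nearest candidate distance vs. the pruning bound)
falls back to brute force over all faces, so the result always equals the
brute-force answer; ties resolve to the lowest face id.

## MLCA analysis

After optimization, PCA is fit per subspace: the shared model on the
flattened vectors, the MLCA model on each within matrix and on the between
matrix (all via the Gram dual, eigenvalues in the 1/(N−1) convention,
components below 1e−12·λ_max truncated, eigenvector signs fixed by making
the largest-magnitude entry positive). The K+1 subspaces are mutually
orthogonal in R^{3M} after per-particle expansion of the between basis.

A sample's MLCA coordinates are its per-organ within coefficients, its
between coefficients, and its offset deviation from the mean offset; the
offset is carried, not modeled (it is a 3-vector of pure translation).
Reconstruction adds the consolidated mean — the full ensemble-mean shape
vector, which by linearity equals mean offset + within means + between
means — plus the retained modes, with between eigenvector blocks broadcast
uniformly to all particles of their organ. With all modes retained,
training samples reconstruct exactly. Mode sweeps (mean ± c√λ·u) inherit
the disentanglement: a between sweep translates organs rigidly and leaves
every organ's centered within-shape unchanged to machine precision, and
vice versa.

## Evaluation metrics

* **Compactness** C(P) = Σ_{p≤P} λ_p per subspace (variance, mm²).
* **Generalization**: leave-one-out; the held-out subject's subspace
  vector (the decomposition is per-subject, so holding out a subject drops
  one column) is projected onto the model refit from N−1 subjects and
  reconstructed with P modes; the error is the Euclidean distance in that
  subspace's coordinates (mm), averaged over folds.
* **Specificity**: T = 1000 vectors sampled from the subspace's generative
  model (coefficients independently N(0, λ_p) on the leading P modes),
  each scored by the distance to its nearest training sample, in the same
  subspace as the sampling; seeded and reproducible.
* **Coverage area**: a face of mesh A is covered by mesh B iff the ray
  from its centroid along its face normal (one direction only, A's winding
  convention; self-intersections ignored) hits any face of B
  (Möller–Trumbore); the metric is the summed area of covered faces, and
  relative error against a reference area is |â − a|/a.

## Synthetic benchmark

The generator emulates a multi-object study with exactly one known
morphology factor per object and one known pose factor per subject:

* K supershapes (Gielis superformula, spherical product) per subject;
  object k (1-based) has k+2 lobes; the latitude profile is circular, so
  meshes are star-shaped and closed, resolution 24 (554 vertices, 1104
  faces per object), scale 20 mm.
* Morphology: the longitude exponent n1 = 2 + 0.25·χ²(df=4), drawn
  independently per (subject, object). The base of 2 bounds the maximal
  radius by √2·scale ≈ 28 mm, under half the 60 mm object spacing, so
  objects never intersect; the scaled χ² spans visibly different lobe
  depths.
* Pose: object centroids at (x_k, a_n·x_k², 0), x_k = 60k mm,
  a_n ~ U(0, 0.001) shared by a subject's objects — the complex bends
  along a parabola whose curvature is the single pose factor.
* Every draw is recorded in a JSON manifest; ensembles are pure functions
  of their config (one master seed, one spawned substream per subject).

The benchmark study uses N = 20 subjects, K = 3 objects and 128 particles
per object (a density at which each lobed surface is well resolved while
the full experiment, optimization included, runs in a few minutes on one
CPU). A correct disentangled optimization recovers exactly one dominant
mode (≥5% variance share) in every within spectrum and in the between
spectrum, with the mode-1 coefficients tracking the recorded χ² and
parabola draws; the entangled global model is expected to leak pose into
secondary within modes.

What the generator does *not* emulate: segmentation noise, topology
variation across subjects, organs with genuinely articulated (rotational)
pose changes, or non-star-shaped anatomy. Passing the synthetic study
shows the disentanglement and the optimization machinery are correct, not
that the model assumptions fit any particular clinical anatomy.

## Numerical choices and degenerate inputs

* Covariances use 1/(N−1); stated because the entropy eigenvalues and the
  regularization scale depend on it.
* Subspace-entropy regularization must be positive; degenerate (zero)
  covariances sit at the floor ½·D·log α_reg.
* A single particle per organ has zero sampling entropy and zero gradient;
  K = 1 makes the between matrix identically zero and the between gradient
  vanish (global and single modes coincide exactly, same trajectories).
* Closest-point ties take the lowest face id; eigenvector signs follow the
  largest-component rule; rank truncation at 1e−12·λ_max.
* Meshes are cleaned at load (duplicate vertices merged, degenerate faces
  dropped, quads triangulated) and treated as triangle soups for distance
  queries; watertightness is advisory.
* Alignment is translation-only centering of each subject's whole complex
  (the global vertex centroid to the origin): inter-organ pose is signal
  and must survive alignment. No rotation normalization is applied by
  default.

## Known limitations

* Pose is modeled as centroid translation; rotational pose of an organ
  appears as within-organ variation (a nonlinear pose parameterization is
  out of scope).
* The between update moves particles along their fixed surfaces; organ
  geometry never moves, so extreme pose gradients can trade against
  sampling uniformity.
* Specificity's nearest-sample search is in the subspace of the sampling
  (within/between), not the full shape space; both conventions exist in
  the literature.
* LOO generalization refits N PCA models per subspace; fine for desk-scale
  N, quadratic-ish for large cohorts.
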