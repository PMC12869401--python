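# Methods

This note documents the modeling choices behind `cortexage`: what is assumed,
which parameters matter, what the synthetic data does and does not emulate,
and where the design was genuinely open.

## Atlas meshes and hierarchy

Cortical data are assumed to be resampled onto fsaverage-style icosahedral
atlases: per hemisphere, a unit icosphere with 10·4ⁿ+2 vertices at subdivision
level *n*.  `build_icosphere` performs midpoint subdivision with a
deterministic, parents-first vertex ordering (children appended per unique
edge in lexicographic order), so the level-*k* vertices are an exact prefix of
level-(k+1) — the property that makes cross-resolution matching reproducible.
FreeSurfer's own ico files share this prefix structure; we emulate it rather
than require it, and nearest-neighbor matching would also tolerate atlases
without it.

The two hemispheres are concatenated into one joint graph with no
cross-hemisphere edges; the ±2-unit x-translation applied to the joint
coordinates is cosmetic (learning never reads absolute coordinates).  The
medial wall — the non-cortical band excluded from analysis — is taken from the
atlas annotation for real data.  The synthetic wall is a geodesic cap of
angular radius 0.25 rad around each hemisphere's medial pole; the choice is a
configuration value because no geometric definition of the wall is canonical.

## Receptive fields and pooling

Fields are built bottom-up: each coarse vertex matches its nearest fine vertex
by Euclidean distance on the per-hemisphere unit-sphere embedding (ties, which
cannot occur on exact atlases, break to the lowest index for bitwise
reproducibility); the receptive field is the matched vertex plus its fine
1-hop neighbors, and the inverse field is the exact set dual.  Both pooling
directions are unweighted means, materialized as sparse row-stochastic
matrices.  Receptive fields overlap and each field is averaged independently —
no overlap renormalization is attempted.

On nested icospheres every fine vertex is covered by some inverse field, and
the test suite asserts this.  For non-nested level pairs a fine vertex can be
uncovered; its upsampled value is imputed as the mean of its already-covered
1-hop neighbors, iterated deterministically until covered.  Imputation is
composed into the sparse operator, so upsampling stays exactly linear (zeros
were rejected because they would punch artificial holes into age maps).

## Network and training

Widths default to (5, 8, 16): 5 input features, 8 channels at the finest
level, 16 at the middle and coarsest.  Each encoder block is
GCN → batch norm → ReLU; batch statistics pool over all vertices of all graphs
in a batch.  Decoder blocks mirror this after upsampling and concatenation
with the same-level encoder output (so a decoder GCN reads 2× the upsampled
width); the output block is a GCN alone, emitting years per vertex.  Weights
are Glorot-uniform from the run seed; no dropout or weight decay is used.
Training is Adam (lr 0.01), 50 epochs, batch size 128, vertex-wise MAE, with
the training target CA broadcast to every vertex including the medial wall —
the wall is removed only after training, and a mask option exists for the
alternative.

Two standardizations are internal to the model and stored with it: each input
feature is z-scored with training-set global mean/SD (this also defines the
"z-score 0" saliency baseline), and the age target is z-scored with the
training-set CA mean/SD, predictions being mapped back to years.  Target
standardization makes optimization scale-free: the optimizer starts one unit
from the solution regardless of cohort size, rather than ~65 years from it,
so the same learning rate and epoch budget behave identically at desk scale
and at production scale.  Loss histories are therefore reported on the
standardized scale, while every evaluation metric (`evaluate_mae`, maps,
gaps) is in years.  Model losses are computed before bias correction.

Determinism: the implementation is pure NumPy on CPU; a fixed seed fixes
initialization, batch shuffling and hence the loss history bitwise.

## Post-processing

Order: medial-wall removal first, then smoothing, then bias correction.
Smoothing replaces each value by the unweighted mean of itself and its ≤2-hop
neighbors within the working (non-wall) vertex set, repeated 4 times,
synchronously (Jacobi-style) so the result is independent of vertex order.
Including the center vertex is the standard mesh-smoothing reading and
prevents oscillation.  Note that on the desk-scale meshes used in tests
(162 vertices per hemisphere) a 2-hop/4-iteration kernel covers a large
fraction of a hemisphere; on production meshes (40k vertices per hemisphere)
the same parameters are a local filter.  Tests therefore check operator
properties (convexity, oracle equality) rather than kernel size.

The semi-global bias correction fits, per vertex, OLS of LBAG on CA, then
averages slopes and intercepts across vertices into (m_μ, b_μ) and subtracts
m_μ·CA_s + b_μ from every vertex of subject s.  The adjustment term is the
parenthesized quantity (m_μ·CA_s + b_μ).  Two identities follow analytically
and are asserted to 1e-8: on the fitting cohort the grand mean of corrected
gaps is exactly zero, and corrected global gaps regressed on CA give slope
and intercept zero.  Semi-global is the default and tested path; fully global
or fully local correction would be one-line variants but are not exposed as
first-class modes.

## Integrated gradients

Attribution of a scalar f from baseline x̄ to input x uses the right-endpoint
Riemann sum with N = 50 steps by default; completeness
(Σ attributions = f(x) − f(x̄)) converges as 1/N and is verified empirically
at N ∈ {50, 500, 5000}.  The model's vertex-wise output must be reduced to a
differentiable scalar; we use the mean predicted age over non-wall vertices,
the natural cohort-comparable choice, and expose the vertex-weight vector so
per-region targets are possible.  Baselines: all-zero (z-score 0 w.r.t. the
training set) for reference cohorts; for disease cohorts, the feature-wise
mean of one seeded random batch of reference subjects (batch size = training
batch size capped at cohort size), held fixed across all target subjects.
Per-subject maps are averaged element-wise into group maps, which preserve
relative scaling across features.

## Group statistics

Vertex values are averaged within parcellation regions (wall excluded).
Region-level tests are independent two-tailed equal-variance t-tests — the
literal reading of the procedure; a Welch switch exists.  Testing regional
LBA against the subjects' CA vector as two independent samples is
statistically unusual (a one-sample test on the gap would be conventional);
both the literal test and the data needed for the alternative are exposed,
without claiming one is superior.  BH correction runs within one family per
analysis (one region set per comparison; one test battery per cohort).  The
sex comparison resamples one male and one female per overlapping integer year
of CA, 500 replicates, reporting percentile intervals; intervals describe
resampling of the observed cohort, not a null distribution.  Cognition
regressions standardize the score over included subjects, orient it so higher
= worse (a fixed list of higher-is-better tests is sign-flipped, overridable
per call), exclude Trail-Making-B scores equal to 300 (ceiling), and control
for CA, sex (binary indicator) and education years.

For synthetic data the parcellation is deterministic geodesic patching:
farthest-point seeds per hemisphere, nearest-seed assignment.  The default
region count for production-scale meshes is 74 per hemisphere, mirroring
sulcus/gyrus-level atlas granularity; the simulator default is 8 per
hemisphere, matched to its small meshes.

## Synthetic cohorts

The simulator defines the reference study condition used by the test suite:
400 subjects, hierarchy (0, 1, 2) (joint mesh sizes 24/84/324), CA uniform on
45–90 y (an aging-cohort range), baseline spatial fields built by smoothing
white noise on the mesh (spatial autocorrelation like real morphometry), an
age slope of ±0.02–0.04 feature units per year in four of the five features
and feature noise SD 0.5 — about one noise-SD of signal per SD of age per
informative feature — plus an optional lesioned subgroup whose designated
regions carry a +10 y local age offset, an optional male offset, education
drawn from N(14, 3²) clipped to 6–22 y, and cognitive scores equal to half
the true global gap plus unit noise (higher = worse).  The end-to-end fixture
mirrors a case-control design: the model trains on controls only, the
lesioned subgroup is held out entirely, the bias model is fitted on held-out
controls and reused for the lesioned cohort.

What the simulator does *not* emulate: realistic marginal distributions of
thickness/area/etc., inter-feature correlation structure, site or scanner
effects, longitudinal repeats, or any regional aging topography.  Passing
tests therefore demonstrate that the algorithms are implemented correctly and
recover implanted effects under their own assumptions — not that the model
reproduces any particular empirical accuracy on real cohorts, whose headline
errors depend on data this package does not ship.

## Problem sizes and numerical choices

Tests and examples run hierarchies (0, 1, 2) with cohorts of 30–400 subjects;
these sizes keep any single run to seconds while leaving every code path
identical to the production configuration (4, 5, 6), which differs only in
mesh level and cost.  Tolerances: exact set/integer identities are asserted
with equality; linear-algebra identities at 1e-10–1e-12; the analytic
bias-correction zeros at 1e-8; oracle equivalence for the GCN at 1e-6
(float-order sensitivity); stochastic checks use fixed seeds with bounds
derived from the statistic's sampling distribution (e.g. 3σ for a sample
mean).  Degenerate inputs fail loudly: empty cohorts, zero CA variance,
constant design columns, mismatched shapes and malformed files raise typed
errors rather than propagating NaNs.

## Known limitations

- The NumPy U-Net is CPU-only and unbatched across processes; production-size
  meshes (81924 vertices) train slowly compared to a GPU framework, though
  all operations are sparse and memory-light.
- Graph rewiring, learned pooling, dropout and hyperparameter search are out
  of scope by design.
- The medial-wall cap and geodesic parcellation are synthetic stand-ins for
  atlas annotations; real analyses should load FreeSurfer annot files.
- The sex bootstrap requires overlapping integer CA years with both sexes
  present; small cohorts can degenerate to point-mass distributions.
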