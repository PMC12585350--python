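# Methods

This note documents the models and procedures implemented in `stepgrad`,
the parameter choices that matter, what the synthetic cohort does and does
not emulate, and the numerical conventions.

## 1. Connectome preprocessing

Functional connectomes (Pearson r, zero diagonal) are Fisher R-to-Z
transformed (`arctanh`, correlations clipped to |r| ≤ 1 − 1e-7 so the
transform stays finite). Structural streamline-count connectomes are used
raw. Each row then keeps its top `fraction` (default 0.20) of off-diagonal
values by signed value — "fixed edge density" per ROI, which removes weak
and spurious connections while equalizing degree-related confounds. The
number kept per row is round-half-away-from-zero of `fraction × (n − 1)`,
floored at 1 so tiny graphs keep a minimum degree; ties at the cutoff go to
the lower column index so the operation is deterministic.

Row-wise selection breaks symmetry, so edges are re-symmetrized by
**union**: an edge survives if it was in the top fraction of either
endpoint's row. This preserves the per-ROI density target as a lower bound
and is common practice; an intersection rule would undercut it. For walk
counting the surviving graph is **binarized**; surviving *negative* z
values are dropped at that point, since an anti-correlation is not a
connection a walk should traverse. A weighted variant (surviving weights,
negatives clipped) is available behind `binary=False` and feeds the
gradient affinity.

Per-hemisphere analysis: thresholding, walk counting and all statistics are
run on one hemisphere's submatrix at a time, mirroring the separate
left/right reporting convention of seed-based studies.

## 2. Stepwise connectivity

Walk counts from the seed are the seed row of successive adjacency powers,
computed as vector–matrix products (never forming full powers). Counts are
held in float64 with an overflow guard at 2^53, beyond which float64 can no
longer represent integers exactly; at the default 7 steps this triggers
only on graphs far denser than thresholded connectomes.

Each step's map is normalized within subject: subtract the mean across
ROIs, divide by the **population** SD (the ROI set is a fixed frame, not a
sample; the choice only rescales by √(n/(n−1)) and is invariant to
everything downstream that compares groups). Zero-variance step maps are
returned as zeros with a degeneracy flag rather than failing, so edgeless
or near-edgeless graphs survive batch processing.

The convergence diagnostic averages normalized maps across a group's
subjects per step and correlates consecutive steps across ROIs. By
Perron–Frobenius, A^x v aligns with the leading eigenvector as x grows, so
r approaches 1; the default maximum step of 7 is where the default
synthetic world (and the empirical literature this emulates) saturates
(r(6,7) > 0.99).

The seed's own column (self-walks) is included in normalization and maps by
default; `run_analysis(exclude_seed=True)` drops it from the analyzed ROI
set, because at low step sizes the seed's self-walk count is essentially a
degree statistic and can dominate group contrasts.

## 3. Gradients

The affinity is the cosine similarity between thresholded connectivity
rows, negatives clipped to 0, diagonal set to 1. Diffusion-map embedding:
with affinity W and degree d, W is normalized on both sides by d^α
(α = 0.5, balancing geometry against sampling density), the resulting
operator is row-normalized, and its symmetric conjugate is
eigendecomposed. The trivial constant eigenvector (λ = 1) is discarded;
at diffusion time t = 0 component g is scaled by λ_g/(1 − λ_g) (the
multi-scale convention), otherwise by λ_g^t. Eigenvector signs are fixed
by making each component's largest-magnitude entry positive, removing the
inherent sign ambiguity before alignment. "Pseudo-variance explained" is
λ_g over the sum of retained non-trivial eigenvalues.

Templates are embeddings of the entrywise mean of a group's prepped
(weighted, non-negative) matrices. Subject embeddings are aligned to the
template by **orthogonal Procrustes** (rotation/reflection from the SVD of
the cross-product; no scaling, no centering), so pairwise ROI distances are
preserved exactly and the subsequent min-max scaling is comparable across
groups. Between-group statistics are displayed in the *reference group's*
(A−CN) template space; group-mean maps can be binned in each group's own
space. Disconnected affinity graphs are an error that reports the
component sizes rather than silently embedding one component.

## 4. Gradient-space binning

The first two template gradients are min-max scaled to [0, 1] and ROIs are
assigned to 15 equal-width bins per axis (`floor(c × 15)`, with c = 1 in
the last, right-closed bin). "Equally-sized" is read as equal-width, not
equal-count: only fixed-width partitions make min-max-scaled axes
comparable across groups. Cells show the mean of member ROIs; empty cells
are NA, never 0. The FWER-thresholded grid keeps cells containing at least
one ROI that survived correction ("any" rule, matching the reporting
convention of binned significance maps; a strict "all" mode exists).
`n_bins = 0` is a sentinel for unsmoothed per-ROI scatter records.

## 5. Statistics

ROI-wise group comparisons are OLS of (summed) normalized stepwise
connectivity on a group indicator plus age, sex (M = 1) and APOE-ε4
(carrier = 1); the reported t is the group coefficient's with n − p
residual degrees of freedom. The implementation is closed-form and
vectorized across ROIs because it runs inside the permutation loop; tests
cross-check it against statsmodels.

Family-wise error is controlled by **permutation maxT**: the null
distribution of the maximum |t| across ROIs under Freedman–Lane
permutation — residuals from the covariate-only model are permuted and
added back to the covariate fit, keeping covariates attached to subjects
(plain label permutation is anticonservative with confounders).
p_adj = (1 + #{max* ≥ |t_obs|})/(n_perm + 1), which is never below
1/(n_perm + 1) and monotone in |t|. Defaults: α = 0.01 for per-step maps,
α = 0.05 for summed/gradient-space maps. A voxel-level cluster-extent
correction is out of scope at ROI resolution; maxT targets the same
family-wise error rate without voxel geometry.

The tau stage computes, per analysis-group subject, the difference between
their summed normalized map and the reference-group (A−CN) average —
subjects with missing tau are dropped everywhere in this stage, including
from the reference average — and regresses each ROI's tau SUVR on that
difference plus the covariates. ROIs with zero-variance differences are
flagged and skipped. Adjusted p-values use the same maxT machinery with a
shared permutation across ROIs.

Contrasts are pairwise against A−CN (CI vs A−CN, A+CN vs A−CN); no
three-level omnibus is fitted.

## 6. The synthetic cohort

**What it emulates.** Three diagnostic groups (A−CN/A+CN/CI, default
30/20/30 subjects — desk scale versus the hundreds of a real cohort) on an
80-ROI, 8-network atlas split into hemispheres; covariates with realistic
rates (age ~ N(70, 9) truncated to [50, 95]; 60% female; APOE-ε4 carriage
26.5%/25.7%/56.9% by group, as in published cohort demographics); seed ROI
in the medial-temporal block of each hemisphere.

**Functional model.** Each ROI's time series (default 400 frames) is a
unit-variance latent-factor sum: a hierarchy factor, a global factor, any
planted seed-coupling factors, and white noise. ROIs live on a continuous
hierarchy axis (networks ordered somatomotor → visual → … → medial-temporal
→ frontoparietal → DMN, with within-network spread, homotopic pairs
aligned), and factor correlation decays as ρ^distance (Ornstein–Uhlenbeck
kernel, ρ = 0.5) — giving a *continuous* connectivity gradient rather than
point-mass communities, ordered like the unimodal→transmodal axis with the
medial-temporal seed mid-chain. Correlating simulated series (not
perturbing a matrix) guarantees a valid positive-semidefinite correlation
matrix. Between-subject heterogeneity comes from per-subject per-ROI
lognormal jitter (SD 0.35) on the network-factor variance share, traded
against the residual so total variance is fixed; without it, subjects are
nearly identical and even trivial effects reach implausible t ≈ 15–20.

**Planted effects.** An effect (group, target network, direction,
magnitude m) adds a factor loaded by the seed(s) and the target-network
ROIs. A *hyper* effect is carried by the affected group; a *hypo* effect
is carried by every group *except* the affected one — hypoconnectivity is
the loss of a coupling controls have, not an anti-correlation appearing in
patients. The plant's variance is taken out of the residual budget, so the
expected seed-to-target correlation of the affected group differs from the
others by exactly ±m. Default plants: CI hypo-DMN (m = 0.12) and CI
hyper-somatomotor (m = 0.18) functional; CI hypo-visual and
hyper-frontoparietal structural (×0.6 / ×1.4 streamline rates). The
functional magnitudes are *balanced for realized strength* — the DMN sits
two hierarchy steps from the seed and expresses a plant far more strongly
than the distal somatomotor pole — and sized so planted-network group
t-statistics land in the 4–8 range typical of studies of this size. The
planted poles sit at the ends of the hierarchy chain; mid-chain plants are
also supported, but their effects propagate at nearly full strength to
every network downstream of the target (walks route through it), which is
faithful walk physics but makes "localized" ground truth impossible.

**Structural model.** Symmetric Poisson counts with within-network mean
100 and between-network means 30 × 0.6^(distance−1) along the same
hierarchy axis; planted effects multiply seed-to-target rates.

**Tau model.** Baseline SUVR per group (1.0/1.1/1.3) plus
`tau_link_slope` (default 0.1 SUVR per z-unit) times the subject's
*realized* connectivity shift — their sum-normalized walk-count map minus
the A−CN group mean, computed with the package's own default pipeline —
plus N(0, 0.1) noise. Linking tau to the realized subject-level shift
(not the group label) gives the tau-association stage a recoverable
ground-truth slope. One A−CN subject is generated without tau, mirroring
the missing-data handling the tau analyses must implement.

**Ground truth.** `expected_functional_matrix` returns the analytic
noise-free correlation matrix per group, and `true_effect_map` runs the
deterministic pipeline on those matrices to give the propagated effect
direction per ROI — including downstream walk propagation and the
z-normalization compensation (normalized maps are relative, so a planted
increase somewhere implies decreases elsewhere). Recovery tests compare
significant-ROI signs against this map, not against a naive
"only-the-target-network" template.

**What a green test does not establish.** The generator has no spatial
embedding, no scanner/site effects, no motion or physiological artifacts,
no subcortex, hemispheres with mirrored (not lateralized) structure, and a
single 1-D hierarchy rather than the several partially independent axes of
real cortex. Passing recovery tests show the *pipeline* is correct and
calibrated on its stated world; they do not validate neuroscientific
conclusions on real data.

## 7. Numerical conventions and degenerate inputs

- Connectome symmetry: asymmetry ≤ 1e-8 on read is repaired by averaging
  with the transpose; larger is an error. Stored matrices must be
  symmetric to 1e-10 with an exactly zero diagonal.
- Result tables round-trip losslessly at 12 significant digits (`%.12g`).
- Missing tau is an absent file/blank manifest column, never 0 (a 0 would
  look like a valid SUVR).
- Eigenvalue ordering uses a stable sort; with degenerate spectra the
  embedding is still deterministic for identical input (same LAPACK path),
  which is what the reproducibility guarantee promises.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`/`SeedSequence`; two runs of any stochastic
  stage with the same seed are byte-identical.

## 8. Known limitations

- The union re-symmetrization makes realized row densities slightly exceed
  the nominal fraction; the per-row guarantee is exact only before
  symmetrization.
- The maxT null assumes exchangeability of covariate-adjusted residuals
  across the two groups; strong group-specific variance differences would
  violate it.
- Procrustes alignment is unscaled by design; if subject embeddings differ
  from the template by a global scale, that scale is retained.
- At desk scale (40 ROIs per hemisphere) the 15 × 15 grid is sparsely
  occupied, so binned maps are close to per-ROI scatter; the binning only
  smooths meaningfully at atlas scales of several hundred ROIs.
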