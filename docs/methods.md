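# Methods

## The signal model

`niikit` models the diffusion-weighted MRI signal of a voxel as a linear
combination of a small number of axially symmetric anisotropic tensor
compartments and a spectrum of isotropic diffusivities:

    S_k = s0 · [ Σ_i f_i · exp(−b_k λ⊥i) · exp(−b_k (λ∥i − λ⊥i) cos²ψ_ik)
                 + ∫_a^b f(D) exp(−b_k D) dD ],    k = 1 … K

where `b_k` is the b-value of volume k (s/mm²), `ψ_ik` the angle between
fiber i and gradient k, `λ∥i`/`λ⊥i` the fiber's axial/radial diffusivity
(μm²/ms), `f_i` its signal fraction, and `f(D)` the isotropic spectrum on
`[a, b]`.  The product `b·D` is made dimensionless by a factor 10⁻³
(b = 1000 s/mm² with D = 1 μm²/ms gives exponent 1).  The spectrum
integral is discretized as a non-negative sum on a fixed grid (default 40
points, linearly spaced on [0, 3] μm²/ms; 3.0 covers free water at body
temperature).  Signals are divided by the mean over b0 volumes before
fitting, so all fractions are relative to unity; the printed model omits
an explicit s0 and whether raw or normalized signals were fit in the
original processing is not documented, so b0-normalization is an explicit
assumption here.

Seven indices are derived from the fitted voxel, with the isotropic
spectrum split at D ≤ 0.3 μm²/ms (restricted; interpreted as cellularity)
and 0.3 < D ≤ 2.5 μm²/ms (hindered; interpreted as extracellular edema):

* **RF** — restricted fraction of the total signal;
* **HR** — hindered share of the non-restricted isotropic signal,
  `w_h / (w_h + w_free)`, defined as 0 when the denominator vanishes.
  The phrase defining HR in the source description is ambiguous between
  this ratio and the absolute hindered fraction; both are implemented
  (`hr_definition="ratio"` default, `"absolute"` optional);
* **FF** — summed anisotropic (fiber) fraction;
* **AD/RD** — fraction-weighted mean λ∥/λ⊥ over fiber compartments;
* **MD/FA** — from the axially symmetric tensor (AD, RD, RD).

With FF = 0 the tensor-derived indices are reported as NaN, never 0, and
NaN propagates out of all downstream statistics by exclusion.

## Solvers

**Hybrid (default).**  Variable projection: fiber directions are fixed
first (single fiber: principal eigenvector of a log-linear DTI fit; two
fibers: peaks of an NNLS stick-dictionary fit over 100 electrostatically
spaced orientations, second peak kept at ≥ 20 % of the first, each refined
by a cone-weighted mean).  The remaining nonlinear parameters — λ∥ and λ⊥
per fiber, bounded to [0.1, 3.0] and [0, 2.0] μm²/ms — are searched
globally by a particle-swarm/Nelder–Mead hybrid; at each candidate the
linear weights (fiber amplitudes and all spectrum weights) are solved by
NNLS and the objective is the residual sum of squares.  Voxels with DTI
FA < 0.05 are treated as isotropic (spectrum-only NNLS, FF = 0).  The
swarm uses 40 particles with constriction coefficients (inertia 0.729,
cognitive = social = 1.494), reflecting bounds, a simplex refinement of the
swarm best every 10 iterations, a 200-iteration cap with stagnation
patience, and a repeated final simplex polish; one seeded run is the
contract.  Two domain-informed particles (the DTI eigenvalue estimate and
the canonical white-matter tensor (1.7, 0.3)) seed the swarm.

**Regularized NNLS (reference).**  A fixed dictionary of anisotropic atoms
on a λ∥ × λ⊥ lattice (15 × 11, λ⊥ ≤ λ∥) per direction plus the spectrum
atoms, solved as min ‖Ax − S‖² + μ‖x‖², x ≥ 0 (μ = 10⁻³, via the augmented
system), then collapsed to one compartment per direction by weight
averaging.  The hybrid solver attains an equal or lower residual on every
voxel we generate, since it refines the diffusivities continuously.

## Identifiability on a two-shell protocol

The emulated acquisition has two diffusion-weighted shells (27 directions
at b = 1000, 62 at b = 2500 s/mm², 8 b0 volumes).  Isotropic atoms
`exp(−bD)` therefore span a rank-3 measurement space, and the non-negative
decomposition of the spectrum is not unique: linear programming over the
exact-fit polytope shows that mixtures with restricted fractions of 0.1
admit exact solutions with RF anywhere in roughly [0, 0.18].  FF and the
fiber diffusivities *are* identifiable through their angular signature and
are recovered essentially exactly on noise-free data.  Consequences:

* absolute RF/HR values depend on the solver's selection rule (NNLS
  vertex choice) and should be compared only across voxels and subjects
  fitted with the same pipeline — which is how the group statistics use
  them;
* RF remains monotone in the true restricted fraction, so orderings and
  group contrasts are meaningful;
* recovery tests assert FF, λ∥, λ⊥ and the residual tightly, and document
  the RF bias rather than hiding it.

The noise-free recovery factorial (FF ∈ {0.2, 0.5, 0.8} × RF ∈ {0, 0.1,
0.3} × 3 orientations) renormalizes each cell's fractions to sum to one;
the (0.8, 0.3) corner is otherwise infeasible.

At SNR 30 (Rician), the freely fitted diffusivities trade against
spectrum weights, which is the dominant source of FF error (median
absolute error ≈ 0.05–0.06 over 100 repeats; at the true diffusivities
the NNLS weights alone give ≈ 0.01).  Ridge-conditioning the linear
subproblem lowers the noise error but biases the noise-free weights; the
default keeps the unregularized inner NNLS and exact noise-free
consistency.

## Conventional DTI arm

Log-linear least squares for the 6 tensor elements plus log s0, default
two-pass WLS (weights from squared first-pass predictions), OLS optional;
both shells enter by default.  Signals are floored at 10⁻⁶·s0 before the
log.  FA is clamped to [0, 1] and defined as 0 for an all-zero tensor.

## Group statistics

Voxelwise inference is an OLS GLM per voxel with a single contrast
(group, or a clinical score for regressions), with sex, age, BMI, MET,
depression and anxiety as nuisance covariates.  Familywise error over the
mask is controlled by the permutation distribution of the maximum TFCE
statistic under Freedman–Lane (nuisance-model residuals permuted, full
model refit), p = (1 + #{null ≥ obs}) / (n_perm + 1).

TFCE uses E = 0.5, H = 2, dh = max|stat|/100 and 26-connectivity by
default, with positive and negative values enhanced in separate sign
passes.  The production kernel is a union-find sweep that adds voxels in
decreasing order while lowering the threshold, carrying per-component
accumulators with potential offsets so each threshold step costs only the
number of live components; it is verified to 10⁻¹⁰ against an independent
per-threshold `scipy.ndimage.label` implementation, which is kept as the
test oracle.

Two-tailed inference defaults to the exact joint scheme: one null
distribution of the larger of the two per-sign TFCE maxima, compared with
each voxel's enhanced magnitude.  The alternative (doubling the smaller
one-sided max-null p) is available but measurably conservative with
nuisance covariates at small n (familywise rejection ≈ 0.030 vs ≈ 0.040
at a nominal 0.05, on 200 null cohorts of 20 + 20 subjects).  Demographic
tests are the Pearson chi-square without continuity correction (sex) and
the two-sided Wilcoxon rank sum (exact when both n ≤ 10 without ties,
tie-corrected normal approximation otherwise).  The source demographic
table states that continuous variables were compared by rank-sum tests
while its p-values were "based on t-tests"; that contradiction cannot be
resolved from the text, so the demographics command reports the rank-sum
p-values and the chi-square oracle is the only demographic value checked
against a published number.

Permutation counts are configurable up to the 10,000 used for the in-vivo
analyses; the test suite uses 500–1,000 permutations and 12³-voxel masks
so the calibration and power studies run on one CPU in minutes.

## Synthetic data

The phantom generator produces voxel signals from known compartment
mixtures on the emulated acquisition scheme with Rician noise
(σ = s0/SNR), plus ground-truth metric maps computed from the generating
models.  The direction tables are electrostatic-repulsion sets; the
original vendor tables are not public, so shell structure — not exact
orientations — is what is reproduced.

The cohort generator emulates the study design directly in metric space:
two groups of 67 subjects by default; per-subject maps are a smooth
subject baseline (Gaussian-filtered field, SD 0.03) plus iid voxel noise
(SD 0.055) around metric means (RF 0.10, HR 0.60, FF 0.55), with additive
patient effects (RF −0.05, HR −0.05, FF +0.05) inside a central spherical
blob — per-voxel effect size d ≈ 0.8.  Covariates are drawn from common
distributions in both groups (matched by construction) except anxiety and
depression, which are shifted upward in patients as in the study
population; about 8 % of MET values are made missing and are imputed by
age-group means (right-exclusive decade bins over 18–65; an empty bin
falls back to the global mean, logged).  Whether the original imputation
used means or medians per age group is not documented; means are used.
Clinical scores (MCS, PCS, PSQI, BDS, severity, duration) are linear in
the subject-mean of a driving metric plus Gaussian noise, clipped to
their instrument ranges (clipping logged); severity exists for patients
only.  Because maps are generated in metric space, cohort studies do not
inherit the fitting machinery's variance; the end-to-end
signal→fit→statistics route is exercised separately on small grids.

What passing tests show — and do not show: calibration and power results
demonstrate the statistical machinery is valid and sensitive under the
generator's Gaussian, spatially-stationary noise; real skeleton data have
spatially varying variance, registration error and long-range
correlation, which are not emulated.

## Numerical choices and limitations

* b0 threshold 50 s/mm² (vendor b ≈ 5 tolerated), configurable.
* Signal floor 10⁻⁶·s0 before logs; zero signals fit to zero weights.
* Voxelwise fits are independent; the per-voxel swarm seed is derived
  from the voxel coordinate, so processing order cannot change maps.
* Failed voxels are logged and skipped, never fatal; out-of-mask voxels
  are NaN.
* The minimum achievable permutation p is 1/(n_perm + 1); requesting more
  permutations than distinct orderings switches to exact enumeration with
  a warning.
* The specific modification in the cited hybrid swarm/simplex optimizer
  is not described in the available text; the hybridization schedule here
  (periodic simplex refinement of the swarm best plus a final polish) is
  an informed reconstruction, validated against a dense grid oracle.
* Three-or-more-group designs are supported generically through the
  cohort generator's `n_groups`; the appendix-style onset-subgroup
  analysis is not reproduced.
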