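# Methods

## The generative model

`gcpsynth` generates synthetic longitudinal health data in three steps:
compress the observed records into a low-dimensional latent space, synthesize
new patients *in that latent space*, and decompress.

The observed data are arranged as a dense 3-way tensor
X ∈ R^(I×J×K) over patients i, variables j and visits k, paired with a binary
mask W (w_ijk = 1 where a value was observed).  The generalized canonical
polyadic (GCP) decomposition approximates X by a sum of R rank-1 tensors,

    x_ijk ≈ m_ijk = Σ_r λ_r a_ir b_jr c_kr,   λ = 1,

fitted by minimizing the mask-weighted elementwise loss
Σ_ijk w_ijk · ℓ(x_ijk, m_ijk).  The loss ℓ is chosen per data type: Gaussian
(squared error) for continuous labs, Poisson with log link or Gaussian for
integer-coded categorical features, and gamma / β-divergence for nonnegative
skewed data.  The patient factor matrix A (I×R) carries everything
patient-specific; B and C carry variable and visit structure and contain no
per-patient information.

Synthesis never touches the model tensor M directly — its entries are in
one-to-one correspondence with the original cells, which is exactly the
privacy leak the latent-space route avoids.  Instead new rows Â are drawn
from a model of A, and the synthetic tensor is reconstructed as
Â diag(λ) (C ⊙ B)ᵀ (mode-1 unfolding; ⊙ is the Khatri–Rao product).

Missingness is synthesized the same way: the mask tensor W is itself
decomposed (Gaussian loss, rank R′), its patient factors A_w are concatenated
with A, the joint table is sampled so that value/missingness dependence is
preserved, and the reconstructed mask is binarized at a threshold (default
0.5; the reconstruction approximates cell-observation probabilities, so 0.5
is the natural decision boundary, left configurable).  Irregular visit
counts are handled by padding every patient to K = max visits with masked
cells and appending the per-patient visit count v_i as one more latent
column; sampled visit counts are rounded half-up and clipped to [1, K].

## Latent-space samplers

All three samplers consume and produce the same latent table (rows =
patients, columns = a_1..a_R, optional mask factors, visit count, baselines)
and are deterministic given a seed.

**Gaussian copula.**  Draw t ~ MVN(0, P) with P the Pearson correlation of
the latent columns, set u_r = Φ(t_r), invert each marginal â_r = F_r⁻¹(u_r).
Marginals default to the midpoint-rank empirical CDF ((i−0.5)/n plotting
positions, linear interpolation between order statistics, no extrapolation
past the observed extremes); kernel-smoothed and parametric (gamma, beta,
truncated-Gaussian) estimators are available.  Because latent-space sampling
is inexact, a draw is accepted only when ‖corr(Â) − corr(A)‖_F < ε; the loop
retries up to `max_tries` (default 50) and otherwise returns the
best-so-far draw flagged `accepted=False` rather than raising — the
threshold is a soft optimization target, not a hard constraint.  Non-PD
correlation matrices are repaired by eigenvalue clipping with a warning.

**Sequential decision trees.**  For columns in table order, fit R−1
regression trees M_j : (a_1..a_{j−1}) → a_j (scikit-learn CART,
min_samples_leaf = 5, no depth cap).  Sampling bootstraps â_1 from the
observed first column, then routes each partial synthetic row down M_j and
resamples â_j uniformly from the training values in the reached terminal
node.  Every synthetic value is therefore an observed training value;
an optional Silverman-bandwidth jitter relaxes this.

**Hamiltonian Monte Carlo.**  Model the latent rows as i.i.d. MVN(0, Σ)
with Σ = diag(σ) Ω diag(σ), half-Cauchy(2.5) priors on the σ_r and an
LKJ(η) prior on the correlation Ω (η = 1 by default, i.e. flat over valid
correlation matrices; configurable).  The sampler is plain HMC written
against the exact log posterior in the unconstrained Cholesky
parameterization (log-diagonal + strict lower triangle of chol(Σ)), with
the full chain of log-Jacobian corrections z → L → Σ → (σ, Ω); the analytic
gradient is verified against central finite differences in the test suite.
Warmup runs dual-averaging step-size adaptation (target acceptance 0.8) in
two windows, estimating a diagonal mass matrix between them; trajectory
lengths are 24 leapfrog steps with ±10% step-size jitter.  Split-R̂ and
effective sample size come from arviz; R̂ > 1.1 attaches a convergence
warning to the result instead of failing.  Because the MVN model only
matches the latent geometry of a Gaussian-loss fit, tables with other
provenance are refused unless explicitly overridden.  Synthesis cycles
through the retained posterior draws of Σ, emitting one MVN(0, Σ_t) row per
draw until n_out rows exist — so parameter uncertainty propagates into the
synthetic cohort.

## Utility metrics

- **Hellinger distance** per variable, pooling observed values across
  patients and visits: 30 shared equal-width bins over the pooled range for
  continuous variables, category frequencies for coded ones;
  H = sqrt(½ Σ_b (√p_b − √q_b)²) ∈ [0, 1].  The per-variable distances (the
  usual box-plot inputs) are all reported.
- **Correlation structure** on the widened patients × (variable, visit)
  matrix, Pearson by default, Kendall selectable; pairwise-complete
  observations, never imputed.  The absolute upper-triangle differences form
  the diff vector, and **RMSDC** is their root mean square — lower means the
  dependence structure survived synthesis better.
- **Descriptive summaries** (min, quartiles, median, mean, sd, max, missing
  count) per variable for both tables.

## The simulation profiles

No real clinical data ship with the package.  `gcpsynth.simulate` generates
study-shaped fixtures with known ground truth:

    x_ijk = μ_j + s_j (√τ g_ij + √(1−τ) e_ijk)

with patient effects g_i ~ MVN(0, exchangeable corr ρ/τ), AR(1) visit noise
e (coefficient φ, unit marginal sd), MCAR cell deletion, per-patient visit
counts uniform on a range, and categorical features drawn from requested
marginals with per-patient persistence.  The cross-variable correlation of
x is exactly the requested ρ, and the generating equations are documented so
tests can compute closed-form targets.  Defaults: τ = 0.7, φ = 0.6, ρ = 0.5,
variable locations/scales loosely shaped like a critical-care lab panel
(means 1.6 / 4.2 / 138 / 32 — all values synthetic).

Profiles mirror the regimes the method targets: dense 226 × 4 × 5;
226 × 4 × 36 with 21% MCAR; irregular visits uniform on {3..10};
246 patients × 2 categorical features × 5 visits.

What the generator does *not* emulate: skewed/heavy-tailed lab
distributions, informative (MNAR) missingness, visit-time irregularity
within a visit index, and measurement batch effects.  Passing tests
demonstrate that the pipeline preserves dependence and marginals under
Gaussian-like longitudinal structure, not that it handles arbitrary real
EHR pathologies.

## Numerical and design choices

- **Optimizer**: deterministic full-gradient L-BFGS-B over all three factor
  matrices at once (the tensors here are small); nonnegativity is enforced
  with bound constraints — orthant projection inside the quasi-Newton
  iteration — rather than a hand-rolled projected-gradient loop.  Two seeded
  restarts by default; the best final objective wins.  A plain Adam loop
  with projection exists as a cross-check.
- **Fit score**: 1 − ‖W⊛(X−M)‖_F / ‖W⊛X‖_F over observed cells (the
  standard CP fit); undefined (error) when the observed tensor is all zero.
- **Rank selection**: elbow rule — fit ascending candidates (warm-started
  from the previous rank padded with a fresh random column, which keeps the
  objective empirically non-increasing), and return the smallest rank
  beyond which neither the objective (relative to the first candidate's)
  nor the fit score improves by more than the plateau threshold (default
  1%).  R must satisfy R ≤ min(IJ, IK, JK).
- **Weights λ**: fixed at 1 during fitting; scale lives in the factors.
  When a model's λ ≠ 1 it is absorbed into the patient factors before
  sampling so the fitted B and C are used verbatim at reconstruction.
- **β-divergence**: default β = 1.5 with a 1e-10 offset stabilizing the
  m → 0 boundary; both configurable.
- **Standardization**: per-variable observed-entry mean/sd (n−1
  denominator); constant variables raise a named error.  Masked cells hold
  NaN and are never read by any objective, transform or metric.
- **Unfolding convention**: mode-n rows, remaining axes flattened with the
  earlier axis varying fastest (Fortran order), so
  unfold(M, 1) = A diag(λ) (C ⊙ B)ᵀ with ⊙ pairing row (i₁, i₂) ↦
  i₁·rows₂ + i₂.
- **Synthetic values are not clipped** to the observed range by default
  (synthetic extremes legitimately fall on both sides of the originals); a
  clamp flag exists.  Categorical postprocessing rounds to the nearest
  admissible code and clips into the level range, exponentiating first for
  Poisson-log-link fits.
- **Problem sizes**: the shipped acceptance runs factor the dense 226×4×5
  panel at full rank R = 20 (= JK, the rank used for panels of this shape),
  and the 21%-MCAR 226×4×36 panel at R = 12 with mask rank R′ = 6 — a
  desk-scale setting of the same pipeline (the original missing-data
  experiment used R = 100 / R′ = 50).

## Known limitations

- Low-rank modeling of an MCAR (structure-free) mask tensor reconstructs
  each cell near the overall observation rate, so thresholding yields far
  less synthetic missingness than the original when missingness is truly
  random (the method's own missing-data experiments likewise reproduce the
  missing *rate* poorly — in the other direction).  The report always
  carries both fractions; no correction is applied.
- The HMC route assumes a zero-mean Gaussian latent space; it is refused
  (by default) after non-Gaussian-loss fits, and even for Gaussian fits a
  strongly non-Gaussian latent geometry degrades it gracefully rather than
  detectably.
- Copula marginals are fitted per raw latent column, before any rescaling.
- Sequential trees cannot emit unseen values without the smoothing option,
  which slightly inflates within-leaf variance.
- N is fixed at 3 modes; sparse tensor storage and stochastic-gradient
  fitting for massive tensors are out of scope.
- No formal privacy-attack evaluation is included: privacy rests on the
  structural argument that only the latent patient space is ever sampled
  and no synthetic record maps one-to-one to an original record.
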