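# Methods

## The model

`rvrmap` predicts a continuous clinical score (MMSE, DRS, ADAS-Cog or AVLT
percent retention) from a subject's preprocessed grey-matter density map by
relevance vector regression — sparse Bayesian regression over kernel basis
functions.

Each subject's masked voxels form a feature vector x ∈ ℝ^D. The linear
kernel k(x_i, x_j) = x_i·x_j is computed for all training pairs and the
basis matrix is Φ = [**1**, K]: a column of ones modelling the score offset
followed by one kernel column per training subject. With targets t and
weights w,

- likelihood: p(t | w, σ²) = N(t | Φw, σ²I)
- prior: p(w | α) = Π_i N(w_i | 0, α_i⁻¹), one precision per basis
- posterior: N(w | μ, Σ), Σ = (σ⁻²ΦᵀΦ + A)⁻¹, μ = σ⁻²ΣΦᵀt, A = diag(α)
- evidence: p(t | α, σ²) = N(t | 0, C), C = σ²I + ΦA⁻¹Φᵀ.

Fitting maximises the evidence over (α, σ²) — type-II maximum likelihood.
Many α_i diverge during optimisation (automatic relevance determination) and
their bases are pruned; the surviving training subjects are the relevance
vectors. The relevance ratio is their count divided by the number of
training subjects.

Because the kernel is linear, the fitted function can be back-projected into
voxel space: the weighting image w_vox = Σ_i μ_i x_i over active non-offset
bases (rescaled by the kernel conditioning factors), and a new subject's
predicted score is exactly dot(w_vox, features) + offset. This two-path
equivalence is asserted to 1e-8 in the tests.

## Optimiser (numerical choices)

The model definition fixes only the objective; the update scheme is the
classic fixed-point re-estimation:

- γ_i = 1 − α_i Σ_ii (the "well-determinedness" of basis i; an
  implementation symbol, not part of the model statement),
- α_i ← γ_i / μ_i², σ² ← ‖t − Φμ‖² / (N − Σ_i γ_i),
- prune basis i when α_i > 1e12,
- converge when max |Δ log α_i| < 1e-4, cap 500 iterations.

Initialisation: α_i = (1/N)² uniformly, σ² = 0.1·var(t) with a floor of
1e-6·var(t). The offset column is subject to ARD like any other basis.
Defaults live in `FitConfig` and are recorded on every results object.

Two safeguards matter in practice:

- **Best-evidence iterate.** The fixed-point updates are not provably
  monotone; the fit records the log evidence each iteration and returns the
  iterate with the highest evidence seen, so the final evidence never falls
  below the initial value.
- **Internal basis normalisation.** Before fitting, the kernel block of Φ is
  divided by the RMS of its entries (undone transparently at prediction and
  back-projection). This makes predictions *exactly* invariant to an overall
  kernel rescaling — without it, a uniform α initialisation is
  scale-inappropriate for extreme kernels and the optimiser can fall into a
  σ²-floor interpolation trap at one scale but not another. The upstream
  kernel conditioning (dividing K by the mean of its training diagonal)
  keeps stored kernels O(1) and auditable; the internal normalisation makes
  the fit itself scale-free.

Linear solves use Cholesky factorisation with escalating diagonal jitter
(1e-10·trace, ×10, three retries) before raising. N = 1 fits are allowed but
flagged `degenerate_n1`; constant targets are handled (the offset basis
captures them), not rejected.

## Synthetic cohorts

The real cohorts behind this kind of analysis are access-restricted, so the
generator emits cohorts with the structure the method assumes — it is a
stated world for testing, not a simulation of any scanner or dataset:

- **Template**: a fixed sum of three broad Gaussian lobes, shared by all
  subjects; the analysis mask is template > 5% of its maximum.
- **Hidden pattern**: signed ellipsoidal bumps (default: one positive
  medial-temporal-like focus, weight +1, and a smaller negative
  anatomical-adjustment focus, weight −0.6, both scaled to the grid).
- **Subject volume**: max(0, template − s·a·pattern + noise field), where s
  is the subject's latent severity, a = 0.08 volume-units per severity unit,
  and the noise field is white Gaussian noise smoothed to ~1-voxel
  correlation and rescaled to SD 0.02. Volumes are non-negative like real
  GM density maps.
- **Score**: an affine map of ⟨pattern, volume⟩ plus N(0, noise_sd), clipped
  to the instrument bounds (MMSE 0–30, DRS 0–144, ADAS-Cog 0–70, AVLT
  0–100). The affine map is calibrated deterministically so a severity-0
  subject sits at 95% of the instrument's good-to-bad axis and a
  severity-2.5 subject at 30%; for the reverse-scored ADAS-Cog the anchors
  flip, so group ordering reverses as it should. With zero score noise the
  score is an exact linear functional of the emitted volume (asserted
  against direct voxel summation).
- **Groups**: latent severity ~ N(2.0, 0.5²) for AD, N(1.0, 0.4²) for MCI,
  N(0.0, 0.3²) for CN — ordering AD > MCI > CN. Default score noise is 2.0
  instrument units. These values are stand-ins chosen once for a plausible
  dementia-severity spread; they are recorded in every saved cohort's
  metadata.
- **Covariates**: education uniform on 12–20 integer years; an optional
  cognitive-reserve term (off by default) adds
  direction·strength·(education − 16) to the score so reserve analyses have
  signal to find. MCI subjects get days-to-conversion = 2200 − 600·s +
  N(0, 150²), censored into [1, 1500] — decreasing in severity with a
  censoring mass at 1500, the value used for non-converters in rank
  analyses.

All randomness flows through one seed; per-subject streams are spawned as
SeedSequence(seed, spawn_key=(1, subject_index)), so cohorts are
bit-reproducible and insensitive to generation order.

What the generator does **not** emulate: scanners, bias fields, segmentation
or registration error, multi-site effects, age effects, non-Gaussian score
distributions. A green recovery test therefore establishes that the chain
(kernel → evidence maximisation → prediction → back-projection) is
implemented correctly, not that the method would reach any particular
accuracy on real data.

## Validation designs and metrics

- **Leave-one-out CV** retrains on the remaining n−1 subjects per fold,
  rebuilding the kernel (and its conditioning scale) on the reduced set.
  Smoothing/masking/vectorisation are unsupervised and computed once outside
  the folds. A structural test asserts fold-i training data excludes
  subject i, and a perturbation test asserts a held-out score cannot move
  its own fold's prediction.
- **Cross-dataset** fits once on a training cohort and predicts an
  independent cohort on the identical grid/mask and instrument.
- **Metrics**: Pearson r with two-sided p (t transform, n−2 df); RMS error;
  normalized RMS after z-scoring both series by the actual scores' mean and
  *population* (1/n) SD — this convention pins the constant mean predictor
  at exactly 1.0, making 1 an interpretable ceiling; Spearman rho with
  midranks for ties. Prediction error is (actual − predicted) throughout: on
  a higher-is-better instrument, a positive error reads as performance above
  what anatomy predicts (the cognitive-reserve direction).
- **Confound removal**: voxelwise linear residualisation fits per-voxel
  slope/intercept against a covariate on training rows only and applies the
  training coefficients to any rows.

## Known limitations

- LOO correlation on null data is biased negative: a model that predicts
  ~the fold mean produces predictions that are a decreasing function of the
  held-out score, so r → −1 for a pure mean predictor. At n = 60 with the
  default noise the artifact is diluted below the 2/√n null band (verified
  over 20 seeds), but at n ≲ 30 null |r| can be large. This is a property of
  the LOO design, not of the model.
- Metric invariance to subject order holds to optimizer stability (~1e-3 in
  r), not machine precision: ARD pruning decisions can amplify
  summation-order rounding.
- Small cohorts (n ≲ 20) with appreciable noise overfit: in-sample
  predictions are near-perfect while held-out predictions collapse toward
  the training mean. This mirrors the method's known need for adequate
  training samples.
- Relevance ratios depend on the (unreported in the field) prune threshold
  and optimiser settings; they are comparable across runs of this package,
  not across implementations.
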