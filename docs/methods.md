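# Methods

## Overview

`mmconn` builds an individual (per-subject) brain connectivity network from
paired structural and metabolic regional voxel data, and evaluates how well
those networks separate progressive from stable mild cognitive impairment
(pMCI vs sMCI). The construction has three stages:

1. **Bagged regional PCA (auxiliary domain).** An independent cohort of AD
   and NC subjects is resampled with replacement T times, stratified so each
   replicate keeps the original group sizes (n_AD, n_NC). For every
   replicate t, region k and modality m, the top S principal components of
   the regional voxel matrix are computed by SVD of the mean-centered
   resample, together with the resample mean used for centering. Bootstrap
   indices are shared across regions and modalities within a replicate, so
   row t of every projected matrix refers to the same resample — a
   requirement for the cross-region regressions over the replicate dimension
   to be meaningful. PCA is unsupervised on the pooled AD+NC resample;
   diagnosis labels enter only through the stratification.

2. **Multi-task l2,1 connectivity extraction (target domain).** A target
   subject is projected region by region onto each replicate's components,
   giving per modality and PC index i a T x K matrix X_i. For each target
   region k and PC index i, each modality is one regression task: the
   target vector is region k's centered projected column, the design is the
   column-standardized matrix with column k zeroed, and

       min_W  1/2 sum_m ||y^m - X^m w^m||^2 + lambda sum_j ||W_j.||_2

   couples the tasks so a regressor region is selected only when it
   predicts the target jointly across modalities. lambda is a fraction
   (`lambda_ratio`) of that problem's lambda_max — the smallest penalty
   that zeroes all coefficients — so the same ratio is transferable across
   problems. The S per-PC binary supports of each regressor row are read as
   an S-bit number (PC 1 the most significant bit) and normalized by
   2^S - 1, producing an asymmetric K x K weight matrix quantized to
   multiples of 1/(2^S - 1) with zero diagonal.

3. **Evaluation.** Edge weights are flattened to K(K-1) features and fed to
   leave-one-out cross-validation with nested two-step feature selection:
   a pooled-t filter keeps the top 20% of edges, linear SVM-RFE ranks the
   survivors under a dimension-dependent step schedule (500 above 10,000
   features, then 50, 5 below 1,000, and 1 below 100), the SVM cost C is
   tuned by an inner stratified 5-fold search over 2^beta, beta in -8..8,
   and the held-out subject is predicted at feature fractions 10%, 15%, ...,
   100% of the filtered set by RFE rank. Every selection statistic is a
   pure function of the n-1 training subjects; an audit mode poisons the
   held-out row and hard-fails if any selection changes. Sensitivity is
   defined with pMCI (conversion) as the positive class. The reported
   peak-accuracy grid point is flagged as optimistically biased, since the
   fraction is chosen on the evaluation metric itself.

## Solver

The multi-task objective is minimized by accelerated proximal gradient
(FISTA) with a function-value monotonicity safeguard: if an accelerated step
increases the objective, the momentum is reset and a plain proximal step is
taken from the current iterate. The step size is 1/L with L = max_m
sigma_max(X^m)^2. The row-wise group soft-threshold prox produces exact zero
rows, so support extraction uses no epsilon. Convergence is declared when
the relative objective change stays below `tol` (default 1e-8) for 5
consecutive iterations or the l2,1 KKT residual falls below `kkt_tol`
(default 1e-6; polled every 10 iterations, since the KKT check costs as
much as a gradient step). High-precision comparisons against the oracles
tighten both tolerances. In
`l1_single_task` mode with one task the penalty reduces to the lasso, and
the solver is cross-checked in the tests against scikit-learn's coordinate
descent; the multi-task path is cross-checked against an independent
block-coordinate-descent oracle.

Numerical choices worth knowing:

- Design columns are z-scored over the T dimension and then scaled to unit
  l2-norm; targets are centered but not scaled. Selection is therefore
  invariant to per-column affine changes, and the lambda-ratio convention is
  comparable across problems. Constant columns cannot be standardized and
  are zeroed (logged), excluding them structurally.
- The target region's own column is kept in the design but fixed at zero,
  so its coefficient is structurally zero and it never enters lambda_max.
- With lambda set per problem as ratio x that problem's lambda_max, any
  ratio < 1 admits at least the best-correlated regressor; empty rows
  appear only at ratio 1. Sparsity is monotone in the ratio up to solver
  tolerance.
- Zero-variance directions in a rank-deficient resample are completed by a
  deterministic Gram-Schmidt orthonormal completion (logged), keeping the
  stored basis full size.
- Bootstrap eigenvector signs are aligned to full-sample reference
  components (tie-break: force the largest-|loading| element positive).
  PCA signs are otherwise arbitrary and unaligned signs would randomize
  projections across replicates.

## Synthetic study

The generator plants both group structure and connectivity ground truth in
two modalities. Per subject, region k and modality m the voxel vector is

    baseline_{k,m} + g * a_group * effect_size * effect_map_{k,m}
    + sum_couplings z_subject * loading_m * coupling_map + N(0, noise_sd^2)

with g*a_group = 1 for AD, 0 for NC, and the MCI attenuations a_sMCI = 0.2,
a_pMCI = 0.8 interpolating between them; z_subject is a standard-normal
latent shared by coupled region pairs in both modalities. Effect and
coupling patterns are unit-norm and zero-mean within each region: planted
signal redistributes voxel values without moving the regional mean, so raw
regional-mean summaries carry no first-order group information and serve as
a genuine null baseline. A config switch (`modality_specific_couplings`)
decouples the latents across modalities for ablation.

The frozen desk-scale study used by the tests and the acceptance script:
K = 30 regions of 20-40 voxels, groups (60 AD, 60 NC, 40 sMCI, 40 pMCI),
six coupled pairs with loadings 2.0 on both modalities, effect size 1.5
standardized units, unit voxel noise, seed 20191115; basis T = 50, S = 5,
solver lambda_ratio = 0.7. These sizes keep a full end-to-end run in
minutes on one CPU. Effect size and loadings were calibrated once, before
pinning, so that the planted couplings are recoverable: the factor
eigenvalues must clear the Marchenko-Pastur bulk edge of the per-region
sample covariance (p/n up to 40/120), which weaker, individually realistic
loadings do not at this scale.

What the generator does not emulate: spatial autocorrelation, scanner and
site effects, realistic GM-density value ranges, subject-level anatomical
variability beyond the planted factors, and any group difference in
connectivity strength (the model couples regions identically in all
groups). Passing tests therefore demonstrate the pipeline's mechanics and
the recoverability of planted couplings — not clinical performance.

## Known limitation: subject-level signal in the bagged construction

At this scale the construction carries little subject-specific information
into the binarized edges, and one acceptance-level check is deliberately
left failing rather than weakened: the requirement that MMC edge features
beat raw regional-mean features by ten accuracy points in the LOOCV peak.

The reason is structural. A subject's projected profile across replicates,
x_k(t) = <v_t, s_k - mu_t>, varies with t only through the resample means
mu_t and the eigenvector jitter eps_t, both O(1/sqrt(n_aux)) and driven by
the auxiliary cohort. The cross-region-correlated profile components that
determine which regressors are selected (resample-mean fluctuations of the
shared latents) have amplitudes set by the auxiliary cohort and are
identical for every target subject; all subject-specific components — the
group shift and the subject's own latent — multiply region-private jitter
profiles and influence edges only by diluting correlations. Stratified
resampling (which removes group-composition variance from mu_t), target
centering and column standardization (which remove first-order and scale
information), and the symmetric placement of the MCI attenuations about the
auxiliary mean each close one of the remaining channels. Control
experiments in which coupling strength was made directly group-dependent —
outside the generative model — still topped out near chance, confirming the
bottleneck is the construction at this cohort scale rather than the
calibration. With the published cohort sizes, hundreds of regions, and the
rich anatomical covariance of real data, more subject information reaches
the ensemble; at desk scale the honest result is a near-null classifier,
and the test records that.

## Reduced problem sizes

The label-permutation null check runs on a 60-subject subsample with the
inner C grid narrowed to 2^-4..2^4 (20 permutations of a full LOOCV each);
the no-effect null uses K = 100 regions with per-region means. These sizes
are the package's choice for routine verification; the statistical
properties they check do not depend on the full grid.
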