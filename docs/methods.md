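# Methods

`placentaging` scores placental maturation from multi-echo gradient-echo MRI
in three steps: voxelwise T2* relaxometry, automatic placenta segmentation,
and a normative errors-in-variables Gaussian-process (TLS-GP) model of mean
placental T2* against gestational age. Because no suitable cohort is publicly
deposited, the package also ships a synthetic-data generator that defines the
study conditions under which everything is tested.

## T2* relaxometry

Each voxel's signal is modelled as mono-exponential decay,
`S(TE) = S0 exp(-TE / T2*)`, and fitted by damped (Levenberg-Marquardt-style)
least squares with at most 50 iterations and a convergence tolerance of 1e-8
on the relative parameter update. The reference echo times are
13.8 / 70.4 / 127 / 183.6 ms. Implementation choices:

- The amplitude is initialised from the first-echo signal; the decay rate
  from the two-point log estimate of the first two usable echoes, falling
  back to T2* = 50 ms when that estimate is non-positive.
- The solver iterates in `(S0, R2 = 1/T2*)` coordinates, which remain regular
  in the no-decay limit; a non-positive fitted rate means "no measurable
  decay" and is reported at the clip ceiling. It is vectorised across all
  voxels of a volume (per-voxel damping factors), so a full volume is one
  array computation rather than a Python loop.
- Fitted T2* above 300 ms is **set to** 300 ms (not discarded). This limits
  the influence of amniotic-fluid partial volumes on placental means while
  keeping the affected voxels in the average. Clipping happens at map level,
  before any mask statistics.
- Echoes with non-positive signal are excluded from a voxel's fit when at
  least two usable echoes remain; otherwise the voxel is flagged invalid
  rather than raising.

On noiseless series the fit agrees with the log-linear closed form to better
than 1e-4 relative error over T2* in [10, 290] ms (tested), and with SciPy's
Levenberg-Marquardt on noisy series.

## Segmentation

A 2D patch-based U-net operates on T2* map slices. The protocol: training and
inference on 64x64 patches; z-score normalisation with the mean and SD of the
training set (both stored in the model); binary cross-entropy loss; Adam with
learning rate 1e-4 and batch size 5; augmentation by random spatial cropping,
axis mirroring and in-plane rotations within +/-15 degrees; half of all
training patches are forced to contain foreground. Inference tiles each slice
with patches overlapping by 30% (stride `round(64 * 0.7) = 45`, edge patches
shifted inward so every voxel is covered), averages probabilities across
overlaps and binarises at 0.5 with ties counted as foreground.

The network is a compact CPU implementation in NumPy (im2col convolutions,
3x3 kernels, ReLU, 2x2 max-pooling, nearest-neighbour upsampling with skip
concatenation, He initialisation; gradients verified against numerical
differentiation). Depth and width are configurable; the package default is
3 resolution levels with 16 base filters and 2,000 optimizer iterations.
The tests and the acceptance run use a lighter setting (8 base filters,
300-400 iterations) adequate for the phantom task; clinical-scale data would
warrant the full default or larger.

Two deliberate choices:

- **Normalisation includes the SD.** With demean-only inputs (magnitudes up
  to a few hundred ms) and the fixed 1e-4 learning rate, the desk-scale
  network underfits badly; z-scoring — the default preprocessing of the
  nnU-Net family this architecture descends from — fixes the conditioning
  without touching the rest of the protocol.
- **Iteration count means optimizer steps** (batches), not passes over the
  data; this is the only reading under which large published step counts are
  plausible with small batch sizes.

Cross-validation folds are stratified on the risk group and assign each
subject to exactly one fold, so no subject contributes to both training and
evaluation of the same network.

## Normative TLS-GP model

Let `t_b` be biological placental age (proxied by gestational age, weeks) and
`y` the mean T2* inside the placental mask (ms). Both are noisy:
`sigma_eps = (42 - 37) / (2 * 1.96) ~ 1.28` weeks treats the normal term
window as a 95% interval of biological age at delivery, and `sigma_delta`
(default 8.7 ms) summarises measurement and segmentation error of the mean
T2*. Ordinary regression attributes all error to the response and yields
Z-scores that correlate with age; the TLS construction avoids this:

1. demean by the training means and scale per coordinate by the expected
   error SD, `x_s = S (x - mu)`, `S = diag(1/sigma_eps, 1/sigma_delta)`;
2. rotate onto the principal axes of the scaled training cloud (SVD); the
   first coordinate runs along the maturation trend, the second is the
   orthogonal deviation. Singular-vector signs are fixed deterministically
   (positive age component on axis 1, positive T2* component on axis 2);
3. regress the second projected coordinate on the first with a Gaussian
   process: constant mean (implemented by target normalisation), kernel =
   dot product + amplitude-scaled squared exponential + white noise,
   hyperparameters by maximising the log marginal likelihood with 5
   seeded restarts.

Kernel bounds (projected units): dot-product `sigma_0` in [1e-3, 1e3]; RBF
length-scale in [0.2, 1.0] x SD of the input coordinate; white noise level in
[1e-6, 10]. The upper length-scale bound keeps the RBF a *local* correction
to the linear trend. The lower bound matters: allowing length-scales below
the typical training-point spacing lets the RBF impersonate the white-noise
kernel, which injects wiggles into the posterior mean, makes the
back-projected age coordinate non-monotone, and breaks the identity that a
point on the normative curve scores Z = 0.

**Z-scores** are computed in projected space: the observed second coordinate
minus the GP posterior mean at the first coordinate, divided by the full
posterior *predictive* SD (latent plus fitted white noise). With the
predictive SD, normative data score approximately standard normal, which is
what makes the +/-3 range interpretable. **Curves and credible bands**
(`mean +/- z * predictive SD`, z = 1.96 and 3 for 95% and 99.7% coverage) are
formed along a dense grid of the maturation coordinate, back-projected
through `mu + S^-1 U x'`, and interpolated at the query ages.

**Accelerated-aging probability.** The GP posterior assumes noiseless inputs;
the known input noise `N(0, diag(sigma_eps^2, sigma_delta^2))` is integrated
by plain i.i.d. Monte-Carlo (default 10,000 draws; the target distribution is
a known bivariate normal, so no Markov chain is needed): the reported value
is the fraction of perturbed inputs with Z < -3. It is deterministic per
seed, exactly 0/1 in the zero-noise limit, and its across-seed spread matches
the binomial standard error (tested).

The **OLS baseline** regresses age on mean T2* with the same kernel family
and scores the standardized age residual. It exists to demonstrate the bias
the TLS construction removes: on synthetic cohorts whose scatter is entirely
on the T2* axis, OLS Z-scores correlate with age (|r| > 0.3) while TLS
Z-scores do not (|r| < 0.15), and the TLS-based accelerated-aging probability
separates the high-risk group better (AUC higher in 20/20 replicates).

**sigma_delta from age bins.** For small cohorts the T2* error SD is
estimated by pooling narrow age windows: candidate bin centres are scanned
from low to high gestational age, and disjoint windows of half-width
`sigma_eps` containing at least 4 points are accepted greedily until 4 bins
are found (error otherwise, reporting how many bins were achievable); the
estimate is the mean of the per-bin sample SDs. Within such a narrow window
the normative trend contributes little (~2-3 ms in quadrature under default
conditions), so the within-bin spread is dominated by measurement noise.

## Synthetic data

The generator defines the study conditions:

- **Cohorts.** Low-risk mean T2* follows `180 - 3.5 * GA` ms plus
  `N(0, 8.7^2)` scatter; the intercept and slope are invented but give
  ~110 ms at 20 weeks and ~40 ms at 40 weeks, consistent with the reported
  decline of placental T2* over gestation. All scatter is on the T2* axis by
  construction — the regime in which the TLS/OLS contrast is well defined.
  Gestational ages are truncated-normal (mean 29.9, SD 4.3, range 18-40
  weeks), matching a typical late-second/third-trimester scanning
  distribution; high-risk subjects keep their observed GA but their T2* is
  computed at GA + 6 weeks (configurable 4-8), i.e. accelerated aging is an
  age shift, not an additive offset. Default sizes 90 low-risk / 20
  high-risk with a 7:3 normative train/test split.
- **Voxel phantoms.** An 80x80x6 grid at 3 mm isotropic resolution contains
  a plate-like placental ellipsoid (smooth lobule texture, demeaned over the
  mask so the masked mean equals the subject's latent value), a disjoint
  amniotic-fluid ellipsoid with T2* = 1000 ms (exercising the 300 ms clip),
  and maternal tissue (T2* 25 ms) filling the remaining field of view, as in
  a real acquisition where the whole grid carries signal. Gaussian noise with
  SNR 50 relative to the placental S0 is added per echo. A Rician-free noise
  model keeps the relaxometry oracle analytic; at this SNR the Gaussian
  approximation to magnitude noise is adequate. An early design left the
  non-placental field of view empty; fitting pure noise produced nonphysical
  salt-and-pepper T2* speckle and was replaced by the tissue compartment.

What the phantoms do *not* emulate: fetal anatomy, inter-slice motion,
contractions, B0 inhomogeneity, coil shading, Rician noise floors, and the
anatomical variability of real placentas. Passing phantom tests therefore
demonstrates that the pipeline machinery is correct and well calibrated under
its stated assumptions — not that the clinical performance figures of any
particular cohort transfer.

## Problem sizes and numerics

The test suite and `scripts/acceptance.py` run the statistical experiments at
n = 90 + 20 subjects with 20 replicate seeds, Monte-Carlo integration at
2,000 draws per subject inside the replicate loops (10,000 where the binomial
spread itself is under test), and the closed-loop pipeline at 10 subjects
(80x80x6 phantoms, 8-filter U-net, 400 iterations) — sizes chosen so the
whole study re-runs in minutes on one CPU core. Degenerate inputs are
contracts, not crashes: all-noise voxels are flagged invalid, empty
mask/valid intersections raise a dedicated error, collinear training data
collapse the orthogonal coordinate to zero and the bands onto the curve, and
probability ties at the 0.5 segmentation threshold count as foreground.

## Known limitations

- The U-net is desk-scale; clinical-quality segmentation would need the
  full-size architecture, GPU training, and far more annotated subjects.
- `sigma_delta` is treated as known when scoring; uncertainty in its
  estimate is not propagated.
- The normative model is cross-sectional; it says nothing about
  within-subject trajectories.
- Extrapolation beyond the training age range triggers a warning but is not
  prevented; the bands there reflect prior, not data.
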