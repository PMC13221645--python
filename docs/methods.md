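# Methods

## Scope

`frapdyn` implements two quantitative protocols: (i) estimation of
binding/mobility fractions of a nuclear protein from FRAP recovery
curves with the Sprague two-state binding model, and (ii) coarse-grained
characterization of protein flexibility with anisotropic-network-model
(ANM) normal modes and ensemble RMSF.  Both start from plain text inputs
(intensity tables, PDB files); image segmentation, MD simulation and
structure prediction are out of scope.

## FRAP normalization

Intensities are background-corrected frame-wise (`F = I_roi - I_bg`).
Two normalizations are provided:

* percent-of-prebleach, `ROI(t) = (I_t - I_bg)/(I_o - I_bg) x 100`, with
  `I_o` the mean pre-bleach ROI intensity;
* full-scale, `F_norm(t) = (F(t) - F0)/(F_prebleach - F0)`, which maps the
  bleach nadir to 0 and complete recovery to 1 and is the form the model
  is fitted to.

Choices where the protocol leaves freedom:

* `F_prebleach` is the mean over *all* pre-bleach frames (minimum-variance
  choice; at least 2 pre-bleach frames are required).
* The ~30 ms bleach is collapsed to the instant t = 0.  `F0` is the first
  post-bleach frame, which sits at the bleach nadir t = 0; with frames
  every 0.5 s captured for 60 s this gives 120 post-bleach frames
  (t = 0, 0.5, …, 59.5 s).  Anchoring the grid at the nadir makes
  normalization and model evaluation mutually consistent: a noiseless
  simulated trace normalizes back to the generating curve exactly
  (machine precision), which is the closure property the recovery
  experiments rely on.
* Traces whose pre-bleach level does not exceed the first post-bleach
  frame carry no bleach signal and are rejected with a diagnostic rather
  than fitted.
* No photofading / acquisition-bleaching correction is applied
  (limitation: slow monitoring bleaching would bias the apparent immobile
  fraction upward).

## Two-state recovery model

```
frap(t) = (F_eq + C1_eq) e^{-x}(I0(x) + I1(x)) + C2_eq (1 - e^{-k2_off t}),
x = tau1_eff/(2t)
```

* The bracketed effective-diffusion factor is evaluated with
  exponentially scaled Bessel functions (`scipy.special.i0e/i1e`), making
  it stable for arguments up to at least 1e6; at t = 0 it is defined by
  continuity as 0 (from e^{-x} I_nu(x) ~ (2 pi x)^{-1/2}).
* `tau1_eff` is a phenomenological recovery time; no bleach-spot geometry
  enters the closed form, and the argument is implemented exactly as
  written (`tau1_eff/2t`), with no half-time rescaling.
* Fractions are not forced to sum to one: the deficit
  `1 - (F_eq + C1_eq + C2_eq)` is reported as the immobile fraction.
* `F_eq` and `C1_eq` enter only through their sum, so a single recovery
  curve cannot separate them.  The fitter estimates the fast amplitude
  `A = F_eq + C1_eq` and reports `f_eq = A, c1_eq = 0` by convention;
  uncertainties are reported for the identifiable quantities
  (A, C2_eq, immobile fraction, tau1_eff, k2_off).

## Fitting

Unweighted least squares on the normalized post-bleach curve.  The
fraction triple (A, C2, immobile) is reparameterized with softmax logits
(every iterate is a valid simplex point — no clipping), and tau1_eff,
k2_off are optimized on log scales within bounds (tau in [1e-3, 1e4] s,
k in [1e-5, 10] /s).  `scipy.optimize.least_squares` (TRF) with an
analytic Jacobian; a deterministic 5-point multi-start ladder (seeded
jitter of the data-driven initial guess) guards against the local minima
that appear when k2_off ~ 1/tau1_eff.  Standard errors come from the
Jacobian-based covariance at the optimum (delta method for the immobile
fraction); intervals are normal-theory at the configured level, plus a
residual-resampling bootstrap (percentile intervals, warm-started
single-start refits, fully seeded).  Diagnostics: scaled-Jacobian
condition number (flagged above 1e6 — slow-k2off vs immobile
confounding), and a "plateau not reached" flag when `k2_off * t_max < 1`.

Model variants for comparison: `full`, `no_slow_state` (C2 = 0) and
`reaction_dominant` (diffusion factor frozen at its plateau), ranked by
`AIC = n ln(rss/n) + 2k`, ties broken toward fewer parameters.

Two immobile-fraction estimators are available (`plateau`, the default,
and `terminal_mean` = 1 minus the mean of the final 10% of the curve);
per-cell fitting is the default unit, fitting the group mean curve is a
config option.

### Identifiability of tau1_eff

With the default acquisition (0.5 s frames, 60 s window) and noise
sigma = 0.02, tau1_eff is the weakest-determined parameter of a
single-cell fit: a Cramér–Rao analysis over the recovery grid used by the
tests (immobile in {0.02, 0.30, 0.50}, tau in {0.5, 2, 8} s, k2_off in
{0.02, 0.05, 0.2} /s, mobile pool split 70/30 fast/slow) puts the
*best-case* median relative error of per-cell tau1_eff estimates at
roughly 8–48% depending on the grid cell (worst where the recovery rise
is sampled by only a few frames and where k2_off ~ 1/tau1_eff), pooled
median ≈ 19%.  The implemented estimator attains this bound (verified:
multi-start fits coincide with truth-started fits), so per-cell tau
estimates should be interpreted with their reported intervals, or
estimated from averaged curves when replicates exist (averaging 20
replicates shrinks the error by ~sqrt(20)).  Immobile-fraction and
k2_off estimates are much better determined (median errors ~0.008 and
~13% on the same grid).

## Synthetic FRAP data

The generator emulates the target acquisition: 5 pre-bleach frames,
bleach collapsed to t = 0, 120 post-bleach frames at 0.5 s spacing over
60 s; bleach depth 0.3, pre-bleach level 1000 counts, background 50
counts (fixed fixture constants).  Noise is additive Gaussian on the
normalized scale (default sigma 0.02), applied to the recovery
measurements (t > 0); the nadir frame carries the exact bleach level F0,
which *defines* the normalized scale — this keeps the normalized-curve
noise additive iid with SD sigma, the statistical structure all the
recovery experiments assume.  Per-cell variability in cohorts is
logistic-normal on the fraction simplex and log-normal for tau1_eff and
k2_off (CV 0.1 by default), so every cell's parameters are automatically
valid.  What the generator does **not** emulate: photon (Poisson) noise,
acquisition photofading, spatially resolved bleach profiles, ROI drift.
Passing recovery tests therefore demonstrate estimator correctness under
the model's own assumptions, not robustness to those real-data effects.

## ANM and RMSF

Standard ANM on Cα nodes: uniform springs (gamma = 1) between pairs with
`d_ij <= 15 Å` (inclusive), Hessian super-elements
`H_ij = -(gamma/d_ij^2) r_ij r_ij^T`, diagonal = negative row sums.
Eigenpairs are computed dense by default (a sparse shift-invert solver is
available and agrees to 1e-8); rigid-body modes are detected with a
spectrum-relative floor `max(1e-8, 1e-10 lambda_max)` — 6 zero modes for
generic structures, 5 for a collinear pair.  The first 10 non-trivial
modes are retained; per-residue mobility along a mode is the Euclidean
amplitude of the unit eigenvector with **no** 1/sqrt(lambda) scaling.
Ensembles are aligned to their first frame by Kabsch superposition with
the proper-rotation (det +1) correction; RMSF is computed about the
post-alignment time-average position (the variance-minimizing reference).
A collinear alignment selection leaves the rotation underdetermined and
is rejected.

The toy two-domain-linker fixture joins two compact helical domains
(ideal α-helix geometry: rise 1.5 Å, 100°/residue, radius 2.3 Å) by an
extended strand at 4.5 Å spacing with 1.5 Å helical lateral offsets.
The geometry is chosen so that (i) every linker bead keeps i±1/i±2
contacts at the 15 Å cutoff — enough independent constraints that the
network has exactly the six rigid-body zero modes (sparser linkers
introduce floppy mechanism modes), and (ii) the linker remains far
sparser than the domains, so the lowest non-trivial mode localizes on it
(median linker/domain Mode-1 amplitude ratio ~2.6 at n = 40).  Chains
are labelled A / L / B so tests can address the regions.  Very short
linkers (3 residues) are stiff and do not show the elevated-mobility
signature; the default is 5.

## Determinism and numerical choices

Every stochastic component takes a seed (NumPy `default_rng` /
`SeedSequence` spawning); CLI outputs are written with fixed float
formatting so repeated seeded runs are byte-identical.  Problem sizes
used by the test suite and the acceptance script (27-truth grid x 20
replicates, 100-draw bootstraps, 100 cohort repetitions, 1000-frame
ensembles, fixtures of 40–100 residues) were chosen to give stable
statistics for the properties being checked while keeping a full run in
the minutes range on one CPU.

## Known limitations

* The full spatial reaction–diffusion solution (bleach-geometry-aware) is
  not implemented; only the printed closed form.
* No global multi-condition fitting with shared parameters.
* PDB is the only structure/ensemble format (multi-model PDB for
  ensembles); binary MD formats are out of scope.
* RMSF averages over frames only (no replicate-simulation averaging).
* For collinear point sets beyond a pair, the ANM itself is degenerate
  (transverse springs exert no restoring force); such inputs are valid
  but their extra near-zero modes are reported rather than suppressed.
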