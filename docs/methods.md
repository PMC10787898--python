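# Methods

`memfluct` analyses the mechanics of the plasma membrane of adherent cells
during de-adhesion, from four kinds of raw data: interference reflection
microscopy (IRM) movies of the basal membrane, optical-tweezer bead traces
from tether pulling, fluorescence images of endocytic structures, and
spread-area time courses.  Every stage also has a synthetic generator with
recorded ground truth, so the full pipeline is testable end to end without
experimental data.  This note records the models, the parameter choices and
their rationale, the numerical decisions, and what the synthetic tests do
and do not establish.

## Membrane fluctuation model

The basal membrane is modelled as a nearly flat elastic sheet in a viscous
environment, confined near the substrate.  A height mode of wavevector q
has energy density

    E(q) = kappa q^4 + sigma q^2 + gamma,

with bending rigidity kappa (fixed at 15 k_B T throughout, both here and in
the tether analysis), membrane tension sigma (N/m) and a harmonic
confinement gamma (N/m^3) representing the substrate and cortex.  Each mode
relaxes as an overdamped Ornstein-Uhlenbeck process with rate

    omega_q = (kappa q^3 + sigma q + gamma / q) / (4 eta_eff),

where eta_eff is an effective viscosity of the surrounding cytoplasm, and
has stationary variance A k_B T / (L^2 E(q)) on a periodic domain of side
L.  The dimensionless active temperature A >= 1 absorbs non-thermal force
contributions into an enhanced effective temperature.

Summing the modes' Lorentzian spectra over the continuum of q gives the
single-point temporal power spectral density

    PSD(f) = (2s) (4 eta_eff A k_B T / pi)
             Int_{q_min}^{q_max} dq / [(4 eta_eff 2 pi f)^2
                                       + (kappa q^3 + sigma q + gamma/q)^2],

with s = 1 for the one-sided density used throughout this package (our
estimators satisfy the one-sided Parseval identity; the two-sided form,
s = 1/2, is available via a flag).  `model_psd` evaluates the integral by
Gauss-Legendre quadrature in ln q with adaptive node doubling to a relative
tolerance of 1e-6; a 1e6-point trapezoid agrees to better than 1e-8.

### Simulator

`simulate_membrane_patch` inverts this model: the Fourier modes of an
N x N periodic grid are integrated with the exact OU update (exponential
decay plus an exact-variance Gaussian increment), so stationary statistics
are exact at any frame interval.  Hermitian symmetry is enforced by a
symmetrised construction that makes the pixel variance exactly the plain
sum of mode variances.  Defaults (chosen once, from the feasibility
analysis below): 96 modes per axis on a 6.93 um domain (72.2 nm pixels, so
a 12 x 12-pixel analysis window covers 0.75 um^2), sigma = 5e-7 N/m,
gamma = 2e6 N/m^3, eta_eff = 0.1 Pa s, A = 1, T = 300 K, 2048 frames at
20 Hz, mean height 51 nm (the middle of the first interference branch).

Why gamma = 2e6: tension is spectrally identifiable only when a band of
modes is tension-dominated, which requires gamma < sigma^2/kappa ~ 4e6;
but weak confinement lets the membrane roughen as SD ~ sqrt(k_B T /
2 pi sigma) ~ 35 nm, sending excursions across several interference
branches where IRM height conversion is impossible.  gamma = 2e6 N/m^3 is
the compromise: height SD ~31 nm, ~10% of samples leave the first branch
(handled by the folded-observation model below), and the
confinement-tension-curvature crossovers all fall inside the measured
frequency band.  eta_eff and gamma defaults are numerical-exercise values,
not biological claims; both are freely configurable.

## IRM height reconstruction

IRM intensity encodes height as I(h) = offset - amplitude cos(4 pi n h /
lambda) with lambda = 546 nm and aqueous n = 1.335 (configurable), darkest
at contact and monotone over the first branch h in [0, lambda/4n = 102.2
nm].  The scale (offset, amplitude) is calibrated by nonlinear least
squares on the radial intensity profile of a large bead of known radius
resting on the coverslip, with the phase fixed by the dark-contact
convention.  Conversion inverts the cosine (arccos); intensities beyond the
branch by more than a 1% clamp tolerance are flagged missing rather than
extrapolated.  First-branch regions (FBRs) are non-overlapping square
windows (default 12 px = 0.75 um^2) whose pixels keep a temporal-mean
normalised intensity within +-0.9, never leave [-1, 1] beyond the clamp
tolerance, and spend < 5% of frames within 2% of an intensity extremum —
the last criterion catches membranes that repeatedly touch a branch edge,
where folded excursions masquerade as valid intensities.

An optional temporal branch-continuation (phase-unwrapping) converter is
provided; at the default simulation parameters frame-to-frame phase steps
(~0.5-1 rad) are too large for reliable tracking, and it is off by default.

## Fluctuation statistics

SD_time is the per-pixel population SD of height over the movie's frames
(FBR value: mean over member pixels); SD_space is the SD across an FBR's
pixels of the height averaged over the first 20 frames (the frame range is
configurable; which 20 frames to use is otherwise an arbitrary choice).
Excess area sums per-pixel surface elements sqrt(1 + h_x^2 + h_y^2) with
central-difference gradients (one-sided at edges) and reports
100 (A - A_P)/A.  All three are invariant under a global height offset.

## PSD estimation and model fitting

Per-pixel spectra use either the raw periodogram (exactly Parseval) or a
Blackman-Tukey estimate (Bartlett window, max lag N/4, rescaled so the
one-sided Parseval identity holds exactly on the discrete grid); per-FBR
spectra are pixel averages.  For fitting, spectra are reduced to 40
log-spaced bins over the fit band (default 0.1 Hz to 0.8 x Nyquist,
excluding the three lowest bins against drift), and residuals on
log10(power) are weighted by the inverse of each bin's empirically
estimated standard error ("evar" weights).  This matters: pixel averaging
buys a large effective number of degrees of freedom at mid and high
frequencies, and uniform weighting wastes it.  R^2 is the weighted
coefficient of determination on log10(power).

Three forward-model refinements remove biases that are each larger than
the target accuracy of the tension estimate:

1. Sampling kernel.  The estimator sees the process sampled at fs, so each
   mode's continuous Lorentzian is replaced by its exact discrete-time
   (AR(1)) spectrum.  Without this, power aliased across the Nyquist
   frequency inflates the upper band by up to ~2x.
2. Discrete-mode kernel (synthetic domains).  For data simulated on a
   finite periodic grid the continuum q-integral misrepresents the handful
   of slowest modes; an option sums the AR(1) kernel over the actual mode
   grid (binned by |q|).  With it, fitting the noiseless expectation
   spectrum recovers all parameters to 0.1%.
3. Folded-observation model.  When heights wander beyond the first
   interference branch, the conversion folds them back (an even-periodic
   map).  For a Gaussian field the autocovariance of the folded
   observation follows exactly from Mehler's expansion,
   ACF_obs = sum_m c_m^2 rho^m with Hermite coefficients c_m of the fold
   map; the model transforms its ACF accordingly and applies the Bartlett
   taper matching the periodogram expectation.  This is what makes tension
   recovery through the rendering chain possible at sigma = 5e-7 N/m.

Identifiability.  With kappa fixed, jointly rescaling (A, eta_eff, sigma,
gamma) changes the model curve over an experimentally accessible band by
less than typical periodogram scatter (measured: < 1e-4 rms in log10 after
re-optimising the other parameters), so a free 4-parameter fit determines
tension only up to that scaling.  The default therefore fixes eta_eff at a
configured value (0.1 Pa s) and fits (A, sigma, gamma) — i.e. reported
fluctuation-tension is conditional on the assumed viscosity; relative
comparisons between conditions, the biological use, are unaffected.  The
full 4-parameter fit remains available (`fit_eta=True`).  An optional free
constant floor absorbs camera noise (whose height-equivalent level is
amplified near branch edges by the arccos inversion) and residual
broadband distortion.  Optimisation uses `scipy.optimize.least_squares`
from a fixed log-spaced multi-start grid (3 starts per free axis), lowest
cost winning, ties broken by the smaller tension.

Even so, a single 12 x 12-pixel FBR of one 102-s movie carries roughly a
factor-2 uncertainty in sigma (a Whittle-information estimate at the
default parameters gives ~1.9 sigma separation between tensions a factor 2
apart).  Recovery tests therefore pool the averaged PSD of a 36 x 36-pixel
block — nine FBR-sized windows of the same homogeneous patch — which is the
synthetic analogue of the per-FBR pixel averaging applied to real movies.

Measured calibration of the tension estimator at the default study
conditions (pooled 36 x 36 block, 2048 frames at 20 Hz): on unfolded
heights the median fitted tension over 20 independent records is 0.99x the
generator's value with interquartile range (0.73, 1.29).  Through the full
interferometric chain the picture degrades qualitatively: after the fold,
the profiled chi^2 separates sigma = 0 from sigma = truth by only ~1.5, the
(sigma, gamma) likelihood ridge is flat for decades below the truth and
bends sharply around twice it, and the per-record estimate consequently
piles up near that bend (1.2-1.9x) or collapses toward zero — a structural
~+25% median bias that is a property of the measurement, not of the
optimiser.  Single-record absolute tensions reconstructed through the
first-branch fold at such low tension should therefore be treated as
upper-bound-flavoured estimates; comparisons across conditions, which share
the fold, remain meaningful.  An optional ridge-marginalising
profile-posterior estimator is provided but is only useful when the data
exclude sigma ~ 0 decisively.

## Activity (entropy-production) bound

Pixel series of an FBR are reduced by PCA (components sign-fixed against
the mean height for reproducibility); the first two component series form
the state for a short-time thermodynamic-uncertainty estimator: over
linear Stratonovich currents J_w = sum w_ij x_i o dx_j, the entropy
production rate is bounded by max_w 2 <J_w>^2 / (Dt Var J_w), available in
closed form as a generalised Rayleigh quotient.  A delay embedding of one
component is NOT a valid state: for any reversible series the delayed pair
circulates deterministically (E[x_t o dx_{t-lag}] = (r(0) - r(2 lag))/2),
producing a spurious positive bound that does not shrink with record
length; the two-component state is the default for exactly this reason.
The raw quadratic statistic carries a positive sampling bias inflated by
the currents' serial correlation; a moving-block bootstrap (200 resamples,
64-frame blocks) supplies both the bias correction and a basic (reflected)
confidence interval, so equilibrium input yields estimates scattered about
zero with a CI that covers zero.  The two-temperature coupled-bead fixture
(exact Gaussian integration; entropy rate from the Lyapunov-equation
stationary covariance as tr(D^-1 Lam C Lam^T), Lam = A + D C^-1) provides
the analytic oracle: at its defaults the estimator returns 50-70% of the
true rate and never exceeds it.

## Tether mechanics

Trap stiffness comes from equipartition, k = k_B T / Var(x), on a no-load
segment (default: the first 10 s); the tether force is k times the mean
parked-window displacement; and the apparent membrane tension follows the
Canham-Helfrich tether relation sigma_A = F^2 / (8 pi^2 kappa) with kappa
= 15 k_B T.  Because sigma_A is quadratic in F, fractional reductions map
as r_sigma = 1 - (1 - r_F)^2 (2% force -> ~4% tension, 52% -> ~77%).
Temperature defaults to 300 K wherever unrecorded.

## Fluorescence quantification

Puncta detection: Gaussian blur (sigma 5 px) -> subtract the blur from the
original (negatives clipped) -> min-max normalise -> threshold (default
0.25 of the normalised range; Otsu optional) -> ROI mask -> single-pixel
removal by cross-erosion-seeded morphological reconstruction (a plain
opening would clip object corners and break exact-area accounting) ->
8-connected labelling.  Area fraction divides summed object area by ROI
area; colocalization intersects binary masks (area fraction of overlap,
and percent of each channel's object area); Mander's M1/M2 weight by
intensity.  Nearest-neighbour distances between channel centroids are
summarised per distance cutoff (defaults 525/165/150 nm).

Tubules are counted as line-scan intensity peaks with prominence >= 6 raw
camera units and width at half prominence >= 5 samples (the width unit is
ambiguous in the source convention; samples is our documented choice);
intensity density subtracts a 5th-percentile baseline.

## De-adhesion phases

Spread-area series are labelled C before treatment; P1 until the area
falls below 90% of the pre-treatment baseline; P2 while the area decays,
having reached at least 67%; and P3 once the area is rate-stable (relative
slope < 2%/min over a 2-min window — the stability rule is ours and
configurable) inside the 20-40%-of-baseline band.  The de-adhesion time
t67 is the linearly interpolated first crossing of 67% of baseline.
Normalisation divides each cell's P2/P3 measurement by its C value.

## Statistics

Pairwise Mann-Whitney U tests use a Bonferroni-adjusted alpha
(0.05/comparisons, reported floored to 3 decimals: 0.016 for 3); an ANOVA
route sits behind a Shapiro normality gate.  The linear mixed model for
FBR-level quantities uses log tension as response, phase (categorical) or
time (continuous) as fixed effect, and random intercepts for replicate set
and for cell nested within set (cells belong to one set), fit by REML via
statsmodels.  Fixed effects are tested against a t distribution with
cell-level degrees of freedom rather than the Wald normal, which is
anti-conservative with a handful of cells.  This guards against
pseudo-replication: in null simulations with strong cell-level intercepts
the pooled rank test over FBRs is spuriously significant in most runs
while the mixed model keeps its nominal size.

## What the synthetic tests do and do not show

The generators produce Gaussian, stationary, homogeneous fields with
exactly the fitted model's spectra, geometric fluorophore shapes, and
noiseless or Gaussian-noise cameras.  Passing tests therefore demonstrate
the estimators' correctness and calibration under the model's own
assumptions — unbiased tension recovery through the full optical chain,
valid entropy-bound coverage, exact geometric accounting.  They do not
establish robustness to real-data pathologies: non-Gaussian heights near
adhesions, spatial heterogeneity inside an FBR, photobleaching, uneven
illumination, drift, or segmentation ambiguity.  Biological effect sizes
(which treatments change tension by how much) are outside the scope of
synthetic validation.

## Problem sizes

Default test and validation sizes were chosen to make each check
statistically decisive at desk scale: 2048-frame movies (the standard
record length), 96-mode domains, 10-seed recovery batches, 2e5-sample trap
traces, 5e4-sample bead trajectories, and 100-run mixed-model size
simulations.
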