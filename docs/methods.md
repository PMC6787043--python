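# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of the `ramanmargin` pipeline, in the order data flows through
it.

## Instrument model

Two portable spectrometer profiles are hard-coded from their operating
characteristics: a 1064 nm system (512-pixel InGaAs detector, 428 effective
channels over 247–2500 cm⁻¹, 5.07 cm⁻¹ resolution) and a 785 nm system
(2048-pixel CCD, 1804 channels over 175–3201 cm⁻¹, 1.78 cm⁻¹ resolution).
The working axis is the uniform grid over each range; the quoted resolution
is carried as metadata (it is the vendor's inter-pixel figure at
1600 cm⁻¹, close to but not identical with the grid spacing).  Only the
785 nm system reaches the high-wavenumber C–H stretch region, which is why
its area-normalization region (400–3200 cm⁻¹) differs from the 1064 nm
one (400–1800 cm⁻¹).

## Synthetic spectrum generator

The generator is the package's study population: all statistical claims in
the test suite are claims about pipelines run on it.

**Signal model.**  intensity = baseline + Σᵢ aᵢ·G(x; cᵢ, wᵢ) + noise
(+ spikes, + ink peaks), with Gaussian peaks.  Peak shape is a modeling
choice — Gaussians have closed-form areas, which gives every quadrature
test an analytic oracle; Voigt profiles would change nothing the pipeline
measures.  Default widths are 2× the instrument resolution, so the
1064 nm system produces visibly blended clusters (1442/1453,
1627–1746) while the 785 nm system resolves them.

**Class structure.**  Each band carries a healthy and a tumor amplitude
(counts/s).  Tumor elevates nucleic-acid/protein bands (742, 941,
1002/1006, 1331, 1448/1453, 1663, 2933 cm⁻¹) and depresses lipid bands
(1062/1063, 1082, 1302/1303, 1439/1442, 1653/1657, 1746, 2850,
2893 cm⁻¹); the signs reproduce the published tumor-minus-healthy
difference-spectrum direction, which a generator invariant test pins.
Mixed-histology sites are a convex amplitude mixture with default tumor
fraction 0.5.  No per-band effect sizes are published; the default
magnitudes (roughly 20–40% class differences) were calibrated once so that
the full pipeline lands in the reported accuracy regime (≥88% LOO
accuracy) and reproduces the reported variance concentration (>98% in
3 PCs); they are configuration, not measured fact.

**Between-spectrum variability** has three layers:

* two shared lognormal *pool factors* (lipid pool, protein/nucleic pool,
  cv 0.22) multiplying all bands of a pool coherently — emulating
  site-to-site adiposity/cellularity variation, the dominant biological
  variance in breast tissue and the reason a few principal components
  carry almost all feature variance;
* independent per-band lognormal jitter (cv 0.015);
* iid Gaussian channel noise (sd 0.3 cps).

The pool-factor layer is deliberate structure beyond a plain independent
per-band model: without it the feature covariance is near-isotropic and no
low-dimensional factor structure exists to find.

**Background.**  baseline(x) = flat + A·exp(−(x−x₀)/τ), with the constant
chosen so the level at 400 cm⁻¹ equals the published 39.9 cps (1064 nm)
or 83.7 cps (785 nm); A = 35/90 cps and τ = 250 cm⁻¹ give a background
that is nearly flat through the fingerprint region and rises increasingly
below 400 cm⁻¹, about twice as strong for 785 nm excitation.

**Artifacts.**  Cosmic-ray spikes: Poisson count (default rate 0.1 per
spectrum), uniform channel, multiplying the local intensity by
uniform(5, 15).  Surgical ink: with configurable probability (default 0 —
ink appears only in specific experiments), Gaussian peaks at 693, 1260,
1348, 1398, 1541, 1597 cm⁻¹.

**Determinism.**  Every output is a pure function of (inputs, seed);
cohort and transit members draw per-spectrum seeds from a SeedSequence of
the config seed, and the random stream is consumed identically for every
label so that zero effect size yields bitwise-identical classes.

**What the generator does not model** — and hence what passing tests do
not establish about patient data: detector quantum-efficiency curves and
shot/read-noise physics, tissue optics (penetration depth, scattering),
wavenumber-calibration drift, patient-level clustering of sites (all
spectra are exchangeable given their class), non-Gaussian lineshapes, and
any dark-current level (the vendor software's ambient-noise subtraction is
taken as already applied).

## Despiking

A channel is a spike when |intensity − running median(window 7)| exceeds
*both* 10 robust standard deviations (1.4826·MAD of the residuals; if the
MAD is exactly zero — noise-free data — the 99.5th-percentile residual is
used so the guard stays meaningful) *and* 0.5× the local median level.
The two-part rule encodes the physical separation: a cosmic-ray hit rivals
or dwarfs the entire local signal (a 10×-local spike deviates by 9× the
local level), while a genuine Raman peak top deviates from the running
median by a modest fraction of its band amplitude — many noise sd's, but
far below the local level.  A z-threshold alone cannot be set to pass
sharp real peaks and still catch spikes at the coarse 1064 nm resolution.
Flagged channels are replaced by the local median; counts are logged.
Despiking precedes baseline estimation because spikes corrupt quantile
anchors.

## Fluorescence baseline

Iterative shifted-window spline, with anchors placed on the curve:

1. Overlapping windows (width 200 cm⁻¹, step 100 cm⁻¹) cover the axis;
   within each, the lowest 10% of samples are taken and the anchor is
   their *median position paired with their median value*.  Anchoring at
   the sample location rather than the window center is essential: on a
   sloped or curved background, the low-quantile values come from one side
   of the window, and pinning them to the center biases the whole estimate
   downhill.
2. Short edge windows fit a least-squares line through their near-baseline
   points and evaluate it at the exact end channel — otherwise the spline
   extrapolates across the steep low-wavenumber rise and misses it.
3. A natural cubic spline interpolates the anchors (linear continuation
   outside the anchor range).
4. Refinement: anchors are re-estimated from the points at or below the
   current spline + 1 robust sd, and the spline refit with a decaying
   relaxation step (the raw anchor map flips borderline channels and
   oscillates; averaging the trajectory converges).  Iteration stops when
   the max change per iteration falls below 10⁻³ of the baseline range
   (20 iterations cap, warning on non-convergence).  A tolerance much
   below 10⁻³ is below the order-statistic granularity of the anchors and
   only produces spurious warnings.
5. The result is clipped to the 9-channel running maximum of the data, so
   the baseline never exceeds the spectrum's upper envelope.

With the default generator this recovers the true background within 5% of
its range everywhere more than 3σ from a band center, and preserves
isolated band areas within 5%.

## Normalization

Trapezoidal integral on the native uniform grid; the corrected spectrum is
divided by its integral over the instrument's region, making the unit-area
property exact to machine precision.  Negative post-subtraction values are
clipped to zero first so the integral is positive.  Processing stages
(raw → despiked → baseline_corrected → normalized) are enforced
monotonically; re-running a stage raises.

## Class envelopes and band selection

Envelopes are channelwise mean ± t₍ₙ₋₁,0.975₎·s/√n (level configurable;
the t-interval is used rather than a 1σ band, with the multiplier exposed
through `level`).  The separation gap is
max(healthy.lo − tumor.hi, tumor.lo − healthy.hi, 0); runs of positive gap
wider than `min_width` (default 2× the channel spacing, i.e. ≥3 channels)
become regions, runs closer than `merge_gap` (same default) merge, and
regions are scored by integrated gap area, reported at their gap-area
centroid, sorted by score with lower wavenumber breaking ties.

Two calibration facts shape the defaults and are pinned by tests: at zero
effect size the selector returns ≤1 spurious region on average (the
channelwise t-intervals are conservative for region-level claims), and a
single strong differing band is recovered as exactly one region.  Note an
intrinsic feature of normalized spectra: because spectra are scaled to
unit area, a genuine increase in one band induces a small compensating
decrease everywhere else ("compositional echo").  With enough samples the
CI criterion will correctly flag that echo as a real class difference at
the strongest other bands; the null-calibration property therefore holds
at zero effect, not in the presence of a large planted effect.

## Reference bands and ink exclusion

The shipped sets use the published 12 (1064 nm) and 17 (785 nm) band
centers.  Half-widths: 10.14 cm⁻¹ (2× resolution) at 1064 nm; 8 cm⁻¹ at
785 nm — wide enough to cover the band-assignment ranges (e.g. 1325–1333
for the DNA band) and to register overlap between the B_1331 window and
the 1348 cm⁻¹ ink line.  Ink exclusion intersects closed intervals
(window ± half-width vs line ± tolerance, default 10 cm⁻¹); a shared
endpoint counts.  Applied to the 785 nm set this drops exactly one window
(B_1331), leaving 16 active bands — 13 fingerprint + 3 high-wavenumber —
with B_1302 retained; the operation is idempotent and logs what it
dropped.  The printed band tables contain no window at 1260 cm⁻¹, so the
contaminated window here is the 1348-line overlap, the only geometrically
possible one.

## PCA-LDA

Band features are windowed *mean* intensities (robust at coarse
resolution and proportional to area on a uniform grid; peak height and
fitted areas were rejected as noisier or out of scope).  PCA is an
eigendecomposition of the covariance of the mean-centered feature table —
with a `scale` flag for the correlation matrix instead, since
autoscaling is a defensible alternative reading of "analysis of the
correlations" — eigenvalues descending, loadings unit-norm with each
column's largest-magnitude entry positive.  Rank deficiency (n ≤ p) and
constant columns warn and yield trailing zero eigenvalues.

LDA uses Gaussian class models with the pooled within-class covariance
(n−2 denominator), empirical priors by default, and a 0/1 misclassification
cost matrix; prediction minimizes expected cost, which with 0/1 costs is
the maximum-posterior rule.  Posteriors come from Cholesky-whitened
log-likelihoods; exact ties break to the first class in fixed order
(healthy).  A singular pooled covariance is ridge-stabilized with
10⁻⁸·trace/dim and logged.

Leave-one-out cross-validation refits PCA inside every fold by default
(fixing PCA on the full table is methodologically leaky; the flag
`refit_pca_per_fold=False` exposes the leaky variant for comparison).
Mixed-label rows never enter training or the two-class metrics.  Metrics
are integer percents, rounded half away from zero — the only rounding rule
consistent with all nine published percentages — with tumor as the
positive class.  Note a known property of LOO under the null: with no
class signal, removing a sample shifts its own class mean away from it, so
null LOO accuracy is biased *below* 50% (measured ≈45–46% at n=40 here);
calibration checks must use a per-experiment binomial band, not a
pooled-trials band.

## Transit analysis

Sites are classified independently, in order; no smoothing or HMM is
applied across the sequence (each site must stand on its own
intraoperatively, and the published workflow classifies sites
independently).  A boundary is declared between consecutive sites whose
thresholded (default 0.5) posteriors disagree.  Mixed ground-truth sites
count as correct under either call for boundary scoring: mixed tissue is
descriptive, never a trained class, and surfaces only through its
continuous posterior.

## Problem sizes

The test suite and acceptance script use the cohort sizes the analysis is
specified at (28/29 and 10/40 sites, 10-site transits) and seed counts of
20–200 per stochastic property; these complete in a few minutes on one
CPU.  Scaling the generator up (more sites, more seeds) changes no
default.

## Known limitations

* All accuracy/calibration statements are properties of the synthetic
  population; no deposited patient spectra exist to replay.
* The baseline estimator assumes the background is smooth at the
  200 cm⁻¹ window scale; narrow fluorescence features would be absorbed
  into the signal.
* The CI band selector tests channels marginally; coherent latent
  variability (the pool factors) makes its per-region false-positive rate
  somewhat anti-conservative in small samples, which the null-calibration
  test quantifies rather than eliminates.
* Wavenumber calibration is taken as given; no Teflon-standard alignment
  is modeled.
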