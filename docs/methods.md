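# Methods

This note documents the models, estimators and numerical choices behind
`synmux`, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the analysis left genuine freedom.

## FLIM [Ca²⁺] readout

### Decay model

The indicator's excited-state decay is modelled phenomenologically as a
two-lifetime mixture: a fast Ca-free component (`tau_free`, default 0.4 ns)
and a slow Ca-bound component (`tau_bound`, default 2.0 ns), with the bound
photon fraction given by single-site binding, `f = ca / (ca + Kd)` with
`Kd = 560 nM` (the indicator's low-affinity regime is what makes the lifetime
sensitive at tens of nanomolar). Photon arrival delays are exponential in the
component lifetime, shifted so the decay peaks ~1.3 ns after pulse onset,
jittered by a Gaussian instrument response (σ = 0.15 ns), and wrapped within
the 12.5 ns laser period (80 MHz). The component lifetimes are free generator
parameters — they are not literature values — and the calibration step makes
the [Ca²⁺] readout self-consistent for any choice with `tau_free ≠ tau_bound`.

### NTC estimator

`compute_ntc` finds the histogram peak on a 3-bin moving-mean smoothed copy
(raw argmax is noise-sensitive at low counts; ties resolve to the earliest
bin), then integrates the raw counts over a 3 ns post-peak window and divides
by the raw peak count. The integral uses Simpson quadrature over the binned
samples (with a linearly interpolated fractional end bin); a rectangle-rule
sum cannot reach the sub-ppm accuracy on smooth decays that the quadrature
does at realistic TCSPC bin widths, while both are identical on flat
histograms. Whether one normalises the curve first and then integrates, or
integrates and divides by the peak, is numerically the same ratio.

One practical constraint worth stating: NTC has units of time but its value
depends on the TCSPC binning through the peak-count normalisation, so
calibration and readout must share the same binning (256 bins per laser
period throughout this package), exactly as a calibration is only valid for
the acquisition system it was measured on.

### Calibration

The NTC–[Ca²⁺] relation is fitted with a 4-parameter logistic in
log₁₀[Ca²⁺] (floor, span, EC50, Hill slope), initialised from the data range
and fitted by bounded least squares. Monotonicity is enforced structurally
(positive Hill slope, span > 0), and point sets whose rank correlation is not
clearly positive are rejected rather than silently fitted. Requires ≥ 5
distinct concentrations. The inversion is closed-form; NTC values at or
outside the asymptotes return NaN (flagged, never extrapolated). The
`valid_range` reports the central 5–95 % of the sigmoid span. Zero-concentration
calibration points are pinned one decade below the smallest positive point on
the log axis so they still anchor the floor.

`flim_readout` pools photons over a global-time window — and across trials,
mirroring cross-trial summation used to reach reliable counts — before a
single NTC inversion. The default minimum of 10⁴ pooled photons per estimate
is a conservative quantification of "sufficiently high"; per-pixel maps return
NaN below it, scalar readouts raise.

## Quantal analysis

Amplitudes are extracted per AP as the ΔF/F at the evoked peak minus the mean
of an 8 ms pre-AP baseline. The peak sample is located on the across-trial
average trace within the response window and every trial is read at that
sample: taking each trial's own maximum would bias failure amplitudes upward
(max of noise) and censor their negative half, destroying the zero-centred
failure distribution the noise fit relies on.

The failure-noise dispersion σ₀ is fitted as a zero-centred Gaussian with one
free parameter, by maximum likelihood on the amplitudes within ±2.5 initial
dispersions of zero (truncation-corrected). The initial dispersion comes from
the negative half-sample, which successes cannot contaminate. A binned
least-squares Gaussian fit was tried first and abandoned: with a few dozen
failures it occasionally diverges to a wide, flat solution.

The histogram model is a sum of Gaussians with component 0 pinned at
(0, σ₀) and components k ≥ 1 initialised at spacing q₀ (from local maxima of
a kernel-smoothed histogram), their centres and dispersions bounded within
±15 % of initial values, fitted by Levenberg–Marquardt on the binned counts.
Bin width follows Freedman–Diaconis clamped to [σ₀/2, 2σ₀] so each component
always spans several bins. The component count is chosen by BIC computed on
the *sample* mixture log-likelihood (area-proportional weights), not on the
binned residuals: a residual-based criterion is nearly blind to a rare
highest-quantal peak that carries only a few percent of the mass, while the
sample likelihood penalises leaving those amplitudes stranded 5σ from any
component. Quantal content is assigned by maximum posterior; Pr is the
fraction of first-AP amplitudes above 2σ₀ (the printed per-bouton cut-offs in
this kind of experiment, ~0.12 ΔF/F, correspond to ≈2–2.5 σ₀; the cut-off is
overridable).

Recovery behaviour: at q/σ ≥ 5 with ~300 amplitudes the median error of q is
~2 % and the 0–3-quanta component count is selected in ≈95 % of runs; below
q/σ ≈ 3 adjacent components merge and q degrades gracefully toward multiples.

## Bouton geometry

Boutons are rotational ellipsoids: major semi-axis `a` along the axon,
rotation radius `b` (`a ≥ b`), defaults 1.18 µm and 0.89 µm with aspect ratio
1.35 when drawn as populations. Profile fitting uses image moments for masks
and algebraic least squares for outlines; near-circular fits (a/b within 2 %)
are flagged and given orientation 0.

Geodesic corrections: `geodesic_circle` is the closed-form `b·arcsin(x/b)`;
`geodesic_ellipse` evaluates the apex-to-point elliptical arc by adaptive
quadrature (relative tolerance 1e-8 by default; closed-form incomplete
elliptic integrals would add no accuracy at this scale). The worst-case
relative difference between elliptical and circular corrections at a/b = 1.5
over the half-radius range is ≈2.5 %.

`geodesic_correct_map` applies the per-axis arcsin stretch (each image axis
governed by its own semi-axis) and resamples bilinearly onto a regular
geodesic grid at the source pixel pitch; pixels mapping outside the
elliptical profile are masked. This stretched plane is faithful along the
principal axes but its Euclidean metric underestimates oblique surface
distances by up to ~10 %; the spatial-decay fit therefore computes its radial
distances differently (below).

The thin-shell projection factor at projected offset (x, y) is the column
length through the shell, `b²·sqrt(x²/a⁴ + (y²+z²)/b⁴)/z` with
`z = b·sqrt(1 − (x/a)² − (y/b)²)`, normalised to 1 at the centre; it diverges
at the silhouette, so a rim band (default 5 % of the radius) is masked.
Ratiometric ΔF/F maps are unaffected by this bias by construction — the
factor cancels between response and baseline — which the tests assert; the
correction matters for raw intensity maps. The validation oracle is a
Monte-Carlo projection of a uniformly labelled 40 nm shell, which the
correction flattens to within 5 %.

## Bouton-scan simulator

The membrane glutamate signal spreads from the release site with an
exponential geodesic decay (default constant 0.55 µm). Surface geodesics are
computed by Dijkstra on a 180×90 parametric mesh with 1- and 2-ring
knight-move edges (metric error ≲0.5 %). Surface patches are projected to the
focal plane weighted by area (which reproduces shell-projection edge
brightening automatically), attenuated by a Gaussian two-photon
axial-sectioning profile — FWHM 1.0 µm, the middle of the realistic axial-PSF
range of 0.8–1.5 µm, centred by default on the release-site depth, where an
experimenter optimising the evoked signal would focus — blurred by the
lateral PSF (default FWHM 0.3 µm, constrained to the two-photon range
0.2–0.4 µm), and Poisson-sampled per pixel and time sample. Omitting axial
sectioning entirely would mix near- and far-membrane signal almost equally
and cap the achievable signal drop across the profile at ~6-fold, which is
unrealistically shallow for this kind of recording. The Ca²⁺ channel is a
blurred cytosolic column-depth signal plus a Gaussian entry hotspot
(σ = 0.2 µm) riding on a diffuse volume-equilibrated transient.

Per-trial release is binomial (`n_sites`, `pv`); each AP's transient decays
with a 15 ms sensor off-rate; trials are independent. Default photon budgets
(4000 glutamate and 1500 Ca²⁺ photons per 2 ms sample over the image) give
the per-pixel signal-to-noise at which 20-trial averages localise hotspots to
a few tens of nanometres.

What the generators do **not** emulate: photobleaching, focal drift and
scattering (the lifetime readout's insensitivity to them is the method's
selling point, so they are out of scope), z-axis localisation, vesicle-fusion
kinetics, sensor saturation, and bouton-to-bouton crosstalk. Passing recovery
tests on these simulations therefore shows the estimators are correct and
well-calibrated under the stated noise model — not that real tissue holds no
further surprises (indicator nonlinearity, motion, heterogeneous expression).

## Hotspot localisation and the spatial decay fit

Response heat maps average the per-pixel signal between 2 ms before and 10 ms
after each AP-evoked peak of the pooled average trace (troughs excluded),
with the per-pixel baseline from the 300 ms prepulse; maps with no detectable
evoked peak raise. Localisation mean-filters over ~100 nm (odd pixel
footprint) and takes the intensity-weighted centroid of the top-5 %
brightness set; if that set splits into two connected components separated by
more than one PSF FWHM (and the minor component carries >20 % of the major
mass), the profile is classed bimodal and both centroids are returned.

The spatial decay constant is fitted as a single exponential
`A·exp(−r/σ)` on the radial profile about the located peak, normalised to its
maximum, over r ∈ [0.3, 1.3] µm in 26 bins. Three numerical safeguards keep
the recovery unbiased at the few-percent level:

1. **Distances.** Per-pixel distances use the exact planar-section arc from
   the apex: for a displacement at angle φ with silhouette radius s(φ), the
   arc of the ellipse with semi-axes (s(φ), b). This is exact for a central
   hotspot on a sphere and correct to well under a percent for the ellipsoid
   aspect ratios involved, whereas distances measured as Euclidean norms in
   the per-axis-stretched plane are biased low off-axis.
2. **Rim exclusion.** Pixels beyond 85 % of the local silhouette radius are
   excluded: there the geodesic stretch amplifies the lateral PSF blur
   without bound.
3. **Blur compensation.** A Gaussian blur of width σ_psf multiplies an
   exponential tail by `exp(σ_eff²/2σ²)` with σ_eff = σ_psf × (local stretch
   factor); this known first-order flattening is divided out and the fit
   iterated twice. The fit also starts beyond the diffraction-dominated core
   (r_min = one PSF FWHM).

With these, 23 simulated boutons drawn from the measured geometry
distribution recover a 0.547 µm truth with ≈1 % bias, within two standard
errors of the bouton-to-bouton mean. Fitting the uncorrected projected map
underestimates the constant, as expected from distance compression.

Ca²⁺ hotspot detection estimates the background median and SD from the
smoothed masked map excluding the brightest decile and requires a contiguous
region above background + 2 SD of at least 1.5 PSF half-max footprints
(≈0.11 µm²): a genuine diffraction-limited hotspot always exceeds this,
while correlated-noise clusters at the 2 SD level stay below the nominal 5 %
false-positive rate. Entry maps are analysed uncorrected, since Ca²⁺ entry
need not lie on the imaged surface.

The distance null draws independent uniform point pairs in a disc
(mean distance `(128/45π)·R`). The default null radius of 0.52 µm is a
back-calculation from the scale of reported null distances, not a printed
value, and is exposed as a parameter. The comparison uses Welch's t-test by
default: the two samples are small-vs-large (≈10 vs 80) and pooled-variance
assumptions would be unsafe.

## Trial statistics

Simple OLS with the slope t-test (two-sided, α = 0.05) and Pearson r; the
paired-pulse ratio is the ratio of mean amplitudes (means over trials,
failures included — per-trial ratios are undefined on failures); the
short-term-plasticity slope is OLS of first-AP-normalised mean amplitudes
against AP number 1–4, its sign classifying facilitation vs depression. Rows
are pooled across boutons where a figure-level statistic is computed, with n
reported. The stability check regresses photon count, resting [Ca²⁺] and
evoked Δ[Ca²⁺] on trial number; on a dye-equilibration ramp (photon rate
×2.5 over 20 trials, true Ca²⁺ constant) the photon slope is significant in
every run and each FLIM readout stays non-significant in ≥90 % of runs, the
signature that the readout is concentration-independent.

## Pipeline and reproducibility

`RunConfig` nests per-stage settings whose defaults equal the module
defaults; it round-trips losslessly through JSON/YAML and its SHA1 hash
stamps every output table. A single run seed deterministically spawns all
stage seeds (`numpy.random.SeedSequence`), so identical configurations yield
byte-identical reports. Stage failures halt with the stage name and offending
input in the exception. Default study sizes (12 quantal and 8 imaged boutons)
keep an end-to-end run under a minute on one core; the full study-scale setting
(26 quantal boutons, 20–22 trials; 23 imaged boutons) completes in a few
minutes and is exercised by the test suite.

## Known limitations

* The two-lifetime decay model is phenomenological; real indicator
  photophysics (multi-exponential decays, temperature and wavelength
  dependence) is not modelled, and NTC calibrations are binning-specific.
* Geodesic corrections assume a centred, axis-aligned rotational ellipsoid
  and arcs measured from the apex; strongly off-centre hotspots inherit the
  method's approximation error.
* The spatial-decay blur compensation is first-order; residual bias changes
  sign with PSF width (≈+1 % at 0.3 µm FWHM, ≈−2 % at 0.2 µm).
* σ₀ estimation needs a detectable failure population; high-Pr boutons
  (success rate ≳95 % at realistic trial counts) are reported as
  unanalysable rather than guessed.
* The release-probability estimator carries a small positive bias
  (~+1 % absolute at the 2σ₀ cut-off) from failure-tail false positives.
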