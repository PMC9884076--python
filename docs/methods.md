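# Methods

## Scope and model

`switchkin` treats a dSTORM acquisition as a collection of immobile,
independent two-state emitters. Each molecule at position (x, y) sees a
local excitation intensity I(x, y) and an expected spot brightness
R = c·I(x, y) in photons per frame (c, `brightness_coeff`, converts
kW cm⁻² to photons/frame). Switching is a continuous-time alternating
renewal process with exponential dwells:

* off→on (recovery):  k_on = k_on⁰ + β·R   [s⁻¹]
* on→off (dark-state formation):  k_off = R / (N_τon · Δt)   [s⁻¹]

where Δt is the frame time. The k_off law encodes a fixed photon budget:
the expected photons emitted per on-event equal
R · E[dwell]/Δt = N_τon regardless of intensity. The k_on law separates
thermal recovery (intercept k_on⁰, the inverse thermal off-state lifetime
τ_off⁰) from photoinduced recovery (slope β). Both laws are linear in
brightness, which is what the per-ROI rate fits assume and recover.

All molecules start in the off state; there is no diffusion, no drift
and (by default) no photobleaching — switching is fully reversible. An
optional bleach rate and optional Gaussian localization error exist but
default to zero.

## Illumination

`mems_gradient` models a micromirror-generated profile as an isotropic
Gaussian centred in the square FOV, parameterized by `edge_fraction`
(default 0.2): the intensity at the field corner is that fraction of the
peak. The instrument's true profile is not parameterized anywhere we can
copy, so this is a deliberate idealization with the right qualitative
structure (smooth, radially monotone, interior maximum); `flat` is a
constant field for flat-field acquisitions. Default peak intensities:
0.48 kW cm⁻² (gradient, single-molecule) and 0.72 kW cm⁻² (flat, cell
imaging).

## Frame discretization and noise

An on-event contributes to each overlapped camera frame in proportion to
its temporal overlap; expected counts from events sharing a (molecule,
frame) pair are summed before noise. Photon counts are drawn from a
gamma–Poisson mixture with variance = F × mean, F = 2 by default, which
mimics EMCCD excess noise and is consistent with the √2 inflation of the
localization precision. Setting F = 1 gives pure Poisson counts.

## Defaults of the synthetic benchmark

30,000 frames at 20 Hz (tests and the acceptance benchmark use 3,000
frames to keep runtimes in seconds; the geometry is unchanged), a
(62.5 µm)² FOV, molecule density 5 µm⁻² (Poisson count, uniform
positions), background b² = 49 photons. The default kinetic truth —
N_τon = 6,000 photons, τ_off⁰ = 300 s, β = 2×10⁻⁵ s⁻¹ per photon/frame,
c = 1,667 photons/frame per kW cm⁻² — sits mid-range of the
experimentally characterized behaviour of AF647 (photon budgets of a few
thousand to ~10⁴, thermal off lifetimes of a few hundred seconds) and
yields centre-of-field τ_on ≈ 0.37 s and τ_off ≈ 52 s.

What the generator does *not* emulate: PSF rendering and localization
(tables are produced directly, with optional positional jitter),
multi-emitter overlap, drift, bleaching-limited budgets, and any
saturation of k_on at high intensity or thiolate. Passing tests
demonstrate internal consistency of estimator and model, not agreement
with any particular dye's measured values.

## Dwell-time estimation

Detected frames per molecule are converted to maximal on-runs
(`extract_dwells`), optionally bridging gaps up to `max_gap_frames`
missed detections. Runs touching the first or last frame are flagged
censored.

* **τ_on** is the mean of uncensored run lengths minus one frame, times
  Δt: an event of continuous duration d touches on average d/Δt + 1
  frames, so the raw mean overestimates by exactly one frame time. At
  the default settings censoring of on-events is negligible and censored
  runs are simply excluded.
* **τ_off** uses the right-censored exponential MLE — total off exposure
  divided by the number of completed off dwells — because off lifetimes
  are comparable to the acquisition window and a complete-dwells-only
  mean would be biased low several-fold (conditioning on completion).
  Exposure accounting: interior gaps of g frames contribute (g+1)Δt as
  complete draws; the leading dark interval (molecules start off, so its
  length is itself an exponential draw) contributes (g+0.5)Δt complete;
  the trailing interval contributes (g+0.5)Δt censored; molecules never
  detected contribute the whole window as censored exposure. The ±0.5
  frame terms are the expected phase of the bounding on-events. SE is
  τ/√n_completed.
* `estimate_tau` also offers an `expfit` method (least-squares fit of a
  single exponential to the dwell histogram, mapped to the mean of the
  frame-quantized dwell so that both methods estimate the same quantity);
  it is a cross-check, not the default.

ROIs with fewer than `min_events` (default 10) dwells are flagged
invalid rather than raising.

## Spot brightness N_Det

N_Det is the median over on-events of the event's mean photons per
*interior* frame. Two choices matter here: (i) the first and last frame
of an event overlap the dwell only partially and would bias brightness
low; (ii) weighting per event (not per frame) matches the event-weighted
pooling of the dwell means, so each ROI's (N_Det, k) point falls on the
underlying rate line even though intensity varies within an ROI.
Frame-weighted medians produced a measurable (~1 %) tilt of the fitted
line in validation runs; the event-weighted estimator removed it. If no
event in an ROI has interior frames (very short dwells), the per-frame
median over all detected frames is used as a fallback.

## Rate-law fits

Per-ROI rates k_off = 1/τ_on and k_on = 1/τ_off (with delta-method SEs)
are fit against N_Det by weighted least squares (weights 1/SE², plain
OLS when SEs are absent), via statsmodels. The photon budget is
N_τon = 1/(slope_off · Δt) with the delta-method SE; the on-fit intercept
gives k_on⁰ and τ_off⁰ = 1/k_on⁰ (flagged undefined if the intercept is
non-positive), and the slope gives β. Outliers are masked iteratively
(internally studentized residual > 3, at most 2 rounds, never below 3
remaining points, always reported in the result); numerically exact fits
skip masking. Degenerate designs (constant brightness, < 3 points) raise.

Whether the original analysis weighted its fits is not documented;
both modes are exposed and weighted-when-SEs-exist is the default.

## Resolution calculus

Photon-limited: Δx² = (σ_a²/N)(16/9 + 8π σ_a² b²/(N a²)) with
σ_a² = σ² + a²/12 (the pixelation term is a²/12 on dimensional grounds),
precision √(2Δx²) for EMCCD excess noise, FWHM factor 2.355. Defaults:
σ = 140 nm, a = 120 nm, b² = 49 photons. Two photon scenarios are
exposed: N = N_τon (entire budget in one localization) and
N = N_τon/2 (`split_budget`, emission uncorrelated with frame clocking;
the divisor is configurable).

Nyquist-limited: R = 2/√n for 2D label density n; the tolerable density
is n = (spots per DLR) × (τ_off/τ_on) / (DLR area), with the
conservative default DLR = 1 µm² and 1 spot per DLR (a high-density
variant uses 5). `spots_per_fwhm_dlr` gives the alternative FWHM-disk
DLR reading (340 nm → ~11 µm⁻²).

Gain curves: reciprocal resolutions normalized to their own maxima over
the thiolate range; the photon gain is fit with a single exponential and
the Nyquist gain with a double exponential (falling back to a monotone
PCHIP spline with a warning if the fit fails, e.g. with only four
points). The combined gain is the renormalized product of the two fitted
curves; band edges at a level (defaults 0.707 ≈ 1/√2 and 0.90) are found
by bisection on each side of the peak, with one-sided results flagged
when a level is not attained. The product-of-normalized-curves definition
makes the 70.7 % level the natural half-power crossing.

## Buffer rating and acidification

The report rates a buffer purely by its thiolate concentration: "+"
inside [1.5, 15.6] mM, "○" inside [0.85, 30.15] mM but outside the inner
band, "–" otherwise. The bands are the 90 % and 70.7 % combined-gain
bandwidths of the characterized system; the "○"/"–" boundary is an
explicit convention of this package.

`simulate_acidification_series` models gluconic-acid drift of an
unsealed glucose-oxidase chamber as a linear pH decline (floored at a
configurable minimum), converts pH to thiolate and interpolates
(τ_on, τ_off) from a user-supplied calibration keyed by thiolate. It
reproduces the qualitative time course (τ_on grows, τ_off shrinks) and
the worked percent-change arithmetic; it does not model the underlying
enzyme kinetics.

## Numerical and reproducibility notes

* One integer seed fixes every stochastic stage; identical config + seed
  gives byte-identical localization tables and report bundles.
* Benchmark problem sizes: the recovery benchmark uses 49 ROIs, 3,000
  frames, ~19,500 molecules per run; CI coverage uses 100 such runs.
* Molecules are assigned to ROIs by their mean position; ROI binning is
  half-open with the top/right edge inclusive.
* Trace linking clusters localizations by position (molecules are
  immobile) with a 250 nm default radius and resolves ambiguity to the
  nearest trace; the true linking rules of upstream experimental
  workflows are not reproduced, and defaults are declared, not inferred.

## Known limitations

* The censored-MLE off-lifetime estimator assumes exponential off dwells
  and known molecule positions for never-detected emitters; from a bare
  localization table (no ground truth) the never-on exposure is
  unobservable and τ_off⁰ recovering depends on the window being not too
  short relative to τ_off.
* Within-ROI intensity variation makes each ROI point an aggregate;
  residual aggregation bias of the fitted parameters is at the percent
  level at the default geometry.
* The gain-curve functional forms (single/double exponential) are
  empirical fits, and band edges computed from them inherit that
  choice.
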