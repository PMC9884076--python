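# switchkin

Thiolate-driven photoswitching kinetics and resolution analysis for
single-molecule localization microscopy (SMLM/dSTORM) buffers.

Carbocyanine photoswitches such as Alexa Fluor 647 blink between a
fluorescent on-state and a thiol-adduct dark state. How well they perform
in SMLM depends on the switching buffer: the deprotonated thiolate (RS⁻)
of the reducing agent (MEA/cysteamine, BME, ...) drives dark-state
formation, so the thiolate concentration — set by total thiol, pH and the
thiol pKa through the Henderson–Hasselbalch relation

    [RS⁻]/[RS]₀ = 1 / (1 + 10^(pKa − pH))

— controls the photon budget per on-event (N_τon), the on/off lifetimes
(τ_on, τ_off) and, through them, the achievable image resolution.
`switchkin` implements that whole chain as a tested, reproducible
pipeline:

* **chemistry** — thiolate speciation arithmetic and buffer design
  (what thiol concentration at what pH gives a target [RS⁻]).
* **simulate** — a ground-truth-labelled blinking simulator: molecules on
  a (62.5 µm)² field under a centre-peaked (MEMS-style) or flat
  illumination profile, exponential on/off dwells with
  k_off = R/(N_τon·Δt) and k_on = k_on⁰ + β·R for local expected
  brightness R (photons/frame), EMCCD excess-noise photon counts, and
  localization-table output (`frame,x_nm,y_nm,photons`).
* **kinetics** — per-ROI (7×7 grid) estimation of τ_on, τ_off, median
  spot brightness N_Det, τ_off/τ_on and duty cycle from dwell intervals,
  with censoring-aware lifetime estimators.
* **ratefit** — the linear rate laws across ROIs: k_off vs N_Det gives
  the photon budget N_τon = 1/(slope·Δt); k_on vs N_Det gives the thermal
  recovery rate k_on⁰ (intercept, hence τ_off⁰ = 1/k_on⁰) and the
  intensity response β (slope).
* **resolution** — photon-limited localization resolution
  (Δx² = (σ_a²/N)(16/9 + 8πσ_a²b²/(Na²)), σ_a² = σ² + a²/12, ×√2 for
  EMCCD excess noise, ×2.355 for FWHM), Nyquist-limited structural
  resolution R = 2/√n with label density capped by τ_off/τ_on per
  diffraction-limited region, and the combined-gain *concentration
  bandpass*: thiolate acts as a low-pass filter on brightness and a
  long-pass filter on density, so their normalized product peaks at an
  optimal [RS⁻].
* **pipeline / CLI** — `switchkin simulate|kinetics|ratefit|resolution|
  buffer|run`, one seed end to end.

## Worked example

Buffer design from the shell:

```
$ switchkin buffer --thiol-mM 50 --ph 7.4 --fmt json
{"label": "50 mM thiol pH 7.4", "fraction_pct": 10.025778336392822,
 "thiolate_mM": 5.012889168196411, "rating": "+"}
```

At pH 7.4 with the MEA thiol pKa of 8.353, 10.0 % of the thiol is
deprotonated, so 50 mM MEA provides ~5.0 mM thiolate — inside the
1.5–15.6 mM band rated "+" (very good) for cyanine photoswitching.

Parameter recovery from a simulated gradient acquisition (49 ROIs,
3,000 frames at 20 Hz, ~19,500 molecules, truth N_τon = 6,000 photons and
τ_off⁰ = 300 s):

```python
>>> from switchkin.pipeline import recover_rate_parameters
>>> r = recover_rate_parameters(seed=1)
>>> round(r["N_tau_on"]), round(r["tau_off0_s"])
(5925, 274)
```

The off-switching fit recovers the photon budget within ~1 % and the
thermal off-state lifetime within ~9 % for this seed; both are inside
the pipeline's 15 % recovery tolerance at this acquisition length.

A full report bundle (localization CSVs, per-ROI kinetics TSVs, fit
JSONs, per-thiolate summary with +/○/– ratings, resolution profile and
bandpass edges):

```
switchkin run --scale tiny --seed 2 --out out/
```

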