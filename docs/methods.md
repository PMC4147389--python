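# Methods

## The model

`bbbkinetics` implements the multiple-time graphical (Patlak) analysis of
unidirectional solute influx across the blood–brain barrier. For a tracer
that moves from plasma into tissue without appreciable back-flux during the
observation window, the tissue/serum ratio is linear in *exposure time*:

    A(t) / Cp(t) = Ki · Θ(t) + Vi,        Θ(t) = ∫₀ᵗ Cp(T) dT / Cp(t)

where `Cp` is the arterial serum concentration (cpm/µl), `A` the tracer
amount per gram of extravascular tissue (cpm/g), `Ki` the unidirectional
influx rate (µl/g·min), and `Vi` the rapidly equilibrating ("functional")
distribution volume (µl/g) — vascular space plus any compartment that
exchanges quickly with plasma. The method's assumptions: influx is
unidirectional over the fitted window (efflux negligible), `Cp > 0`
throughout, and the tissue measurement reflects extravascular tracer (the
vascular contribution is absorbed into `Vi`).

Plotting the ratio against `Θ` "stretches" time so that a decaying input
function still yields a straight line; OLS on the windowed points gives `Ki`
as the slope and `Vi` as the intercept. Carrier-mediated (saturable)
transport bends this plot downward at late exposure times; restricting the
regression to the early linear phase keeps the slope an estimate of the
initial influx rate, and a reduced slope under co-injection of excess
unlabeled compound is the classic diagnostic of a shared transporter.

Units are fixed package-wide: time min, serum cpm/µl, tissue cpm/g, ratios
and `Vi` µl/g, `Ki` µl/g·min.

## Numerical choices

* **Integration.** `∫Cp dT` uses the composite trapezoid over the sampled
  serum points. The unsampled interval `[0, t₁]` is closed by linear
  back-extrapolation of the first two samples to `t = 0`, clamped from below
  at the first observed value (conservative for a decaying bolus curve); an
  option holds the first value constant instead. For constant `Cp` this
  makes `Θ(t) = t` exact. Against a closed-form biexponential integral the
  trapezoid error falls with step halving while discretisation dominates; at
  very dense sampling the signed error crosses zero (interior overshoot
  cancels the back-extrapolation undershoot), so convergence is asserted in
  the coarse regime.
* **Regression.** Unweighted OLS with explicit normal equations so that the
  saturated case `n = 2` reports `se = 0`, `R² = 1`, and a zero-residual fit
  reports `R² = 1` even when the ordinate is constant. Degenerate designs
  (all exposure times equal) and under-determined windows raise typed
  errors. Refitting a fit's stored `(exposure_times, ratios)` reproduces it
  exactly.
* **Linear-phase detection.** The largest prefix (in exposure-time order)
  whose fit has `R² ≥ 0.95`, capped at 20 min of exposure by default —
  the window over which uptake is near-linear in this preparation. The
  threshold is configurable; if no prefix of ≥ 3 points passes, the minimal
  2-point window is returned with a warning flag rather than an error.
* **Slope comparison.** Welch t on the two fitted slopes with
  Welch–Satterthwaite degrees of freedom (component df = n − 2). Two
  zero-se fits compare to `p = 1` when equal and `t = ±∞, p = 0` (flagged)
  when not.
* **Ties and degenerate inputs.** Duplicate sample times are rejected at
  validation; serum must be strictly positive at every sampled time.

## The synthetic-data generator

The generator emulates a rat bolus study — ~250,000 cpm injected i.v.,
arterial sampling at 5/20/30/45/60 min (the cold-competitor arm supports the
denser 1-min schedule used in that protocol), terminal regional dissection,
and an acid-precipitation stability assay — with known ground truth for
every estimator.

* **Serum.** Biexponential decay, defaults `a₁ = 15, a₂ = 16` cpm/µl
  (`Cp(0) = 31` ≈ 250,000 cpm distributed in ~8 ml rat plasma),
  `λ₁ = 0.12, λ₂ = 0.0055` min⁻¹, leaving ~37% of the initial concentration
  at 60 min. The shape is a stated invention: the study conditions fix the
  dose and schedule but not the input function.
* **Transport.** Linear mode generates tissue as `Ki·∫Cp + Vi·Cp` with the
  *same* trapezoid convention as the estimator, so the zero-noise round trip
  recovers `(Ki, Vi)` to machine precision. Saturable mode uses competitive
  Michaelis–Menten influx `Vmax·Cp/(Km + Cp + C_cold)` — the simplest
  mechanism consistent with reduced uptake under cold co-injection.
  Defaults are anchored in the excess-competitor regime (`Cp ≪ Km`): the
  cold dose is mapped to `C_cold = 8000` serum-concentration units, and per
  tissue `Km = C_cold/(r − 1)` with `r` the uninhibited/inhibited rate ratio
  (brain 0.218/0.084, liver 9.7/4.4), `Vmax = Ki·Km`. Kidney is linear at
  17.4 µl/g·min, matching its observed insensitivity to the competitor.
  Brain `Vi` defaults to 15 µl/g (invented, of vascular-plus-fast-space
  magnitude).
* **Noise.** Multiplicative lognormal with exact unit mean, default CV 0.10
  (gamma counting and biological dispersion have roughly constant CV; counts
  are positive). Crucially, the generator is *coherent*: a subject's
  realised serum samples are drawn first and the tissue uptake is integrated
  over that realised curve, because the animal's tissue is exposed to its
  own input function and the arterial samples estimate that same function.
  The tissue measurement then carries its own independent noise. Driving
  uptake from the population-mean curve instead, while recording a different
  noisy serum, makes subjects internally inconsistent and introduces a
  shared-denominator errors-in-variables bias in the fitted slope (≈ +4%
  when `Vi/Ki` is large at CV 0.10) with no physical counterpart.
* **Regional tissue.** Terminal activity = true ratio × terminal serum ×
  mass × noise, one shared noisy terminal serum draw per subject. Default
  true ratios are the study's tabulated regional values (13 CNS regions,
  substantia nigra 60.7 µl/g the highest); masses are plausible dissection
  weights (not reported in the source study), so the whole-CNS aggregate is
  reproducible only as a mass-weighted mean of the configured profile.
* **Degradation.** First-order loss of acid-precipitable label per
  compartment on top of the spiked-control fractions (serum 0.78, brain
  0.67). The serum rate solves `e^(−60r) = 0.92` (~0.00139 min⁻¹), anchoring
  percent-of-control to ~92% at 60 min; the brain rate is set smaller
  (0.0005 min⁻¹, invented) to reproduce the qualitative ordering that the
  label is more stable in brain. A first-order model cannot produce the
  >100% percent-of-control values seen in real assays at early times
  (matrix effects on precipitation efficiency); the analysis side therefore
  accepts and passes through values above 100% without clamping.
* **Determinism.** All randomness flows through a single seed; arms and
  assays draw from spawned sub-streams, and the same seed reproduces output
  files byte-for-byte.

### What the generator does not emulate

Smooth within-subject serum dynamics (noise is drawn independently per
sample), radioactive decay of the label (measurements assumed
decay-corrected), plasma protein binding, efflux, vascular-space error after
perfusion, and any whole-body PBPK structure. Passing recovery tests
therefore shows that the estimators are consistent and well-calibrated for
data generated by this idealised measurement chain — not that the biological
conclusions of any in-vivo study are reproduced.

## Statistical analysis choices

* Regional heterogeneity is tested with one-way ANOVA across regions
  (subjects as replicates); per-region contrasts against the whole-CNS
  aggregate use two-sided pooled-variance t tests, unadjusted by default
  (a Bonferroni option exists but is off, since the source analysis reports
  no multiplicity correction).
* The whole-CNS aggregate sums activities and masses — the mass-weighted
  mean of regional ratios — and is invariant to how regions are partitioned.
* Inhibition is summarised as `100·(1 − rate_cold/rate_labeled)` from arm
  means with a Welch t test across subjects; values ≤ 0 indicate no
  inhibition (e.g. kidney).
* Two-arm slope comparisons default to pooling subjects into one regression
  per arm (whether the original analysis pooled animals or fitted
  per-animal is unstated; both are supported).

## Problem sizes in the recovery suite

Recovery runs use 200 simulated subjects for whole-organ influx rates, 100
replicates for the early-phase window analysis (1-min sampling over 1–30
min, CV 0.05), 500 replicates for regional ratios, and 100 six-subject
replicates for the ANOVA and arm-separation rejection rates — sizes at which
the Monte-Carlo error of each reported mean is well under the tolerance it
is checked against. The early-phase simulation uses `Vi = 5` µl/g: a
variance analysis of the prefix-R² selection shows that with the larger
whole-brain default the intercept would dominate the early window's dynamic
range at CV 0.05, degrading window detection for reasons unrelated to the
kinetics under test; a small fast-equilibrating space is the appropriate
regime for an early-window design.

## Known limitations

* OLS on ratio coordinates inherits mild attenuation from noisy exposure
  times; at the default CV this is below 1% of the slope but it grows with
  serum noise.
* The linear-phase detector assumes the nonlinearity is a late-exposure
  bend; it will not isolate an early-time anomaly.
* `percent_of_control` treats the spiked control as exact; uncertainty in
  the control fraction is not propagated.
* The saturable mode treats the competitor concentration as constant over
  the observation window (no competitor pharmacokinetics).
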