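# bbbkinetics

Multiple-time regression (Patlak graphical) analysis of blood–brain-barrier
tracer influx, together with a fully parameterised synthetic
tracer-kinetics generator for validating the estimators end to end.

## Who this is for

Pharmacokinetics work on BBB permeability often rests on the intravenous
injection / multiple-time-point design: a radiolabelled solute is injected
as a bolus, arterial serum is sampled over an hour, and terminal tissue
measurements are expressed as tissue/serum ratios. This package provides
the analysis half of that design — exposure-time transform, influx-rate
regression, linear-phase selection, saturable-transport comparison,
degradation correction, and regional statistics — plus a simulation half
that generates complete experiments with known ground truth, so every
estimate can be checked as a parameter-recovery round trip.

## The model

For unidirectional influx from plasma into tissue, the tissue/serum ratio is
linear in exposure time:

```
A(t) / Cp(t) = Ki · Θ(t) + Vi        Θ(t) = ∫₀ᵗ Cp(T) dT / Cp(t)
```

* `Ki` — unidirectional influx rate (µl/g·min): solute flux across the
  barrier divided by plasma concentration. The slope of the Patlak plot.
* `Vi` — functional distribution volume (µl/g): vascular plus
  fast-exchanging space. The ordinate intercept.
* `Θ(t)` — exposure time (min): integrated serum concentration normalised by
  the instantaneous level, computed by composite trapezoid with linear
  back-extrapolation over `[0, first sample]`.

Saturable (carrier-mediated) transport shows up as a downward bend of the
plot at late exposure times and as a reduced `Ki` when excess unlabelled
compound competes for the carrier — modelled in the generator as competitive
Michaelis–Menten influx `Vmax·Cp/(Km + Cp + C_cold)`.

## Worked example

Simulate the default two-arm study (6 subjects per arm, brain/liver/kidney,
10% measurement CV) and compare the brain influx rate with and without the
cold competitor:

```python
import numpy as np
from bbbkinetics import (
    ExperimentConfig, simulate_experiment, fit_series, patlak_transform,
    patlak_fit, compare_ki, inhibition_analysis,
)

cfg = ExperimentConfig(n_subjects=6, noise_cv=0.10, rng_seed=7)
exp = simulate_experiment(config=cfg)

def pooled_fit(arm):
    xs, ys = [], []
    for subj in exp.arms[arm].subjects:
        x, y = patlak_transform(subj["brain"])
        xs.append(x); ys.append(y)
    return patlak_fit(np.concatenate(xs), np.concatenate(ys))

hot, cold = pooled_fit("labeled_only"), pooled_fit("with_cold")
print(f"labeled-only brain: Ki = {hot.ki:.3f} +/- {hot.ki_se:.3f} ul/g/min, "
      f"Vi = {hot.vi:.1f} ul/g (R2 = {hot.r_squared:.3f}, n = {hot.n_points})")
print(f"with cold BM:       Ki = {cold.ki:.3f} +/- {cold.ki_se:.3f} ul/g/min, "
      f"Vi = {cold.vi:.1f} ul/g")
cmp_ = compare_ki(hot, cold)
print(f"slope difference: {cmp_.estimate:.3f} (t = {cmp_.t_stat:.2f}, p = {cmp_.p_value:.2g})")

per_subject = lambda arm: [fit_series(s["brain"]).ki for s in exp.arms[arm].subjects]
inh = inhibition_analysis(per_subject("labeled_only"), per_subject("with_cold"))
print(f"percent inhibition: {inh.percent_inhibition:.0f}% (Welch p = {inh.p_value:.2g})")
```

Output:

```
labeled-only brain: Ki = 0.208 +/- 0.017 ul/g/min, Vi = 14.9 ul/g (R2 = 0.844, n = 30)
with cold BM:       Ki = 0.095 +/- 0.010 ul/g/min, Vi = 13.6 ul/g
slope difference: 0.113 (t = 5.77, p = 6.6e-07)
percent inhibition: 54% (Welch p = 7.1e-05)
```

The labelled-only pooled fit recovers the generative uninhibited influx rate
(0.218 µl/g·min) within its standard error; the cold arm's slope drops to
near the generative inhibited rate (0.084 µl/g·min), the slope difference is
highly significant, and the per-subject inhibition estimate is ~54% — the
signature of a saturable transporter. `exp.manifest` records every
generative parameter and the seed.

There is also a CLI for file-based workflows:

```
bbbkinetics simulate --out run/ --seed 7
bbbkinetics fit --serum run/labeled_only_subject01_brain.csv \
                --cold-serum run/with_cold_subject01_brain.csv
bbbkinetics report --results run/
```

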