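# capdyn

Quantification of cortical actin-cap dynamics in the syncytial embryo.

During the rapid nuclear cycles that precede cellularization, an apical
filamentous-actin "cap" assembles above each cortical nucleus, expands
roughly sixfold in area within two minutes, stabilizes, elongates as the
centrosomes separate, and finally fragments. `capdyn` implements the
measurements used to characterize this life cycle from live fluorescence
imaging, together with a synthetic-data generator that provides analytic
ground truth for every estimator:

- **Cap morphometrics** — selection of the measurement plane 0.9 µm below the
  apical surface, background subtraction, deterministic cap segmentation,
  per-cap area / mean intensity / intensity-SD / shape measurement, and
  frame-to-frame track linking.
- **Dynamics** — alignment of traces to elongation onset (initiation is taken
  180 s earlier), normalization of area and heterogeneity (intensity SD) to
  their initiation values, 30 s rolling-window expansion rates, four-phase
  classification (expansion → stabilization → elongation → fragmentation),
  exponential growth fits `Y = a·exp(k·X)` over the first 60 s of expansion,
  and per-phase fold changes.
- **FRAP kinetics** — reference-cap normalization

  `Y = ((bleached − background)·bleached area) / ((reference − background)·reference area)`

  followed by a two-phase association fit with `Y₀` fixed at the first
  postbleach point:

  `Y = Y₀ + SpanFast·(1 − e^(−K_fast X)) + SpanSlow·(1 − e^(−K_slow X))`

  with `SpanFast = (Plateau − Y₀)·(%fast/100)`, and the derived readouts
  `t₅₀ = ln 2 / K_fast`,
  `PlateauFast = 2·SpanFast·(1 − e^(−K_fast t₅₀)) + Y₀`, and
  `immobile fraction = (Y₋₁ − PlateauFast)/(Y₋₁ − Y₀)`,
  where `Y₋₁` is the normalized intensity 1 s before the bleach.
- **Colocalization** — object-based mito-tag scoring (puncta gated strictly
  above 8 µm², colocalized when ≥ 10 pixels are shared), recruitment-ability
  ratios, and Costes-threshold Pearson correlation with block randomization
  (PSF = 3 px, 10 randomizations).
- **Statistics** — Shapiro-Wilk normality, Student's *t* (Welch optional)
  with the significance bands `*: p<0.05, **: p<0.005, ***: p<0.0005`, and
  the nuclear-fallout vs. expansion-rate linear correlation (Pearson P, R²).

## Worked example

Simulate a FRAP experiment in the wild-type cap regime (fast half-time 8.2 s,
~19 % immobile fraction, 1 s sampling over 60 s, 2 % proportional noise),
normalize it, and refit:

```python
from capdyn import (FrapSimParams, simulate_frap_experiment, normalize_frap,
                    fit_two_phase, derive_metrics)

trace, truth = simulate_frap_experiment(FrapSimParams(noise_sd=0.02, seed=1))
norm = normalize_frap(trace)
fit = fit_two_phase(norm.x, norm.y)
metrics = derive_metrics(fit, norm.y_minus1)
print(f"Y0 = {fit.y0:.3f}, plateau = {fit.plateau:.3f}, %fast = {fit.pct_fast:.1f}")
print(f"t50 = {metrics.t50_s:.2f} s   (truth {truth.t50_s:.2f} s)")
print(f"immobile fraction = {metrics.immobile_fraction:.3f}   (truth {truth.immobile_fraction:.3f})")
```

prints

```
Y0 = 0.201, plateau = 0.932, %fast = 88.0
t50 = 8.17 s   (truth 8.20 s)
immobile fraction = 0.195   (truth 0.190)
```

`t50` is the half-time of the fast recovery component (turnover of the
surrounding G-actin pool); the immobile fraction is the share of prebleach
signal that the fast phase never recovers. Both land on the simulated truth
well within the estimator's documented tolerance.

The same workflow is available from a shell:

```bash
capdyn simulate movie --out out/ --seed 1      # synthetic cap movie + truth
capdyn segment --stack out/movie.tif --out out/seg
capdyn frap --trace my_trace.csv --out out/frap
capdyn coloc --gfp a.tif --mch b.tif --out out/coloc
capdyn report --out out/report --seed 1        # full synthetic pipeline
```

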