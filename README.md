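# craniodyn

Analysis pipeline for quantifying **post-craniotomy recovery** of neuronal
function and microglial/neuronal morphology in mesoscale fluorescence
imaging of mouse cortex.

Opening the skull for a chronic imaging window triggers a neuroimmune
response: microglia activate and hyper-ramify over the first days,
neuronal structural fluorescence rises with a delay, and visually evoked
population activity is transiently disrupted before recovering over
roughly eight weeks. `craniodyn` implements the quantitative machinery for
following that recovery longitudinally:

* **Stimulus-responsive neuron detection** — a neuron is responsive to a
  grating orientation when its mean ΔF/F over the 2-s stimulus windows
  exceeds the pre-stimulus baseline mean plus 3 baseline standard
  deviations.
* **Population decoding** — orientation decoding accuracy
  `Acc = N_correct / N_total` from a linear SVM under stratified 4-fold
  cross-validation, plus an LDA embedding of trial responses.
* **Functional networks** — pairwise Pearson connectivity
  `r(x, y) = Σ(xᵢ − x̄)(yᵢ − ȳ) / √(Σ(xᵢ − x̄)² Σ(yᵢ − ȳ)²)` between
  neurons or region-averaged traces; mean connectivity; the
  strong-connection ratio (fraction of pairs with r > 0.8); spectral
  partitioning into k = 3 clusters; Newman modularity with resolution γ,
  `Q = (1/2m) Σᵢⱼ [Aᵢⱼ − γ kᵢkⱼ/2m] δ(cᵢ, cⱼ)`; and weighted degree
  centrality `Σᵤ k(v, u)`.
* **2-D morphology** — Sholl intersection profiles (2-µm concentric
  steps) with max-intersection and area-under-curve metrics, mean
  fluorescence intensity, positive-area fraction and cell density.
* **Longitudinal statistics** — day-1 baseline normalization, linear
  interpolation to daily resolution over days 1–56, sliding-window lag
  correlation between modalities (window widths 7–35 days), and
  normality-gated timepoint comparisons (repeated-measures ANOVA + Tukey,
  or Friedman + Dunn with Bonferroni correction).

Because raw mesoscale recordings of this kind run to terabytes and are
not redistributable, the package ships a first-class **synthetic-data
generator** that emulates the study design — layer-2/3 neurons on a
parcellated cortical sheet (19 regions), 4 grating orientations × 3 sets
× 8 repeats (96 trials) at 20 Hz, community-structured correlated
activity, per-animal morphology time series with a controllable
cross-modal lag, and star-shaped cell images with analytically known
Sholl profiles — so every stage is testable against ground truth.

## Worked example

```python
from craniodyn.synth import disruption_scenario
from craniodyn.pipeline import run_recovery_analysis

scenario = disruption_scenario(trough_day=21, seed=0)
report = run_recovery_analysis(scenario)
print(report.per_day[["day", "n_responsive", "decoding_accuracy",
                      "modularity_day1_partition"]].round(3))
```

```
 day  n_responsive  decoding_accuracy  modularity_day1_partition
   1            45                1.0                      0.542
   4            55                1.0                      0.550
   7            62                1.0                      0.484
  10            61                1.0                      0.347
  14             0                1.0                      0.127
  21             0                1.0                      0.020
  28             0                1.0                      0.123
  56            49                1.0                      0.568
```

The scenario injects a global (between-community) coupling that peaks at
day 21; the pipeline recovers this as a modularity trough at day 21
(0.020) with recovery toward day 56, and as a collapse of detected
responsive neurons during peak disruption. The cross-modal lag analysis
recovers the designed 4-day delay between the microglial and neuronal
intensity curves:

```python
lag, width, r, p = report.lag_results["micro_vs_neuro"].best
print(lag, r)      # -> 4  0.992
```

The same machinery applies unchanged to real data: HDF5 sessions
(`CalciumDataset.from_hdf5`), CSV day-series and TIFF images.

A command-line interface mirrors the library:

```
craniodyn synth recovery --seed 0 --out out/
craniodyn detect out/session_day01.h5
craniodyn decode out/session_day01.h5 --folds 4
craniodyn pipeline --seed 0 --out report/
```

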