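# srtpipe

Analysis pipeline for eccentricity-dependent **saccadic reaction times
(SRT)** with collicular-magnification-based stimulus scaling.

In visually guided saccade experiments, the latency between a "Go" event
and saccade onset grows with target eccentricity. One candidate cause is
foveal magnification in the superior colliculus (SC): a fixed-size target
occupies ever less map tissue — and drives its neurons ever more weakly —
the farther out it sits. This package implements the computational chain
used to study that question in behaving macaques:

- **SC mapping and stimulus scaling** (`srtpipe.sc_map`): the log-polar
  visual-field → SC tissue map
  `X = 1.1 ln(√(R² + 1.8 R cosθ + 0.81)/0.9)`,
  `Y = 1.8 atan2(R sinθ, R cosθ + 0.9)` (mm, with R in dva and θ in
  degrees), its local magnification `dX/dR = 1.1/(R + 0.9)`, and the
  construction of *Scaled* target sets whose SC image length is constant
  across eccentricity (solved by root-finding, not the linear
  approximation).
- **Contrast arithmetic** (`srtpipe.stimulus_metrics`): Weber and Michelson
  contrast and log-units-above-background for the stimulus luminances.
- **Ex-Gaussian SRT distributions** (`srtpipe.exgauss`): stable density,
  maximum-likelihood fitting, sampling, and numerical **mode** (typical
  SRT) and **FWHM** (SRT variability) — the summary statistics regressed
  downstream.
- **Saccade detection** (`srtpipe.saccades`): Engbert–Kliegl 2-D velocity
  threshold (5-sample symmetric difference, median-based spread, λ = 10),
  SRT extraction from fixation-dot offset, and the behavioural inclusion
  rules (SRT ∈ [100, 500) ms, landing within 1.0 dva, post-flash window).
- **Inference** (`srtpipe.inference`): OLS of mode/FWHM on
  `(eccentricity − 2)` with an optional `(eccentricity − 2) × isScaled`
  interaction, label-permutation p-values (N = 1000), trial-level bootstrap
  percentile CIs (N = 1000), percent-per-dva conversion, and fixed-effect
  aggregation across subjects.
- **Point-image activity model** (`srtpipe.sc_activity`): stimuli projected
  onto a 1-D SC axis and convolved with a homogeneous Gaussian connectivity
  kernel; predicts equal peak activity for Scaled stimuli and decreasing
  peaks for Equal stimuli.
- **Power analysis** (`srtpipe.power`): Monte-Carlo Mann-Whitney power for
  detecting a small SRT shift, reproducing the design requirement of >200
  trials per condition.
- **Synthetic data** (`srtpipe.synthetic_data`): seeded generators for
  trial tables and 500 Hz gaze traces with known ground truth, emulating
  the Step and Delayed tasks (with foveal-flash condition).
- **Pipeline + CLI** (`srtpipe.pipeline`, `srtpipe` command): the full
  chain simulate → detect → include → fit → regress, CSV I/O, YAML
  configuration.

## Worked example

Simulate a Step-task experiment (250 trials per condition, 7 eccentricities
× Equal/Scaled, SRT level) and run the condition-level analysis:

```python
from srtpipe import AnalysisConfig, run_full_analysis
from srtpipe.synthetic_data import ExperimentDesign

cfg = AnalysisConfig(
    tasks=("Step",),
    design=ExperimentDesign(task="Step", trials_per_condition=250),
    simulate_gaze=False,   # SRT-level generation; True exercises the detector
    n_perm=1000, n_boot=200,
    seed=42,
)
report = run_full_analysis(cfg)
print(report.regressions[report.regressions.response == "mode"])
```

With the default generative model (mode 160 ms + 5 ms/dva for Equal,
0 ms/dva for Scaled) this prints, for the SRT mode:

```
interaction  combined  beta0:  157.86  CI95 [155.29, 159.88]
interaction  combined  beta1:    5.26  CI95 [  4.68,   5.83]  p=0.0230
interaction  combined  beta2:   -4.98  CI95 [ -5.67,  -4.26]  p=0.0340
simple       Equal     beta1:    4.91  CI95 [  4.18,   5.72]  p=0.0010
simple       Scaled    beta1:    0.62  CI95 [ -0.26,   1.41]  p=0.1708
```

Reading: the Equal-target SRT mode rises by ≈4.9 ms per dva of eccentricity
(clearly nonzero by permutation test), the Scaled set is flat (0.6 ms/dva,
n.s.), and the interaction coefficient β2 ≈ −5.0 ms/dva quantifies how much
scaling flattens the slope — all three bracketing the generative truth
(+5, 0, −5). `inference.percent_per_dva(4.91, 159.75)` converts the raw
slope to 3.1 %/dva of the 2-dva value.

The same stages are available from the shell:

```sh
srtpipe scmap --slope 2.6        # map table + scaled diameters + tissue speed
srtpipe simulate --seed 1 --out sim/
srtpipe detect --trials sim/trials.csv --gaze sim/gaze.csv --out det.csv
srtpipe regress --trials det.csv --seed 1
srtpipe power --seed 1           # Mann-Whitney power curve
srtpipe run --seed 1 --out report/
```

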