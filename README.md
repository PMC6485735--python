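# vhlift

Simulation and analysis of visuo-haptic object lifting: grip/load force
trace processing, adaptive-staircase weight-perception analysis, and
sigmoid load-force modelling of how delayed visual feedback reshapes force
scaling.

The package provides five building blocks:

| module                 | what it does |
|------------------------|--------------|
| `vhlift.synthetic`     | generates lift trials (closed-form sigmoid load-force curves, coupled grip force, pre-load dip, smooth noise), minimum-jerk reaches with delay-dependent curvature/overshoot, and simulated observers for magnitude estimation and two-interval heaviness comparison |
| `vhlift.processing`    | zero-phase Butterworth filtering (15 Hz), grip/load combination, onset/lift-off detection (0.1-N thresholds, lift-off at cube weight), scalar force parameters (LFRmax, GFRmax, LPD, GFatLO), 100-ms binned areas, reach kinematics, trial screening, condition averaging |
| `vhlift.psychophysics` | rating z-scores, the two-chain interleaved one-up/one-down staircase (110–290 g, 15-g steps, 15 comparisons), weighted cumulative-Gaussian psychometric fits, and the total-bias computation with its 45% clamp |
| `vhlift.models`        | the double-integrated-sine load-force curve and its three delay transformations (shift, stretch, sum), RMSE fitting of duration (no-delay curves) and visual weight (delay curves), and model comparison |
| `vhlift.io` / `vhlift.pipeline` / `vhlift.cli` | CSV trace files, JSON manifests, YAML configuration, and the orchestrated pipeline |

## Command line

```sh
# full pipeline: simulate -> process -> psych -> modelfit -> report
vhlift run --seed 1 --outdir out/

# individual stages (each reads the previous stage's artifacts)
vhlift simulate --config my_run.yaml
vhlift process  --outdir out/
vhlift psych    --outdir out/
vhlift modelfit --outdir out/
vhlift report   --outdir out/
```

Outputs are tidy delimited tables with unit-bearing headers
(`trial_parameters.csv`, `exclusions.csv`, `binned_areas.csv`,
`kinematics.csv`, `averaged_curves.csv`, `zscores.csv`,
`psychometric_fits.csv`, `bias_summary.csv`, `model_fits.csv`,
`model_comparison.csv`) plus `report.json` and a stage log.  The whole
pipeline is a pure function of (config, seed): identical inputs give
byte-identical tables.

Configuration is a flat YAML file mirroring `vhlift.io.RunConfig`; every
default matches the apparatus constants (500-Hz sampling, g = 9.81 m/s²,
15-Hz second-order bidirectional Butterworth, 0.1-N onset thresholds).
The default design is a small two-participant run; scale
`participants_exp1`, `n_no_delay`, and `n_delay` up for full-size
experiments (40 no-delay + 10 per delay level per mass).

## Python API sketch

```python
import numpy as np
from vhlift.synthetic import LiftSimConfig, synth_lift_trial
from vhlift import processing as proc
from vhlift.models import SineLiftParams, fit_duration, fit_weight

cfg = LiftSimConfig(cube_mass=200, visual_delay=200, true_w_v=0.36,
                    noise_sd=0.02, seed=1)
rec = synth_lift_trial(cfg)
gls = proc.grip_load(proc.preprocess(rec.trace))
events = proc.detect_events(gls, cfg.cube_weight)
params = proc.force_parameters(gls, events)
```
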