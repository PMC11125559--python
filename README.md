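# delayti

Modeling pipeline for **delay transitive inference (TI)**: networks are
trained on premise pairs of a 7-item transitive hierarchy presented as two
input pulses separated by a working-memory delay, then analyzed for their
behavior (choices and response times under titrated noise) and for the
population-level dynamics and geometry that implement the task.

Everything runs on synthetic inputs — random item panels and, for the
subject-level analysis stage, synthetic subject cohorts with planted
behavioral effects. No external data is required.

## What's inside

| module | contents |
|---|---|
| `delayti.task` | transitive schema, trial-type enumeration, trial timing, input/target tensors (delay and traditional formats) |
| `delayti.synthdata` | random item panels, synthetic subject trial tables, Gaussian activity surrogates |
| `delayti.models` | continuous-time tanh RNN (Euler, dt = tau/10) with f-/r-/ff-trainable variants and five constraint regimes; LR and MLP feedforward baselines |
| `delayti.training` | BPTT + Adam in NumPy, task loss + L2 + metabolic-rate regularizers, stopping rules, generalization evaluation |
| `delayti.behavior` | saturating threshold readout (choice + RT), noise titration, behavioral simulation, symbolic-distance / end-item / end-order indices, subject-table analysis |
| `delayti.dynamics` | activity axes, least-squares linear-dynamics fits, fixed-point finding and linearization, comparison-oscillation identification, reduced oscillatory-mode simulation |
| `delayti.geometry` | collinearity family (plain/ordered/angle/distance), axis-angle tables with random baselines, end-item encoding index |
| `delayti.pipeline` | variant x regime sweeps with caching, cohort report tables |

The package is pure NumPy/SciPy/pandas — training (backpropagation through
time) is implemented directly rather than via a deep-learning framework.

## CLI

```bash
ti train --variant f-RNN --regime highest --n-instances 3 --seed 0 --out runs/train
ti behave --checkpoint runs/train/f-RNN_highest_0.npz --out runs/behave
ti dynamics --checkpoint runs/train/f-RNN_highest_0.npz --analyses linfit,oscillation,fps
ti geometry --checkpoint runs/train/f-RNN_highest_0.npz --pcs 10
ti sweep --config experiment.yaml
ti report --manifest runs/sweep/manifest.csv
```

A sweep config is a YAML file with the fields of
`delayti.pipeline.ExperimentConfig` (variants, regimes, instance counts,
seeds, analysis toggles, output directory).

## Reproducibility notes

- All generators accept integer seeds; identical seeds give bit-identical
  panels, subjects, and training runs.
- Trained-model checkpoints are NumPy `.npz` archives with exact round-trip
  of all parameter blocks plus variant/regime metadata.
- RNN training uses float32 internally for speed; analyses run in float64.
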