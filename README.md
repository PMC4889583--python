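# remapnet

A sheet-based neural network model of **presaccadic visual remapping**.

Every saccade displaces the image on the retina, yet we perceive a stable
world. A leading hypothesis is that just before each saccade, visual neurons
(e.g. in the frontal eye field, FEF) shift their sensitivity from their
receptive field (RF) to the location it will occupy after the movement — the
future field (FF) — using a corollary discharge (CD) of the motor command.
`remapnet` tests this mechanism *in silico*: a hierarchy of topographic
sheets (Retina → Hidden → FEF, with SC supplying CD and an eye-position
signal EP joining at a body-centered stage BC) is trained by
backpropagation-through-time on a single behavioral objective — **point
continuously at a visible target despite saccades**. Presaccadic remapping
is not built in; it emerges from training, can be timed against the
eye-position update, and can then be lesioned: the CD and visual pathways
are scaled down in the trained model to map remapping strength onto pathway
integrity, the model analogue of reversible inactivation experiments.

The package is for computational/systems neuroscientists who want a small,
fully inspectable model of CD-dependent updating: every sheet, weight
matrix, trial timeline, and measurement (RF/FF activity traces, remapping
onset, jump-vs-spread statistic, centroid trajectories, lesion sweeps) is a
plain Python object or tidy table.

## Model sketch

* A location `p` is encoded on a 21 × 21 sheet (±50°, 5°/unit) as a
  unit-peak Gaussian bump, `a_ij = exp(-|x_ij - p|² / 2σ²)`, σ = 3°; a sheet
  is decoded by its activity centroid.
* Hidden and FEF units are logistic:
  `h = σ(g_h (W_r x + W_s c) + g_rec W_h h_prev + b_h)`,
  `f = σ(g_f W_f h + b_f)`, all connections all-to-all, initialized
  uniformly in [−0.1, 0.1].
* The frozen BC stage convolves the FEF and EP sheets (vector addition of
  bump codes) and applies a small least-squares kernel, so the decoded BC
  coordinate is `retinal + eye`.
* Two variants: *delayed feedforward* (70 ms visual afference, 10 ms CD
  delay, 50 ms efferent delay, no recurrence) and *recurrent* (no imposed
  delays, one-step Hidden→Hidden feedback, timing learned).
* The loss is the squared mismatch between the BC sheet and the encoded
  desired-output bump at the (stationary) ball's workspace location, summed
  over all 17–19 steps of the trial; the reported behavioral measure is the
  decoded pointing error in degrees.

See `docs/methods.md` for the full model description, parameter rationale,
and known limitations.

## Worked example

Train the recurrent model on the 20-combination training set (5 retinal
target locations × 4 cardinal 20° saccades), then probe its remapping
dynamics and lesion the CD pathway:

```python
import numpy as np
from remapnet.experiments import default_recurrent_config, default_hyper
from remapnet.trials import recurrent_training_set, make_trial
from remapnet.training import train_core
from remapnet.network import run_trial
from remapnet.metrics import (extract_trace, remapping_onset, jump_statistic,
                              presaccadic_slice)
from remapnet.lesions import cd_sweep, find_factor_for_reduction

net = default_recurrent_config()            # EP updates 50 ms after the command
specs = recurrent_training_set()
model, history = train_core(net, specs,
                            default_hyper(seed=0, max_trials=4000,
                                          eval_every=0, variant="recurrent"))

# show the configuration with the clearest presaccadic remapping
traces = []
for s in specs:
    tl = make_trial(s, net.latencies, net.sheet)
    tr = extract_trace(run_trial(tl, model.weights, net), net.sheet)
    traces.append((tr.ff[presaccadic_slice(tl)].mean(), s, tr))
ffpre, spec, trace = max(traces, key=lambda x: x[0])
print("config: target", spec.target_retinal, "saccade", spec.saccade_vector)
print("FF activity:", np.round(trace.ff, 2))
print("RF activity:", np.round(trace.rf, 2))
print("onset:", round(remapping_onset(trace), 1), "ms re saccade;",
      "jump statistic:", round(jump_statistic(trace), 3))

sweep = cd_sweep(model.weights, net, specs, np.linspace(0.3, 1.0, 36))
print("CD factor for a 53% remapping loss:",
      round(find_factor_for_reduction(sweep, 0.53), 3))
```

Output from this exact run (a few minutes on one CPU):

```
config: target (0.0, -20.0) saccade (20.0, 0.0)
FF activity: [0.   0.   0.02 0.02 0.02 0.01 0.12 0.52 0.78 0.8  0.81 0.81 0.85 0.68
 1.   1.   1.   1.   1.  ]
RF activity: [1.   0.99 0.88 0.89 0.88 1.   0.9  0.7  0.67 0.62 0.59 0.54 0.   0.01
 0.   0.   0.   0.   0.  ]
onset: -50.5 ms re saccade; jump statistic: 0.005
CD factor for a 53% remapping loss: 0.419
```

Reading it: the trial's SC command starts at 50 ms (step 5), the
eye-position signal updates at 100 ms, and the saccade begins at 120 ms
(step 12). Future-field activity ramps up from steps 7–9 — after the CD
arrives and around the EP update, *before* the eye moves — while
receptive-field activity ramps down and midpoint activity stays flat (jump
statistic ≪ 0.1: activity jumps from RF to FF rather than sweeping across
the sheet). The lesion sweep then says that presaccadic remapping in this
trained model falls to 47% of its intact level when the CD weights are
scaled to ~0.42: remapping strength is a nonlinear readout of CD integrity,
so a given remapping deficit does not pin down the underlying CD loss.

The same experiments are packaged as presets mirroring the main analyses
(`fig2`, `fig3`, `fig4_5`, `fig7`, `fig8`, `fig9_11`, `fig12`):

```sh
remapnet preset fig8 --seed 0 --out results/fig8     # EP-delay entrainment
remapnet preset fig9_11 --seed 0 --out results/cd    # CD lesion mapping
remapnet report --out results/cd
```

Each preset writes tidy CSV metrics, a JSON summary, and a config snapshot.

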