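# albring

A rate-based model of how visual landmarks stabilize the head-direction
(HD) system in complex, multi-cue environments.

HD cells fire when an animal faces one allocentric direction. Their
underlying ring attractor integrates angular velocity (path integration)
and therefore drifts without sensory correction. Classic models anchor the
attractor to a single idealized cue. Real scenes are harder: they contain
several cues of differing stability and directional specificity — e.g. an
ambiguous landmark that looks identical from two opposite headings, next to
a broad unambiguous one. `albring` implements a two-stage answer:

1. **Abstract landmark-bearing (aLB) cells** learn — with a modified Oja
   Subspace Algorithm (mOSA) — a sparse code for the egocentric bearing of
   the *whole* cue array. Feature-specific visual channels (von Mises tuning
   over egocentric direction, mean-normalized per channel) project to a
   competitive layer with lateral inhibition; weights evolve as

   `W_j <- [ W_j + eta f_aLB (f_vis_j - W_j^T f_aLB)^T ]_+`

   The Oja feedback term depresses connections from absent features, so the
   code sheds unstable cues, absorbs novel ones, and recruits a distinct
   cell subset per environment (remapping, hence high storage capacity).

2. **A subcortical loop** — ring attractor -> gRSC -> dRSC -> attractor —
   associates the aLB code with the internal HD signal by Hebbian learning
   with row-norm capping and returns it as corrective 1-to-1 feedback,
   keeping the decoded direction `theta_hat = atan2(sum f sin(theta),
   sum f cos(theta))` locked to the scene despite path-integration drift.

A "direct" variant (visual channels straight to dRSC, classic Hebbian)
serves as the control: in scenes with an ambiguous salient cue it follows
the wrong rotation interpretation, which is the model's key testable
prediction.

## Worked example

```
$ python examples/environment_capacity.py
recruited set sizes per environment: [29, 30, 28, 29]
IoU similarity map (final weights):
  1.00 0.02 0.00 0.00
  0.02 1.00 0.02 0.00
  0.00 0.02 1.00 0.00
  0.00 0.00 0.00 1.00
first-exposure vs end-of-learning IoU per environment: ['0.91', '0.97', '0.97', '1.00']
```

The agent visited four environments that share two cues and differ only in
the position of a third. Each recruits its own ~30-cell aLB subset: the
similarity (Jaccard/IoU) map is 1 on the diagonal and near 0 elsewhere —
distinct feedback codes per environment — and the subsets recruited on
first exposure are still (almost entirely) recruited after all later
learning: no catastrophic forgetting.

```
$ python examples/scene_rotation_feedback.py
full model firing-field shift:   +117.5 deg (expect ~ +120)
direct model firing-field shift: -60.5 deg (expect ~ -60)
```

After the whole scenery is rotated 120 degrees anticlockwise, the full
model's HD firing fields follow the true rotation, while the direct-pathway
control is captured by the ambiguous (180-degree-symmetric) salient cue and
shifts 60 degrees the opposite way — the model's key testable prediction.

Other examples, one per capability: `attractor_path_integration.py` (bump
stability, velocity-calibrated integration, drift under gain mismatch),
`landmark_learning.py` (unimodal aLB tuning from an ambiguous scenery),
`scene_rotation_feedback.py` (full vs direct model under a 120-degree scene
rotation), `trajectories.py` (synthetic foraging statistics and file I/O).

## Library layout

- `albring.core` — rate transfer, Euler step, inhibition matrices
- `albring.world` — cues, environments, feature channels, cue dynamics
- `albring.alb` — aLB layer, mOSA and alternative learning rules
- `albring.hd_circuit` — ring attractor, velocity calibration, gRSC/dRSC,
  Hebbian updates with norm capping
- `albring.trajectory` — recorded (MAT/CSV) and synthetic trajectories,
  uniform test rotations
- `albring.analysis` — population-vector decoding, tuning maps, IoU,
  circular heading errors, unimodality, weight convergence
- `albring.experiments` — protocols, the scenario library, full/direct
  model assembly, `run_protocol`
- `albring.fixtures` — miniature worlds and regression digests

Model parameters live in `albring.config` (`default_config()`,
`direct_config()`; YAML round-trip via `save_config`/`load_config`). See
`docs/methods.md` for the model description and the rationale behind every
default.

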