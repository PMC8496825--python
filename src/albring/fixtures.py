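"""Deterministic miniature inputs for fast testing.

Every study scenario has a scaled twin that runs in seconds: neuron counts
and dwell times shrink together while time step and gains stay fixed, so the
dynamical regime (competition, plasticity, bump motion) is preserved.
"""

from __future__ import annotations

import json

import numpy as np

from .config import ModelConfig, default_config
from .trajectory import Trajectory, synth_trajectory
from .world import Cue, Environment

__all__ = ["mini_world", "mini_config", "golden_summary", "DIGEST_SCHEMA"]


def mini_world(seed: int = 0, n_vis: int = 36, duration: float = 60.0) -> tuple[Environment, Trajectory]:
    """A miniature of the standard two-cue scenery plus a short trajectory.

    36-neuron channels (10 degree resolution), bimodal narrow 'red' cues
    North/South and a broad 'blue' cue East, with a seeded synthetic
    trajectory; the full pipeline runs through it in seconds.
    """
    cues = (
        Cue("red", "bimodal", (90.0, -90.0), kappa=20.0),
        Cue("blue", "broad", (0.0,), kappa=20.0, width=90.0),
    )
    env = Environment("mini", cues, ("red", "blue", "green"), n_per_channel=n_vis)
    traj = synth_trajectory(duration, dt=0.005, seed=seed)
    return env, traj


def mini_config(n_vis: int = 36, n_alb: int = 72, **overrides) -> ModelConfig:
    """Default configuration shrunk to miniature layer sizes.

    The visual gain is scaled by 360/n_vis (channel drive sums over n_vis
    neurons) and the lateral inhibition re-derives from n_alb, so the
    competition and learning regime of the full-size model is preserved.
    """
    cfg = default_config(n_vis=n_vis, **overrides)
    cfg.alb.n = n_alb
    cfg.alb.g_lat = -0.75 * (n_alb - 1)
    cfg.alb.g_vis = 0.45 * 360.0 / n_vis
    return cfg


DIGEST_SCHEMA = {
    "type": "object",
    "required": ["name", "recruited_counts", "lobe_counts", "iou_diag_mean"],
    "properties": {
        "name": {"type": "string"},
        "recruited_counts": {"type": "array", "items": {"type": "integer"}},
        "lobe_counts": {"type": "array", "items": {"type": "integer"}},
        "iou_diag_mean": {"type": "number"},
        "iou_offdiag_mean": {"type": "number"},
        "heading_error_mean": {"type": ["number", "null"]},
    },
    "additionalProperties": False,
}


def golden_summary(result) -> dict:
    """Compact digest of a run for regression comparison.

    Contains recruited-cell counts per tested environment, tuning lobe
    counts of the recruited cells, and the mean diagonal / off-diagonal of
    the environment-similarity (IoU) map; validates against DIGEST_SCHEMA.
    """
    from .analysis import heading_error, iou, unimodality_score

    sets = result.recruited_final
    lobes: list[int] = []
    for rep in result.reps_final:
        for cell in sorted(rep.recruited):
            lobes.append(unimodality_score(rep.tuning[cell], rep.epsilon)[0])
    n = len(sets)
    diag = [iou(sets[i], sets[i]) for i in range(n)]
    off = [iou(sets[i], sets[j]) for i in range(n) for j in range(n) if i != j]
    err = None
    if result.decode_log.size:
        err = heading_error(result.decode_log[:, 2], result.decode_log[:, 1])[0]
    digest = {
        "name": result.protocol.name,
        "recruited_counts": [len(s) for s in sets],
        "lobe_counts": lobes,
        "iou_diag_mean": float(np.mean(diag)) if diag else 0.0,
        "iou_offdiag_mean": float(np.mean(off)) if off else 0.0,
        "heading_error_mean": err,
    }
    json.dumps(digest)  # must be serializable
    return digest
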