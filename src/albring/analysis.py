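"""Decoding and quantification.

Population-vector readout of the internal HD estimate, tuning-curve
construction from test-phase rate logs, recruited-set / Jaccard (IoU)
remapping metrics, circular heading-error statistics, and unimodality and
weight-convergence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alb import recruit_report
from .world import wrap_deg

__all__ = [
    "UndefinedDecodeError",
    "RepresentationMap",
    "population_vector",
    "build_representation",
    "iou",
    "heading_error",
    "unimodality_score",
    "weight_convergence",
]


class UndefinedDecodeError(ValueError):
    """Raised when the population vector has (near-)zero resultant."""


def population_vector(rates: np.ndarray, preferred_dirs: np.ndarray) -> float:
    """Firing-rate-weighted circular mean of preferred directions (degrees).

    Decodes via arctan2(sum f sin(theta), sum f cos(theta)), in [-180, 180).
    All-zero rates or a perfectly balanced (e.g. antipodal bimodal) pattern
    leave the resultant at zero, where the decode is undefined.
    """
    f = np.asarray(rates, dtype=float)
    th = np.deg2rad(np.asarray(preferred_dirs, dtype=float))
    s, c = float(f @ np.sin(th)), float(f @ np.cos(th))
    norm = np.hypot(s, c)
    if norm < 1e-9 * max(f.sum(), 1e-30) or f.sum() == 0:
        raise UndefinedDecodeError("zero resultant: population vector undefined")
    ang = np.rad2deg(np.arctan2(s, c))
    return float(wrap_deg(ang))


@dataclass
class RepresentationMap:
    """Per-cell mean firing rate binned by true HD (cells x bins).

    bin_centers are the centers of 1-degree bins over [-180, 180);
    recruited holds the ids of cells whose peak rate reached epsilon.
    """

    tuning: np.ndarray
    bin_centers: np.ndarray
    recruited: set[int]
    epsilon: float

    def peak_direction(self, cell: int) -> float:
        """True-HD bin (degrees) where the cell fires maximally."""
        return float(self.bin_centers[int(np.argmax(self.tuning[cell]))])


def build_representation(
    rate_log: np.ndarray,
    true_hd_log: np.ndarray,
    bins: int = 360,
    epsilon: float = 0.5,
) -> RepresentationMap:
    """Tuning matrix from a test-phase rate log aligned to true HD.

    rate_log is (timesteps, cells); for each cell the mean rate per true-HD
    bin is computed.  Empty bins are left at zero.  A cell counts as
    recruited when its *binned* tuning curve reaches epsilon - averaging
    the repeated visits of each HD bin, which is robust to per-step noise
    (a raw per-step maximum is upward-biased under noisy input).
    """
    rates = np.asarray(rate_log, dtype=float)
    hd = wrap_deg(np.asarray(true_hd_log, dtype=float))
    if rates.shape[0] != hd.shape[0]:
        raise ValueError("rate log and HD log must be time-aligned")
    edges = np.linspace(-180.0, 180.0, bins + 1)
    idx = np.clip(np.digitize(hd, edges) - 1, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    n_cells = rates.shape[1]
    sums = np.zeros((n_cells, bins))
    for b in range(bins):
        mask = idx == b
        if counts[b]:
            sums[:, b] = rates[mask].mean(axis=0)
    centers = (edges[:-1] + edges[1:]) / 2.0
    recruited = set(np.flatnonzero(sums.max(axis=1) >= epsilon).tolist())
    if epsilon == 0.0:
        recruited = set(np.flatnonzero(sums.max(axis=1) > 0.0).tolist())
    return RepresentationMap(
        tuning=sums,
        bin_centers=centers,
        recruited=recruited,
        epsilon=epsilon,
    )


def iou(set_a: set, set_b: set) -> float:
    """Jaccard similarity |A intersect B| / |A union B|, in [0, 1].

    Two empty sets are defined to have IoU 0, so silent populations are
    never reported as similar.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def heading_error(decoded, true) -> tuple[float, float]:
    """Signed circular heading error: (circular mean deg, SEM deg).

    Per-sample error is wrap(decoded - true); the mean is the circular mean
    of the error angles, and the SEM is the circular standard deviation over
    samples divided by sqrt(n).
    """
    err = np.deg2rad(wrap_deg(np.asarray(decoded, dtype=float) - np.asarray(true, dtype=float)))
    n = err.size
    if n == 0:
        raise ValueError("empty error series")
    s, c = np.mean(np.sin(err)), np.mean(np.cos(err))
    mean = np.rad2deg(np.arctan2(s, c))
    R = np.hypot(s, c)
    circ_sd = np.rad2deg(np.sqrt(max(0.0, -2.0 * np.log(R)))) if R > 0 else 180.0
    return float(wrap_deg(mean)), float(circ_sd / np.sqrt(n))


def unimodality_score(tuning_row: np.ndarray, epsilon: float = 0.5) -> tuple[int, bool]:
    """Count contiguous circular runs of bins at or above epsilon.

    Returns (n_lobes, is_unimodal); a cell is unimodal iff its supra-
    threshold support forms exactly one contiguous arc on the circle.
    """
    above = np.asarray(tuning_row, dtype=float) >= epsilon
    if not above.any():
        return 0, False
    if above.all():
        return 1, True
    # count rising edges on the circle
    rises = int(np.sum(above & ~np.roll(above, 1)))
    return rises, rises == 1


def weight_convergence(snapshots, final: np.ndarray) -> list[tuple[float, float]]:
    """Per-snapshot (euclidean distance, Pearson correlation) to the final weights.

    A zero-variance snapshot (e.g. all-zero weights) has undefined
    correlation, reported as 0.
    """
    f = np.asarray(final, dtype=float).ravel()
    out = []
    for snap in snapshots:
        s = np.asarray(snap, dtype=float).ravel()
        if s.shape != f.shape:
            raise ValueError("snapshot shape differs from final weights")
        dist = float(np.linalg.norm(s - f))
        if np.std(s) == 0 or np.std(f) == 0:
            corr = 1.0 if dist == 0 else 0.0
        else:
            corr = float(np.corrcoef(s, f)[0, 1])
        out.append((dist, corr))
    return out
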