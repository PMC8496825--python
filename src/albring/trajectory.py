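"""Head-direction trajectories: recorded, synthetic, and uniform rotation.

A trajectory is a regularly sampled allocentric HD series (degrees,
[-180, 180)) plus the matching angular velocity (deg/s).  Recorded rat data
can be read from MAT files; a seeded generator produces synthetic foraging
trajectories whose mean absolute angular speed emulates the recordings
(~72.88 deg/s over 20 minutes); and a constant-speed rotation supplies the
standardized testing sweep that samples every HD equally often.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.io

from .world import wrap_deg

__all__ = ["Trajectory", "load_recorded", "synth_trajectory", "test_rotation"]

RECORDED_MEAN_SPEED = 72.88  # deg/s, mean |omega| of the reference recording


@dataclass(frozen=True)
class Trajectory:
    """Time series of true head direction and angular velocity.

    Invariant (wrap consistency): hd[k+1] == wrap(hd[k] + omega[k]*dt).
    """

    dt: float
    hd: np.ndarray
    omega: np.ndarray
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.hd.shape != self.omega.shape:
            raise ValueError("hd and omega must have equal length")

    def __len__(self) -> int:
        return len(self.hd)

    @property
    def duration(self) -> float:
        return len(self.hd) * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.hd)) * self.dt

    def mean_speed(self) -> float:
        return float(np.mean(np.abs(self.omega)))

    def to_csv(self, path) -> None:
        data = np.column_stack([self.time, self.hd, self.omega])
        np.savetxt(
            path,
            data,
            delimiter=",",
            header="time_s,hd_deg,omega_deg_s",
            comments="",
            fmt="%.10g",
        )

    @classmethod
    def from_csv(cls, path, source: str = "csv") -> "Trajectory":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        t, hd, omega = data[:, 0], data[:, 1], data[:, 2]
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        return cls(dt=dt, hd=wrap_deg(hd), omega=omega, source=source)


def _omega_from_hd(hd: np.ndarray, dt: float) -> np.ndarray:
    """Angular velocity by wrapped forward differences (last value repeated)."""
    d = wrap_deg(np.diff(hd))
    omega = np.empty_like(hd)
    omega[:-1] = d / dt
    omega[-1] = omega[-2] if len(hd) > 1 else 0.0
    return omega


def load_recorded(path, hd_key: str | None = None, dt: float | None = None) -> Trajectory:
    """Read an HD trajectory from a MAT file.

    Looks for an HD variable (``hd_key`` or the first 1-D numeric array) in
    degrees; angular velocity is derived by wrapped finite differences when
    no velocity variable is stored.  ``dt`` overrides any sampling step
    stored in the file (variable 'dt' or 'fs').
    """
    try:
        mat = scipy.io.loadmat(path, squeeze_me=True)
    except (FileNotFoundError, OSError) as exc:
        raise IOError(f"cannot read MAT trajectory file {path!r}: {exc}") from exc
    names = [k for k in mat if not k.startswith("__")]
    if hd_key is None:
        candidates = [
            k
            for k in names
            if isinstance(mat[k], np.ndarray) and np.asarray(mat[k]).squeeze().ndim == 1
        ]
        if not candidates:
            raise IOError(f"no 1-D HD series found in {path!r}; variables: {names}")
        hd_key = candidates[0]
    elif hd_key not in mat:
        raise IOError(f"variable {hd_key!r} not in {path!r}; variables: {names}")
    hd = wrap_deg(np.asarray(mat[hd_key], dtype=float).squeeze())
    if dt is None:
        if "dt" in mat:
            dt = float(np.asarray(mat["dt"]).squeeze())
        elif "fs" in mat:
            dt = 1.0 / float(np.asarray(mat["fs"]).squeeze())
        else:
            dt = 0.02  # common video-tracking rate; resample downstream as needed
    omega = (
        np.asarray(mat["omega"], dtype=float).squeeze()
        if "omega" in mat
        else _omega_from_hd(hd, dt)
    )
    return Trajectory(dt=dt, hd=hd, omega=omega, source=f"recorded:{path}")


def synth_trajectory(
    duration_s: float = 1200.0,
    target_mean_speed: float = RECORDED_MEAN_SPEED,
    dt: float = 0.005,
    seed: int = 0,
    corr_time: float = 0.5,
) -> Trajectory:
    """Seeded synthetic foraging trajectory.

    Angular velocity follows a mean-reverting (Ornstein-Uhlenbeck) process
    with ~corr_time seconds of autocorrelation - smooth, naturalistic head
    turns with zero-mean, symmetric velocity - rescaled exactly so the
    realized mean |omega| equals target_mean_speed.  HD is the wrapped
    integral of omega.
    """
    if duration_s <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt))
    omega = np.empty(n)
    x = 0.0
    decay = np.exp(-dt / corr_time)
    noise_sd = np.sqrt(1.0 - decay**2)
    draws = rng.standard_normal(n)
    for k in range(n):
        x = decay * x + noise_sd * draws[k]
        omega[k] = x
    realized = np.mean(np.abs(omega))
    omega *= target_mean_speed / realized
    hd0 = float(rng.uniform(-180.0, 180.0))
    hd = wrap_deg(hd0 + np.concatenate([[0.0], np.cumsum(omega[:-1]) * dt]))
    return Trajectory(dt=dt, hd=hd, omega=omega, source=f"synthetic(seed={seed})")


def test_rotation(
    start_hd: float = 0.0, speed: float = 60.0, duration: float = 60.0, dt: float = 0.005
) -> Trajectory:
    """Constant-speed rotation used for the standardized testing phase.

    With the defaults (60 deg/s for 60 s) the sweep covers 10 full
    revolutions, so every 1-degree HD bin is sampled 10 times.
    """
    n = int(round(duration / dt))
    omega = np.full(n, float(speed))
    hd = wrap_deg(start_hd + speed * dt * np.arange(n))
    return Trajectory(dt=dt, hd=hd, omega=omega, source="uniform-rotation")
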