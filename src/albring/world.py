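"""Feature-specific visual (and odor) input channels.

The agent's surroundings are described declaratively as a set of *cues*, each
belonging to one feature channel (think color / texture / odor).  Every
channel is a population of neurons with egocentric directional receptive
fields on a common grid over [-180, 180) degrees (0 = straight ahead).  Given
the true allocentric head direction, each cue's allocentric center(s) are
converted to egocentric bearings and rendered as von-Mises-shaped firing
profiles; all cue profiles within a channel are summed, low-amplitude
background noise is added, and every non-silent channel is rescaled to a
common mean rate.  This mean-normalization emulates upstream sensory
adaptation and is what makes narrow cues more salient (higher peaks) than
broad ones.

All cues are treated as distal: a cue's bearing depends only on head
direction, never on position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "wrap_deg",
    "theta_grid",
    "Cue",
    "CueDynamics",
    "Environment",
    "unimodal_profile",
    "broad_profile",
    "channel_response",
    "advance_cues",
    "odor_channel",
]


def wrap_deg(x):
    """Wrap angle(s) in degrees to [-180, 180)."""
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


def theta_grid(n: int) -> np.ndarray:
    """n equally spaced egocentric preferred directions on [-180, 180)."""
    return -180.0 + 360.0 * np.arange(n) / n


@dataclass(frozen=True)
class CueDynamics:
    """How a cue's allocentric position evolves over time.

    kind   : 'static' | 'rotate' | 'teleport' | 'window'
    speed  : rotation speed in deg/s, anticlockwise positive ('rotate')
    period : seconds between random jumps ('teleport')
    t_on, t_off : interval during which the cue is present ('window')
    """

    kind: str = "static"
    speed: float = 0.0
    period: float = 10.0
    t_on: float = 0.0
    t_off: float = np.inf


@dataclass(frozen=True)
class Cue:
    """One visual feature source.

    profile 'unimodal' is a scaled von Mises bump; 'broad' a plateau built by
    tiling von Mises bumps across `width` degrees; 'bimodal' two summed
    bumps (exactly two centers); 'constant' a direction-independent rate
    (used for odors).  `kappa` is the encoding precision, `fmax` the peak
    rate before channel normalization.
    """

    feature_id: str
    profile: str = "unimodal"
    centers: tuple[float, ...] = (0.0,)
    kappa: float = 20.0
    fmax: float = 1.0
    width: float = 90.0
    dynamics: CueDynamics = field(default_factory=CueDynamics)

    def __post_init__(self) -> None:
        if self.profile not in ("unimodal", "broad", "bimodal", "constant"):
            raise ValueError(f"unknown cue profile {self.profile!r}")
        if self.profile == "bimodal" and len(self.centers) != 2:
            raise ValueError("bimodal cue needs exactly 2 centers")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not 0.0 < self.fmax <= 1.0:
            raise ValueError("fmax must lie in (0, 1]")
        object.__setattr__(self, "centers", tuple(float(wrap_deg(c)) for c in self.centers))

    def active(self, t: float) -> bool:
        d = self.dynamics
        if d.kind == "window":
            return d.t_on <= t <= d.t_off
        return True


@dataclass(frozen=True)
class Environment:
    """A named scenery: a set of cues plus the shared channel layout.

    feature_ids fixes the channel ordering; cues whose feature_id is not
    listed are rejected.  n_per_channel neurons tile [-180, 180) per channel.
    noise_amp/noise_kappa parameterize the broad-bump background noise added
    to each channel before normalization; target_mean is the common mean rate
    every non-silent cue channel is scaled to.
    """

    name: str
    cues: tuple[Cue, ...]
    feature_ids: tuple[str, ...] = ()
    n_per_channel: int = 360
    target_mean: float = 0.08
    noise_amp: float = 0.0
    noise_kappa: float = 1.0

    def __post_init__(self) -> None:
        if not self.feature_ids:
            seen: list[str] = []
            for c in self.cues:
                if c.feature_id not in seen:
                    seen.append(c.feature_id)
            object.__setattr__(self, "feature_ids", tuple(seen))
        for c in self.cues:
            if c.feature_id not in self.feature_ids:
                raise ValueError(
                    f"cue feature {c.feature_id!r} not in channel layout {self.feature_ids}"
                )

    @property
    def theta(self) -> np.ndarray:
        return theta_grid(self.n_per_channel)


def unimodal_profile(theta, phi: float, kappa: float, fmax: float = 1.0) -> np.ndarray:
    """Scaled von Mises bump: f(theta) = fmax * exp(kappa (cos(theta-phi) - 1)).

    Peak value fmax at theta = phi; kappa = 0 gives a flat profile at fmax.
    """
    d = np.deg2rad(np.asarray(theta, dtype=float) - phi)
    return fmax * np.exp(kappa * (np.cos(d) - 1.0))


def broad_profile(
    theta, phi: float, kappa1: float, width: float, fmax: float = 1.0, step: float = 1.0
) -> np.ndarray:
    """Plateau profile: von Mises bumps tiled across [phi - width/2, phi + width/2].

    The sum of offset bumps approximates a von Mises cumulative distribution
    on each shoulder, yielding a near-flat top of extent ~width; the result is
    rescaled so its maximum equals fmax.  width -> 0 degenerates to a single
    unimodal bump.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    half = width / 2.0
    centers = np.arange(-half, half + step / 2, step) if width > 0 else np.array([0.0])
    theta = np.asarray(theta, dtype=float)
    d = np.deg2rad(theta[:, None] - (phi + centers)[None, :])
    prof = np.exp(kappa1 * (np.cos(d) - 1.0)).sum(axis=1)
    return fmax * prof / prof.max()


from functools import lru_cache


@lru_cache(maxsize=512)
def _profile_template(profile: str, kappa: float, fmax: float, width: float, n: int):
    """Profile shape centered at bearing 0 on the n-point grid (cached)."""
    theta = theta_grid(n)
    if profile == "broad":
        return broad_profile(theta, 0.0, kappa, width, fmax)
    return unimodal_profile(theta, 0.0, kappa, fmax)


def _shift_template(template: np.ndarray, bearing: float, n: int) -> np.ndarray:
    """Circularly shift a centered template to an arbitrary bearing.

    Integer-degree bearings are exact rolls (preserving shift equivariance on
    the grid); fractional bearings interpolate linearly between rolls.
    """
    s = bearing * n / 360.0
    i0 = int(np.floor(s))
    frac = s - i0
    rolled = np.roll(template, i0)
    if frac == 0.0:
        return rolled
    return (1.0 - frac) * rolled + frac * np.roll(template, i0 + 1)


def _cue_profile(cue: Cue, theta: np.ndarray, hd: float) -> np.ndarray:
    """Egocentric firing profile of one cue at true head direction hd."""
    if cue.profile == "constant":
        return np.full(theta.shape, cue.fmax)
    n = theta.shape[0]
    bearings = wrap_deg(np.asarray(cue.centers) - hd)
    tmpl = _profile_template(cue.profile if cue.profile == "broad" else "unimodal",
                             cue.kappa, cue.fmax, cue.width, n)
    out = np.zeros_like(theta)
    for b in np.atleast_1d(bearings):
        out += _shift_template(tmpl, float(b), n)
    return out


def channel_response(
    env: Environment,
    hd: float,
    t: float = 0.0,
    rng: np.random.Generator | None = None,
    feature_ids: tuple[str, ...] | None = None,
    noise_rel: float = 0.0,
) -> dict[str, np.ndarray]:
    """Per-channel firing-rate vectors for true head direction ``hd``.

    For each channel: cue profiles are summed at their current egocentric
    bearings, background noise (a random low-amplitude broad bump, if
    env.noise_amp > 0) is added, and channels containing at least one active
    cue are rescaled to env.target_mean.  Channels with no active cue are not
    rescaled, so a silent channel stays (near) zero.  With noise_rel > 0,
    uniform random noise with 1-norm equal to noise_rel times the channel's
    1-norm is added after normalization (redrawn each call).  Rates are
    clipped to [0, 1].
    """
    theta = env.theta
    ids = feature_ids if feature_ids is not None else env.feature_ids
    out: dict[str, np.ndarray] = {}
    for fid in ids:
        cues = [c for c in env.cues if c.feature_id == fid and c.active(t)]
        signal = np.zeros_like(theta)
        for cue in cues:
            signal += _cue_profile(cue, theta, hd)
        if env.noise_amp > 0 and rng is not None:
            center = float(rng.uniform(-180.0, 180.0))
            signal = signal + env.noise_amp * unimodal_profile(theta, center, env.noise_kappa)
        if cues and signal.mean() > 0:
            signal = signal * (env.target_mean / signal.mean())
        if noise_rel > 0 and rng is not None:
            u = rng.uniform(0.0, 1.0, size=theta.shape)
            s1 = np.abs(signal).sum()
            if s1 > 0:
                signal = signal + u * (noise_rel * s1 / u.sum())
        out[fid] = np.clip(signal, 0.0, 1.0)
    return out


def advance_cues(
    env: Environment, t: float, dt: float, rng: np.random.Generator | None = None
) -> Environment:
    """Advance cue dynamics from t to t + dt; returns an updated Environment.

    Rotating cues advance by speed*dt (anticlockwise positive); teleporting
    cues jump to a uniformly random allocentric direction whenever a period
    boundary falls inside (t, t + dt]; window cues are handled at render time.
    """
    new_cues = []
    for cue in env.cues:
        d = cue.dynamics
        if d.kind == "rotate":
            new_cues.append(
                replace(cue, centers=tuple(float(wrap_deg(c + d.speed * dt)) for c in cue.centers))
            )
        elif d.kind == "teleport":
            if np.floor((t + dt) / d.period) > np.floor(t / d.period):
                if rng is None:
                    raise ValueError("teleport dynamics require an rng")
                jump = float(rng.uniform(-180.0, 180.0))
                new_cues.append(replace(cue, centers=tuple(jump for _ in cue.centers)))
            else:
                new_cues.append(cue)
        else:
            new_cues.append(cue)
    return replace(env, cues=tuple(new_cues))


def odor_channel(env: Environment, feature_id: str | None = None) -> np.ndarray:
    """Rate vector of a constant ('odor') channel, independent of HD.

    Constant cues span all 360 degrees; like any other non-silent channel the
    result is normalized to env.target_mean.  Without a constant cue on the
    requested channel the response is zero.
    """
    ids = [feature_id] if feature_id is not None else list(env.feature_ids)
    for fid in ids:
        if any(c.feature_id == fid and c.profile == "constant" for c in env.cues):
            return channel_response(env, hd=0.0, feature_ids=(fid,))[fid]
    return np.zeros(env.n_per_channel)
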