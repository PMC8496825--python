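"""Abstract landmark-bearing (aLB) population.

aLB cells receive feed-forward drive from every feature-specific visual
channel and inhibit each other laterally, producing winner-take-all
competition.  Their incoming weights are learned online with a modified Oja
Subspace Algorithm (mOSA): a Hebbian outer-product term minus a feedback term
(the visual input the current aLB activity "expects"), with negative weights
clipped to zero.  The feedback term depresses connections from absent visual
features, which is what lets the population drop unstable cues and remap
between environments; the non-negativity clip respects the fact that
biological synapses do not change sign.

Alternative rules (plain Hebbian, Hebbian covariance, Intrator's BCM, and the
original unclipped OSA) are provided behind the same interface for
comparison; none of them yields unimodal landmark-bearing tuning in sceneries
with ambiguous cues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TransferParams, rate_transfer

__all__ = [
    "AlbParams",
    "AlbLayer",
    "mosa_update",
    "alt_rule_update",
    "recruit_report",
    "LEARNING_RULES",
]

_ACTIVE_EPS = 1e-12  # rows with f_aLB below this are untouched by learning


@dataclass
class AlbParams:
    """Tunable parameters of the aLB layer.

    n          : number of aLB cells
    tau        : membrane time constant (s)
    g_lat      : gain on the fixed lateral-inhibition matrix (must be < 0)
    g_vis      : total visual drive gain, divided equally among the feature
                 channels that currently carry signal (divisive input
                 normalization: sceneries with two or five active features
                 produce drives on the same scale)
    eta        : mOSA learning rate
    zeta       : prefactor on the feedback term (>= 1; 1 recovers plain mOSA)
    init_scale : upper bound of the uniform weight initialization
    a_min      : activation floor; bounds hyperpolarization under the strong
                 lateral inhibition so losing cells can re-enter competition
                 quickly when the view changes

    The lateral kernel is row-stochastic, so the inhibition one active cell
    exerts on another is g_lat/(n-1); winner-take-all competition therefore
    needs |g_lat| of order n.
    """

    n: int = 360
    tau: float = 0.02
    transfer: TransferParams = None  # type: ignore[assignment]
    g_lat: float | None = None  # default -0.75 * (n - 1): 0.75 per cell pair
    g_vis: float = 0.45
    eta: float = 0.001
    zeta: float = 1.0
    init_scale: float = 0.55
    a_min: float = -1.0

    def __post_init__(self) -> None:
        if self.transfer is None:
            self.transfer = TransferParams(alpha=2.4, beta=2.0)
        if self.g_lat is None:
            self.g_lat = -0.75 * (self.n - 1)
        if self.g_lat >= 0:
            raise ValueError("lateral inhibition gain g_lat must be negative")
        if self.zeta < 1:
            raise ValueError("zeta must be >= 1")


def mosa_update(
    weights: dict[str, np.ndarray],
    alb_rates: np.ndarray,
    visual: dict[str, np.ndarray],
    eta: float,
    zeta: float = 1.0,
) -> dict[str, np.ndarray]:
    """One modified-OSA step, in place, for every visual channel.

    W^(j) <- [ W^(j) + eta * f_aLB (f_vis^(j) - zeta * W^(j)T f_aLB)^T ]_+

    Only rows of active aLB cells change, so the update is applied sparsely.
    Entries are clipped at zero after every step.
    """
    f = np.asarray(alb_rates, dtype=float)
    active = np.flatnonzero(f > _ACTIVE_EPS)
    if active.size == 0:
        return weights
    fa = f[active]
    for fid, W in weights.items():
        fv = visual[fid]
        expected = W[active].T @ fa  # = W^T f_aLB (inactive rows contribute 0)
        W[active] = np.clip(W[active] + eta * np.outer(fa, fv - zeta * expected), 0.0, None)
    return weights


class _MosaRule:
    def __init__(self, eta: float, zeta: float = 1.0):
        self.eta, self.zeta = eta, zeta

    def __call__(self, weights, alb_rates, visual):
        return mosa_update(weights, alb_rates, visual, self.eta, self.zeta)


class _OsaOriginalRule:
    """Oja's subspace rule without the non-negativity clip."""

    def __init__(self, eta: float):
        self.eta = eta

    def __call__(self, weights, alb_rates, visual):
        f = np.asarray(alb_rates, dtype=float)
        active = np.flatnonzero(np.abs(f) > _ACTIVE_EPS)
        if active.size == 0:
            return weights
        fa = f[active]
        for fid, W in weights.items():
            expected = W[active].T @ fa
            W[active] += self.eta * np.outer(fa, visual[fid] - expected)
        return weights


class _HebbRule:
    """Plain Hebbian outer product (the potentiation term of mOSA alone)."""

    def __init__(self, eta: float):
        self.eta = eta

    def __call__(self, weights, alb_rates, visual):
        f = np.asarray(alb_rates, dtype=float)
        active = np.flatnonzero(f > _ACTIVE_EPS)
        if active.size == 0:
            return weights
        fa = f[active]
        for fid, W in weights.items():
            W[active] += self.eta * np.outer(fa, visual[fid])
        return weights


class _HebbCovarianceRule:
    """Hebbian covariance: outer product of mean-centered rates.

    Running means are exponential moving averages with time constant
    ``tau_avg`` expressed in update steps.
    """

    def __init__(self, eta: float, tau_avg: float = 200.0):
        self.eta = eta
        self.decay = 1.0 / tau_avg
        self._mean_post: np.ndarray | None = None
        self._mean_pre: dict[str, np.ndarray] = {}

    def __call__(self, weights, alb_rates, visual):
        f = np.asarray(alb_rates, dtype=float)
        if self._mean_post is None:
            self._mean_post = f.copy()
        self._mean_post += self.decay * (f - self._mean_post)
        dpost = f - self._mean_post
        for fid, W in weights.items():
            fv = visual[fid]
            if fid not in self._mean_pre:
                self._mean_pre[fid] = fv.copy()
            m = self._mean_pre[fid]
            m += self.decay * (fv - m)
            W += self.eta * np.outer(dpost, fv - m)
        return weights


class _IntratorBcmRule:
    """Intrator's BCM: Hebbian term gated by a sliding modification threshold.

    dW = eta * f_post (f_post - theta_m) f_pre^T with theta_m a running
    average of f_post^2 (time constant ``tau_theta`` in update steps).
    """

    def __init__(self, eta: float, tau_theta: float = 200.0):
        self.eta = eta
        self.decay = 1.0 / tau_theta
        self._theta: np.ndarray | None = None

    def __call__(self, weights, alb_rates, visual):
        f = np.asarray(alb_rates, dtype=float)
        if self._theta is None:
            self._theta = np.full_like(f, 1e-3)
        self._theta += self.decay * (f**2 - self._theta)
        phi = f * (f - self._theta)
        for fid, W in weights.items():
            W += self.eta * np.outer(phi, visual[fid])
        return weights


LEARNING_RULES = {
    "mosa": _MosaRule,
    "osa_original": _OsaOriginalRule,
    "hebb": _HebbRule,
    "hebb_covariance": _HebbCovarianceRule,
    "intrator_bcm": _IntratorBcmRule,
}


def alt_rule_update(
    rule: str,
    weights: dict[str, np.ndarray],
    alb_rates: np.ndarray,
    visual: dict[str, np.ndarray],
    eta: float,
    **kwargs,
) -> dict[str, np.ndarray]:
    """Apply one named learning-rule step (same interface as mosa_update)."""
    if rule not in LEARNING_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {sorted(LEARNING_RULES)}")
    return LEARNING_RULES[rule](eta, **kwargs)(weights, alb_rates, visual)


def recruit_report(rate_log: np.ndarray, epsilon: float = 0.5) -> set[int]:
    """Ids of cells whose maximum rate over the log reaches epsilon.

    ``rate_log`` is (timesteps, cells); epsilon in [0, 1].  With epsilon = 0
    every cell with any activity is reported.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    peaks = np.asarray(rate_log, dtype=float).max(axis=0)
    if epsilon == 0.0:
        return set(np.flatnonzero(peaks > 0.0).tolist())
    return set(np.flatnonzero(peaks >= epsilon).tolist())


class AlbLayer:
    """State + weights of the aLB population, with pluggable plasticity."""

    def __init__(
        self,
        params: AlbParams,
        feature_ids: tuple[str, ...],
        n_vis: int,
        rng: np.random.Generator,
        rule: str = "mosa",
        **rule_kwargs,
    ):
        self.params = params
        self.feature_ids = tuple(feature_ids)
        self.n_vis = n_vis
        self.weights: dict[str, np.ndarray] = {
            fid: rng.uniform(0.0, params.init_scale, size=(params.n, n_vis))
            for fid in self.feature_ids
        }
        self.a = np.zeros(params.n)
        self.f = np.zeros(params.n)
        self.rule_name = rule
        if rule == "mosa":
            self._rule = _MosaRule(params.eta, params.zeta)
        elif rule in LEARNING_RULES:
            self._rule = LEARNING_RULES[rule](params.eta, **rule_kwargs)
        else:
            raise ValueError(f"unknown rule {rule!r}; choose from {sorted(LEARNING_RULES)}")

    def reset_state(self) -> None:
        self.a[:] = 0.0
        self.f[:] = 0.0

    def step(self, visual: dict[str, np.ndarray], dt: float) -> np.ndarray:
        """One Euler step of the competitive rate dynamics; returns rates.

        Leaky decay + lateral inhibition (g_lat < 0 on the zero-diagonal
        inhibition kernel, computed as (sum - self)/(N-1)) + per-channel
        feed-forward drive.
        """
        p = self.params
        n = p.n
        lateral = (self.f.sum() - self.f) / (n - 1)
        drive = p.g_lat * lateral
        # channels carrying signal share the total gain (divisive input
        # normalization); channel means are equalized upstream, so "active"
        # is simply a mean above half the largest channel mean
        means = {fid: float(visual[fid].mean()) for fid in self.feature_ids}
        top = max(means.values(), default=0.0)
        active = [fid for fid in self.feature_ids if top > 0 and means[fid] > 0.5 * top]
        if active:
            g = p.g_vis / len(active)
            for fid in active:
                drive = drive + g * (self.weights[fid] @ visual[fid])
        self.a += (dt / p.tau) * (-self.a + drive)
        np.clip(self.a, p.a_min, None, out=self.a)
        self.f = np.clip(rate_transfer(self.a, p.transfer), 0.0, 1.0)
        return self.f

    def learn(self, visual: dict[str, np.ndarray]) -> float:
        """Apply one plasticity step using the current rates.

        Returns the summed absolute weight change of the step (the
        convergence diagnostic tracked during learning).
        """
        dense_rule = self.rule_name in ("hebb_covariance", "intrator_bcm")
        active = (
            np.arange(self.params.n)
            if dense_rule
            else np.flatnonzero(self.f > _ACTIVE_EPS)
        )
        if active.size == 0:
            return 0.0
        before = [self.weights[fid][active].copy() for fid in self.feature_ids]
        self._rule(self.weights, self.f, visual)
        return float(
            sum(
                np.abs(self.weights[fid][active] - b).sum()
                for fid, b in zip(self.feature_ids, before)
            )
        )

    def snapshot(self) -> dict[str, np.ndarray]:
        return {fid: W.copy() for fid, W in self.weights.items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for fid in self.feature_ids:
            self.weights[fid] = snap[fid].copy()
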