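"""Shared rate-neuron primitives.

All layers in the model are populations of rate neurons.  A neuron's
activation ``a`` decays leakily toward the weighted sum of its inputs and is
converted to a firing rate in [0, 1) through a thresholded hyperbolic
tangent.  Inhibition within a layer is either *global* (every neuron inhibits
every neuron, itself included) or *lateral* (every neuron inhibits all the
others); both are fixed, row-stochastic matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransferParams",
    "LayerSpec",
    "rate_transfer",
    "euler_step",
    "global_inhibition_matrix",
    "lateral_inhibition_matrix",
]


@dataclass(frozen=True)
class TransferParams:
    """Parameters of the thresholded-tanh activation function.

    alpha : activation threshold (dimensionless)
    beta  : slope above threshold (dimensionless, > 0)
    """

    alpha: float = 0.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one rate-neuron layer.

    input_specs lists (source layer id, gain g_j, weight matrix id) triples;
    the gains' signs encode excitation (g > 0) versus inhibition (g < 0).
    """

    size: int
    tau: float
    transfer: TransferParams = field(default_factory=TransferParams)
    input_specs: tuple[tuple[str, float, str], ...] = ()

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"layer size must be >= 1, got {self.size}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


def rate_transfer(a: np.ndarray, p: TransferParams) -> np.ndarray:
    """Firing rate f = tanh(beta * (a - alpha)) for a >= alpha, else 0.

    Output is elementwise in [0, 1): zero at and below threshold,
    saturating toward 1 for strong activation.
    """
    a = np.asarray(a, dtype=float)
    return np.where(a >= p.alpha, np.tanh(p.beta * (a - p.alpha)), 0.0)


def euler_step(
    a: np.ndarray,
    inputs: list[tuple[float, np.ndarray, np.ndarray]],
    tau: float,
    dt: float,
) -> np.ndarray:
    """One explicit-Euler step of leaky rate dynamics.

    tau * da/dt = -a + sum_j g_j W^(j) f^(j)

    ``inputs`` holds (gain, weight matrix, presynaptic rate vector) triples.
    With no inputs the activation decays exponentially toward zero.  The
    stability guard dt <= tau keeps the explicit scheme from overshooting.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dt > tau:
        raise ValueError(f"dt={dt} exceeds tau={tau}; explicit Euler unstable")
    a = np.asarray(a, dtype=float)
    drive = np.zeros_like(a)
    for gain, W, f in inputs:
        f = np.asarray(f, dtype=float)
        if W.shape[1] != f.shape[0] or W.shape[0] != a.shape[0]:
            raise ValueError(
                f"weight matrix {W.shape} incompatible with presynaptic rates "
                f"{f.shape} and postsynaptic activations {a.shape}"
            )
        drive += gain * (W @ f)
    return a + (dt / tau) * (-a + drive)


def global_inhibition_matrix(N: int) -> np.ndarray:
    """All-to-all inhibition kernel J(N)/N: every entry 1/N, rows sum to 1."""
    if N < 1:
        raise ValueError(f"need N >= 1, got {N}")
    return np.full((N, N), 1.0 / N)


def lateral_inhibition_matrix(N: int) -> np.ndarray:
    """Lateral inhibition kernel (J(N) - I(N))/(N - 1).

    Zero diagonal (no self-inhibition), off-diagonal entries 1/(N-1);
    every row sums to 1.  Requires N >= 2.
    """
    if N < 2:
        raise ValueError(f"need N >= 2 for lateral inhibition, got {N}")
    M = np.full((N, N), 1.0 / (N - 1))
    np.fill_diagonal(M, 0.0)
    return M
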