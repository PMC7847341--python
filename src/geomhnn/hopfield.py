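"""Classical Hopfield network: Hebbian storage, asynchronous recall, energy.

The network is the bipolar autoassociative memory: N fully connected units
with symmetric weights and zero self-coupling, whose asynchronous dynamics
descend the quadratic Lyapunov energy

    E(s) = -1/2 sum_ij psi_ij s_i s_j - sum_i b_i s_i

to a fixed point.  Both the binary (sign activation) and continuous
(logistic activation) variants are represented; the binary variant is the
one the recall dynamics and the probability-flow learner operate on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HopfieldNet",
    "propagate",
    "step_activation",
    "sigmoid_activation",
    "hebbian_learn",
    "energy",
    "run_async",
]


@dataclass
class HopfieldNet:
    """Weights, biases and activation parameters of one Hopfield network.

    ``weights`` must be symmetric; binary mode additionally requires a zero
    diagonal (no self-connection), which is what guarantees energy descent
    under asynchronous updates.
    """

    weights: np.ndarray
    biases: np.ndarray = None
    sigmoid_shift: float = 0.0
    mode: str = "binary"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if self.mode == "binary" and np.abs(np.diag(self.weights)).max(initial=0.0) > 0:
            raise ValueError("binary mode requires a zero weight diagonal")
        if self.mode not in ("binary", "continuous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.biases is None:
            self.biases = np.zeros(n)
        self.biases = np.asarray(self.biases, dtype=np.float64)
        if self.biases.shape != (n,):
            raise ValueError("biases must have length n_nodes")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_nodes": self.n_nodes,
                "weights": self.weights.tolist(),
                "biases": self.biases.tolist(),
                "sigmoid_shift": self.sigmoid_shift,
                "mode": self.mode,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "HopfieldNet":
        doc = json.loads(text)
        return cls(
            weights=np.array(doc["weights"]),
            biases=np.array(doc["biases"]),
            sigmoid_shift=doc.get("sigmoid_shift", 0.0),
            mode=doc.get("mode", "binary"),
        )


def _check_state(net: HopfieldNet, state) -> np.ndarray:
    state = np.asarray(state, dtype=np.float64).ravel()
    if state.shape != (net.n_nodes,):
        raise ValueError(f"state length {state.size} != {net.n_nodes} nodes")
    return state


def propagate(net: HopfieldNet, state, i: int) -> float:
    """Net input of unit i: phi_i = sum_j psi_ij s_j + b_i."""
    state = _check_state(net, state)
    if not 0 <= i < net.n_nodes:
        raise IndexError(f"node index {i} out of range for {net.n_nodes} nodes")
    return float(net.weights[i] @ state + net.biases[i])


def step_activation(phi: float, current: int) -> int:
    """Sign activation; a zero net input holds the current state.

    The hold-on-tie convention is what keeps the energy monotone: flipping
    on phi == 0 would leave E unchanged and could cycle.
    """
    if phi > 0:
        return 1
    if phi < 0:
        return -1
    return int(current)


def sigmoid_activation(net: HopfieldNet, phi: float) -> float:
    """Logistic activation of the continuous variant, 1/(1+exp(-(phi-shift)))."""
    if net.mode != "continuous":
        raise ValueError("sigmoid activation applies to continuous mode")
    return float(1.0 / (1.0 + np.exp(-(phi - net.sigmoid_shift))))


def hebbian_learn(patterns) -> HopfieldNet:
    """Store bipolar patterns by the Hebbian outer-product rule.

    psi_ij = sum_eta g_i^eta g_j^eta for i != j, zero diagonal, zero biases.
    """
    pats = np.asarray(patterns, dtype=np.float64)
    if pats.ndim == 1:
        pats = pats[None, :]
    if pats.ndim != 2 or pats.shape[0] < 1:
        raise ValueError("need at least one pattern, all of equal length")
    if not np.isin(pats, (-1.0, 1.0)).all():
        raise ValueError("patterns must be bipolar (-1/+1)")
    w = pats.T @ pats
    np.fill_diagonal(w, 0.0)
    return HopfieldNet(weights=w)


def energy(net: HopfieldNet, state) -> float:
    """Lyapunov energy E = -1/2 s'Ws - b's."""
    state = _check_state(net, state)
    return float(-0.5 * state @ net.weights @ state - net.biases @ state)


def _update_order(n: int, order: str, sweep: int, rng, shape=None) -> np.ndarray:
    if order == "sequential":
        return np.arange(n)
    if order == "checkerboard":
        if shape is not None:
            rows, cols = np.unravel_index(np.arange(n), shape)
            parity = (rows + cols) % 2
        else:
            parity = np.arange(n) % 2
        return np.concatenate([np.flatnonzero(parity == 0), np.flatnonzero(parity == 1)])
    if order == "random":
        return rng.permutation(n)
    raise ValueError(f"unknown update order {order!r}")


def run_async(
    net: HopfieldNet,
    init,
    max_sweeps: int = 100,
    order: str = "sequential",
    seed: int = 0,
    shape: tuple[int, int] | None = None,
):
    """Asynchronous recall until a full sweep changes no state.

    Returns ``(final_state, energy_trace, converged)``.  The energy trace
    has one entry per completed sweep (plus the initial energy) and is
    non-increasing for any symmetric zero-diagonal weight matrix.  The
    ``shape`` argument gives the pixel-grid geometry used by the
    checkerboard order; without it, parity of the flat index is used.
    """
    state = _check_state(net, init).astype(np.int8)
    if not np.isin(state, (-1, 1)).all():
        raise ValueError("initial state must be bipolar")
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    trace = [energy(net, state)]
    converged = False
    for sweep in range(max_sweeps):
        changed = False
        for i in _update_order(net.n_nodes, order, sweep, rng, shape):
            phi = net.weights[i] @ state + net.biases[i]
            new = step_activation(phi, state[i])
            if new != state[i]:
                state[i] = new
                changed = True
        trace.append(energy(net, state))
        if not changed:
            converged = True
            break
    return state, np.array(trace), converged
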