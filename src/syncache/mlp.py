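"""Single-hidden-layer backprop network with plasticity-energy accounting.

A deliberately plain network: logistic units in the hidden and output
layers, one-hot targets over 10 classes, mean-squared-error loss, pure
online (batch size 1) stochastic gradient descent, no regularization.
Energy is accounted exactly as for the perceptron: every weight change
(biases included) costs |Δw|^α, and the minimal energy is the L1 distance
from the initial weights.  Optionally all weights are routed through a
synaptic cache with a single global-any trigger across the whole network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .caching import CacheParams
from .energy import CostParams
from .patterns import LabeledImageSet

__all__ = [
    "MLPState",
    "mlp_forward",
    "mlp_backprop_step",
    "init_mlp",
    "train_mlp",
    "hidden_unit_sweep",
]

N_CLASSES = 10


@dataclass
class MLPState:
    """Network weights; last column of each matrix holds the biases."""

    W1: np.ndarray  # n_hidden x (d+1)
    W2: np.ndarray  # 10 x (n_hidden+1)

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    def flat(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.W2.ravel()])


def init_mlp(n_inputs: int, n_hidden: int = 100, seed: int = 0) -> MLPState:
    """Uniform init in [−r, r] with r = 1/√fan_in (biases included)."""
    rng = np.random.default_rng(seed)
    r1 = 1.0 / math.sqrt(n_inputs + 1)
    r2 = 1.0 / math.sqrt(n_hidden + 1)
    return MLPState(
        W1=rng.uniform(-r1, r1, size=(n_hidden, n_inputs + 1)),
        W2=rng.uniform(-r2, r2, size=(N_CLASSES, n_hidden + 1)),
    )


def _forward(W1, W2, x):
    h = expit(W1[:, :-1] @ x + W1[:, -1])
    o = expit(W2[:, :-1] @ h + W2[:, -1])
    return h, o


def mlp_forward(state: MLPState, x) -> np.ndarray:
    """Class scores: logistic hidden layer then logistic outputs."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (state.W1.shape[1] - 1,):
        raise ValueError("input dimension does not match the network")
    return _forward(state.W1, state.W2, x)[1]


def predict_class(state: MLPState, x) -> int:
    """argmax of the output scores (lowest index on ties)."""
    return int(np.argmax(mlp_forward(state, x)))


def mlp_backprop_step(state: MLPState, x, target, eta: float):
    """Gradient-descent deltas for one sample under ½Σ(o−t)² loss.

    ``target`` is normally a one-hot vector but any vector in the output
    space is accepted.  Returns ``(dW1, dW2)``; the caller applies them.
    """
    x = np.asarray(x, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    h, o = _forward(state.W1, state.W2, x)
    delta_o = (o - t) * o * (1.0 - o)
    delta_h = (state.W2[:, :-1].T @ delta_o) * h * (1.0 - h)
    xb = np.append(x, 1.0)
    hb = np.append(h, 1.0)
    dW2 = -eta * np.outer(delta_o, hb)
    dW1 = -eta * np.outer(delta_h, xb)
    return dW1, dW2


def _accuracy(W1, W2, images, labels) -> float:
    h = expit(images @ W1[:, :-1].T + W1[:, -1])
    o = expit(h @ W2[:, :-1].T + W2[:, -1])
    return float(np.mean(np.argmax(o, axis=1) == labels))


def _abs_pow(a, alpha):
    return np.abs(a) if alpha == 1.0 else np.abs(a) ** alpha


def train_mlp(
    data: LabeledImageSet,
    test: LabeledImageSet,
    n_hidden: int = 100,
    eta: float = 0.1,
    epochs: int = 20,
    costs: CostParams = CostParams(),
    cache: CacheParams | None = None,
    eval_every: int | None = None,
    seed: int = 0,
):
    """Online backprop with energy accounting; optional synaptic caching.

    Without caching every update is consolidated directly (energy Σ|Δw|^α
    per sample).  With caching each weight carries a transient component
    with decay τ and maintenance cost c, and one global trigger across all
    weights fires when any |s| reaches θ (consolidating the whole network)
    — θ=∞ postpones consolidation to the end of training.  The recorded
    curve holds cumulative energies, the running minimal energy
    Σ|w − w(0)|, and held-out accuracy at each evaluation point.

    Divergence (non-finite weights, expected at large η) terminates the run
    and returns the partial curve.

    Returns ``(state, curve)`` with the curve as a DataFrame.
    """
    images, labels = data.images, data.labels
    n, d = images.shape
    if eval_every is None:
        eval_every = max(1, n // 2)
    state = init_mlp(d, n_hidden, seed=seed)
    w0_1, w0_2 = state.W1.copy(), state.W2.copy()
    rng = np.random.default_rng(seed + 1)
    onehot = np.eye(N_CLASSES)
    caching = cache is not None
    if caching:
        lam = 1.0 if math.isinf(cache.tau) else math.exp(-1.0 / cache.tau)
        s1 = np.zeros_like(state.W1)
        s2 = np.zeros_like(state.W2)
    M_pers = M_maint = M_change = 0.0
    rows = []
    step = 0
    diverged = False

    def record(epoch):
        if caching:
            weff1, weff2 = state.W1 + s1, state.W2 + s2
        else:
            weff1, weff2 = state.W1, state.W2
        m_min = float(np.abs(weff1 - w0_1).sum() + np.abs(weff2 - w0_2).sum())
        rows.append(
            {
                "step": step,
                "epoch": epoch,
                "cum_energy_persistent": M_pers,
                "cum_energy_maintenance": M_maint,
                "cum_energy_change": M_change,
                "cum_energy_total": M_pers + M_maint + M_change,
                "cum_minimal_energy": m_min,
                "test_accuracy": _accuracy(weff1, weff2, test.images, test.labels),
            }
        )

    record(0)
    for epoch in range(epochs):
        order = rng.permutation(n)
        for p in order:
            x = images[p]
            t = onehot[labels[p]]
            if caching:
                if lam < 1.0:
                    s1 *= lam
                    s2 *= lam
                h = expit((state.W1[:, :-1] + s1[:, :-1]) @ x + state.W1[:, -1] + s1[:, -1])
                o = expit((state.W2[:, :-1] + s2[:, :-1]) @ h + state.W2[:, -1] + s2[:, -1])
                delta_o = (o - t) * o * (1.0 - o)
                delta_h = ((state.W2[:, :-1] + s2[:, :-1]).T @ delta_o) * h * (1.0 - h)
                d1 = -eta * np.outer(delta_h, np.append(x, 1.0))
                d2 = -eta * np.outer(delta_o, np.append(h, 1.0))
                s1 += d1
                s2 += d2
                fired = max(np.abs(s1).max(), np.abs(s2).max()) >= cache.theta
                if costs.b > 0 and not fired:
                    M_change += costs.b * (np.abs(d1).sum() + np.abs(d2).sum())
                if fired:
                    for s_mat, w_mat in ((s1, state.W1), (s2, state.W2)):
                        dl = s_mat if not costs.potentiation_only else s_mat[s_mat > 0]
                        M_pers += float(_abs_pow(dl, costs.alpha).sum())
                        w_mat += s_mat
                        s_mat[:] = 0.0
                if costs.c > 0:
                    M_maint += costs.c * float(np.abs(s1).sum() + np.abs(s2).sum())
            else:
                dW1, dW2 = mlp_backprop_step(state, x, t, eta)
                state.W1 += dW1
                state.W2 += dW2
                if costs.potentiation_only:
                    M_pers += float(_abs_pow(dW1[dW1 > 0], costs.alpha).sum()
                                    + _abs_pow(dW2[dW2 > 0], costs.alpha).sum())
                else:
                    M_pers += float(_abs_pow(dW1, costs.alpha).sum()
                                    + _abs_pow(dW2, costs.alpha).sum())
            step += 1
            if step % eval_every == 0:
                record(epoch + (step - epoch * n) / n)
        if not (np.isfinite(state.W1).all() and np.isfinite(state.W2).all()):
            diverged = True
            break
    if caching and not diverged:
        # consolidate the residual transient weights once
        for s_mat, w_mat in ((s1, state.W1), (s2, state.W2)):
            dl = s_mat if not costs.potentiation_only else s_mat[s_mat > 0]
            M_pers += float(_abs_pow(dl, costs.alpha).sum())
            w_mat += s_mat
            s_mat[:] = 0.0
    record(epochs)
    curve = pd.DataFrame(rows)
    curve.attrs["diverged"] = diverged
    return state, curve


def energy_at_accuracy(curve: pd.DataFrame, accuracy: float):
    """Cumulative total energy at the first recorded crossing of ``accuracy``.

    Linear interpolation between the bracketing evaluation points; ``None``
    if the accuracy is never reached.
    """
    acc = curve["test_accuracy"].to_numpy()
    en = curve["cum_energy_total"].to_numpy()
    hit = np.nonzero(acc >= accuracy)[0]
    if hit.size == 0:
        return None
    i = hit[0]
    if i == 0 or acc[i] == acc[i - 1]:
        return float(en[i])
    f = (accuracy - acc[i - 1]) / (acc[i] - acc[i - 1])
    return float(en[i - 1] + f * (en[i] - en[i - 1]))


def hidden_unit_sweep(
    data: LabeledImageSet,
    test: LabeledImageSet,
    hidden_grid: Sequence[int],
    target_accuracy: float,
    eta: float = 0.1,
    epochs: int = 40,
    costs: CostParams = CostParams(),
    cache: CacheParams | None = None,
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Energy needed to reach a target accuracy versus network size.

    For each hidden-layer size, trains until the held-out accuracy first
    crosses ``target_accuracy`` (or the epoch cap) and records the
    cumulative energy at the crossing, averaged over the seeds that reach
    it.  Undersized networks that never reach the target are flagged.
    """
    if not list(hidden_grid):
        raise ValueError("hidden_grid must be non-empty")
    rows = []
    for n_hidden in hidden_grid:
        energies = []
        n_reached = 0
        for seed in seeds:
            _, curve = train_mlp(
                data, test, n_hidden=n_hidden, eta=eta, epochs=epochs,
                costs=costs, cache=cache, seed=seed,
            )
            e = energy_at_accuracy(curve, target_accuracy)
            if e is not None:
                n_reached += 1
                energies.append(e)
        rows.append(
            {
                "n_hidden": n_hidden,
                "energy": float(np.mean(energies)) if energies else math.nan,
                "reached": n_reached == len(list(seeds)),
                "n_reached": n_reached,
            }
        )
    return pd.DataFrame(rows)
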