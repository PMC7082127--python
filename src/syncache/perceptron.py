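"""Classic perceptron training with full energy accounting.

The perceptron is a single threshold unit y = Θ(w·x) trained with the
error-correction rule Δw = η(d−y)x on random ±1 patterns.  Learning cycles
through the patterns until a full pass produces no update.  Because inputs
are ±1, every update changes every weight (bias included) by exactly ±η, so
the path energy Σ|Δw|^α is (N+1)·K·η^α for K update events — the weights
follow an unbiased random walk whose L1 path length vastly exceeds the L1
displacement when many patterns are stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .energy import CostParams, EnergyLedger
from .patterns import PatternSet

__all__ = [
    "TrainConfig",
    "TrainResult",
    "predict",
    "perceptron_step",
    "train_perceptron",
    "default_max_epochs",
]

_ORDERS = ("cyclic", "shuffled")


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration.

    eta
        Learning rate (arbitrary units; the noise-free perceptron is
        scale-free, so the default 1 loses no generality).
    max_epochs
        Cap on full passes through the pattern set; ``None`` selects a
        load-dependent default via :func:`default_max_epochs`.
    seed
        Seeds the per-epoch shuffle when ``order="shuffled"``.
    order
        ``"cyclic"`` presents patterns in fixed order (default);
        ``"shuffled"`` reshuffles every epoch.
    """

    eta: float = 1.0
    max_epochs: int | None = None
    seed: int = 0
    order: str = "cyclic"

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.max_epochs is not None and self.max_epochs < 1:
            raise ValueError("max_epochs must be at least 1")
        if self.order not in _ORDERS:
            raise ValueError(f"order must be one of {_ORDERS}")


@dataclass
class TrainResult:
    """Outcome of a training run with its attached energy ledger."""

    converged: bool
    epochs_used: int
    T: int
    K: int
    initial_weights: np.ndarray
    final_weights: np.ndarray
    ledger: EnergyLedger
    n_consolidations: int = 0
    epoch_log: dict | None = None


def default_max_epochs(n_patterns: int, n_synapses: int) -> int:
    """Load-dependent epoch cap: ~20× the expected learning time.

    Expected epochs scale as T/P = P^{1/2}/(2−P/N)² below capacity; a 20×
    margin leaves room for slow seeds and for decay-slowed cached runs.
    Above capacity (P/N ≥ 2) there is no finite expectation and a large
    fixed cap is used; such runs are reported as non-converged.
    """
    load = n_patterns / n_synapses
    if load < 2.0:
        expected = max(
            2.0 / (2.0 - load) ** 2,  # K / P
            math.sqrt(n_patterns) / (2.0 - load) ** 2,  # T / P
        )
        return max(100, int(math.ceil(20.0 * expected)))
    return 200_000


def predict(w, x) -> int:
    """Heaviside output: 1 if w·x > 0 else 0 (ties break to 0)."""
    w = np.asarray(w, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if w.shape != x.shape:
        raise ValueError("weight and pattern dimensions disagree")
    return int(w @ x > 0.0)


def perceptron_step(w, x, d: int, eta: float = 1.0):
    """One error-correction step: returns (new_weights, updated_flag)."""
    w = np.asarray(w, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    y = predict(w, x)
    if y == d:
        return w.copy(), False
    return w + eta * (d - y) * x, True


def train_perceptron(
    patterns: PatternSet,
    cfg: TrainConfig = TrainConfig(),
    costs: CostParams = CostParams(),
) -> TrainResult:
    """Train to zero errors from all-zero initial weights.

    Repeats epochs until a full pass makes no update or ``max_epochs`` is
    reached (reported with ``converged=False``; expected near and above the
    critical capacity P ≈ 2N).  The ledger charges |Δw|^α for every weight
    change; with ±1 inputs each update moves every weight by exactly η, so
    the energy is accumulated in closed form rather than per step.
    """
    X = patterns.inputs
    d = patterns.targets.astype(np.float64)
    max_epochs = cfg.max_epochs
    if max_epochs is None:
        max_epochs = default_max_epochs(patterns.n_patterns, patterns.n_synapses)
    n_plus = ((X > 0).sum(axis=1)).astype(np.int64)  # count of +1 entries per pattern
    w, K, T, epochs, converged, n_pos = _kernels.plain_perceptron_loop(
        X, d, n_plus, cfg.eta, max_epochs, cfg.order == "shuffled", cfg.seed % 2**32
    )
    n_changes = n_pos if costs.potentiation_only else K * patterns.n_weights
    ledger = EnergyLedger(
        M_persistent=n_changes * cfg.eta**costs.alpha,
        M_maintenance=0.0,
        M_change=0.0,
        K=K,
        T=T,
    )
    return TrainResult(
        converged=converged,
        epochs_used=epochs,
        T=T,
        K=K,
        initial_weights=np.zeros(patterns.n_weights),
        final_weights=w,
        ledger=ledger,
    )
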