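"""The metabolic cost model for synaptic plasticity.

Every change of a persistent (consolidated) weight costs |Δl|^α; holding a
transient weight costs c·|s| per time step; changing a transient weight
costs b·|Δs|.  All energies are in arbitrary units — the model only ever
compares energies, so no calibration to joules or ATP is attempted.  The
minimal energy to reach a weight configuration is the L1 distance from the
initial weights, i.e. the cost of moving each synapse straight to its final
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CostParams",
    "EnergyLedger",
    "path_energy",
    "minimal_energy",
    "maintenance_cost",
    "transient_change_cost",
]


@dataclass(frozen=True)
class CostParams:
    """Energy cost parameters.

    alpha
        Exponent on the magnitude of each persistent weight change
        (default 1: cost proportional to the change).
    c
        Maintenance cost per unit of transient weight per time step.
    b
        Cost per unit of transient weight change.  A change that is
        immediately consolidated is exempt.
    potentiation_only
        If set, only positive (potentiating) weight changes cost energy;
        depression is free.
    """

    alpha: float = 1.0
    c: float = 0.0
    b: float = 0.0
    potentiation_only: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.c < 0 or self.b < 0:
            raise ValueError("alpha, c and b must be non-negative")


@dataclass
class EnergyLedger:
    """Accumulated energy of a training run, split by cost channel.

    ``M_persistent`` is the consolidation energy Σ|Δl|^α (for plain
    perceptron learning, every update is a consolidation), ``M_maintenance``
    the summed per-step transient holding cost, and ``M_change`` the summed
    transient-change cost.  ``K`` counts update events and ``T`` pattern
    presentations (time steps).
    """

    M_persistent: float = 0.0
    M_maintenance: float = 0.0
    M_change: float = 0.0
    K: int = 0
    T: int = 0

    @property
    def M_total(self) -> float:
        return self.M_persistent + self.M_maintenance + self.M_change


def path_energy(weight_deltas, alpha: float = 1.0, potentiation_only: bool = False) -> float:
    """Energy of a weight trajectory: Σ over all entries of |Δw|^α.

    ``weight_deltas`` may be any array of per-step per-synapse changes.
    With ``alpha=0`` this counts the nonzero changes (0^0 taken as 0, so
    no-change entries are free).  With ``potentiation_only`` only positive
    changes are charged.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    deltas = np.asarray(weight_deltas, dtype=np.float64)
    if not np.all(np.isfinite(deltas)):
        raise ValueError("weight deltas must be finite")
    if potentiation_only:
        deltas = deltas[deltas > 0]
    else:
        deltas = deltas[deltas != 0]
    if alpha == 0:
        return float(deltas.size)
    return float(np.sum(np.abs(deltas) ** alpha))


def minimal_energy(w_start, w_end) -> float:
    """L1 distance between two weight vectors: the straight-path cost."""
    w0 = np.asarray(w_start, dtype=np.float64)
    w1 = np.asarray(w_end, dtype=np.float64)
    if w0.shape != w1.shape:
        raise ValueError("weight vectors must have the same shape")
    return float(np.sum(np.abs(w1 - w0)))


def maintenance_cost(s_snapshot, c: float) -> float:
    """One time step of transient maintenance: c·Σ|s|."""
    if c < 0:
        raise ValueError("c must be non-negative")
    return float(c * np.sum(np.abs(np.asarray(s_snapshot, dtype=np.float64))))


def transient_change_cost(delta_s, b: float) -> float:
    """Cost b·Σ|Δs| of changing the transient weights."""
    if b < 0:
        raise ValueError("b must be non-negative")
    return float(b * np.sum(np.abs(np.asarray(delta_s, dtype=np.float64))))
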