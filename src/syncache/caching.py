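"""Synaptic caching: transient accumulation with threshold-triggered consolidation.

Each synapse carries a transient component s (cheap to hold, decays with
time constant τ) and a persistent component l (expensive to change, stable);
the effective weight is their sum.  Perceptron updates land in s.  When the
accumulated transient plasticity crosses the consolidation threshold θ it
is transferred to l, in one of three trigger variants:

``local``
    a synapse whose own |s_i| reaches θ consolidates alone;
``global-any``
    one synapse reaching θ consolidates the whole neuron (the variant
    matching synaptic tagging-and-capture, and the default);
``global-sum``
    the summed Σ|s_i| reaching θ consolidates the whole neuron.

Consolidation transfers s into l exactly, so with no decay the effective
weight trajectory — and hence learning — is identical to the plain
perceptron; only the energy bookkeeping changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .energy import CostParams, EnergyLedger
from .patterns import PatternSet
from .perceptron import TrainConfig, TrainResult, default_max_epochs

__all__ = [
    "CacheParams",
    "CachedState",
    "decay_step",
    "check_trigger",
    "consolidate",
    "train_cached_perceptron",
    "optimize_threshold",
]

_MODES = {"local": _kernels.MODE_LOCAL, "global-any": _kernels.MODE_GLOBAL_ANY,
          "global-sum": _kernels.MODE_GLOBAL_SUM}


@dataclass(frozen=True)
class CacheParams:
    """Caching parameters: threshold θ, decay constant τ, trigger mode.

    θ may be ``inf`` (single final consolidation) and τ may be ``inf``
    (no decay).  θ is on the per-synapse |s| scale for modes local and
    global-any, and on the Σ|s| scale for global-sum.  The time step is
    one pattern presentation.
    """

    theta: float = math.inf
    tau: float = math.inf
    mode: str = "global-any"

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive (inf allowed)")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {tuple(_MODES)}")


@dataclass
class CachedState:
    """Per-synapse transient (s) and persistent (l) weights; w = s + l."""

    s: np.ndarray
    l: np.ndarray
    theta: float = math.inf
    tau: float = math.inf
    mode: str = "global-any"

    @property
    def weights(self) -> np.ndarray:
        return self.s + self.l


def decay_step(s, tau: float) -> np.ndarray:
    """One time step of exponential decay: s → s·exp(−1/τ); no-op at τ=∞."""
    if not tau > 0:
        raise ValueError("tau must be positive")
    s = np.asarray(s, dtype=np.float64)
    if math.isinf(tau):
        return s.copy()
    return s * math.exp(-1.0 / tau)


def check_trigger(s, theta: float, mode: str = "global-any"):
    """Does the transient state trigger consolidation?

    Returns ``(fire, crossing_index)``.  Modes local and global-any fire
    when max|s_i| ≥ θ (crossing index = first argmax); global-sum fires when
    Σ|s_i| ≥ θ (no single crossing synapse, index ``None``).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {tuple(_MODES)}")
    a = np.abs(np.asarray(s, dtype=np.float64))
    if mode == "global-sum":
        return bool(a.sum() >= theta), None
    idx = int(np.argmax(a))
    return bool(a[idx] >= theta), idx


def consolidate(state: CachedState, mode: str | None = None, crossing_index: int | None = None):
    """Transfer transient weight into the persistent store.

    Global modes move all of s into l; local mode moves only the crossing
    synapse.  The effective weight s + l is unchanged by the event.
    Returns ``(new_state, delta_l)``; the caller charges path energy on
    ``delta_l``.
    """
    mode = state.mode if mode is None else mode
    fired, idx = check_trigger(state.s, state.theta, mode)
    if not fired:
        raise ValueError("consolidate called without a fired trigger")
    if mode == "local":
        if crossing_index is None:
            crossing_index = idx
        dl = np.zeros_like(state.s)
        dl[crossing_index] = state.s[crossing_index]
    else:
        dl = state.s.copy()
    new = replace(state, s=state.s - dl, l=state.l + dl)
    return new, dl


def train_cached_perceptron(
    patterns: PatternSet,
    cfg: TrainConfig = TrainConfig(),
    costs: CostParams = CostParams(),
    cache: CacheParams = CacheParams(),
) -> TrainResult:
    """Perceptron training through the synaptic cache.

    Per presentation, in order: decay s; predict with w = s + l; on error
    add η(d−y)x to s and charge the b-cost (waived for synapses consolidated
    in the same step); check the trigger; consolidate and charge |Δl|^α;
    charge maintenance c·Σ|s| on the end-of-step state.  At convergence the
    residual transient weight is consolidated once.  Non-convergence at
    ``max_epochs`` (expected for strong decay / low θ) is reported via
    ``converged=False``, not an error.

    The result's ``epoch_log`` maps ``updates``, ``maintenance_energy``,
    ``consolidation_energy`` and ``n_consolidations`` to per-epoch arrays.
    """
    X = patterns.inputs
    d = patterns.targets.astype(np.float64)
    max_epochs = cfg.max_epochs
    if max_epochs is None:
        max_epochs = default_max_epochs(patterns.n_patterns, patterns.n_synapses)
    lam = 1.0 if math.isinf(cache.tau) else math.exp(-1.0 / cache.tau)
    (l, s, K, T, epochs, converged, n_cons, M_pers, M_maint, M_change,
     ep_updates, ep_maint, ep_cons, ep_ncons) = _kernels.cached_perceptron_loop(
        X,
        d,
        cfg.eta,
        max_epochs,
        cache.theta,
        lam,
        _MODES[cache.mode],
        costs.c,
        costs.b,
        costs.alpha,
        costs.potentiation_only,
        cfg.order == "shuffled",
        cfg.seed % 2**32,
    )
    ledger = EnergyLedger(M_persistent=M_pers, M_maintenance=M_maint, M_change=M_change, K=K, T=T)
    return TrainResult(
        converged=converged,
        epochs_used=epochs,
        T=T,
        K=K,
        initial_weights=np.zeros(patterns.n_weights),
        final_weights=l + s,
        ledger=ledger,
        n_consolidations=n_cons,
        epoch_log={
            "updates": ep_updates[:epochs],
            "maintenance_energy": ep_maint[:epochs],
            "consolidation_energy": ep_cons[:epochs],
            "n_consolidations": ep_ncons[:epochs],
        },
    )


def optimize_threshold(
    patterns: PatternSet | Sequence[PatternSet],
    cfg: TrainConfig,
    costs: CostParams,
    thetas: Sequence[float],
    cache: CacheParams = CacheParams(),
):
    """Scan consolidation thresholds and return the energy-optimal one.

    ``patterns`` may be a single :class:`PatternSet` (each seed then only
    reshuffles the presentation order) or one set per seed.  Runs that do
    not converge are excluded from the energy averages; the per-θ exclusion
    count is reported.  Returns ``(theta_star, table)`` where the table has
    one row per θ with mean total energy, mean learning time, convergence
    rate and exclusion count over the converged runs.
    """
    thetas = list(thetas)
    if not thetas:
        raise ValueError("threshold grid must be non-empty")
    if isinstance(patterns, PatternSet):
        pattern_sets = [patterns]
    else:
        pattern_sets = list(patterns)
    rows = []
    for theta in thetas:
        energies, times, n_conv = [], [], 0
        for k, pset in enumerate(pattern_sets):
            run_cfg = replace(cfg, seed=cfg.seed + k)
            res = train_cached_perceptron(
                pset, run_cfg, costs, replace(cache, theta=theta)
            )
            if res.converged:
                n_conv += 1
                energies.append(res.ledger.M_total)
                times.append(res.T)
        rows.append(
            {
                "theta": theta,
                "mean_energy": float(np.mean(energies)) if energies else math.nan,
                "mean_T": float(np.mean(times)) if times else math.nan,
                "convergence_rate": n_conv / len(pattern_sets),
                "n_excluded": len(pattern_sets) - n_conv,
            }
        )
    table = pd.DataFrame(rows)
    if table["mean_energy"].isna().all():
        raise RuntimeError("no threshold in the grid produced a converged run")
    theta_star = float(table.loc[table["mean_energy"].idxmin(), "theta"])
    return theta_star, table
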