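"""Named experiment drivers with reproducibility manifests.

Each experiment is a deterministic function of its configuration: it writes
a CSV of results plus a JSON manifest holding the parameters, seeds,
package version and wall time, so every output file is regenerable from its
manifest alone.  Configurations are flat YAML/JSON mappings validated
against a per-experiment schema; unknown keys are errors (typos in sweep
definitions should fail loudly).
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, theory
from .caching import CacheParams, optimize_threshold, train_cached_perceptron
from .energy import CostParams
from .mlp import train_mlp
from .patterns import generate_pattern_set, generate_synthetic_digits, read_idx
from .perceptron import TrainConfig, train_perceptron

__all__ = ["run_experiment", "load_config", "EXPERIMENTS"]


def load_config(path) -> dict:
    """Read a YAML (or JSON — a YAML subset) experiment configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _validate(cfg: dict, schema: dict) -> dict:
    unknown = set(cfg) - set(schema) - {"experiment", "out_dir"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(schema)
    merged.update({k: v for k, v in cfg.items() if k not in ("experiment", "out_dir")})
    return merged


def _seeds(spec) -> list[int]:
    if isinstance(spec, int):
        return list(range(spec))
    return [int(s) for s in spec]


def _costs(p: dict) -> CostParams:
    return CostParams(
        alpha=p.get("alpha", 1.0),
        c=p.get("cost_c", 0.0),
        b=p.get("cost_b", 0.0),
        potentiation_only=p.get("potentiation_only", False),
    )


def _fig1_inefficiency(p: dict) -> pd.DataFrame:
    n = p["n"]
    rows = []
    for load in p["loads"]:
        n_patterns = int(round(load * n))
        for seed in _seeds(p["seeds"]):
            pats = generate_pattern_set(n, n_patterns, seed)
            res = train_perceptron(pats, TrainConfig(eta=p["eta"], seed=seed), _costs(p))
            m_min = float(np.abs(res.final_weights).sum())
            rows.append(
                {
                    "load": load,
                    "n": n,
                    "p": n_patterns,
                    "seed": seed,
                    "converged": res.converged,
                    "epochs": res.epochs_used,
                    "T": res.T,
                    "K": res.K,
                    "M_actual": res.ledger.M_total,
                    "M_min": m_min,
                    "inefficiency": res.ledger.M_total / m_min if m_min else math.nan,
                    "inefficiency_theory": theory.perceptron_inefficiency(n_patterns, n),
                }
            )
    return pd.DataFrame(rows)


def _fig2_threshold_scan(p: dict) -> pd.DataFrame:
    rows = []
    cache = CacheParams(tau=p["tau"], mode=p["mode"])
    for theta in p["thetas"]:
        for seed in _seeds(p["seeds"]):
            pats = generate_pattern_set(p["n"], p["p"], seed)
            res = train_cached_perceptron(
                pats, TrainConfig(eta=p["eta"], seed=seed), _costs(p),
                replace(cache, theta=theta),
            )
            rows.append(
                {
                    "theta": theta,
                    "seed": seed,
                    "converged": res.converged,
                    "T": res.T,
                    "K": res.K,
                    "n_consolidations": res.n_consolidations,
                    "M_persistent": res.ledger.M_persistent,
                    "M_maintenance": res.ledger.M_maintenance,
                    "M_change": res.ledger.M_change,
                    "M_total": res.ledger.M_total,
                    "M_min": float(np.abs(res.final_weights).sum()),
                }
            )
    return pd.DataFrame(rows)


def _fig3_decay_sweep(p: dict) -> pd.DataFrame:
    rows = []
    for tau in p["taus"]:
        for cost_c in p["costs_c"]:
            costs = CostParams(alpha=p.get("alpha", 1.0), c=cost_c, b=p.get("cost_b", 0.0))
            pattern_sets = [generate_pattern_set(p["n"], p["p"], s) for s in _seeds(p["seeds"])]
            theta_star, table = optimize_threshold(
                pattern_sets, TrainConfig(eta=p["eta"]), costs, p["thetas"],
                CacheParams(tau=tau, mode=p.get("mode", "global-any")),
            )
            best = table.loc[table["theta"] == theta_star].iloc[0]
            rows.append(
                {
                    "tau": tau,
                    "decay_rate": 0.0 if math.isinf(tau) else 1.0 / tau,
                    "cost_c": cost_c,
                    "theta_star": theta_star,
                    "mean_energy": best["mean_energy"],
                    "mean_T": best["mean_T"],
                    "convergence_rate": best["convergence_rate"],
                }
            )
    return pd.DataFrame(rows)


def _fig4_variants(p: dict) -> pd.DataFrame:
    rows = []
    for cost_c in p["costs_c"]:
        costs = CostParams(alpha=p.get("alpha", 1.0), c=cost_c)
        for mode in ("local", "global-any", "global-sum"):
            thetas = np.asarray(p["thetas"], dtype=float)
            if mode == "global-sum":
                thetas = thetas * (p.get("sum_scale") or p["n"])
            pattern_sets = [generate_pattern_set(p["n"], p["p"], s) for s in _seeds(p["seeds"])]
            theta_star, table = optimize_threshold(
                pattern_sets, TrainConfig(eta=p["eta"]), costs, list(thetas),
                CacheParams(tau=p.get("tau", math.inf), mode=mode),
            )
            best = table.loc[table["theta"] == theta_star].iloc[0]
            rows.append(
                {
                    "cost_c": cost_c,
                    "mode": mode,
                    "theta_star": theta_star,
                    "mean_energy": best["mean_energy"],
                    "mean_T": best["mean_T"],
                }
            )
    return pd.DataFrame(rows)


def _fig5_mlp(p: dict) -> pd.DataFrame:
    if p.get("idx_dir"):
        base = Path(p["idx_dir"])
        data = read_idx(base / "train-images-idx3-ubyte", base / "train-labels-idx1-ubyte")
        test = read_idx(base / "t10k-images-idx3-ubyte", base / "t10k-labels-idx1-ubyte")
    else:
        data = generate_synthetic_digits(
            10, p.get("n_per_class", 100), p.get("side", 8), p.get("noise_sd", 0.2),
            seed=p.get("data_seed", 0),
        )
        test = generate_synthetic_digits(
            10, p.get("n_test_per_class", 50), p.get("side", 8), p.get("noise_sd", 0.2),
            seed=p.get("data_seed", 0) + 1, prototype_seed=p.get("data_seed", 0),
        )
    cache = None
    if p.get("theta") is not None:
        cache = CacheParams(theta=p["theta"], tau=p.get("tau", math.inf))
    frames = []
    for seed in _seeds(p["seeds"]):
        _, curve = train_mlp(
            data, test, n_hidden=p.get("hidden", 100), eta=p["eta"],
            epochs=p.get("epochs", 20), costs=_costs(p), cache=cache,
            eval_every=p.get("eval_every"), seed=seed,
        )
        curve.insert(0, "seed", seed)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)


def _fig6_power(p: dict) -> pd.DataFrame:
    costs = _costs(p)
    frames = []
    for seed in _seeds(p["seeds"]):
        pats = generate_pattern_set(p["n"], p["p"], seed)
        res = train_cached_perceptron(
            pats, TrainConfig(eta=p["eta"], seed=seed), costs,
            CacheParams(theta=p["theta"], tau=p["tau"], mode=p.get("mode", "global-any")),
        )
        log = res.epoch_log
        n_weights = pats.n_weights
        upd_rate = log["updates"] / p["p"]
        m_trans_th = np.zeros_like(upd_rate)
        m_cons_th = np.zeros_like(upd_rate)
        for i, pr in enumerate(upd_rate):
            m_trans_th[i], m_cons_th[i] = theory.powers(
                costs.c, n_weights, pr, p["eta"], p["tau"], p["theta"]
            )
        frames.append(
            pd.DataFrame(
                {
                    "seed": seed,
                    "epoch": np.arange(1, res.epochs_used + 1),
                    "update_rate": upd_rate,
                    "maintenance_power_sim": log["maintenance_energy"] / p["p"],
                    "consolidation_power_sim": log["consolidation_energy"] / p["p"],
                    "maintenance_power_theory": m_trans_th,
                    "consolidation_power_theory": m_cons_th,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


EXPERIMENTS = {
    "fig1-inefficiency": (
        _fig1_inefficiency,
        {"n": 200, "loads": [0.5, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8], "eta": 1.0, "seeds": 5,
         "alpha": 1.0, "potentiation_only": False},
    ),
    "fig2-threshold-scan": (
        _fig2_threshold_scan,
        {"n": 1000, "p": 1000, "eta": 1.0, "thetas": [1, 2, 5, 10, 20, 50, 100],
         "tau": math.inf, "mode": "global-any", "seeds": 5, "alpha": 1.0,
         "cost_c": 0.001, "cost_b": 0.0, "potentiation_only": False},
    ),
    "fig3-decay-sweep": (
        _fig3_decay_sweep,
        {"n": 500, "p": 500, "eta": 1.0, "thetas": [1, 2, 5, 10, 20, 50],
         "taus": [math.inf, 10000, 3000, 1000, 300], "costs_c": [0.0, 0.001, 0.01],
         "mode": "global-any", "seeds": 3, "alpha": 1.0, "cost_b": 0.0},
    ),
    "fig4-variants": (
        _fig4_variants,
        {"n": 500, "p": 500, "eta": 1.0, "thetas": [1, 2, 4, 8, 16, 32, 64],
         "tau": math.inf, "costs_c": [0.0, 0.001, 0.01], "seeds": 3, "alpha": 1.0,
         "sum_scale": None},
    ),
    "fig5-mlp": (
        _fig5_mlp,
        {"idx_dir": None, "hidden": 100, "eta": 0.1, "epochs": 20, "seeds": 1,
         "theta": None, "tau": math.inf, "alpha": 1.0, "cost_c": 0.0, "cost_b": 0.0,
         "potentiation_only": False, "eval_every": None, "n_per_class": 100,
         "n_test_per_class": 50, "side": 8, "noise_sd": 0.2, "data_seed": 0},
    ),
    "fig6-power": (
        _fig6_power,
        {"n": 1000, "p": 1000, "eta": 1.0, "theta": 5.0, "tau": 500.0,
         "cost_c": 0.01, "cost_b": 0.0, "alpha": 1.0, "mode": "global-any",
         "seeds": 3, "potentiation_only": False},
    ),
}


def run_experiment(config: dict | str | Path, out_dir=None) -> Path:
    """Run a named experiment and write ``<name>.csv`` plus a JSON manifest.

    ``config`` is a mapping (or path to a YAML/JSON file) with an
    ``experiment`` key naming one of ``EXPERIMENTS`` and experiment-specific
    parameters; unknown keys are rejected.  Returns the CSV path.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    name = config.get("experiment")
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    func, schema = EXPERIMENTS[name]
    params = _validate(config, schema)
    out_dir = Path(out_dir if out_dir is not None else config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    df = func(params)
    wall = time.time() - t0
    csv_path = out_dir / f"{name}.csv"
    df.to_csv(csv_path, index=False)
    manifest = {
        "experiment": name,
        "parameters": {k: (str(v) if isinstance(v, float) and math.isinf(v) else v)
                       for k, v in params.items()},
        "seeds": _seeds(params["seeds"]) if "seeds" in params else [],
        "version": __version__,
        "wall_time_s": round(wall, 3),
    }
    (out_dir / f"{name}.manifest.json").write_text(json.dumps(manifest, indent=2))
    return csv_path
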