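"""Closed-form predictions for perceptron energy and the transient-weight process.

Scaling laws (random-walk approximation of perceptron learning below the
critical capacity P = 2N):

* updates       K = 2P / (2 − P/N)²
* presentations T = P^{3/2} / (2 − P/N)²
* path energy   M = N K η  (α = 1)
* minimal energy  M_min = √(2/π) η N √K
* inefficiency  M / M_min = √(πP) / (2 − P/N)

Caching (no decay): optimal threshold θ̂ = η√(3K/(1+cT)) and cached
inefficiency min(√(2π(1+cT)/3), √(πK/2)).

With decay, the transient weight of a synapse performs a random walk
(update variance σ_s² = pη² per step, p the update probability) with
exponential decay (time constant τ), absorbed at ±θ and re-inserted at 0.
Its quasi-stationary density solves the Fokker–Planck equation

    0 = (1/τ) ∂_s [s P(s)] + (σ_s²/2) ∂²_s P(s) + r δ(s),  P(±θ) = 0,

whose solution is P(s) = (1/Z) e^{−s²/σ²} [erfi(θ/σ) − erfi(|s|/σ)] with
σ² = τ σ_s².  The normalization Z has a closed form in the generalized
hypergeometric ₂F₂; the mean |s| and the boundary flux (consolidation rate
r) follow in closed form, giving the maintenance power m_trans = cN⟨|s|⟩
and consolidation power m_cons = Nθr.  A vectorized Monte-Carlo of the
decay/update/reset process is provided as an independent check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import mpmath
import numpy as np
from scipy import integrate, special

__all__ = [
    "K_theory",
    "T_theory",
    "perceptron_inefficiency",
    "minimal_energy_theory",
    "optimal_threshold",
    "cached_inefficiency",
    "steady_state_density",
    "normalization_Z",
    "normalization_Z_quadrature",
    "mean_abs_transient",
    "consolidation_rate",
    "powers",
    "SteadyState",
    "steady_state",
    "WalkResult",
    "simulate_reset_walk",
    "simulate_two_threshold_walk",
    "ks_distance",
]


def _check_load(P: float, N: float) -> float:
    if P <= 0 or N <= 0:
        raise ValueError("P and N must be positive")
    load = P / N
    if load >= 2.0:
        raise ValueError("P/N must be below the critical capacity 2 (learning time diverges)")
    return load


def K_theory(P: float, N: float) -> float:
    """Expected total number of updates: 2P/(2 − P/N)²."""
    load = _check_load(P, N)
    return 2.0 * P / (2.0 - load) ** 2


def T_theory(P: float, N: float) -> float:
    """Expected number of pattern presentations: P^{3/2}/(2 − P/N)²."""
    load = _check_load(P, N)
    return P**1.5 / (2.0 - load) ** 2


def perceptron_inefficiency(P: float, N: float) -> float:
    """Energy ÷ minimal energy for plain perceptron learning: √(πP)/(2 − P/N).

    Algebraically equal to √(π/2)·√K_theory.
    """
    load = _check_load(P, N)
    return math.sqrt(math.pi * P) / (2.0 - load)


def minimal_energy_theory(N: float, K: float, eta: float = 1.0) -> float:
    """Random-walk estimate of the minimal energy: √(2/π)·η·N·√K."""
    if N <= 0 or K <= 0 or eta <= 0:
        raise ValueError("N, K and eta must be positive")
    return math.sqrt(2.0 / math.pi) * eta * N * math.sqrt(K)


def optimal_threshold(eta: float, K: float, c: float, T: float) -> float:
    """Energy-optimal consolidation threshold θ̂ = η√(3K/(1+cT)), floored at η.

    Below η every update would consolidate immediately anyway, so the
    analytic optimum is clipped there.
    """
    if eta <= 0 or K <= 0 or T <= 0:
        raise ValueError("eta, K and T must be positive")
    if c < 0:
        raise ValueError("c must be non-negative")
    return max(eta, eta * math.sqrt(3.0 * K / (1.0 + c * T)))


def cached_inefficiency(c: float, T: float, K: float) -> float:
    """Cached energy ÷ minimal energy: min(√(2π(1+cT)/3), √(πK/2)).

    The second branch is the plain-perceptron inefficiency: consolidation
    can occur at most once per time step, so caching never costs more than
    consolidating every update.
    """
    if K <= 0 or T <= 0:
        raise ValueError("K and T must be positive")
    if c < 0:
        raise ValueError("c must be non-negative")
    return min(math.sqrt(2.0 * math.pi * (1.0 + c * T) / 3.0), math.sqrt(math.pi * K / 2.0))


# ---------------------------------------------------------------------------
# Fokker-Planck steady state of the decaying, resetting transient weight
# ---------------------------------------------------------------------------


# For θ/σ beyond this the closed forms are evaluated in a scaled form
# (everything divided by the huge erfi(θ/σ)); below it, directly.
_A_BIG = 20.0


def _check_scales(sigma: float, theta: float) -> float:
    if sigma <= 0 or theta <= 0:
        raise ValueError("sigma and theta must be positive")
    return theta / sigma


def _log_erfi(a: float) -> float:
    if a <= 25.0:
        return math.log(special.erfi(a))
    # erfi(a) ~ e^{a^2}/(a sqrt(pi)) (1 + 1/(2a^2) + 3/(4a^4) + ...)
    return a * a - math.log(a * math.sqrt(math.pi)) + math.log1p(0.5 / a**2 + 0.75 / a**4)


def _z_ratio(sigma: float, theta: float) -> float:
    """Z / erfi(θ/σ): finite for any θ/σ."""
    a = theta / sigma
    if a <= _A_BIG:
        return normalization_Z(sigma, theta) / special.erfi(a)
    # the 2F2 term is O(log a · e^{-a^2}) relative: below double precision
    return math.sqrt(math.pi) * sigma * special.erf(a)


def _unnormalized_density(s, sigma: float, theta: float):
    a = np.abs(np.asarray(s, dtype=np.float64))
    return np.exp(-(a / sigma) ** 2) * (special.erfi(theta / sigma) - special.erfi(a / sigma))


def _scaled_unnormalized_density(s, sigma: float, theta: float):
    """Unnormalized density divided by erfi(θ/σ), stable for any θ/σ.

    Uses e^{−x²} erfi(x) = (2/√π) dawsn(x) to avoid the exploding erfi.
    """
    a = theta / sigma
    x = np.abs(np.asarray(s, dtype=np.float64)) / sigma
    inv_erfi = math.exp(-_log_erfi(a)) if _log_erfi(a) < 709 else 0.0
    vals = np.exp(-(x**2)) - 2.0 / math.sqrt(math.pi) * special.dawsn(x) * inv_erfi
    return np.where(x >= a, 0.0, np.maximum(vals, 0.0))


def normalization_Z(sigma: float, theta: float) -> float:
    """Closed-form normalization of the steady-state density.

    Z = √π σ erf(a) erfi(a) − (2θ²/(√π σ)) ₂F₂(1,1;3/2,2;−a²), a = θ/σ.
    The ₂F₂ term is evaluated with mpmath (arbitrary precision), which
    handles the large-argument cancellation; quadrature of the
    unnormalized density is available as a permanent cross-check.  For
    θ/σ ≳ 26 the value exceeds the double-precision range and an
    OverflowError is raised — the density, ⟨|s|⟩ and rate functions use a
    scaled representation internally and remain usable there.
    """
    a = _check_scales(sigma, theta)
    if a > _A_BIG:
        log_z = math.log(math.sqrt(math.pi) * sigma * special.erf(a)) + _log_erfi(a)
        if log_z > 709.0:
            raise OverflowError(
                f"Z(sigma={sigma}, theta={theta}) ~ exp({log_z:.1f}) exceeds double range"
            )
        return math.exp(log_z)
    f = float(mpmath.hyp2f2(1, 1, 1.5, 2, -(a * a)))
    z = (
        math.sqrt(math.pi) * sigma * special.erf(a) * special.erfi(a)
        - 2.0 * theta**2 / (math.sqrt(math.pi) * sigma) * f
    )
    if not np.isfinite(z) or z <= 0:
        raise ArithmeticError(f"normalization evaluation failed: Z={z}")
    return float(z)


def normalization_Z_quadrature(sigma: float, theta: float) -> float:
    """Numeric integration of the unnormalized density over (−θ, θ)."""
    _check_scales(sigma, theta)
    z, _ = integrate.quad(lambda s: _unnormalized_density(s, sigma, theta), -theta, theta, limit=400)
    return float(z)


def steady_state_density(s, sigma: float, theta: float):
    """Steady-state density P(s) = (1/Z)·e^{−s²/σ²}·[erfi(θ/σ) − erfi(|s|/σ)].

    Defined on (−θ, θ); vanishes at ±θ; symmetric in s.  σ is the diffusion
    scale σ² = τσ_s².  Raises for |s| > θ.
    """
    a = _check_scales(sigma, theta)
    s_arr = np.asarray(s, dtype=np.float64)
    if np.any(np.abs(s_arr) > theta):
        raise ValueError("density is only defined on [-theta, theta]")
    if a <= _A_BIG:
        out = _unnormalized_density(s_arr, sigma, theta) / normalization_Z(sigma, theta)
    else:
        out = _scaled_unnormalized_density(s_arr, sigma, theta) / _z_ratio(sigma, theta)
    if np.isscalar(s) or s_arr.ndim == 0:
        return float(out)
    return out


def steady_state_cdf(sigma: float, theta: float, n: int = 4001):
    """Grid and CDF of the steady-state density (for KS comparisons)."""
    grid = np.linspace(-theta, theta, n)
    u = _scaled_unnormalized_density(grid, sigma, theta)
    cdf = integrate.cumulative_trapezoid(u, grid, initial=0.0)
    cdf /= cdf[-1]
    return grid, cdf


def mean_abs_transient(sigma: float, theta: float) -> float:
    """⟨|s|⟩ under the steady state: [σ² erfi(θ/σ) − 2θσ/√π] / Z.

    Tends to θ/3 (the triangular distribution) as θ/σ → 0 and saturates at
    the half-normal mean σ/√π for large θ/σ.
    """
    a = _check_scales(sigma, theta)
    if a <= _A_BIG:
        num = sigma**2 * special.erfi(a) - 2.0 * theta * sigma / math.sqrt(math.pi)
        return float(num / normalization_Z(sigma, theta))
    inv_erfi = math.exp(-_log_erfi(a)) if _log_erfi(a) < 709 else 0.0
    num_scaled = sigma**2 - 2.0 * theta * sigma / math.sqrt(math.pi) * inv_erfi
    return float(num_scaled / _z_ratio(sigma, theta))


def consolidation_rate(sigma: float, theta: float, tau: float = 1.0) -> float:
    """Consolidation (reset) rate per synapse per time step.

    Fick's law at the absorbing boundaries gives the outgoing flux
    r = 2σ_s²/(√π σ Z) with σ_s² = σ²/τ; the no-decay limit is σ_s²/θ².
    In the decay-dominated regime (large θ/σ) the threshold is essentially
    never reached and the rate underflows to zero.
    """
    a = _check_scales(sigma, theta)
    if tau <= 0:
        raise ValueError("tau must be positive")
    sigma_s2 = sigma**2 / tau
    pref = 2.0 * sigma_s2 / (math.sqrt(math.pi) * sigma * _z_ratio(sigma, theta))
    log_r = math.log(pref) - _log_erfi(a)
    return math.exp(log_r) if log_r > -745.0 else 0.0


def powers(c: float, N: float, p: float, eta: float, tau: float, theta: float):
    """Maintenance and consolidation power (energy per time step).

    m_trans = cN⟨|s|⟩ and m_cons = Nθr, with the steady state determined by
    the update probability p via σ_s² = pη² and σ² = τσ_s².  For small θ/σ
    (weak decay) m_trans ≈ cNθ/3 and m_cons ≈ pNη²/θ.
    """
    if p < 0 or p > 1:
        raise ValueError("update probability p must be in [0, 1]")
    if p == 0:
        return 0.0, 0.0
    sigma = math.sqrt(tau * p) * eta
    m_trans = c * N * mean_abs_transient(sigma, theta)
    m_cons = N * theta * consolidation_rate(sigma, theta, tau)
    return float(m_trans), float(m_cons)


@dataclass(frozen=True)
class SteadyState:
    """Analytic steady state of the transient-weight process."""

    p: float
    eta: float
    tau: float
    theta: float
    sigma_s2: float
    sigma: float
    Z: float
    mean_abs: float
    rate: float
    m_trans: float
    m_cons: float

    def density(self, s):
        return steady_state_density(s, self.sigma, self.theta)


def steady_state(p: float, eta: float, tau: float, theta: float, c: float = 0.0,
                 N: float = 1.0) -> SteadyState:
    """Bundle the analytic solution for given process parameters."""
    if p <= 0 or p > 1:
        raise ValueError("update probability p must be in (0, 1]")
    sigma_s2 = p * eta**2
    sigma = math.sqrt(tau * sigma_s2)
    z = normalization_Z(sigma, theta)
    mean_abs = mean_abs_transient(sigma, theta)
    rate = consolidation_rate(sigma, theta, tau)
    return SteadyState(
        p=p, eta=eta, tau=tau, theta=theta, sigma_s2=sigma_s2, sigma=sigma, Z=z,
        mean_abs=mean_abs, rate=rate, m_trans=c * N * mean_abs, m_cons=N * theta * rate,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo oracles
# ---------------------------------------------------------------------------


@dataclass
class WalkResult:
    """Summary of a Monte-Carlo run of the decay/update/reset process."""

    samples: np.ndarray
    mean_abs: float
    mean_abs_se: float
    rate: float
    rate_se: float
    n_resets: int
    n_steps: int


def simulate_reset_walk(
    sigma: float,
    theta: float,
    tau: float = 200.0,
    n_walkers: int = 25_000,
    n_burn: int | None = None,
    n_record: int = 40,
    seed: int = 0,
) -> WalkResult:
    """Monte-Carlo of the Gaussian-increment / decay / reset process.

    An ensemble of walkers evolves with the exact Ornstein–Uhlenbeck
    transition per unit time step (decay e^{−1/τ}, Gaussian forcing with
    stationary variance σ²/2), is absorbed at ±θ — including within-step
    crossings, detected with a Brownian-bridge correction — and re-inserted
    at 0.  After burn-in (default 12τ), ``n_record`` consecutive steps are
    recorded from every walker.  Standard errors are computed across
    walkers, which are independent.
    """
    if sigma <= 0 or theta <= 0 or tau <= 0:
        raise ValueError("sigma, theta, tau must be positive")
    if n_burn is None:
        n_burn = int(12 * tau)
    rng = np.random.default_rng(seed)
    lam = math.exp(-1.0 / tau)
    sd_free = math.sqrt(sigma**2 / 2.0 * (1.0 - lam * lam))
    v_bridge = sigma**2 / tau  # short-time increment variance per step
    s = np.zeros(n_walkers)
    samples = np.empty((n_record, n_walkers))
    abs_sum = np.zeros(n_walkers)
    resets = np.zeros(n_walkers, dtype=np.int64)
    for t in range(n_burn + n_record):
        s_new = s * lam + rng.normal(0.0, sd_free, n_walkers)
        crossed = np.abs(s_new) >= theta
        inside = ~crossed
        s0, s1 = s[inside], s_new[inside]
        p_up = np.exp(-2.0 * (theta - s0) * (theta - s1) / v_bridge)
        p_dn = np.exp(-2.0 * (theta + s0) * (theta + s1) / v_bridge)
        crossed[inside] = rng.random(s0.size) < np.clip(p_up + p_dn, 0.0, 1.0)
        s_new[crossed] = 0.0
        s = s_new
        if t >= n_burn:
            k = t - n_burn
            samples[k] = s
            abs_sum += np.abs(s)
            resets += crossed
    per_walker_mean = abs_sum / n_record
    mean_abs = float(per_walker_mean.mean())
    mean_abs_se = float(per_walker_mean.std(ddof=1) / math.sqrt(n_walkers))
    per_walker_rate = resets / n_record
    rate = float(per_walker_rate.mean())
    rate_se = float(per_walker_rate.std(ddof=1) / math.sqrt(n_walkers))
    return WalkResult(
        samples=samples.ravel(),
        mean_abs=mean_abs,
        mean_abs_se=mean_abs_se,
        rate=rate,
        rate_se=rate_se,
        n_resets=int(resets.sum()),
        n_steps=n_record * n_walkers,
    )


def simulate_two_threshold_walk(
    eta: float = 1.0,
    theta: float = 20.0,
    p: float = 1.0,
    n_walkers: int = 100,
    n_steps: int = 10_000,
    burn_frac: float = 0.2,
    seed: int = 0,
):
    """No-decay ±η random walk between ±θ with reset to 0.

    Returns the time- and ensemble-averaged ⟨|s|⟩ after burn-in.  In the
    θ/η → ∞ limit the stationary distribution is triangular and
    ⟨|s|⟩/θ → 1/3 (exactly (1 − (η/θ)²)/3 on the lattice).
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    rng = np.random.default_rng(seed)
    s = np.zeros(n_walkers)
    n_burn = int(burn_frac * n_steps)
    total = 0.0
    count = 0
    for t in range(n_steps):
        step = rng.choice((-eta, 0.0, eta), size=n_walkers, p=(p / 2, 1 - p, p / 2))
        s = s + step
        s[np.abs(s) >= theta] = 0.0
        if t >= n_burn:
            total += np.abs(s).sum()
            count += n_walkers
    return total / count


def ks_distance(samples, sigma: float, theta: float) -> float:
    """Kolmogorov–Smirnov distance between samples and the analytic density."""
    srt = np.sort(np.asarray(samples, dtype=np.float64))
    grid, cdf = steady_state_cdf(sigma, theta)
    f = np.interp(srt, grid, cdf)
    n = srt.size
    up = np.abs(f - np.arange(1, n + 1) / n).max()
    dn = np.abs(f - np.arange(n) / n).max()
    return float(max(up, dn))
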