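import math

import numpy as np
import pytest

from syncache import (
    CachedState,
    CacheParams,
    CostParams,
    TrainConfig,
    check_trigger,
    consolidate,
    decay_step,
    generate_pattern_set,
    optimize_threshold,
    train_cached_perceptron,
    train_perceptron,
)


class TestDecay:
    def test_no_decay_limit(self):
        s = np.array([0.5, -2.0])
        assert np.array_equal(decay_step(s, math.inf), s)

    def test_single_step_factor(self):
        assert decay_step(np.array([1.0]), 1.0)[0] == pytest.approx(math.exp(-1.0))

    def test_semigroup_property(self):
        s = np.array([3.0, -1.5])
        out = s.copy()
        for _ in range(40):
            out = decay_step(out, 500.0)
        assert out == pytest.approx(s * math.exp(-40 / 500.0), rel=1e-12)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            decay_step(np.array([1.0]), 0.0)


class TestTrigger:
    @pytest.mark.parametrize(
        "s, theta, mode, fire, idx",
        [
            ((1.2, 0.4), 1.0, "global-any", True, 0),
            ((0.6, 0.6), 1.0, "global-sum", True, None),
            ((0.6, 0.6), 1.0, "local", False, 0),
            ((0.5, -1.0), 1.0, "local", True, 1),  # >= fires at exact threshold
        ],
    )
    def test_variants(self, s, theta, mode, fire, idx):
        got_fire, got_idx = check_trigger(np.array(s, dtype=float), theta, mode)
        assert got_fire == fire
        if fire and mode != "global-sum":
            assert got_idx == idx

    def test_tie_breaks_to_lowest_index(self):
        fire, idx = check_trigger(np.array([2.0, -2.0]), 1.0, "global-any")
        assert fire and idx == 0


class TestConsolidate:
    def test_global_transfer(self):
        state = CachedState(s=np.array([0.3, -0.2]), l=np.array([1.0, 0.5]),
                            theta=0.25, mode="global-any")
        new, dl = consolidate(state)
        assert np.allclose(new.l, [1.3, 0.3]) and np.all(new.s == 0.0)
        assert np.abs(dl).sum() == pytest.approx(0.5)

    def test_effective_weight_conserved(self):
        rng = np.random.default_rng(0)
        for mode in ("local", "global-any", "global-sum"):
            s = rng.normal(size=8) * 2
            l = rng.normal(size=8)
            state = CachedState(s=s.copy(), l=l.copy(), theta=1.0, mode=mode)
            new, _ = consolidate(state)
            assert np.allclose(new.s + new.l, s + l)

    def test_local_transfers_only_crossing_synapse(self):
        state = CachedState(s=np.array([0.3, -1.0]), l=np.zeros(2), theta=1.0, mode="local")
        new, dl = consolidate(state, crossing_index=1)
        assert np.allclose(new.s, [0.3, 0.0])
        assert np.allclose(new.l, [0.0, -1.0])

    def test_unfired_trigger_rejected(self):
        state = CachedState(s=np.array([0.1]), l=np.zeros(1), theta=1.0)
        with pytest.raises(ValueError):
            consolidate(state)


class TestDegenerateLimits:
    """Limits in which caching must reproduce plain training exactly."""

    def test_low_threshold_equals_plain_energy(self, small_patterns):
        plain = train_perceptron(small_patterns)
        for mode in ("local", "global-any"):
            cached = train_cached_perceptron(
                small_patterns, cache=CacheParams(theta=1.0, mode=mode)
            )
            assert cached.ledger.M_total == plain.ledger.M_total
            assert cached.K == plain.K and cached.T == plain.T

    def test_infinite_threshold_attains_minimal_energy(self, small_patterns):
        plain = train_perceptron(small_patterns)
        cached = train_cached_perceptron(small_patterns, cache=CacheParams(theta=math.inf))
        assert cached.ledger.M_total == np.abs(plain.final_weights).sum()
        assert cached.n_consolidations == 1

    def test_no_decay_trajectory_matches_plain(self, small_patterns):
        """Caching without decay changes bookkeeping, not learning dynamics."""
        plain = train_perceptron(small_patterns)
        for theta in (3.0, 10.0, math.inf):
            cached = train_cached_perceptron(small_patterns, cache=CacheParams(theta=theta))
            assert np.allclose(cached.final_weights, plain.final_weights)
            assert cached.K == plain.K and cached.T == plain.T

    def test_ledger_decomposes_and_is_nonnegative(self, small_patterns):
        res = train_cached_perceptron(
            small_patterns,
            costs=CostParams(c=0.01, b=0.1),
            cache=CacheParams(theta=5.0, tau=200.0),
        )
        led = res.ledger
        assert led.M_persistent >= 0 and led.M_maintenance >= 0 and led.M_change >= 0
        assert led.M_total == pytest.approx(led.M_persistent + led.M_maintenance + led.M_change)

    def test_caching_disabled_costs_leave_no_transient_terms(self, small_patterns):
        res = train_perceptron(small_patterns, costs=CostParams(c=0.5, b=0.5))
        assert res.ledger.M_maintenance == 0.0 and res.ledger.M_change == 0.0


class TestEnergyShapes:
    def test_free_transience_makes_energy_nonincreasing_in_theta(self):
        pats = [generate_pattern_set(100, 100, seed=s) for s in range(3)]
        thetas = [1.0, 3.0, 10.0, 30.0]
        theta_star, table = optimize_threshold(
            pats, TrainConfig(), CostParams(c=0.0), thetas, CacheParams()
        )
        energies = table["mean_energy"].to_numpy()
        assert np.all(np.diff(energies) <= 1e-9)
        assert theta_star == thetas[-1]

    def test_high_maintenance_prefers_immediate_consolidation(self):
        pats = [generate_pattern_set(100, 100, seed=s) for s in range(3)]
        theta_star, _ = optimize_threshold(
            pats, TrainConfig(), CostParams(c=1.0), [1.0, 3.0, 10.0, 30.0], CacheParams()
        )
        assert theta_star == 1.0

    def test_u_shape_at_intermediate_maintenance(self):
        pats = [generate_pattern_set(200, 200, seed=s) for s in range(3)]
        _, table = optimize_threshold(
            pats, TrainConfig(), CostParams(c=0.005),
            [1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 150.0], CacheParams()
        )
        e = table["mean_energy"].to_numpy()
        imin = int(np.argmin(e))
        assert 0 < imin < len(e) - 1
        assert e[0] > e[imin] and e[-1] > e[imin]

    def test_unit_change_cost_never_beats_immediate_consolidation(self):
        """With b >= 1 the cheapest local-mode threshold is to consolidate every update.

        The claim is a per-synapse random-walk argument, so it is scanned in
        local trigger mode; cell-wide triggers co-consolidate sub-threshold
        synapses and can undercut it by a percent.
        """
        pats = generate_pattern_set(100, 100, seed=2)
        plain_energy = train_perceptron(pats).ledger.M_total
        for theta in (1.0, 2.0, 5.0, 20.0, math.inf):
            res = train_cached_perceptron(
                pats, costs=CostParams(b=1.0), cache=CacheParams(theta=theta, mode="local")
            )
            assert res.ledger.M_total >= plain_energy - 1e-9

    def test_strong_decay_slows_learning(self):
        """Forgetting of unconsolidated changes lengthens training markedly.

        Mild decay can even shorten training, so the check contrasts the
        no-decay limit with decay strong enough to lose transient progress.
        """
        mean_t = {}
        for tau in (math.inf, 150.0):
            ts = []
            for seed in range(5):
                pats = generate_pattern_set(150, 150, seed=seed)
                res = train_cached_perceptron(pats, cache=CacheParams(theta=8.0, tau=tau))
                assert res.converged
                ts.append(res.T)
            mean_t[tau] = np.mean(ts)
        assert mean_t[150.0] > 2 * mean_t[math.inf]

    def test_epoch_log_totals_match_ledger(self, square_patterns):
        res = train_cached_perceptron(
            square_patterns, costs=CostParams(c=0.01),
            cache=CacheParams(theta=5.0, tau=500.0),
        )
        log = res.epoch_log
        assert log["updates"].sum() == res.K
        assert log["maintenance_energy"].sum() == pytest.approx(res.ledger.M_maintenance)
        assert log["consolidation_energy"].sum() == pytest.approx(res.ledger.M_persistent)


class TestReferenceImplementation:
    def test_kernel_matches_slow_reference(self):
        """Step-by-step pure-Python replay of the cached training loop."""
        pats = generate_pattern_set(12, 10, seed=3)
        costs = CostParams(c=0.01, b=0.2)
        cache = CacheParams(theta=2.0, tau=50.0, mode="global-any")
        eta = 1.0
        X, d = pats.inputs, pats.targets
        s = np.zeros(pats.n_weights)
        l = np.zeros(pats.n_weights)
        lam = math.exp(-1.0 / cache.tau)
        M_pers = M_maint = M_change = 0.0
        K = T = 0
        for _ in range(200):
            errs = 0
            for p in range(pats.n_patterns):
                s = s * lam
                y = int((s + l) @ X[p] > 0)
                if y != d[p]:
                    delta = eta * (d[p] - y)
                    s = s + delta * X[p]
                    K += 1
                    errs += 1
                    fired, _ = check_trigger(s, cache.theta, cache.mode)
                    if fired:
                        l = l + s
                        M_pers += np.abs(s).sum()
                        s = np.zeros_like(s)
                    else:
                        M_change += costs.b * eta * pats.n_weights
                M_maint += costs.c * np.abs(s).sum()
                T += 1
            if errs == 0:
                break
        M_pers += np.abs(s).sum()
        l = l + s
        res = train_cached_perceptron(pats, TrainConfig(eta=eta), costs, cache)
        assert res.K == K and res.T == T
        assert res.ledger.M_persistent == pytest.approx(M_pers, rel=1e-12)
        assert res.ledger.M_maintenance == pytest.approx(M_maint, rel=1e-12)
        assert res.ledger.M_change == pytest.approx(M_change, rel=1e-12)
        assert np.allclose(res.final_weights, l, atol=1e-12)
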