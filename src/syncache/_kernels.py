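"""Compiled inner loops for perceptron training.

The flagship experiments present patterns ~10^7 times, so the
presentation-by-presentation loops are JIT-compiled with numba.  Both
kernels treat one pattern presentation as one time step.

The cached kernel keeps the transient vector in a lazily-scaled form
``s_true = s * g``: exponential decay multiplies only the scalar ``g`` (and
the running Σ|s| and max|s|), so presentations without an update cost O(N)
for the prediction dot product only.  ``g`` is folded back into ``s``
at every update and whenever it risks underflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# mode codes for the cached kernel
MODE_LOCAL = 0
MODE_GLOBAL_ANY = 1
MODE_GLOBAL_SUM = 2


@njit(cache=False, fastmath=True)
def plain_perceptron_loop(X, d, n_plus, eta, max_epochs, shuffle, seed):
    """Classic perceptron training on ±1 patterns.

    Returns (w, K, T, epochs, converged, n_pos) where n_pos counts the
    individual positive weight changes (for potentiation-only accounting);
    every update changes all weights by exactly ±eta because inputs are ±1.
    """
    P, M = X.shape
    w = np.zeros(M)
    order = np.arange(P)
    np.random.seed(seed)
    K = 0
    T = 0
    n_pos = 0
    epochs = 0
    converged = False
    for _ in range(max_epochs):
        if shuffle:
            np.random.shuffle(order)
        errs = 0
        for q in range(P):
            p = order[q]
            dot = 0.0
            for i in range(M):
                dot += w[i] * X[p, i]
            y = 1.0 if dot > 0.0 else 0.0
            if y != d[p]:
                delta = eta * (d[p] - y)
                for i in range(M):
                    w[i] += delta * X[p, i]
                K += 1
                errs += 1
                # sign of Delta w_i is sign(delta * x_i); x_i = +1 on n_plus[p] entries
                if delta > 0.0:
                    n_pos += n_plus[p]
                else:
                    n_pos += M - n_plus[p]
            T += 1
        epochs += 1
        if errs == 0:
            converged = True
            break
    return w, K, T, epochs, converged, n_pos


@njit(cache=False, fastmath=True)
def cached_perceptron_loop(
    X,
    d,
    eta,
    max_epochs,
    theta,
    lam,
    mode,
    c,
    b,
    alpha,
    pot_only,
    shuffle,
    seed,
):
    """Perceptron training with transient/persistent weight split.

    Per presentation: decay s; predict with w = s + l; on error add the
    perceptron update to s (b-cost, waived for synapses consolidated in the
    same step); check the consolidation trigger; consolidate (α-cost on Δl);
    charge maintenance c·Σ|s| on the end-of-step state.  On convergence the
    residual transient weight is consolidated once.

    Returns (l, s, K, T, epochs, converged, n_cons, M_pers, M_maint,
    M_change, ep_updates, ep_maint, ep_cons, ep_ncons) with per-epoch
    arrays trimmed by the caller to ``epochs`` entries.
    """
    P, M = X.shape
    l = np.zeros(M)
    s = np.zeros(M)
    g = 1.0  # lazy decay scale; true transient weight is s * g
    S1 = 0.0  # running sum of |s_true|
    smax = 0.0  # running max of |s_true|
    order = np.arange(P)
    np.random.seed(seed)
    K = 0
    T = 0
    n_cons = 0
    M_pers = 0.0
    M_maint = 0.0
    M_change = 0.0
    ep_updates = np.zeros(max_epochs)
    ep_maint = np.zeros(max_epochs)
    ep_cons = np.zeros(max_epochs)
    ep_ncons = np.zeros(max_epochs)
    epochs = 0
    converged = False
    for ep in range(max_epochs):
        if shuffle:
            np.random.shuffle(order)
        errs = 0
        for q in range(P):
            p = order[q]
            if lam < 1.0:
                g *= lam
                S1 *= lam
                smax *= lam
                if g < 1e-150:
                    for i in range(M):
                        s[i] *= g
                    g = 1.0
            dot = 0.0
            if g != 0.0 and S1 > 0.0:
                for i in range(M):
                    dot += (l[i] + s[i] * g) * X[p, i]
            else:
                for i in range(M):
                    dot += l[i] * X[p, i]
            y = 1.0 if dot > 0.0 else 0.0
            if y != d[p]:
                delta = eta * (d[p] - y)
                if g != 1.0:
                    for i in range(M):
                        s[i] *= g
                    g = 1.0
                S1 = 0.0
                smax = 0.0
                for i in range(M):
                    s[i] += delta * X[p, i]
                    a = abs(s[i])
                    S1 += a
                    if a > smax:
                        smax = a
                K += 1
                errs += 1
                ep_updates[ep] += 1.0
                fired = (S1 >= theta) if mode == MODE_GLOBAL_SUM else (smax >= theta)
                if fired:
                    n_waived = 0
                    if mode == MODE_LOCAL:
                        for i in range(M):
                            dl = s[i]
                            if abs(dl) >= theta:
                                l[i] += dl
                                s[i] = 0.0
                                n_cons += 1
                                ep_ncons[ep] += 1.0
                                n_waived += 1
                                if (not pot_only) or dl > 0.0:
                                    e = abs(dl) ** alpha
                                    M_pers += e
                                    ep_cons[ep] += e
                        S1 = 0.0
                        smax = 0.0
                        for i in range(M):
                            a = abs(s[i])
                            S1 += a
                            if a > smax:
                                smax = a
                    else:
                        for i in range(M):
                            dl = s[i]
                            if dl != 0.0:
                                l[i] += dl
                                s[i] = 0.0
                                if (not pot_only) or dl > 0.0:
                                    e = abs(dl) ** alpha
                                    M_pers += e
                                    ep_cons[ep] += e
                        S1 = 0.0
                        smax = 0.0
                        n_cons += 1
                        ep_ncons[ep] += 1.0
                        n_waived = M
                    if b > 0.0 and n_waived < M:
                        M_change += b * eta * (M - n_waived)
                elif b > 0.0:
                    M_change += b * eta * M
            if c > 0.0 and S1 > 0.0:
                m = c * S1
                M_maint += m
                ep_maint[ep] += m
            T += 1
        epochs += 1
        if errs == 0:
            converged = True
            break
    # fold the decay scale back in before returning / final consolidation
    if g != 1.0:
        for i in range(M):
            s[i] *= g
        g = 1.0
    if converged:
        # single final consolidation of the residual transient weight
        for i in range(M):
            dl = s[i]
            if dl != 0.0:
                l[i] += dl
                s[i] = 0.0
                if (not pot_only) or dl > 0.0:
                    e = abs(dl) ** alpha
                    M_pers += e
                    ep_cons[epochs - 1] += e
        n_cons += 1
        ep_ncons[epochs - 1] += 1.0
    return (
        l,
        s,
        K,
        T,
        epochs,
        converged,
        n_cons,
        M_pers,
        M_maint,
        M_change,
        ep_updates,
        ep_maint,
        ep_cons,
        ep_ncons,
    )
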