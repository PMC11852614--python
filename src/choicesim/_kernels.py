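"""Compiled inner loops for the loss evaluations.

The simplex search evaluates the compromise loss thousands of times per
simulated step; these numba kernels compute the same quantities as the numpy
implementations in :mod:`choicesim.objective` (asserted to agree in the test
suite) without per-call array-allocation overhead.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_FLOOR = np.log(1e-300)


@njit(cache=False)
def nll_kernel(w, sigma_a, n_actions, s, a_idx):  # pragma: no cover - compiled
    """Summed surprisal of recorded actions a_idx (1-based) at stimuli s."""
    n = s.shape[0]
    nw = w.shape[0] // 2
    inv2 = 1.0 / (2.0 * sigma_a * sigma_a)
    logmix = np.empty(n_actions)
    total = 0.0
    for j in range(n):
        gmax = -1.0e308
        for act in range(n_actions):
            loc = float(act + 1)
            zmax = -1.0e308
            for i in range(nw):
                m = w[2 * i] + w[2 * i + 1] * s[j]
                z = -(loc - m) * (loc - m) * inv2
                if z > zmax:
                    zmax = z
            acc = 0.0
            for i in range(nw):
                m = w[2 * i] + w[2 * i + 1] * s[j]
                z = -(loc - m) * (loc - m) * inv2
                acc += np.exp(z - zmax)
            logmix[act] = zmax + np.log(acc)
            if logmix[act] > gmax:
                gmax = logmix[act]
        norm = 0.0
        for act in range(n_actions):
            norm += np.exp(logmix[act] - gmax)
        logz = gmax + np.log(norm)
        lp = logmix[a_idx[j] - 1] - logz
        if lp < _LOG_FLOOR:
            lp = _LOG_FLOOR
        total -= lp
    return total


@njit(cache=False)
def neg_expected_reward_kernel(
    w, sigma_a, n_actions, s, s_weights, alpha, beta, bilinear
):  # pragma: no cover - compiled
    """Negative weighted expected reward of the policy at stimuli s."""
    n = s.shape[0]
    nw = w.shape[0] // 2
    inv2 = 1.0 / (2.0 * sigma_a * sigma_a)
    logmix = np.empty(n_actions)
    total = 0.0
    for j in range(n):
        gmax = -1.0e308
        for act in range(n_actions):
            loc = float(act + 1)
            zmax = -1.0e308
            for i in range(nw):
                m = w[2 * i] + w[2 * i + 1] * s[j]
                z = -(loc - m) * (loc - m) * inv2
                if z > zmax:
                    zmax = z
            acc = 0.0
            for i in range(nw):
                m = w[2 * i] + w[2 * i + 1] * s[j]
                z = -(loc - m) * (loc - m) * inv2
                acc += np.exp(z - zmax)
            logmix[act] = zmax + np.log(acc)
            if logmix[act] > gmax:
                gmax = logmix[act]
        norm = 0.0
        for act in range(n_actions):
            norm += np.exp(logmix[act] - gmax)
        expected = 0.0
        for act in range(n_actions):
            p = np.exp(logmix[act] - gmax) / norm
            loc = float(act + 1)
            if bilinear:
                mu = alpha * (loc - beta) * s[j]
            else:
                mu = alpha * loc + beta * s[j]
            expected += p * mu
        total += s_weights[j] * expected
    return -total


# objective selectors for the compiled simplex search
OBJ_CONSISTENCY = 0
OBJ_REWARD = 1
OBJ_MIXTURE = 2


@njit(cache=False)
def _objective(
    which, w, sigma_a, n_actions, s, a_idx, rs, rw, alpha, beta, bilinear, lam
):  # pragma: no cover - compiled
    # rs/rw: stimulus locations and weights of the reward expectation
    # (quadrature nodes for the prior form, window stimuli otherwise)
    if which == OBJ_CONSISTENCY:
        return nll_kernel(w, sigma_a, n_actions, s, a_idx)
    if which == OBJ_REWARD:
        return neg_expected_reward_kernel(
            w, sigma_a, n_actions, rs, rw, alpha, beta, bilinear
        )
    la = nll_kernel(w, sigma_a, n_actions, s, a_idx)
    lr = neg_expected_reward_kernel(
        w, sigma_a, n_actions, rs, rw, alpha, beta, bilinear
    )
    return lam * lr + (1.0 - lam) * la


@njit(cache=False)
def nm_minimize(
    which, x0, sigma_a, n_actions, s, a_idx, rs, rw, alpha, beta, bilinear, lam,
    xatol, fatol, maxiter,
):  # pragma: no cover - compiled
    """Nelder-Mead simplex search with the Lagarias et al. update coefficients.

    A compiled port of the standard implementation (same initial simplex,
    reflection/expansion/contraction/shrink coefficients 1, 2, 0.5, 0.5,
    per-iteration resorting, and the xatol/fatol termination rule); the test
    suite asserts agreement with scipy's optimizer on random instances.
    Returns (x_best, f_best).
    """
    rho, chi, psi, sigma = 1.0, 2.0, 0.5, 0.5
    nonzdelt, zdelt = 0.05, 0.00025
    n = x0.shape[0]
    sim = np.empty((n + 1, n))
    sim[0] = x0
    for k in range(n):
        for j in range(n):
            sim[k + 1, j] = x0[j]
        if sim[k + 1, k] != 0.0:
            sim[k + 1, k] = (1.0 + nonzdelt) * sim[k + 1, k]
        else:
            sim[k + 1, k] = zdelt
    fsim = np.empty(n + 1)
    for k in range(n + 1):
        fsim[k] = _objective(
            which, sim[k], sigma_a, n_actions, s, a_idx, rs, rw, alpha, beta, bilinear, lam
        )
    order = np.argsort(fsim)
    sim = sim[order]
    fsim = fsim[order]

    iterations = 1
    while iterations < maxiter:
        maxdx = 0.0
        maxdf = 0.0
        for i in range(1, n + 1):
            for j in range(n):
                d = abs(sim[i, j] - sim[0, j])
                if d > maxdx:
                    maxdx = d
            df = abs(fsim[0] - fsim[i])
            if df > maxdf:
                maxdf = df
        if maxdx <= xatol and maxdf <= fatol:
            break

        xbar = np.zeros(n)
        for i in range(n):
            for j in range(n):
                xbar[j] += sim[i, j]
        xbar /= n
        xr = (1.0 + rho) * xbar - rho * sim[n]
        fxr = _objective(
            which, xr, sigma_a, n_actions, s, a_idx, rs, rw, alpha, beta, bilinear, lam
        )
        doshrink = False
        if fxr < fsim[0]:
            xe = (1.0 + rho * chi) * xbar - rho * chi * sim[n]
            fxe = _objective(
                which, xe, sigma_a, n_actions, s, a_idx, rs, rw, alpha, beta, bilinear, lam
            )
            if fxe < fxr:
                sim[n] = xe
                fsim[n] = fxe
            else:
                sim[n] = xr
                fsim[n] = fxr
        else:
            if fxr < fsim[n - 1]:
                sim[n] = xr
                fsim[n] = fxr
            else:
                if fxr < fsim[n]:
                    xc = (1.0 + psi * rho) * xbar - psi * rho * sim[n]
                    fxc = _objective(
                        which, xc, sigma_a, n_actions, s, a_idx, rs, rw, alpha, beta,
                        bilinear, lam,
                    )
                    if fxc <= fxr:
                        sim[n] = xc
                        fsim[n] = fxc
                    else:
                        doshrink = True
                else:
                    xcc = (1.0 - psi) * xbar + psi * sim[n]
                    fxcc = _objective(
                        which, xcc, sigma_a, n_actions, s, a_idx, rs, rw, alpha, beta,
                        bilinear, lam,
                    )
                    if fxcc < fsim[n]:
                        sim[n] = xcc
                        fsim[n] = fxcc
                    else:
                        doshrink = True
                if doshrink:
                    for i in range(1, n + 1):
                        for j in range(n):
                            sim[i, j] = sim[0, j] + sigma * (sim[i, j] - sim[0, j])
                        fsim[i] = _objective(
                            which, sim[i], sigma_a, n_actions, s, a_idx, rs, rw, alpha, beta,
                            bilinear, lam,
                        )
        iterations += 1
        order = np.argsort(fsim)
        sim = sim[order]
        fsim = fsim[order]

    return sim[0], fsim[0]
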