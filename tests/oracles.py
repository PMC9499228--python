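"""Independent test oracles: Gillespie SSA, quadrature, and brute force.

Everything here is deliberately written without reusing the package's own
closed-form machinery, so the tests compare two independent routes to the
same quantity.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def total_variation(pmf: np.ndarray, samples_u: np.ndarray, samples_s: np.ndarray) -> float:
    """TV distance between a truncated joint PMF and an empirical sample.

    Samples beyond the truncation bounds count fully against the distance.
    """
    nu, ns = pmf.shape
    inside = (samples_u < nu) & (samples_s < ns)
    hist = np.zeros_like(pmf)
    np.add.at(hist, (samples_u[inside], samples_s[inside]), 1.0)
    hist /= samples_u.size
    outside = 1.0 - inside.mean()
    return 0.5 * (np.abs(pmf - hist).sum() + outside + abs(1.0 - pmf.sum()))


@njit(cache=True)
def _ssa_two_species(
    boundaries, alphas, beta, gamma, t_sample, u0, s0
):  # pragma: no cover - numba
    """One exact SSA trajectory of 0 -> U -> S -> 0 with piecewise alpha."""
    t = 0.0
    u = u0
    s = s0
    k = 0
    while True:
        alpha = alphas[k]
        rate = alpha + beta * u + gamma * s
        if rate <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / rate)
        # cap the jump at the next rate-switch boundary
        while k < boundaries.size - 2 and t_next > boundaries[k + 1]:
            if t_sample <= boundaries[k + 1]:
                break
            t = boundaries[k + 1]
            k += 1
            alpha = alphas[k]
            rate = alpha + beta * u + gamma * s
            if rate <= 0.0:
                t_next = np.inf
            else:
                t_next = t + np.random.exponential(1.0 / rate)
        if t_next >= t_sample:
            return u, s
        t = t_next
        r = np.random.random() * rate
        if r < alpha:
            u += 1
        elif r < alpha + beta * u:
            u -= 1
            s += 1
        else:
            s -= 1


@njit(cache=True)
def ssa_canonical(
    boundaries, alphas, beta, gamma, t_sample, n_traj, seed
):  # pragma: no cover - numba
    """SSA sample of the canonical model at time ``t_sample``.

    Each trajectory starts from a Poisson draw at the steady state of the
    first interval, matching the model's initial condition.
    """
    np.random.seed(seed)
    out_u = np.empty(n_traj, dtype=np.int64)
    out_s = np.empty(n_traj, dtype=np.int64)
    for i in range(n_traj):
        u0 = np.random.poisson(alphas[0] / beta)
        s0 = np.random.poisson(alphas[0] / gamma)
        out_u[i], out_s[i] = _ssa_two_species(
            boundaries, alphas, beta, gamma, t_sample, u0, s0
        )
    return out_u, out_s


@njit(cache=True)
def ssa_bursty(
    burst_mean, burst_freq, beta, gamma, t_end, n_traj, seed
):  # pragma: no cover - numba
    """SSA sample of the stationary bursty model after a long burn-in."""
    np.random.seed(seed)
    p_burst = 1.0 / (1.0 + burst_mean)
    out_u = np.empty(n_traj, dtype=np.int64)
    out_s = np.empty(n_traj, dtype=np.int64)
    for i in range(n_traj):
        t = 0.0
        u = 0
        s = 0
        while True:
            rate = burst_freq + beta * u + gamma * s
            t += np.random.exponential(1.0 / rate)
            if t >= t_end:
                break
            r = np.random.random() * rate
            if r < burst_freq:
                u += np.random.geometric(p_burst) - 1
            elif r < burst_freq + beta * u:
                u -= 1
                s += 1
            else:
                s -= 1
        out_u[i] = u
        out_s[i] = s
    return out_u, out_s


def brute_knn_impute(matrix: np.ndarray, coords: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive pairwise-distance pooling oracle (anchor included)."""
    n = coords.shape[0]
    out = np.empty_like(matrix, dtype=float)
    for i in range(n):
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        order = sorted(range(n), key=lambda j: (d[j], j))
        neighbors = [j for j in order if j != i][:k]
        out[i] = matrix[[i] + neighbors].mean(axis=0)
    return out


def brute_softmax_weights(
    displacements: np.ndarray, delta_s: np.ndarray, sigma: float, transform
) -> np.ndarray:
    """Softmax-of-correlations oracle for one cell's neighbor weights."""
    rs = []
    for d in displacements:
        x = transform(d)
        y = transform(delta_s)
        rs.append(np.corrcoef(x, y)[0, 1])
    rs = np.array(rs)
    e = np.exp(rs / sigma)
    return e / e.sum()


def brute_grid_arrows(
    coords: np.ndarray, arrows: np.ndarray, grid: np.ndarray,
    n_neighbors: int, bandwidth: float,
) -> np.ndarray:
    """Gaussian-kernel grid aggregation oracle."""
    out = np.empty((grid.shape[0], 2))
    for g in range(grid.shape[0]):
        d = np.sqrt(((coords - grid[g]) ** 2).sum(axis=1))
        order = sorted(range(coords.shape[0]), key=lambda j: (d[j], j))
        near = order[: min(n_neighbors, len(order))]
        w = np.exp(-0.5 * (d[near] / bandwidth) ** 2)
        w = w / w.sum()
        out[g] = (w[:, None] * arrows[near]).sum(axis=0)
    return out


def brute_knn_sets(coords: np.ndarray, k: int) -> list[set]:
    """kNN index sets by explicit sort with (distance, index) keys."""
    n = coords.shape[0]
    sets = []
    for i in range(n):
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        order = sorted((j for j in range(n) if j != i), key=lambda j: (d[j], j))
        sets.append(set(order[:k]))
    return sets
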