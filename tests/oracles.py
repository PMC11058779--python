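"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: isotonic fits are
found by exhaustive search over monotone block partitions, Ward trees by
greedy variance recomputation from raw coordinates, and 1-D NMDS stress by a
dense grid search over configurations.
"""

from __future__ import annotations

import itertools

import numpy as np


def isotonic_bruteforce(y: np.ndarray) -> np.ndarray:
    """Least-squares non-decreasing fit via exhaustive block partitions.

    Enumerates every composition of the index range into contiguous blocks,
    fits each block at its mean, keeps partitions whose block means are
    non-decreasing, and returns the feasible fit of minimum SSE.  The
    isotonic optimum always has this piecewise-constant form.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    best_sse = np.inf
    best_fit = None
    for cuts in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        means = [y[a:b].mean() for a, b in zip(bounds, bounds[1:])]
        if any(m2 < m1 for m1, m2 in zip(means, means[1:])):
            continue
        fit = np.concatenate(
            [np.full(b - a, m) for (a, b), m in zip(zip(bounds, bounds[1:]), means)]
        )
        sse = float(np.sum((y - fit) ** 2))
        if sse < best_sse - 1e-15:
            best_sse = sse
            best_fit = fit
    return best_fit


def ward_bruteforce(points: np.ndarray):
    """Greedy Ward agglomeration recomputing cluster variances from scratch.

    At each step merges the pair of clusters whose merge distance
    sqrt(2 * |A||B|/(|A|+|B|) * ||centroid_A - centroid_B||^2)
    (equal to the increase in within-cluster sum of squares, times two,
    under a square root) is smallest; ties broken by lowest cluster indices.
    Returns the list of merge heights in order.
    """
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = points[clusters[a]].mean(axis=0)
                cb = points[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                d2 = 2.0 * na * nb / (na + nb) * float(np.sum((ca - cb) ** 2))
                d = np.sqrt(d2)
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return heights


def _compositions_masks(n: int):
    """All monotone block partitions of range(n) as (starts, ends) lists."""
    out = []
    for cuts in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        out.append(list(zip(bounds, bounds[1:])))
    return out


def grid_stress_1d_4pt(delta: np.ndarray, step_coarse=0.05, step_fine=0.005) -> float:
    """Brute-force minimum stress-1 for embedding 4 points on a line.

    Fixes x1 = 0 (stress-1 is translation- and scale-invariant) and scans a
    dense grid over the other three coordinates; the isotonic fit per
    configuration is itself brute-forced over monotone block partitions.
    A fine grid pass refines around the coarse optimum.
    """
    delta = np.asarray(delta, dtype=float)
    order = np.argsort(delta, kind="stable")  # assumes no ties in delta
    partitions = _compositions_masks(6)
    pairs = list(itertools.combinations(range(4), 2))

    def batch_stress(coords2, coords3, coords4):
        g2, g3, g4 = np.meshgrid(coords2, coords3, coords4, indexing="ij")
        X = np.stack([np.zeros_like(g2), g2, g3, g4], axis=-1).reshape(-1, 4)
        d = np.stack([np.abs(X[:, i] - X[:, j]) for i, j in pairs], axis=1)
        ds = d[:, order]
        T = (d * d).sum(axis=1)
        # exclude (near-)coincident configurations: stress-1 is scale-free,
        # so nothing is lost, and float noise at scale 1e-15 would otherwise
        # defeat the monotone-feasibility tolerance below
        ok = T > 1e-6
        best_sse = np.full(len(X), np.inf)
        for part in partitions:
            fit = np.empty_like(ds)
            feasible = np.ones(len(X), dtype=bool)
            prev_mean = np.full(len(X), -np.inf)
            for a, b in part:
                m = ds[:, a:b].mean(axis=1)
                feasible &= m >= prev_mean - 1e-12
                prev_mean = m
                fit[:, a:b] = m[:, None]
            sse = ((ds - fit) ** 2).sum(axis=1)
            upd = feasible & (sse < best_sse)
            best_sse[upd] = sse[upd]
        stress = np.sqrt(best_sse[ok] / T[ok])
        idx = np.argmin(stress)
        return float(stress[idx]), X[np.flatnonzero(ok)[idx]]

    grid = np.arange(-1.5, 1.5 + 1e-9, step_coarse)
    s_coarse, xbest = batch_stress(grid, grid, grid)
    fine = [np.arange(x - step_coarse, x + step_coarse + 1e-9, step_fine) for x in xbest[1:]]
    s_fine, _ = batch_stress(*fine)
    return min(s_coarse, s_fine)
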