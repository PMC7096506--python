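"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle re-derives a quantity by exhaustive search or direct
optimisation, never through the code path it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def _euler_rotation(angles: np.ndarray) -> np.ndarray:
    a, b, c = angles
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def brute_force_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimal RMSD over rotation space by multi-start search on Euler
    angles (translation handled by centring); independent of Kabsch."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)

    def cost(angles: np.ndarray) -> float:
        rot = _euler_rotation(angles)
        return float(np.sqrt(np.mean(np.sum((x @ rot.T - y) ** 2, axis=1))))

    best = np.inf
    grid = np.linspace(0, 2 * np.pi, 5, endpoint=False)
    for start in itertools.product(grid, repeat=3):
        res = minimize(
            cost, np.array(start), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
        )
        best = min(best, res.fun)
    return best


def brute_force_complete_linkage(dist: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Exhaustive agglomerative complete linkage: repeatedly merge the two
    clusters with the smallest farthest-point distance.

    Returns the merge sequence as (members_a, members_b, height).
    """
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = max(
                dist[i, j] for i in clusters[a] for j in clusters[b]
            )
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((clusters[a], clusters[b], h))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges


def brute_force_partition_at_k(dist: np.ndarray, k: int) -> set[frozenset]:
    """Partition after cutting the exhaustive complete-linkage tree at k
    clusters."""
    n = dist.shape[0]
    merges = brute_force_complete_linkage(dist)
    clusters = [frozenset([i]) for i in range(n)]
    for a, b, _h in merges:
        if len(clusters) <= k:
            break
        clusters = [c for c in clusters if c not in (a, b)]
        clusters.append(a | b)
    return set(clusters)


def brute_force_best_2partition(points: np.ndarray) -> float:
    """Optimal 2-means inertia by exhaustive enumeration of all non-trivial
    2-partitions (feasible up to ~12 points)."""
    n = points.shape[0]
    best = np.inf
    for mask_bits in range(1, 2 ** (n - 1)):
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        inertia = 0.0
        for side in (mask, ~mask):
            pts = points[side]
            inertia += float(np.sum((pts - pts.mean(axis=0)) ** 2))
        best = min(best, inertia)
    return best


def brute_force_segmentation(x: np.ndarray, n_changes: int) -> tuple[list[int], float]:
    """Optimal piecewise-constant segmentation by exhaustive enumeration of
    change-point positions."""
    n = len(x)

    def sse(lo: int, hi: int) -> float:
        seg = x[lo:hi]
        return float(np.sum((seg - seg.mean()) ** 2))

    best_cost, best_cps = np.inf, []
    for cps in itertools.combinations(range(1, n), n_changes):
        bounds = [0, *cps, n]
        cost = sum(sse(a, b) for a, b in zip(bounds, bounds[1:]))
        if cost < best_cost - 1e-12:
            best_cost, best_cps = cost, list(cps)
    return best_cps, best_cost
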