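"""Conformational-state discovery along trajectories.

k-means over fitted Cα coordinates with Davies-Bouldin / Calinski-Harabasz
model selection, RMSD-histogram clustering, the internal-vs-displacement
RMSD decomposition, and least-squares change-point detection on metric
series.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from kitcd.core import CA, DomainScheme, Trajectory
from kitcd.geometry import MetricSeries, rmsd_series, superpose_frames, select


@dataclasses.dataclass
class ClusterSolution:
    """One k-means solution with its validity indices."""

    k: int
    assignment: np.ndarray
    centroids: np.ndarray
    inertia: float
    davies_bouldin: float
    calinski_harabasz: float
    seed: int

    def __post_init__(self) -> None:
        labels = np.unique(self.assignment)
        if len(labels) != self.k or labels.min() < 0 or labels.max() >= self.k:
            raise ValueError("assignment must use every label in [0, k)")


@dataclasses.dataclass
class TransitionReport:
    """Change points of a piecewise-constant segmentation."""

    change_points: list[int]
    segment_means: list[float]
    segment_sds: list[float]

    def __post_init__(self) -> None:
        cps = self.change_points
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("change points must be strictly increasing")


def _validity_indices(features: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DB (lower better) and CH (higher better), with the degenerate
    zero-within-dispersion case mapped to (0, inf)."""
    within = 0.0
    for lab in np.unique(labels):
        pts = features[labels == lab]
        within += float(np.sum((pts - pts.mean(axis=0)) ** 2))
    if within <= 1e-12:
        return 0.0, float("inf")
    return (
        float(davies_bouldin_score(features, labels)),
        float(calinski_harabasz_score(features, labels)),
    )


def davies_bouldin(features: np.ndarray, assignment: np.ndarray) -> float:
    return _validity_indices(np.asarray(features), np.asarray(assignment))[0]


def calinski_harabasz(features: np.ndarray, assignment: np.ndarray) -> float:
    return _validity_indices(np.asarray(features), np.asarray(assignment))[1]


def kmeans(
    features: np.ndarray, k: int, seed: int, n_restarts: int = 10
) -> ClusterSolution:
    """Lloyd's algorithm with k-means++ seeding, best of ``n_restarts`` by
    inertia; deterministic for a fixed seed."""
    features = np.asarray(features, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k >= features.shape[0]:
        raise ValueError(f"k={k} must be below the number of points")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(features)
    db, ch = _validity_indices(features, km.labels_)
    return ClusterSolution(
        k=k,
        assignment=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        davies_bouldin=db,
        calinski_harabasz=ch,
        seed=seed,
    )


def choose_k(
    features: np.ndarray,
    k_range: range | list[int],
    seed: int,
    n_restarts: int = 10,
) -> tuple[ClusterSolution, dict]:
    """Run k-means over ``k_range`` and pick the solution.

    Primary criterion: maximise Calinski-Harabasz.  When Davies-Bouldin's
    argmin disagrees, the smaller of the two k values is chosen and the
    conflict recorded in the report.
    """
    solutions = {k: kmeans(features, k, seed, n_restarts) for k in k_range}
    ks = sorted(solutions)
    ch_curve = {k: solutions[k].calinski_harabasz for k in ks}
    db_curve = {k: solutions[k].davies_bouldin for k in ks}
    k_ch = max(ks, key=lambda k: (ch_curve[k], -k))
    k_db = min(ks, key=lambda k: (db_curve[k], k))
    conflict = k_ch != k_db
    chosen = min(k_ch, k_db) if conflict else k_ch
    report = {
        "k_by_calinski_harabasz": k_ch,
        "k_by_davies_bouldin": k_db,
        "conflict": conflict,
        "chosen_k": chosen,
        "ch_curve": ch_curve,
        "db_curve": db_curve,
    }
    return solutions[chosen], report


def conformation_features(
    traj: Trajectory,
    domain: tuple[int, int] | None = None,
    burn_in: int = 0,
    frame_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Fitted Cα coordinates flattened per frame — the Euclidean feature
    space for conformational k-means."""
    _, coords = select(traj, CA, domain)
    if frame_range is not None:
        coords = coords[frame_range[0] : frame_range[1]]
    coords = coords[burn_in:]
    fitted = superpose_frames(coords, coords[0])
    return fitted.reshape(fitted.shape[0], -1)


def cluster_representatives(
    solution: ClusterSolution, features: np.ndarray
) -> dict[int, int]:
    """Medoid frame per cluster (closest member to the centroid)."""
    reps = {}
    for lab in range(solution.k):
        members = np.nonzero(solution.assignment == lab)[0]
        dist = np.linalg.norm(
            features[members] - solution.centroids[lab], axis=1
        )
        reps[lab] = int(members[np.argmin(dist)])
    return reps


def rmsd_distribution(
    traj: Trajectory,
    scheme: DomainScheme,
    regions: list[str],
    reference_frame: int = 0,
    bins: int = 1000,
    prominence: float = 0.05,
) -> dict[str, dict]:
    """Per-region RMSD-to-first-conformation histograms.

    Histograms are area-normalised; the multimodality report counts local
    maxima with prominence above ``prominence`` × the peak density.
    """
    out = {}
    for name in regions:
        domain = scheme[name]
        series = rmsd_series(
            traj, CA, reference_frame=reference_frame,
            fit_domain=domain,
        )
        hi = max(float(series.values.max()) * 1.05, 1e-6)
        density, edges = np.histogram(
            series.values, bins=bins, range=(0.0, hi), density=True
        )
        peaks, _ = find_peaks(
            np.concatenate([[0.0], density, [0.0]]),
            prominence=prominence * density.max(),
        )
        centers = (edges[:-1] + edges[1:]) / 2
        out[name] = {
            "series": series,
            "density": density,
            "bin_edges": edges,
            "n_modes": int(len(peaks)),
            "mode_positions": centers[peaks - 1].tolist(),
        }
    return out


def internal_vs_displacement(
    traj: Trajectory, scheme: DomainScheme, domain: str
) -> tuple[MetricSeries, MetricSeries, MetricSeries]:
    """Decompose a domain's RMSD into total displacement and internal motion.

    Series A: domain RMSD after fitting on the whole protein ("all
    displacements"); series B: after fitting on the domain itself
    ("internal components"); series C = A − B per frame (sign not
    guaranteed).
    """
    dom = scheme[domain]
    a = rmsd_series(traj, CA, CA, fit_domain=None, compute_domain=dom)
    b = rmsd_series(traj, CA, fit_domain=dom)
    c = MetricSeries(
        values=a.values - b.values, label="difference_A", time_step=traj.time_step
    )
    a.label, b.label = "all_displacements_A", "internal_components_A"
    return a, b, c


# ---------------------------------------------------------------------------
# Change-point detection
# ---------------------------------------------------------------------------


def _segment_cost_table(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums enabling O(1) SSE of any segment [i, j)."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x**2)])
    return s1, s2


def _sse(s1: np.ndarray, s2: np.ndarray, i: int, j: int) -> float:
    n = j - i
    tot = s1[j] - s1[i]
    return float(s2[j] - s2[i] - tot * tot / n)


def _dp_segmentations(x: np.ndarray, max_changes: int) -> list[tuple[list[int], float]]:
    """Exact least-squares piecewise-constant segmentations for every number
    of change points m = 0..max_changes (one dynamic program, vectorised
    over split positions)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    s1, s2 = _segment_cost_table(x)
    big = np.inf

    def seg_sse_vec(i_arr: np.ndarray, j: int) -> np.ndarray:
        length = j - i_arr
        tot = s1[j] - s1[i_arr]
        return s2[j] - s2[i_arr] - tot * tot / length

    # d[m][j]: best cost of x[:j] split into m+1 segments
    d_prev = np.array(
        [_sse(s1, s2, 0, j) if j > 0 else big for j in range(n + 1)]
    )
    results: list[tuple[list[int], float]] = [([], float(d_prev[n]))]
    backs: list[np.ndarray] = []
    for m in range(1, max_changes + 1):
        d_cur = np.full(n + 1, big)
        arg = np.full(n + 1, -1, dtype=int)
        for j in range(m + 1, n + 1):
            i_arr = np.arange(m, j)
            cand = d_prev[i_arr] + seg_sse_vec(i_arr, j)
            best = int(np.argmin(cand))
            d_cur[j], arg[j] = float(cand[best]), int(i_arr[best])
        backs.append(arg)
        d_prev = d_cur
        cps: list[int] = []
        j = n
        for back in reversed(backs):
            i = int(back[j])
            cps.append(i)
            j = i
        results.append((sorted(cps), float(d_cur[n])))
    return results


def optimal_segmentation(x: np.ndarray, n_changes: int) -> tuple[list[int], float]:
    """Exact least-squares segmentation with exactly ``n_changes`` change
    points."""
    return _dp_segmentations(x, n_changes)[n_changes]


def detect_transitions(
    series: MetricSeries | np.ndarray,
    max_changes: int = 5,
    penalty: float | None = None,
) -> TransitionReport:
    """Least-squares piecewise-constant change-point detection.

    The number of changes m ∈ [0, max_changes] is chosen by penalised cost
    (BIC-style: penalty = 2 σ̂² log n per change, σ̂ from the median absolute
    first difference).
    """
    x = series.values if isinstance(series, MetricSeries) else np.asarray(series, float)
    n = len(x)
    if n < 10:
        raise ValueError("series too short for segmentation")
    if penalty is None:
        diffs = np.abs(np.diff(x))
        sigma = np.median(diffs) / 0.6745 / np.sqrt(2) if diffs.size else 0.0
        sigma = max(sigma, 1e-12)
        penalty = 2.0 * sigma**2 * np.log(n)
    best_cost, best_cps = np.inf, []
    for m, (cps, cost) in enumerate(_dp_segmentations(x, max_changes)):
        total = cost + penalty * m
        if total < best_cost - 1e-12:
            best_cost, best_cps = total, cps
    bounds = [0] + best_cps + [n]
    means = [float(np.mean(x[a:b])) for a, b in zip(bounds, bounds[1:])]
    sds = [float(np.std(x[a:b])) for a, b in zip(bounds, bounds[1:])]
    return TransitionReport(
        change_points=best_cps, segment_means=means, segment_sds=sds
    )
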