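"""Stage 1 — filter, rank, cluster and pick representative candidate models.

The screening funnel mirrors the modelling protocol: an ensemble of
candidate models is filtered on the F689–D768 end-to-end distance
(9.9 ± 1.0 Å, the crystallographic value), screened for steric clashes,
ranked by an externally supplied model-quality score (DOPE-like, lower =
better energy), clustered by secondary-structure similarity under
farthest-point (complete) linkage, and reduced to one medoid representative
per cluster.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from kitcd.core import DomainScheme, Structure
from kitcd.geometry import end_to_end_distance
from kitcd.secstruct import ss_similarity_matrix

DEFAULT_TARGET_D = 9.9  # Å, crystallographic F689-D768 distance
DEFAULT_TOL = 1.0  # Å
DEFAULT_CLASH_CUTOFF = 1.5  # Å, non-bonded heavy-atom pair


@dataclasses.dataclass
class CandidateModel:
    """A candidate structural model with its screening attributes."""

    id: str
    structure: Structure | None = None
    d: float | None = None
    external_score: float | None = None
    ss: str | None = None

    def __post_init__(self) -> None:
        if self.d is not None and self.d < 0:
            raise ValueError("end-to-end distance must be non-negative")


@dataclasses.dataclass
class LinkageTree:
    """Ordered merge list of an agglomerative clustering."""

    merges: list[tuple[int, int, float]]
    n_leaves: int

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a tree over n leaves has exactly n-1 merges")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("complete-linkage merge heights must be non-decreasing")


def distance_filter(
    models: Sequence[CandidateModel],
    target: float = DEFAULT_TARGET_D,
    tol: float = DEFAULT_TOL,
) -> list[CandidateModel]:
    """Keep models with |d − target| ≤ tol (inclusive bounds), input order
    preserved."""
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    missing = [m.id for m in models if m.d is None]
    if missing:
        raise ValueError(f"models lack end-to-end distance: {missing}")
    return [m for m in models if abs(m.d - target) <= tol]


def has_steric_clash(
    structure: Structure, cutoff: float = DEFAULT_CLASH_CUTOFF
) -> bool:
    """True when any non-bonded heavy-atom pair lies below ``cutoff`` Å.

    Atoms in the same residue or in consecutive residues are treated as
    bonded context and exempt (covalent distances are shorter than the
    cutoff by construction).
    """
    heavy = structure.atoms.element != "H"
    coords = structure.coords[heavy]
    res = structure.residue_numbers[heavy]
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff):
        if abs(int(res[i]) - int(res[j])) >= 2:
            return True
    return False


def clash_screen(
    models: Sequence[CandidateModel], cutoff: float = DEFAULT_CLASH_CUTOFF
) -> list[CandidateModel]:
    """Reject models with intramolecular steric clashes (automated stand-in
    for visual elimination of models with intramolecular 'nodes')."""
    kept = []
    for m in models:
        if m.structure is None or not has_steric_clash(m.structure, cutoff):
            kept.append(m)
    return kept


def rank_by_score(models: Sequence[CandidateModel], k: int) -> list[CandidateModel]:
    """The k best models by external score (lowest energy first); ties broken
    by model id."""
    if k > len(models):
        raise ValueError(f"k={k} exceeds ensemble size {len(models)}")
    missing = [m.id for m in models if m.external_score is None]
    if missing:
        raise ValueError(f"models lack external scores: {missing}")
    ranked = sorted(models, key=lambda m: (m.external_score, m.id))
    return ranked[:k]


def _check_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")
    return dist


def cluster_farthest_point(
    distance_matrix: np.ndarray, n_clusters: int
) -> tuple[np.ndarray, LinkageTree]:
    """Agglomerative complete-linkage clustering,
    d(u, v) = max over i in u, j in v of dist(u[i], v[j]).

    Returns a 0-based cluster assignment (cut at ``n_clusters``) and the
    full merge tree.
    """
    dist = _check_distance_matrix(distance_matrix)
    n = dist.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=n_clusters, criterion="maxclust") - 1
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return labels, LinkageTree(merges=merges, n_leaves=n)


def select_representatives(
    assignment: np.ndarray, distance_matrix: np.ndarray
) -> dict[int, int]:
    """Medoid (minimal summed distance to cluster members) per cluster,
    ties broken by the lower index."""
    dist = _check_distance_matrix(distance_matrix)
    assignment = np.asarray(assignment)
    out: dict[int, int] = {}
    for label in np.unique(assignment):
        members = np.nonzero(assignment == label)[0]
        sums = dist[np.ix_(members, members)].sum(axis=1)
        out[int(label)] = int(members[np.argmin(sums)])
    return out


class EmptyStageError(RuntimeError):
    """A pipeline stage produced an empty candidate set."""

    def __init__(self, stage: str):
        super().__init__(f"screening stage '{stage}' produced no models")
        self.stage = stage


def screen_pipeline(
    models: Sequence[CandidateModel],
    scheme: DomainScheme | None = None,
    target_d: float = DEFAULT_TARGET_D,
    tol: float = DEFAULT_TOL,
    k_top: int = 26,
    n_clusters: int = 4,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> dict:
    """End-to-end screening: distance filter → clash screen → score ranking →
    SS-similarity clustering → medoid representatives.

    Returns a report dict with stage counts, kept ids, cluster membership
    and representative ids.  Deterministic for fixed inputs.
    """
    report: dict = {"stages": {}, "parameters": {
        "target_d": target_d, "tol": tol, "k_top": k_top,
        "n_clusters": n_clusters, "clash_cutoff": clash_cutoff,
        "ss_distance": "1 - positional identity",
    }}
    report["stages"]["input"] = len(models)
    if not models:
        raise EmptyStageError("input")

    for m in models:
        if m.d is None:
            if m.structure is None or scheme is None:
                raise ValueError(f"model {m.id}: no distance and no structure/scheme")
            m.d = end_to_end_distance(m.structure, scheme)

    filtered = distance_filter(models, target_d, tol)
    report["stages"]["distance_filter"] = len(filtered)
    if not filtered:
        raise EmptyStageError("distance_filter")

    unclashed = clash_screen(filtered, clash_cutoff)
    report["stages"]["clash_screen"] = len(unclashed)
    if not unclashed:
        raise EmptyStageError("clash_screen")

    k = min(k_top, len(unclashed))
    top = rank_by_score(unclashed, k)
    report["stages"]["score_ranking"] = len(top)

    missing_ss = [m.id for m in top if m.ss is None]
    if missing_ss:
        raise ValueError(f"models lack SS strings: {missing_ss}")
    dist = ss_similarity_matrix([m.ss for m in top])
    n_clusters_eff = min(n_clusters, len(top))
    labels, tree = cluster_farthest_point(dist, n_clusters_eff)
    reps = select_representatives(labels, dist)
    report["stages"]["representatives"] = len(reps)

    report["kept_ids"] = [m.id for m in top]
    report["cluster_membership"] = {
        m.id: int(label) for m, label in zip(top, labels)
    }
    report["representative_ids"] = {
        int(c): top[i].id for c, i in sorted(reps.items())
    }
    report["representatives"] = [top[i] for _, i in sorted(reps.items())]
    report["linkage_merges"] = tree.merges
    return report


def write_report(report: dict, path) -> None:
    """Serialise a screening report (models themselves excluded) to JSON."""
    serialisable = {k: v for k, v in report.items() if k != "representatives"}
    with open(path, "w") as fh:
        json.dump(serialisable, fh, indent=2)
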