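"""Stage 3 — multi-metric characterisation and consensus ranking of
candidate-model trajectories.

Each candidate trajectory is summarised into a report of per-domain RMSD
and RMSF statistics, the end-to-end distance d, the KID radius of gyration
and the secondary-structure conservation of the kinase lobes; candidates
are then ranked per metric and aggregated by unweighted rank-sum (Borda),
the minimal formalisation of a qualitative consensus over independent
structural metrics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from kitcd.core import CA, DomainScheme, Trajectory
from kitcd.geometry import MetricSeries, d_series, rg_series, rmsd_series, rmsf
from kitcd.secstruct import SSTimeline, ss_conservation


@dataclasses.dataclass
class CandidateReport:
    """Per-candidate metric summary over the production window."""

    id: str
    domain_rmsd_mean: dict[str, float]
    domain_rmsd_sd: dict[str, float]
    rmsf_mean: float
    d_mean: float
    d_sd: float
    d_deviation: float  # |d_mean − d_ref|
    rg_mean: float
    rg_sd: float
    ss_conservation: float | None
    plateau: dict[str, bool]

    def __post_init__(self) -> None:
        values = list(self.domain_rmsd_mean.values()) + [
            self.rmsf_mean, self.d_mean, self.rg_mean
        ]
        if not np.all(np.isfinite(values)):
            raise ValueError("metric means must be finite")
        if self.ss_conservation is not None and not 0 <= self.ss_conservation <= 1:
            raise ValueError("SS conservation must lie in [0, 1]")


@dataclasses.dataclass
class ConsensusRanking:
    """Aggregated ordering with the per-metric audit trail."""

    order: list[str]
    per_metric_ranks: dict[str, dict[str, int]]
    scores: dict[str, float]
    conflicts: list[str]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("ranking must be a permutation of candidate ids")


def plateau_flag(series: MetricSeries, fraction: float = 0.25) -> bool:
    """True when the OLS slope over the final ``fraction`` of frames is
    indistinguishable from zero (|slope| < 2 × its standard error)."""
    tail = series.values[int(len(series) * (1 - fraction)):]
    if len(tail) < 3 or np.allclose(tail, tail[0]):
        return True
    t = np.arange(len(tail), dtype=float)
    fit = stats.linregress(t, tail)
    return bool(abs(fit.slope) < 2.0 * fit.stderr)


def candidate_metrics(
    traj: Trajectory,
    scheme: DomainScheme,
    d_ref: float = 9.9,
    burn_in: int = 0,
    candidate_id: str = "",
    template_ss: str | None = None,
    timeline: SSTimeline | None = None,
    kid_domain: str = "KID",
    lobe_domains: tuple[str, str] = ("N-lobe", "C-lobe"),
) -> CandidateReport:
    """Assemble the metric suite for one candidate trajectory.

    Frames before ``burn_in`` are excluded (the non-equilibrated part).  SS
    conservation requires both a template assignment and a timeline (full
    backbones); for Cα-only trajectories pass a precomputed timeline or
    leave both unset to omit the metric.
    """
    if burn_in >= traj.n_frames:
        raise ValueError("burn_in leaves no frames")
    domains = scheme.domains_within(traj.topology)
    if not domains:
        raise ValueError("trajectory covers no scheme domain completely")
    rmsd_mean, rmsd_sd, plateaus = {}, {}, {}
    for name in domains:
        series = rmsd_series(traj, CA, fit_domain=scheme[name])
        prod = series.values[burn_in:]
        rmsd_mean[name] = float(np.mean(prod))
        rmsd_sd[name] = float(np.std(prod))
        plateaus[name] = plateau_flag(series)

    fluct = rmsf(traj, CA, burn_in=burn_in)
    d = d_series(traj, scheme)
    d_prod = d.values[burn_in:]

    if kid_domain in domains:
        rg = rg_series(traj, CA, domain=scheme[kid_domain], mass_weighted=False)
    else:
        rg = rg_series(traj, CA, mass_weighted=False)
    rg_prod = rg.values[burn_in:]

    conservation = None
    if template_ss is not None and timeline is not None:
        fractions = []
        for lobe in lobe_domains:
            if lobe in domains:
                fractions.append(
                    ss_conservation(timeline, template_ss, region=scheme[lobe])
                )
        if fractions:
            conservation = float(np.mean(fractions))

    return CandidateReport(
        id=candidate_id,
        domain_rmsd_mean=rmsd_mean,
        domain_rmsd_sd=rmsd_sd,
        rmsf_mean=float(np.mean(fluct)),
        d_mean=float(np.mean(d_prod)),
        d_sd=float(np.std(d_prod)),
        d_deviation=float(abs(np.mean(d_prod) - d_ref)),
        rg_mean=float(np.mean(rg_prod)),
        rg_sd=float(np.std(rg_prod)),
        ss_conservation=conservation,
        plateau=plateaus,
    )


# metric extractors: (name, lower_is_better, fn)
def _metric_table(reports: list[CandidateReport]) -> list[tuple[str, bool, list[float]]]:
    table = [
        ("rmsd_mean", True, [float(np.mean(list(r.domain_rmsd_mean.values())))
                             for r in reports]),
        ("rmsd_sd", True, [float(np.mean(list(r.domain_rmsd_sd.values())))
                           for r in reports]),
        ("rmsf_mean", True, [r.rmsf_mean for r in reports]),
        ("d_deviation", True, [r.d_deviation for r in reports]),
        ("rg_sd", True, [r.rg_sd for r in reports]),
    ]
    if all(r.ss_conservation is not None for r in reports):
        table.append(
            ("ss_conservation", False, [r.ss_conservation for r in reports])
        )
    return table


def consensus_rank(
    reports: list[CandidateReport],
    weights: dict[str, float] | None = None,
) -> ConsensusRanking:
    """Rank candidates per metric and aggregate by rank-sum.

    Lower is better for RMSD means/sds, RMSF mean, |d − d_ref| and the KID
    Rg sd; higher is better for SS conservation.  Ties in the aggregate are
    broken by |d − d_ref|, then by id.  Ranking is invariant under report
    ordering.
    """
    if len(reports) < 2:
        raise ValueError("consensus needs at least two candidates")
    ids = [r.id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError("candidate ids must be unique")
    per_metric: dict[str, dict[str, int]] = {}
    scores = {i: 0.0 for i in ids}
    conflicts: list[str] = []
    for name, lower_better, values in _metric_table(reports):
        vals = np.asarray(values, dtype=float)
        if not lower_better:
            vals = -vals
        ranks = [int(r) for r in stats.rankdata(vals, method="min")]
        per_metric[name] = dict(zip(ids, ranks))
        w = 1.0 if weights is None else weights.get(name, 1.0)
        for i, rk in zip(ids, ranks):
            scores[i] += w * rk
        if len(set(ranks)) < len(ranks):
            conflicts.append(f"metric {name}: tied candidates")

    dev = {r.id: r.d_deviation for r in reports}
    order = sorted(ids, key=lambda i: (scores[i], dev[i], i))
    # flag full ties in the aggregate
    agg = sorted((scores[i], dev[i]) for i in ids)
    if any(a == b for a, b in zip(agg, agg[1:])):
        conflicts.append("aggregate tie broken by |d - d_ref| then id")
    return ConsensusRanking(
        order=order, per_metric_ranks=per_metric, scores=scores, conflicts=conflicts
    )
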