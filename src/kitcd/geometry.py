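"""Rigid-body superposition and scalar structural metrics.

Implements the metric suite used throughout the pipeline: weighted Kabsch
superposition, RMSD series with independent fit/compute regions, RMSF about
the time-average structure, radius of gyration, the size-normalised RMSD100,
the F689–D768 end-to-end distance d, and the Ramachandran allowed-region
fraction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import biotite.structure as bst

from kitcd.core import CA, AtomSelection, DomainScheme, Structure, Trajectory, select

# Standard atomic masses for the elements occurring in protein backbones.
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


@dataclasses.dataclass
class Superposition:
    """Optimal proper rotation + translation: x' = x @ rotation.T + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclasses.dataclass
class MetricSeries:
    """Per-frame scalar series with summary statistics."""

    values: np.ndarray
    label: str = ""
    time_step: float = 1.0  # ns per frame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values))

    def __len__(self) -> int:
        return len(self.values)

    def summary_string(self) -> str:
        """Mean with the standard deviation's leading digit in parentheses,
        e.g. ``'12.6 (2)'``."""
        sd = self.sd
        if sd == 0:
            return f"{self.mean:.1f} (0)"
        exponent = int(np.floor(np.log10(sd)))
        leading = int(round(sd / 10.0**exponent))
        decimals = max(0, -exponent)
        return f"{self.mean:.{decimals}f} ({leading})"

    def to_csv(self, path) -> None:
        times = np.arange(len(self.values)) * self.time_step
        np.savetxt(
            path,
            np.column_stack([times, self.values]),
            delimiter=",",
            header=f"time_ns,{self.label or 'value'}",
            comments="",
        )


def kabsch_fit(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> Superposition:
    """Weighted least-squares optimal superposition of ``mobile`` onto
    ``reference`` (Kabsch algorithm, reflection branch corrected).

    Requires ≥ 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("point sets must have equal shape")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_r = w @ reference
    x = mobile - mu_m
    y = reference - mu_r
    # covariance between the two centred clouds
    h = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    moved = x @ rot.T
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - y) ** 2, axis=1))))
    trans = mu_r - mu_m @ rot.T
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory,
    fit_region: AtomSelection = CA,
    compute_region: AtomSelection | None = None,
    reference_frame: int = 0,
    fit_domain: tuple[int, int] | None = None,
    compute_domain: tuple[int, int] | None = None,
) -> MetricSeries:
    """Per-frame RMSD to a reference frame.

    Each frame is superposed on the reference using ``fit_region``; the RMSD
    is then evaluated over ``compute_region`` (default: same as the fit
    region).  Distinct fit/compute regions expose domain displacement within
    a larger body ("all displacements" vs "internal components").
    """
    if compute_region is None:
        compute_region = fit_region
        if compute_domain is None:
            compute_domain = fit_domain
    if not -traj.n_frames <= reference_frame < traj.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    fit_idx, fit_coords = select(traj, fit_region, fit_domain)
    cmp_idx, cmp_coords = select(traj, compute_region, compute_domain)
    ref_fit = fit_coords[reference_frame]
    ref_cmp = cmp_coords[reference_frame]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        sup = kabsch_fit(fit_coords[f], ref_fit)
        values[f] = _rmsd(sup.transform(cmp_coords[f]), ref_cmp)
    return MetricSeries(values=values, label="rmsd_A", time_step=traj.time_step)


def superpose_frames(
    coords: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Superpose every frame of (F, N, 3) onto the (N, 3) reference."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        out[f] = kabsch_fit(coords[f], reference).transform(coords[f])
    return out


def iterative_average_fit(
    coords: np.ndarray, tol: float = 1e-6, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Fit frames to their average, iterating fit ↔ mean to convergence.

    Returns (fitted coords, converged mean).  Tolerance is the max atom
    displacement of the mean between iterations, in Å.
    """
    fitted = superpose_frames(coords, coords[0])
    mean = fitted.mean(axis=0)
    for _ in range(max_iter):
        fitted = superpose_frames(coords, mean)
        new_mean = fitted.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return fitted, mean


def rmsf(
    traj: Trajectory,
    selection: AtomSelection = CA,
    fit_region: AtomSelection | None = None,
    burn_in: int = 0,
    domain: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-average position.

    Frames before ``burn_in`` (non-equilibrated part) are discarded; the
    remaining frames are iteratively fitted to their average structure on
    ``fit_region`` (default: the analysis selection itself).
    """
    if burn_in >= traj.n_frames:
        raise ValueError("burn_in leaves no frames")
    if fit_region is None:
        fit_region = selection
    idx_sel, sel_coords = select(traj, selection, domain)
    idx_fit, fit_coords = select(traj, fit_region, domain)
    sel_coords = sel_coords[burn_in:]
    fit_coords = fit_coords[burn_in:]
    if sel_coords.shape[0] < 2:
        raise ValueError("need at least 2 retained frames")
    # iterate the fit on the fit region, apply transforms to the analysis set
    _, mean_fit = iterative_average_fit(fit_coords)
    moved = np.empty_like(sel_coords)
    for f in range(sel_coords.shape[0]):
        sup = kabsch_fit(fit_coords[f], mean_fit)
        moved[f] = sup.transform(sel_coords[f])
    mean_pos = moved.mean(axis=0)
    return np.sqrt(np.mean(np.sum((moved - mean_pos) ** 2, axis=2), axis=0))


def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> float:
    """Mass-weighted radius of gyration about the centre of mass (Å)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one point")
    if masses is None:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    com = masses @ coords / masses.sum()
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(masses @ sq / masses.sum()))


def structure_masses(structure: Structure, indices: np.ndarray) -> np.ndarray:
    elements = structure.atoms.element[indices]
    return np.array([_MASSES.get(e.upper(), 12.011) for e in elements])


def rg_series(
    traj: Trajectory,
    selection: AtomSelection = CA,
    domain: tuple[int, int] | None = None,
    mass_weighted: bool = True,
) -> MetricSeries:
    """Radius of gyration per frame over a region."""
    idx, coords = select(traj, selection, domain)
    masses = structure_masses(traj.topology, idx) if mass_weighted else None
    values = np.array([radius_of_gyration(c, masses) for c in coords])
    return MetricSeries(values=values, label="rg_A", time_step=traj.time_step)


def rmsd100(rmsd: float, n_residues: int) -> float:
    """Size-normalised RMSD: rmsd / (1 + ln sqrt(n/100)).

    The denominator vanishes near n ≈ 13; n is clamped to ≥ 20.
    """
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    if n_residues < 20:
        raise ValueError("rmsd100 requires at least 20 residues")
    return float(rmsd / (1.0 + np.log(np.sqrt(n_residues / 100.0))))


def end_to_end_distance(
    obj: Structure | np.ndarray,
    scheme: DomainScheme,
    topology: Structure | None = None,
) -> float:
    """Cα–Cα distance d between the scheme's reference-pair residues (Å)."""
    if isinstance(obj, Structure):
        structure, coords = obj, obj.coords
    else:
        if topology is None:
            raise ValueError("raw coordinates require a topology")
        structure, coords = topology, np.asarray(obj, dtype=float)
    res_a, res_b = scheme.reference_pair
    pos = {}
    for res in (res_a, res_b):
        mask = (structure.residue_numbers == res) & (structure.atom_names == "CA")
        hits = np.nonzero(mask)[0]
        if hits.size == 0:
            raise ValueError(f"residue {res} has no CA atom in this structure")
        pos[res] = coords[hits[0]]
    return float(np.linalg.norm(pos[res_a] - pos[res_b]))


def d_series(traj: Trajectory, scheme: DomainScheme) -> MetricSeries:
    """End-to-end distance d per frame."""
    values = np.array(
        [end_to_end_distance(traj.coords[f], scheme, traj.topology)
         for f in range(traj.n_frames)]
    )
    return MetricSeries(values=values, label="d_A", time_step=traj.time_step)


# ---------------------------------------------------------------------------
# Ramachandran allowed-region fraction
# ---------------------------------------------------------------------------

# Coarse allowed-region map (favored + allowed), axis-aligned boxes in
# (phi, psi) degrees: right-handed helix, beta/extended (with the psi
# wrap-around strip), the polyproline-II bridge and the left-handed helix.
_ALLOWED_BOXES = [
    (-180.0, -40.0, -80.0, 0.0),    # alpha region
    (-180.0, -40.0, 60.0, 180.0),   # beta region
    (-180.0, -40.0, -180.0, -150.0),  # beta wrap-around
    (-180.0, -90.0, 0.0, 60.0),     # bridge / ppII
    (30.0, 90.0, -20.0, 90.0),      # left-handed alpha
]


def _in_allowed(phi: float, psi: float) -> bool:
    return any(
        lo_f <= phi <= hi_f and lo_s <= psi <= hi_s
        for lo_f, hi_f, lo_s, hi_s in _ALLOWED_BOXES
    )


def backbone_dihedrals(structure: Structure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-residue (phi, psi) in degrees plus the residue numbers."""
    phi, psi, _ = bst.dihedral_backbone(structure.atoms)
    res_ids = np.unique(structure.residue_numbers)
    return np.degrees(phi), np.degrees(psi), res_ids


def ramachandran_fraction(
    obj: Structure | Trajectory,
    region: tuple[int, int] | None = None,
) -> float:
    """Fraction of non-Gly/non-Pro residues with (phi, psi) inside the
    allowed-region map.  For a trajectory, pooled over frames."""
    frames = (
        [obj.frame(i) for i in range(obj.n_frames)]
        if isinstance(obj, Trajectory)
        else [obj]
    )
    n_in = n_tot = 0
    for frame in frames:
        phi, psi, res_ids = backbone_dihedrals(frame)
        res_names = {}
        for rid, rname in zip(frame.residue_numbers, frame.residue_names):
            res_names[int(rid)] = rname
        for p, s, rid in zip(phi, psi, res_ids):
            if region is not None and not region[0] <= rid <= region[1]:
                continue
            if res_names.get(int(rid)) in ("GLY", "PRO"):
                continue
            if np.isnan(p) or np.isnan(s):  # chain termini
                continue
            n_tot += 1
            if _in_allowed(float(p), float(s)):
                n_in += 1
    if n_tot == 0:
        raise ValueError("no evaluable (non-Gly/Pro, complete-backbone) residues")
    return n_in / n_tot
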