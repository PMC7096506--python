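"""Essential dynamics: covariance, PCA, mode export, cross-correlation maps.

The positional covariance matrix C of the fitted Cα coordinates is
diagonalised, C = V Λ Vᵀ; the leading eigenvectors (principal modes)
describe the concerted displacements, the eigenvalues the variance (Å²)
each mode carries.  The dynamic cross-correlation map (DCCM) holds the
normalised fluctuation correlations ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)
for all Cα pairs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from kitcd.core import CA, AtomSelection, Structure, Trajectory, write_pdb
from kitcd.geometry import iterative_average_fit, superpose_frames, select


@dataclasses.dataclass
class EssentialDynamics:
    """Covariance matrix with (optionally) its eigendecomposition."""

    covariance: np.ndarray  # (3N, 3N), Å²
    mean_structure: np.ndarray  # (N, 3)
    atom_indices: np.ndarray
    eigenvalues: np.ndarray | None = None  # descending, Å²
    eigenvectors: np.ndarray | None = None  # orthonormal columns

    @property
    def n_atoms(self) -> int:
        return self.mean_structure.shape[0]


def covariance(
    traj: Trajectory,
    selection: AtomSelection = CA,
    fit_target: str = "average",
    burn_in: int = 0,
    domain: tuple[int, int] | None = None,
) -> EssentialDynamics:
    """Positional covariance of the selected atoms after removing rigid-body
    motion.

    ``fit_target='average'`` iterates fit ↔ mean to convergence (1e-6 Å);
    ``'initial'`` fits every frame on the first retained frame.  Frames
    before ``burn_in`` are discarded.
    """
    if fit_target not in ("average", "initial"):
        raise ValueError("fit_target must be 'average' or 'initial'")
    idx, coords = select(traj, selection, domain)
    coords = coords[burn_in:]
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 retained frames")
    if fit_target == "average":
        fitted, mean = iterative_average_fit(coords)
    else:
        fitted = superpose_frames(coords, coords[0])
        mean = fitted.mean(axis=0)
    dev = (fitted - mean).reshape(fitted.shape[0], -1)  # (F, 3N)
    cov = dev.T @ dev / dev.shape[0]
    return EssentialDynamics(covariance=cov, mean_structure=mean, atom_indices=idx)


def pca(ed: EssentialDynamics) -> EssentialDynamics:
    """Diagonalise the covariance matrix in place: C = V Λ Vᵀ.

    Eigenvalues are returned in descending order; each eigenvector is
    oriented so its largest-magnitude component is positive.
    """
    c = ed.covariance
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("covariance matrix must be symmetric")
    vals, vecs = np.linalg.eigh(c)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for k in range(vecs.shape[1]):
        lead = np.argmax(np.abs(vecs[:, k]))
        if vecs[lead, k] < 0:
            vecs[:, k] = -vecs[:, k]
    ed.eigenvalues = vals
    ed.eigenvectors = vecs
    return ed


def cumulative_variance(ed: EssentialDynamics, n_modes: int) -> float:
    """Fraction of total positional variance carried by the first n modes."""
    if ed.eigenvalues is None:
        raise ValueError("run pca() first")
    vals = np.clip(ed.eigenvalues, 0.0, None)
    total = vals.sum()
    if total == 0:
        return 0.0
    return float(vals[:n_modes].sum() / total)


def mode_displacements(
    ed: EssentialDynamics, mode_index: int, cutoff: float = 0.0
) -> dict:
    """Per-atom displacement vectors of one principal mode.

    The per-atom amplitude is the eigenvector's 3-vector norm scaled by
    sqrt(λ); atoms with amplitude below ``cutoff`` (Å) are suppressed.
    """
    if ed.eigenvalues is None or ed.eigenvectors is None:
        raise ValueError("run pca() first")
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if not 0 <= mode_index < len(ed.eigenvalues):
        raise IndexError(f"mode {mode_index} does not exist")
    lam = max(float(ed.eigenvalues[mode_index]), 0.0)
    vec = ed.eigenvectors[:, mode_index].reshape(-1, 3)
    displacement = np.sqrt(lam) * vec
    amplitude = np.linalg.norm(displacement, axis=1)
    keep = amplitude >= cutoff
    return {
        "mode": mode_index,
        "eigenvalue": lam,
        "displacements": displacement,
        "amplitudes": amplitude,
        "kept_atoms": np.nonzero(keep)[0],
    }


def export_mode_pdb(
    ed: EssentialDynamics,
    mode_index: int,
    topology: Structure,
    path,
    scale: float = 2.0,
) -> None:
    """Write a two-frame PDB (mean ± scale·sqrt(λ)·mode) for porcupine-style
    inspection of one principal mode."""
    disp = mode_displacements(ed, mode_index)["displacements"]
    sub = Structure(topology.atoms[ed.atom_indices].copy())
    frames = np.stack(
        [ed.mean_structure - scale * disp, ed.mean_structure + scale * disp]
    )
    write_pdb(Trajectory(coords=frames, topology=sub), path)


def eigenspectrum_csv(ed: EssentialDynamics, path, n_modes: int | None = None) -> None:
    """Mode, eigenvalue (Å²), cumulative variance fraction as CSV."""
    if ed.eigenvalues is None:
        raise ValueError("run pca() first")
    n = n_modes or len(ed.eigenvalues)
    rows = [
        (k + 1, float(ed.eigenvalues[k]), cumulative_variance(ed, k + 1))
        for k in range(n)
    ]
    with open(path, "w") as fh:
        fh.write("mode,eigenvalue_A2,cumulative_fraction\n")
        for mode, lam, frac in rows:
            fh.write(f"{mode},{lam:.6g},{frac:.6f}\n")


def dccm(
    traj: Trajectory,
    selection: AtomSelection = CA,
    fit_target: str = "average",
    burn_in: int = 0,
    domain: tuple[int, int] | None = None,
) -> dict:
    """Dynamic cross-correlation map over the fitted fluctuations.

    Atoms with zero fluctuation get a zero off-diagonal row/column (unit
    diagonal) and are flagged.
    """
    ed = covariance(traj, selection, fit_target, burn_in, domain)
    n = ed.n_atoms
    c = ed.covariance.reshape(n, 3, n, 3)
    inner = np.einsum("iaja->ij", c)  # ⟨Δr_i · Δr_j⟩
    var = np.diag(inner).copy()
    zero = var <= 1e-12
    safe_var = np.where(zero, 1.0, var)
    corr = inner / np.sqrt(np.outer(safe_var, safe_var))
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    return {
        "map": corr,
        "zero_fluctuation_atoms": np.nonzero(zero)[0],
        "atom_indices": ed.atom_indices,
    }
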