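"""Per-residue secondary-structure assignment and SS-based scores.

Assignment follows the Kabsch–Sander scheme: backbone hydrogen bonds are
detected with the electrostatic energy model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond accepted below -0.5 kcal/mol, amide hydrogens reconstructed
1.0 Å from N opposite the preceding carbonyl when absent.  The n-turn and
bridge pattern rules then yield the eight-letter alphabet
{H, G, I, E, B, T, S, C}, resolved with priority H > E > B > G > I > T > S.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from kitcd.core import Structure, Trajectory

SS_ALPHABET = "HGIEBTSC"

_Q1Q2_F = 0.084 * 332.0  # kcal/mol * Å, Kabsch–Sander coupling constant
_HBOND_CUTOFF = -0.5  # kcal/mol
_BEND_ANGLE = 70.0  # degrees


@dataclasses.dataclass
class SSTimeline:
    """Residues × sampled-frames matrix of SS symbols."""

    matrix: np.ndarray  # dtype '<U1', shape (n_residues, n_samples)
    residue_numbers: np.ndarray
    stride_ps: float

    def __post_init__(self) -> None:
        if self.stride_ps <= 0:
            raise ValueError("stride must be positive")
        bad = set(np.unique(self.matrix)) - set(SS_ALPHABET)
        if bad:
            raise ValueError(f"invalid SS symbols {bad}")

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def type_percentages(self) -> dict[str, np.ndarray]:
        """Per-residue percentage of simulation time spent in each SS type."""
        out = {}
        for sym in SS_ALPHABET:
            out[sym] = 100.0 * np.mean(self.matrix == sym, axis=1)
        return out

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# rows: residues, columns: sampled frames\n")
            for row in self.matrix:
                fh.write("".join(row) + "\n")


def _backbone_table(structure: Structure) -> dict:
    """Collect N/CA/C/O coordinates per residue, in residue order."""
    res_order: list[int] = []
    seen = set()
    for rid in structure.residue_numbers:
        if int(rid) not in seen:
            seen.add(int(rid))
            res_order.append(int(rid))
    n_res = len(res_order)
    pos = {name: np.full((n_res, 3), np.nan) for name in ("N", "CA", "C", "O", "H")}
    index = {rid: i for i, rid in enumerate(res_order)}
    names = {rid: "" for rid in res_order}
    for atom_i in range(structure.n_atoms):
        rid = int(structure.residue_numbers[atom_i])
        aname = structure.atom_names[atom_i]
        names[rid] = structure.residue_names[atom_i]
        if aname in pos:
            pos[aname][index[rid]] = structure.coords[atom_i]
    complete = np.ones(n_res, dtype=bool)
    for name in ("N", "CA", "C", "O"):
        complete &= np.all(np.isfinite(pos[name]), axis=1)
    return {
        "res_order": np.array(res_order),
        "pos": pos,
        "complete": complete,
        "res_names": names,
    }


def _reconstruct_h(pos: dict, complete: np.ndarray) -> np.ndarray:
    """Amide H 1.0 Å from N, anti to the preceding C=O.

    Proline is excluded upstream by the energy stage: its N carries no
    amide H, and DSSP likewise skips proline donors."""
    n_res = pos["N"].shape[0]
    h = pos["H"].copy()
    for i in range(1, n_res):
        if np.all(np.isfinite(h[i])):
            continue
        if not (complete[i] and complete[i - 1]):
            continue
        co = pos["C"][i - 1] - pos["O"][i - 1]
        norm = np.linalg.norm(co)
        if norm < 1e-9:
            continue
        h[i] = pos["N"][i] + co / norm
    return h


def _hbond_matrix(table: dict) -> np.ndarray:
    """hb[donor, acceptor]: True when NH(donor) → C=O(acceptor) qualifies."""
    pos, complete = table["pos"], table["complete"]
    res_names = table["res_names"]
    res_order = table["res_order"]
    n = len(res_order)
    h = _reconstruct_h(pos, complete)
    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):  # donor
        if not complete[i] or not np.all(np.isfinite(h[i])):
            continue
        if res_names[int(res_order[i])] == "PRO":
            continue  # proline nitrogen has no amide hydrogen
        for j in range(n):  # acceptor
            if j == i or not complete[j]:
                continue
            if abs(i - j) < 2 and j == i - 1:
                continue  # donor cannot bond its own preceding carbonyl
            r_on = np.linalg.norm(pos["N"][i] - pos["O"][j])
            if r_on > 5.2:  # beyond any plausible H-bond, skip energy
                continue
            r_ch = np.linalg.norm(h[i] - pos["C"][j])
            r_oh = np.linalg.norm(h[i] - pos["O"][j])
            r_cn = np.linalg.norm(pos["N"][i] - pos["C"][j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energy = -9.9  # clash convention
            else:
                energy = _Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HBOND_CUTOFF:
                hb[i, j] = True
    return hb


def hbond_energy(
    n_pos: np.ndarray, h_pos: np.ndarray, c_pos: np.ndarray, o_pos: np.ndarray
) -> float:
    """Kabsch–Sander electrostatic H-bond energy for explicit positions."""
    r_on = np.linalg.norm(n_pos - o_pos)
    r_ch = np.linalg.norm(h_pos - c_pos)
    r_oh = np.linalg.norm(h_pos - o_pos)
    r_cn = np.linalg.norm(n_pos - c_pos)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9
    return _Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def assign_ss(structure: Structure, return_flags: bool = False):
    """Kabsch–Sander-style assignment; one symbol per residue.

    Residues with incomplete backbones are assigned 'C'; with
    ``return_flags`` the residue numbers of those flagged residues are
    returned alongside the SS string.
    """
    table = _backbone_table(structure)
    n = len(table["res_order"])
    hb = _hbond_matrix(table)
    # turn(i, n): H-bond from CO of residue i to NH of residue i+n
    turn = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in (3, 4, 5):
        for i in range(n - m):
            if hb[i + m, i]:
                turn[m][i] = True

    helix = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in (3, 4, 5):
        for i in range(1, n - m):
            if turn[m][i - 1] and turn[m][i]:
                helix[m][i : i + m] = True

    # bridges
    bridge = np.zeros(n, dtype=bool)
    partner: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            anti = (hb[j, i] and hb[i, j]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if para or anti:
                bridge[i] = bridge[j] = True
                partner[i].append(j)
                partner[j].append(i)
    # ladders: a bridge extends to 'E' when an adjacent residue bridges an
    # adjacent partner
    strand = np.zeros(n, dtype=bool)
    for i in range(n):
        if not bridge[i]:
            continue
        for j in partner[i]:
            for di in (-1, 1):
                k = i + di
                if 0 <= k < n and bridge[k]:
                    if any(abs(pj - j) == 1 for pj in partner[k]):
                        strand[i] = strand[k] = True

    # turns: interior residues of an n-turn
    turn_res = np.zeros(n, dtype=bool)
    for m in (3, 4, 5):
        for i in range(n - m):
            if turn[m][i]:
                turn_res[i + 1 : i + m] = True

    # bends from Calpha curvature
    bend = np.zeros(n, dtype=bool)
    ca = table["pos"]["CA"]
    for i in range(2, n - 2):
        v1 = ca[i] - ca[i - 2]
        v2 = ca[i + 2] - ca[i]
        if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
            continue
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle > _BEND_ANGLE:
            bend[i] = True

    out = []
    for i in range(n):
        if not table["complete"][i]:
            out.append("C")
        elif helix[4][i]:
            out.append("H")
        elif strand[i]:
            out.append("E")
        elif bridge[i]:
            out.append("B")
        elif helix[3][i]:
            out.append("G")
        elif helix[5][i]:
            out.append("I")
        elif turn_res[i]:
            out.append("T")
        elif bend[i]:
            out.append("S")
        else:
            out.append("C")
    if return_flags:
        flagged = [int(r) for r, ok in zip(table["res_order"], table["complete"])
                   if not ok]
        return "".join(out), flagged
    return "".join(out)


def ss_timeline(traj: Trajectory, stride_ps: float = 10.0) -> SSTimeline:
    """Assign SS every ``stride_ps`` picoseconds along the trajectory."""
    step_ps = traj.time_step * 1000.0
    if stride_ps < step_ps:
        raise ValueError(
            f"stride {stride_ps} ps is below the trajectory time step {step_ps} ps"
        )
    every = max(1, int(round(stride_ps / step_ps)))
    sample_idx = range(0, traj.n_frames, every)
    columns = [list(assign_ss(traj.frame(i))) for i in sample_idx]
    matrix = np.array(columns).T  # residues × samples
    res_numbers = np.unique(traj.topology.residue_numbers)
    return SSTimeline(matrix=matrix, residue_numbers=res_numbers, stride_ps=stride_ps)


def ss_content_series(timeline: SSTimeline) -> dict[str, np.ndarray]:
    """Per-frame fraction of residues in each SS type, plus the sum of
    folded structure (1 − coil − turn − bend)."""
    if timeline.n_samples == 0 or timeline.n_residues == 0:
        raise ValueError("empty timeline")
    out = {}
    for sym in SS_ALPHABET:
        out[sym] = np.mean(timeline.matrix == sym, axis=0)
    out["folded"] = 1.0 - out["C"] - out["T"] - out["S"]
    return out


def ss_similarity_matrix(ss_strings: list[str]) -> np.ndarray:
    """Pairwise SS distance: 1 − fraction of identical positions."""
    lengths = {len(s) for s in ss_strings}
    if len(lengths) > 1:
        raise ValueError(f"SS strings have unequal lengths: {sorted(lengths)}")
    arr = np.array([list(s) for s in ss_strings])
    n = len(ss_strings)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - float(np.mean(arr[i] == arr[j]))
            dist[i, j] = dist[j, i] = d
    return dist


def _merge_helices(symbols: np.ndarray) -> np.ndarray:
    merged = symbols.copy()
    merged[np.isin(merged, ["G", "I"])] = "H"
    return merged


def ss_conservation(
    timeline: SSTimeline,
    reference_ss: str,
    region: tuple[int, int] | None = None,
) -> float:
    """Mean per-frame identity fraction to a reference assignment.

    Helix subtypes (H/G/I) are merged before comparison; strand subtypes are
    kept distinct.  ``region`` restricts to a residue-number range.
    """
    if len(reference_ss) != timeline.n_residues:
        raise ValueError("reference SS length does not match timeline")
    mask = np.ones(timeline.n_residues, dtype=bool)
    if region is not None:
        mask = (timeline.residue_numbers >= region[0]) & (
            timeline.residue_numbers <= region[1]
        )
        if not mask.any():
            raise ValueError("region outside the timeline's residues")
    ref = _merge_helices(np.array(list(reference_ss)))[mask]
    mat = _merge_helices(timeline.matrix)[mask]
    return float(np.mean(mat == ref[:, None]))
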