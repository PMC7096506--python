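"""Structure/trajectory data model, PDB I/O, domain schemes and atom selection.

Coordinates are in Å throughout; trajectory time steps in ns per frame.
PDB parsing and writing are delegated to :mod:`biotite.structure.io.pdb`;
this module wraps the resulting atom arrays in lightweight containers that
the rest of the pipeline consumes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


_EXTRA_FIELDS = ["atom_id", "occupancy", "b_factor"]


@dataclasses.dataclass
class Structure:
    """A single conformation: a wrapped :class:`biotite.structure.AtomArray`.

    Invariants: coordinates finite; every atom belongs to exactly one
    residue (chain_id, res_id, ins_code triple).
    """

    atoms: bst.AtomArray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("structure contains non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return self.atoms.coord

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.atoms.res_id

    @property
    def atom_names(self) -> np.ndarray:
        return self.atoms.atom_name

    @property
    def residue_names(self) -> np.ndarray:
        return self.atoms.res_name

    @property
    def chain_ids(self) -> np.ndarray:
        return self.atoms.chain_id

    def first_chain(self) -> "Structure":
        """Restrict to the first chain (schemes apply to single chains)."""
        chains = self.atoms.chain_id
        return Structure(self.atoms[chains == chains[0]])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        new = self.atoms.copy()
        new.coord = np.asarray(coords, dtype=float)
        return Structure(new)

    def residue_span(self) -> tuple[int, int]:
        return int(self.atoms.res_id.min()), int(self.atoms.res_id.max())


@dataclasses.dataclass
class Trajectory:
    """Ordered frames over a fixed atom set.

    ``coords`` has shape (n_frames, n_atoms, 3); atom ordering is identical
    across frames and matches ``topology``.
    """

    coords: np.ndarray
    topology: Structure
    time_step: float = 0.001  # ns per frame (coordinates every 1 ps)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.time_step

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])


@dataclasses.dataclass
class AtomSelection:
    """Predicate over atoms: atom-name set and/or residue-number range."""

    atom_names: frozenset[str] | None = None
    first_residue: int | None = None
    last_residue: int | None = None

    def __post_init__(self) -> None:
        if self.atom_names is not None:
            self.atom_names = frozenset(self.atom_names)

    def restricted(self, first: int, last: int) -> "AtomSelection":
        lo = first if self.first_residue is None else max(first, self.first_residue)
        hi = last if self.last_residue is None else min(last, self.last_residue)
        return AtomSelection(self.atom_names, lo, hi)

    def indices(self, structure: Structure) -> np.ndarray:
        mask = np.ones(structure.n_atoms, dtype=bool)
        if self.atom_names is not None:
            mask &= np.isin(structure.atom_names, list(self.atom_names))
        if self.first_residue is not None:
            mask &= structure.residue_numbers >= self.first_residue
        if self.last_residue is not None:
            mask &= structure.residue_numbers <= self.last_residue
        return np.nonzero(mask)[0]


#: Cα-only selection, the universal analysis selection of the pipeline.
CA = AtomSelection(atom_names=frozenset({"CA"}))

#: All-atom selection.
ALL = AtomSelection()


def select(
    obj: Structure | Trajectory,
    selection: AtomSelection,
    domain: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply ``selection`` (optionally restricted to a residue range).

    Returns ``(indices, coords)`` where coords is (n_sel, 3) for a
    Structure and (n_frames, n_sel, 3) for a Trajectory.  The index set is
    computed on the topology, hence identical for every frame.
    """
    topo = obj.topology if isinstance(obj, Trajectory) else obj
    sel = selection if domain is None else selection.restricted(*domain)
    idx = sel.indices(topo)
    if idx.size == 0:
        raise ValueError(f"selection {sel} matches no atoms")
    if isinstance(obj, Trajectory):
        return idx, obj.coords[:, idx, :]
    return idx, topo.coords[idx]


# ---------------------------------------------------------------------------
# Domain schemes
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DomainScheme:
    """Named residue ranges plus the reference pair of the end-to-end metric.

    ``ranges`` must be mutually non-overlapping; ``extra_ranges`` may span
    domain boundaries (the elongated KID deliberately overlaps both kinase
    lobes) and are exempt from the check.  A single shared boundary residue
    between two ranges is recorded in ``overlap_flags`` rather than rejected.
    """

    ranges: dict[str, tuple[int, int]]
    reference_pair: tuple[int, int]
    extra_ranges: dict[str, tuple[int, int]] = dataclasses.field(default_factory=dict)
    overlap_flags: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        items = sorted(self.ranges.items(), key=lambda kv: kv[1][0])
        for (name_a, (a0, a1)), (name_b, (b0, b1)) in zip(items, items[1:]):
            if a1 < b0:
                continue
            if a1 == b0:
                self.overlap_flags.append(
                    f"{name_a} and {name_b} share boundary residue {a1}"
                )
            else:
                raise ValueError(f"domains {name_a} and {name_b} overlap")
        for name, (lo, hi) in {**self.ranges, **self.extra_ranges}.items():
            if lo > hi:
                raise ValueError(f"domain {name}: first residue exceeds last")

    def __getitem__(self, name: str) -> tuple[int, int]:
        if name in self.ranges:
            return self.ranges[name]
        return self.extra_ranges[name]

    @property
    def domain_names(self) -> list[str]:
        return list(self.ranges)

    def domains_within(self, structure: Structure) -> list[str]:
        """Domains fully covered by the structure's residue numbering."""
        lo, hi = structure.residue_span()
        return [n for n, (a, b) in self.ranges.items() if a >= lo and b <= hi]


def kit_domain_scheme() -> DomainScheme:
    """The KIT cytoplasmic-domain scheme in 1T45 author numbering.

    Strict KID is Q694–T753; the elongated KID (ten residues into each
    kinase lobe) is F689–D768; the C-terminal segment is K936–V976.  The
    end-to-end reference pair is (F689, D768).  JMR and lobe boundaries
    follow the standard KIT annotation (JMR Y547–W582 boundary at 581,
    N-lobe up to the KID, C-lobe to residue 935).
    """
    scheme = DomainScheme(
        ranges={
            "JMR": (547, 581),
            "N-lobe": (582, 693),
            "KID": (694, 753),
            "C-lobe": (754, 935),
            "C-term": (936, 976),
        },
        reference_pair=(689, 768),
        extra_ranges={"KID-elongated": (689, 768)},
    )
    # The crystallographic template ends at V936 while the C-terminal build
    # starts at K936: residue 936 is claimed by both descriptions.
    scheme.overlap_flags.append(
        "template coverage (…936) and C-term range (936…) share residue 936"
    )
    return scheme


def write_scheme(scheme: DomainScheme, path: str | Path) -> None:
    """Write a scheme as a plain-text config (name first last per line)."""
    lines = []
    for name, (lo, hi) in scheme.ranges.items():
        lines.append(f"domain {name} {lo} {hi}")
    for name, (lo, hi) in scheme.extra_ranges.items():
        lines.append(f"extra {name} {lo} {hi}")
    lines.append(f"reference_pair {scheme.reference_pair[0]} {scheme.reference_pair[1]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scheme(path: str | Path) -> DomainScheme:
    ranges: dict[str, tuple[int, int]] = {}
    extra: dict[str, tuple[int, int]] = {}
    pair: tuple[int, int] | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            if parts[0] == "domain":
                ranges[parts[1]] = (int(parts[2]), int(parts[3]))
            elif parts[0] == "extra":
                extra[parts[1]] = (int(parts[2]), int(parts[3]))
            elif parts[0] == "reference_pair":
                pair = (int(parts[1]), int(parts[2]))
            else:
                raise ValueError(f"unknown record '{parts[0]}'")
        except (IndexError, ValueError) as exc:
            raise PDBParseError(f"{path}, line {lineno}: {exc}") from exc
    if pair is None:
        raise PDBParseError(f"{path}: missing reference_pair record")
    return DomainScheme(ranges=ranges, reference_pair=pair, extra_ranges=extra)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _load_pdb(path: str | Path) -> PDBFile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise PDBParseError(f"{path}: empty file")
    try:
        return PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite error paths
        raise PDBParseError(f"{path}: {exc}") from exc


def _locate_bad_line(path: Path) -> int | None:
    """Find the first ATOM/HETATM record with a malformed coordinate field."""
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                return lineno
    return None


def read_pdb(path: str | Path) -> Structure:
    """Read the first model of a PDB file.

    Alternate locations resolve to the highest-occupancy conformer (ties go
    to altloc 'A', biotite's occupancy policy).  Malformed coordinate fields
    raise :class:`PDBParseError` with the offending line number.
    """
    pdb = _load_pdb(path)
    try:
        atoms = pdb.get_structure(
            model=1, altloc="occupancy", extra_fields=_EXTRA_FIELDS
        )
    except Exception as exc:
        bad = _locate_bad_line(Path(path))
        where = f", line {bad}" if bad is not None else ""
        raise PDBParseError(f"{path}{where}: {exc}") from exc
    if atoms.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    return Structure(atoms)


def read_multimodel(path: str | Path, time_step: float = 0.001) -> Trajectory:
    """Read a multi-model PDB as a trajectory (frames ordered by model number).

    Models with inconsistent atom counts raise an error naming the first
    offending model.
    """
    pdb = _load_pdb(path)
    counts = _model_atom_counts(Path(path))
    if len(set(counts)) > 1:
        bad = next(i + 1 for i, c in enumerate(counts) if c != counts[0])
        raise PDBParseError(
            f"{path}: model {bad} has {counts[bad - 1]} atoms, "
            f"expected {counts[0]}"
        )
    try:
        stack = pdb.get_structure(altloc="occupancy", extra_fields=_EXTRA_FIELDS)
    except Exception as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if isinstance(stack, bst.AtomArray):  # single model, no MODEL records
        stack = bst.stack([stack])
    topo = Structure(stack[0])
    return Trajectory(coords=stack.coord.copy(), topology=topo, time_step=time_step)


def _model_atom_counts(path: Path) -> list[int]:
    counts: list[int] = []
    current = 0
    in_model = False
    for line in path.read_text().splitlines():
        if line.startswith("MODEL"):
            in_model = True
            current = 0
        elif line.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif line.startswith(("ATOM", "HETATM")):
            current += 1
    if not counts and not in_model:
        # no MODEL records: the whole file is one implicit model
        n = sum(
            1
            for line in path.read_text().splitlines()
            if line.startswith(("ATOM", "HETATM"))
        )
        counts = [n]
    return counts


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a structure (one model) or trajectory (MODEL/ENDMDL blocks)."""
    pdb = PDBFile()
    if isinstance(obj, Trajectory):
        arrays = [obj.topology.atoms.copy() for _ in range(obj.n_frames)]
        for arr, frame in zip(arrays, obj.coords):
            arr.coord = np.asarray(frame, dtype=np.float32)
        pdb.set_structure(bst.stack(arrays))
    else:
        pdb.set_structure(obj.atoms)
    pdb.write(str(path))


def make_ca_structure(
    coords: np.ndarray,
    residue_numbers: Sequence[int] | None = None,
    chain_id: str = "A",
    res_name: str = "ALA",
) -> Structure:
    """Build a Cα-bead structure from raw coordinates (one atom per residue)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if residue_numbers is None:
        residue_numbers = np.arange(1, n + 1)
    atoms = bst.AtomArray(n)
    atoms.coord = coords.astype(np.float32)
    atoms.chain_id = np.full(n, chain_id)
    atoms.res_id = np.asarray(residue_numbers, dtype=int)
    atoms.res_name = np.full(n, res_name)
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.set_annotation("atom_id", np.arange(1, n + 1))
    atoms.set_annotation("occupancy", np.ones(n))
    atoms.set_annotation("b_factor", np.zeros(n))
    return Structure(atoms)


def make_backbone_structure(
    backbone: Iterable[tuple[str, np.ndarray]],
    residue_numbers: Sequence[int],
    res_names: Sequence[str] | None = None,
    chain_id: str = "A",
) -> Structure:
    """Build a full-backbone structure from per-residue (atom_name, xyz) lists.

    ``backbone`` is an iterable over residues, each a list of
    ``(atom_name, coord)`` pairs (typically N, CA, C, O).
    """
    names: list[str] = []
    res_ids: list[int] = []
    rnames: list[str] = []
    coords: list[np.ndarray] = []
    elements: list[str] = []
    name_map = (
        dict(zip(residue_numbers, res_names)) if res_names is not None else {}
    )
    for resi, atoms_of_res in zip(residue_numbers, backbone):
        for atom_name, xyz in atoms_of_res:
            names.append(atom_name)
            res_ids.append(int(resi))
            rnames.append(name_map.get(int(resi), "ALA"))
            coords.append(np.asarray(xyz, dtype=float))
            elements.append(atom_name[0])
    n = len(names)
    atoms = bst.AtomArray(n)
    atoms.coord = np.asarray(coords, dtype=np.float32)
    atoms.chain_id = np.full(n, chain_id)
    atoms.res_id = np.asarray(res_ids, dtype=int)
    atoms.res_name = np.asarray(rnames)
    atoms.atom_name = np.asarray(names)
    atoms.element = np.asarray(elements)
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.set_annotation("atom_id", np.arange(1, n + 1))
    atoms.set_annotation("occupancy", np.ones(n))
    atoms.set_annotation("b_factor", np.zeros(n))
    return Structure(atoms)
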