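"""Molecular structures, trajectories, atom selections and the troponin-C region map.

Structures are plain ordered atom lists read from PDB (or PQR-style PDB,
where the occupancy and B-factor columns carry partial charge and radius).
Trajectories are coordinate frame stacks over a fixed topology, stored on
disk as multi-model PDB.  All coordinates are in Å, times in ps.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "RegionMap",
    "TNC_REGIONS",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "select",
    "reconstruct_amide_hydrogens",
]


@dataclass
class Atom:
    """A single atom with PDB-style identity and optional charge/radius.

    ``radius`` may be negative only for designated phantom atoms (reaction
    markers used by Brownian dynamics), which must be flagged ``phantom=True``.
    """

    serial: int
    name: str
    residue_number: int
    residue_name: str
    chain: str
    coords: np.ndarray
    charge: float | None = None
    radius: float | None = None
    phantom: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if self.radius is not None and self.radius < 0 and not self.phantom:
            raise ValueError(
                f"negative radius {self.radius} only allowed for phantom atoms"
            )


@dataclass
class Structure:
    """Ordered collection of atoms; the static molecular model."""

    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} incompatible with {len(self.atoms)} atoms"
            )
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, title if title is not None else self.title)

    def residue_numbers(self) -> list[int]:
        """Sorted unique residue numbers."""
        return sorted({a.residue_number for a in self.atoms})

    def atom_index(self, residue_number: int, name: str) -> int:
        """Index of the unique atom matching residue number and atom name."""
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_number == residue_number and a.name == name
        ]
        if len(hits) != 1:
            raise KeyError(
                f"expected exactly one atom {name} in residue {residue_number}, "
                f"found {len(hits)}"
            )
        return hits[0]


@dataclass
class Trajectory:
    """Frame series of coordinates sharing a Structure topology.

    ``dt`` is the time between stored frames in ps (the study sampled
    snapshots every 6 ps).
    """

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    dt: float = 6.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] == 0:
            raise ValueError("trajectory must contain at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {len(self.topology)}"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, i: int) -> Structure:
        """Topology with the coordinates of frame ``i``."""
        return self.topology.with_coords(self.frames[i])


# The N-terminal regulatory domain of cardiac troponin C: five helices
# (HN, HA..HD), two short beta strands, the site I/II binding loops and
# the site II chelation residues.
_DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "HN": (4, 8),
    "HA": (14, 24),
    "HB": (38, 48),
    "HC": (54, 64),
    "HD": (73, 85),
    "loop_I": (25, 35),
    "loop_II": (65, 70),
    "beta1": (36, 37),
    "beta2": (71, 72),
}

# residue number -> (3-letter residue name, chelating oxygen atom names)
_DEFAULT_CHELATORS: dict[int, tuple[str, tuple[str, ...]]] = {
    65: ("ASP", ("OD1", "OD2")),
    67: ("ASP", ("OD1", "OD2")),
    69: ("SER", ("OG",)),
    71: ("THR", ("OG1",)),
    76: ("GLU", ("OE1", "OE2")),
}


@dataclass
class RegionMap:
    """Named residue intervals plus the site II chelation residues."""

    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_REGIONS)
    )
    chelators: dict[int, tuple[str, tuple[str, ...]]] = field(
        default_factory=lambda: dict(_DEFAULT_CHELATORS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.regions.items():
            if hi < lo:
                raise ValueError(f"region {name} interval ({lo},{hi}) is empty")

    def residues(self, region: str) -> list[int]:
        lo, hi = self.regions[region]
        return list(range(lo, hi + 1))

    def resolve(self, structure: Structure, region: str, atom_name: str = "CA") -> list[int]:
        """Atom indices of ``atom_name`` atoms in the named region."""
        wanted = set(self.residues(region))
        idx = [
            i
            for i, a in enumerate(structure.atoms)
            if a.residue_number in wanted and a.name == atom_name
        ]
        if not idx:
            raise KeyError(f"region {region} unresolvable in structure (no {atom_name})")
        return idx

    def validate_chelators(self, structure: Structure) -> None:
        """Check that chelator residue names match residue numbers."""
        by_num = {a.residue_number: a.residue_name for a in structure.atoms}
        for num, (resname, _) in self.chelators.items():
            if num in by_num and by_num[num] != resname:
                raise ValueError(
                    f"chelator residue {num} is {by_num[num]}, expected {resname}"
                )


TNC_REGIONS = RegionMap()


# ---------------------------------------------------------------------------
# PDB I/O (biotite does the format work)
# ---------------------------------------------------------------------------


def _atomarray_to_structure(arr: bst.AtomArray, title: str, pqr: bool) -> Structure:
    atoms = []
    occupancy = arr.get_annotation("occupancy") if "occupancy" in arr.get_annotation_categories() else None
    b_factor = arr.get_annotation("b_factor") if "b_factor" in arr.get_annotation_categories() else None
    for i in range(arr.array_length()):
        charge = radius = None
        phantom = False
        if pqr and occupancy is not None and b_factor is not None:
            charge = float(occupancy[i])
            radius = float(b_factor[i])
            phantom = radius < 0
        atoms.append(
            Atom(
                serial=i + 1,
                name=str(arr.atom_name[i]).strip(),
                residue_number=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]).strip(),
                chain=str(arr.chain_id[i]).strip() or "A",
                coords=np.array(arr.coord[i], dtype=float),
                charge=charge,
                radius=radius,
                phantom=phantom,
            )
        )
    return Structure(atoms, title=title)


def read_pdb(
    path: str | Path,
    model: int | None = 1,
    pqr: bool = False,
) -> Structure | list[Structure]:
    """Read a PDB file into a :class:`Structure`.

    Multi-model NMR files yield the requested ``model`` (1-based; default
    model 1).  ``model=None`` returns the full list of models.  With
    ``pqr=True`` the occupancy and B-factor columns are reinterpreted as
    partial charge (e) and radius (Å); negative radii mark phantom atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().replace("\r\n", "\n")
    if not re.search(r"^(ATOM|HETATM)", text, flags=re.M):
        raise ValueError(f"{path} contains no ATOM/HETATM records")
    pdb_file = PDBFile.read(str(path))
    stack = pdb_file.get_structure(extra_fields=["occupancy", "b_factor"])
    title = path.stem
    structures = [
        _atomarray_to_structure(stack[m], title, pqr)
        for m in range(stack.stack_depth())
    ]
    if model is None:
        return structures
    if not 1 <= model <= len(structures):
        raise ValueError(f"model {model} out of range (file has {len(structures)})")
    return structures[model - 1]


def _structure_to_atomarray(structure: Structure, pqr: bool) -> bst.AtomArray:
    n = len(structure)
    arr = bst.AtomArray(n)
    for i, a in enumerate(structure.atoms):
        arr.coord[i] = a.coords
        arr.atom_name[i] = a.name
        arr.res_id[i] = a.residue_number
        arr.res_name[i] = a.residue_name
        arr.chain_id[i] = a.chain
        arr.element[i] = (a.name[:1] or "C")
    arr.set_annotation("hetero", np.zeros(n, dtype=bool))
    if pqr:
        arr.set_annotation(
            "occupancy",
            np.array([a.charge if a.charge is not None else 0.0 for a in structure.atoms]),
        )
        arr.set_annotation(
            "b_factor",
            np.array([a.radius if a.radius is not None else 0.0 for a in structure.atoms]),
        )
    return arr


def write_pdb(structure: Structure, path: str | Path, pqr: bool = False) -> None:
    """Write a Structure as PDB (PQR-style columns when ``pqr=True``)."""
    arr = _structure_to_atomarray(structure, pqr)
    pdb_file = PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB (one MODEL per frame)."""
    arr = _structure_to_atomarray(traj.topology, pqr=False)
    stack = bst.AtomArrayStack(traj.n_frames, traj.n_atoms)
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord[:] = traj.frames
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    with open(path, "w") as fh:
        fh.write(f"REMARK 250 EFDYN DT {traj.dt:.6f} PS\n")
        fh.write("\n".join(pdb_file.lines) + "\n")


def read_trajectory(topology: Structure, path: str | Path, dt: float | None = None) -> Trajectory:
    """Read a multi-model PDB trajectory against a known topology.

    The frame atom count must equal the topology atom count.  ``dt`` falls
    back to the value recorded at write time (or 6 ps).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dt is None:
        dt = 6.0
        with open(path) as fh:
            for line in fh:
                m = re.match(r"REMARK 250 EFDYN DT ([0-9.eE+-]+) PS", line)
                if m:
                    dt = float(m.group(1))
                if line.startswith(("ATOM", "HETATM")):
                    break
    pdb_file = PDBFile.read(str(path))
    stack = pdb_file.get_structure()
    if isinstance(stack, bst.AtomArray):
        stack = bst.stack([stack])
    if stack.stack_depth() == 0:
        raise ValueError("trajectory file contains no frames")
    if stack.array_length() != len(topology):
        raise ValueError(
            f"trajectory atom count {stack.array_length()} does not match "
            f"topology atom count {len(topology)}"
        )
    return Trajectory(topology, np.array(stack.coord, dtype=float), dt=dt)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s+")


def _parse_clause(clause: str, atoms: Sequence[Atom]) -> set[int]:
    parts = _TOKEN.split(clause.strip())
    if len(parts) < 2:
        raise ValueError(f"unparsable selection clause: {clause!r}")
    key, args = parts[0].lower(), parts[1:]
    if key == "resid":
        wanted: set[int] = set()
        for tok in args:
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", tok)
            if not m:
                raise ValueError(f"bad resid token {tok!r} in {clause!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            wanted.update(range(lo, hi + 1))
        return {i for i, a in enumerate(atoms) if a.residue_number in wanted}
    if key == "name":
        names = {t.upper() for t in args}
        return {i for i, a in enumerate(atoms) if a.name.upper() in names}
    if key == "resname":
        names = {t.upper() for t in args}
        return {i for i, a in enumerate(atoms) if a.residue_name.upper() in names}
    if key == "chain":
        chains = set(args)
        return {i for i, a in enumerate(atoms) if a.chain in chains}
    raise ValueError(f"unknown selection keyword {parts[0]!r}")


def select(structure_or_traj: Structure | Trajectory, spec: str) -> list[int]:
    """Resolve a selection spec to sorted atom indices.

    Grammar: clauses ``resid A-B``, ``name X [Y...]``, ``resname X``,
    ``chain X`` combined with ``and`` / ``or`` (``and`` binds tighter).
    Clause order within a conjunction does not affect the result.  An empty
    selection is allowed but triggers a warning.
    """
    structure = (
        structure_or_traj.topology
        if isinstance(structure_or_traj, Trajectory)
        else structure_or_traj
    )
    atoms = structure.atoms
    if not spec.strip():
        raise ValueError("empty selection spec")
    result: set[int] = set()
    for disjunct in re.split(r"\bor\b", spec):
        clause_sets = [
            _parse_clause(c, atoms) for c in re.split(r"\band\b", disjunct)
        ]
        conj = set.intersection(*clause_sets) if clause_sets else set()
        result |= conj
    if not result:
        warnings.warn(f"selection {spec!r} matched no atoms", stacklevel=2)
    return sorted(result)


# ---------------------------------------------------------------------------
# Amide hydrogen reconstruction
# ---------------------------------------------------------------------------


def reconstruct_amide_hydrogens(
    coords: np.ndarray,
    structure: Structure,
    bond_length: float = 1.01,
) -> dict[int, np.ndarray]:
    """Place backbone amide H atoms geometrically for one frame.

    The N–H vector is taken opposed to the bisector of C(i−1)–N and CA–N,
    with a 1.01 Å bond.  Returns residue_number -> H position for every
    residue with N, CA and a preceding C; prolines and chain-leading
    residues are omitted.
    """
    by_res: dict[int, dict[str, int]] = {}
    for i, a in enumerate(structure.atoms):
        by_res.setdefault(a.residue_number, {})[a.name] = i
    resname = {a.residue_number: a.residue_name for a in structure.atoms}
    out: dict[int, np.ndarray] = {}
    for res in sorted(by_res):
        if resname.get(res) == "PRO":
            continue
        names = by_res[res]
        prev = by_res.get(res - 1, {})
        if "N" not in names or "CA" not in names or "C" not in prev:
            continue
        n = coords[names["N"]]
        ca = coords[names["CA"]]
        c_prev = coords[prev["C"]]
        u1 = c_prev - n
        u2 = ca - n
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        bis = u1 + u2
        nrm = np.linalg.norm(bis)
        if nrm < 1e-8:
            continue
        out[res] = n - bond_length * bis / nrm
    return out
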