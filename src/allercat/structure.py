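"""Reference structures: PDB parsing, surface residues, 3D epitope patches.

Surface detection is a Shrake-Rupley-style construction: points are
sampled on every atom's probe-expanded sphere (deterministic Fibonacci
spiral, no RNG), points falling inside any other expanded sphere are
discarded, and a residue's "distance to the solvent-accessible surface"
is the minimum over its atoms of (distance from the atom center to the
nearest retained surface point, minus the atom's van der Waals radius).
A fully exposed atom therefore sits at distance ~= the probe radius
(1.4 A), comfortably below the 2.55 A surface cutoff; buried atoms see
only far-away surface points.

Epitope patches: every surface residue is a hypothetical epitope center;
its members are the surface residues whose minimum heavy-atom distance
to the center residue is <= the patch radius (12 A); patches with fewer
than 13 members are dropped.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SurfaceModel",
    "EpitopeTable",
    "read_structure",
    "write_pdb",
    "surface_residues",
    "build_epitope_table",
    "VDW_RADII",
]

logger = logging.getLogger(__name__)

#: Element-keyed van der Waals radii (A); unknown elements fall back to carbon.
VDW_RADII: Mapping[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70

DEFAULT_PROBE = 1.4
DEFAULT_SURFACE_CUTOFF = 2.55
DEFAULT_EPITOPE_RADIUS = 12.0
DEFAULT_EPITOPE_MIN_SIZE = 13

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class Residue:
    index: int          # 0-based position along the chain
    name: str           # three-letter residue name
    one_letter: str
    atoms: tuple[Atom, ...]


class Structure:
    """An ordered single-chain protein structure (heavy atoms only)."""

    def __init__(self, id: str, residues: Sequence[Residue]) -> None:
        if not residues:
            raise ValueError(f"structure {id!r} has no protein residues")
        self.id = id
        self.residues: tuple[Residue, ...] = tuple(residues)
        for res in self.residues:
            for atom in res.atoms:
                if not all(np.isfinite(atom.coord)):
                    raise ValueError(
                        f"structure {id!r}: non-finite coordinates in residue {res.index}"
                    )

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def atom_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(coords (A,3), vdW radii (A,), residue index per atom (A,))."""
        coords, radii, ridx = [], [], []
        for i, res in enumerate(self.residues):
            for atom in res.atoms:
                coords.append(atom.coord)
                radii.append(atom.radius)
                ridx.append(i)
        return (
            np.asarray(coords, dtype=float),
            np.asarray(radii, dtype=float),
            np.asarray(ridx, dtype=int),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body copy: ``x -> R x + t`` applied to every atom."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        residues = []
        for res in self.residues:
            atoms = tuple(
                Atom(a.name, a.element, tuple(rotation @ np.asarray(a.coord) + translation), a.radius)
                for a in res.atoms
            )
            residues.append(Residue(res.index, res.name, res.one_letter, atoms))
        return Structure(self.id, residues)


def read_structure(path: str | Path, chain: str | None = None) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    First model only; ``chain`` selects a chain id (default: the first
    chain containing protein residues).  Heteroatoms, waters and
    hydrogens are excluded.  Residues with no heavy-atom coordinates are
    skipped with a warning.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PDBParser(QUIET=True).get_structure(path.stem, str(path))[0]

    target = None
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        if any(res.id[0] == " " for res in ch):
            target = ch
            break
    if target is None:
        raise ValueError(f"{path}: no protein residues" + (f" in chain {chain!r}" if chain else ""))

    residues: list[Residue] = []
    for res in target:
        if res.id[0] != " ":
            continue  # waters and other heteroatoms
        atoms = []
        for atom in res:
            element = (atom.element or atom.get_name()[:1]).upper()
            if element in ("H", "D"):
                continue
            atoms.append(
                Atom(
                    name=atom.get_name(),
                    element=element,
                    coord=tuple(float(x) for x in atom.coord),
                    radius=VDW_RADII.get(element, DEFAULT_RADIUS),
                )
            )
        if not atoms:
            logger.warning("%s: residue %s has no heavy-atom coordinates; skipped", path, res.id)
            continue
        residues.append(
            Residue(
                index=len(residues),
                name=res.get_resname(),
                one_letter=_THREE_TO_ONE.get(res.get_resname(), "X"),
                atoms=tuple(atoms),
            )
        )
    return Structure(id=path.stem, residues=residues)


def write_pdb(structure: Structure, path: str | Path, chain: str = "A") -> None:
    """Write a minimal single-chain PDB file (ATOM records + END)."""
    with Path(path).open("w") as fh:
        serial = 1
        for res in structure.residues:
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s}{res.name:>4s} {chain}{res.index + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {atom.element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (spiral lattice)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + 5.0 ** 0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


@dataclass(frozen=True)
class SurfaceModel:
    """Per-residue distance to the solvent-accessible surface plus flags."""

    structure_id: str
    distances: np.ndarray      # (n_residues,) A
    flags: np.ndarray          # (n_residues,) bool; True iff distance < cutoff
    probe: float
    surface_cutoff: float
    n_points: int

    @property
    def surface_indices(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.flags))

    @property
    def n_surface(self) -> int:
        return int(self.flags.sum())


def surface_residues(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    cutoff: float = DEFAULT_SURFACE_CUTOFF,
    n_points: int = 256,
) -> SurfaceModel:
    """Flag residues closer than ``cutoff`` to the solvent-accessible surface.

    See the module docstring for the construction.  ``n_points`` controls
    the sphere sampling density (>= 92).
    """
    if n_points < 92:
        raise ValueError(f"n_points must be >= 92, got {n_points}")
    coords, radii, ridx = structure.atom_arrays()
    expanded = radii + probe
    unit = _fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_exp = float(expanded.max())
    retained: list[np.ndarray] = []
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        neighbors = tree.query_ball_point(coords[i], expanded[i] + max_exp)
        keep = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d = np.linalg.norm(pts - coords[j], axis=1)
            keep &= d >= expanded[j] - 1e-9
            if not keep.any():
                break
        if keep.any():
            retained.append(pts[keep])

    n_res = len(structure)
    distances = np.full(n_res, np.inf)
    if retained:
        surface_pts = np.vstack(retained)
        ptree = cKDTree(surface_pts)
        atom_d, _ = ptree.query(coords)
        atom_d = atom_d - radii
        np.minimum.at(distances, ridx, atom_d)
    flags = distances < cutoff
    return SurfaceModel(
        structure_id=structure.id,
        distances=distances,
        flags=flags,
        probe=probe,
        surface_cutoff=cutoff,
        n_points=n_points,
    )


@dataclass(frozen=True)
class EpitopeTable:
    """Per-structure map: surface center residue -> its surface patch.

    Residue indices are 0-based chain positions (aligned with
    ``Structure.sequence``); member tuples are sorted and always contain
    the center.
    """

    structure_id: str
    epitopes: Mapping[int, tuple[int, ...]]
    radius: float
    min_size: int

    def __len__(self) -> int:
        return len(self.epitopes)

    def __bool__(self) -> bool:
        return bool(self.epitopes)

    def to_json_dict(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "radius": self.radius,
            "min_size": self.min_size,
            "epitopes": {str(c): list(m) for c, m in sorted(self.epitopes.items())},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "EpitopeTable":
        return cls(
            structure_id=d["structure_id"],
            epitopes={int(c): tuple(m) for c, m in d["epitopes"].items()},
            radius=float(d["radius"]),
            min_size=int(d["min_size"]),
        )


def save_epitope_tables(tables: Iterable[EpitopeTable], path: str | Path) -> None:
    payload = [t.to_json_dict() for t in tables]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_epitope_tables(path: str | Path) -> dict[str, EpitopeTable]:
    payload = json.loads(Path(path).read_text())
    tables = [EpitopeTable.from_json_dict(d) for d in payload]
    return {t.structure_id: t for t in tables}


def build_epitope_table(
    structure: Structure,
    surface: SurfaceModel,
    radius: float = DEFAULT_EPITOPE_RADIUS,
    min_size: int = DEFAULT_EPITOPE_MIN_SIZE,
) -> EpitopeTable:
    """Enumerate epitope-sized surface patches around every surface residue.

    Two residues belong together when their minimum heavy-atom pair
    distance is <= ``radius``; patches smaller than ``min_size`` are
    dropped.  Deterministic for fixed input.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")

    surf = set(surface.surface_indices)
    epitopes: dict[int, tuple[int, ...]] = {}
    if not surf:
        return EpitopeTable(structure.id, epitopes, radius, min_size)

    coords, _, ridx = structure.atom_arrays()
    keep = np.isin(ridx, sorted(surf))
    coords, ridx = coords[keep], ridx[keep]

    # any atom pair within `radius` links its two residues (min-distance <= radius)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    adjacency: dict[int, set[int]] = {int(r): {int(r)} for r in surf}
    if len(pairs):
        ri = ridx[pairs[:, 0]]
        rj = ridx[pairs[:, 1]]
        for a, b in zip(ri.tolist(), rj.tolist()):
            if a != b:
                adjacency[a].add(b)
                adjacency[b].add(a)

    for center in sorted(surf):
        members = tuple(sorted(adjacency[center]))
        if len(members) >= min_size:
            epitopes[center] = members
    return EpitopeTable(structure.id, epitopes, radius, min_size)


def structure_from_coords(
    id: str,
    sequence: str,
    atoms_per_residue: Sequence[Sequence[tuple[str, str, tuple[float, float, float]]]],
) -> Structure:
    """Build a structure from explicit per-residue (name, element, xyz) atoms."""
    if len(sequence) != len(atoms_per_residue):
        raise ValueError("sequence length must equal number of residue atom groups")
    residues = []
    for i, (aa, atom_spec) in enumerate(zip(sequence, atoms_per_residue)):
        atoms = tuple(
            Atom(name=n, element=e, coord=xyz, radius=VDW_RADII.get(e, DEFAULT_RADIUS))
            for n, e, xyz in atom_spec
        )
        residues.append(
            Residue(index=i, name=_ONE_TO_THREE.get(aa, "UNK"), one_letter=aa, atoms=atoms)
        )
    return Structure(id=id, residues=residues)
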