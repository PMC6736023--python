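"""Deterministic synthetic-data generation for tests, demos and benchmarks.

Everything here is seed-deterministic and emits the same standard
formats the rest of the package consumes (FASTA, PDB, plain peptide
lists, epitope JSON), so every stage can be exercised without any
download.  The reversed-sequence control (:func:`reverse_db`) is the
packaged negative set for hexamer benchmarking: reversal preserves
sequence count, lengths and residue composition while destroying
biological meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from allercat.qrepeat import STANDARD_20, train_fingerprint
from allercat.seqdb import ProteinRecord, SequenceDatabase, write_fasta
from allercat.structure import (
    EpitopeTable,
    Structure,
    build_epitope_table,
    save_epitope_tables,
    structure_from_coords,
    surface_residues,
    write_pdb,
)

__all__ = [
    "FixtureSpec",
    "make_synthetic_db",
    "mutate_homolog",
    "reverse_db",
    "make_helix_structure",
    "make_buried_cluster",
    "make_qrich_peptides",
    "make_demo_bundle",
    "build_synthetic_bundle",
]

_RESIDUES = np.array(list(STANDARD_20))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic sequence set; same spec => same bytes."""

    seed: int
    n_sequences: int
    length_range: tuple[int, int] = (50, 200)
    mutation_rate: float = 0.1
    composition: Mapping[str, float] | None = None  # None => uniform over 20
    id_prefix: str = "syn"

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError(f"n_sequences must be >= 1, got {self.n_sequences}")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")


def _weights(composition: Mapping[str, float] | None) -> np.ndarray:
    if composition is None:
        return np.full(20, 1.0 / 20.0)
    w = np.array([composition.get(a, 0.0) for a in STANDARD_20], dtype=float)
    if w.sum() <= 0:
        raise ValueError("composition has no mass on the 20 standard residues")
    return w / w.sum()


def make_synthetic_db(spec: FixtureSpec, name: str = "synthetic") -> SequenceDatabase:
    """Seeded i.i.d. sequences from the spec's composition table."""
    rng = np.random.default_rng(spec.seed)
    weights = _weights(spec.composition)
    lo, hi = spec.length_range
    db = SequenceDatabase(name=name)
    width = max(4, len(str(spec.n_sequences)))
    for i in range(spec.n_sequences):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_RESIDUES, size=length, p=weights))
        db.add(
            ProteinRecord(
                id=f"{spec.id_prefix}{i + 1:0{width}d}",
                sequence=seq,
                sources=frozenset(["synthetic"]),
            )
        )
    return db


def mutate_homolog(seq: str, target_identity: float, seed: int) -> str:
    """Substitute random positions to hit a target ungapped identity.

    Exactly ``len(seq) - round(target * len(seq))`` positions are
    substituted, each with a residue different from the original, so the
    realized same-length identity matches the target to within one
    position.  ``target_identity`` 1.0 returns the sequence unchanged.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError(f"target_identity must be in (0, 1], got {target_identity}")
    n = len(seq)
    n_sub = n - round(target_identity * n)
    if n_sub == 0:
        return seq
    rng = np.random.default_rng(seed)
    positions = rng.choice(n, size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [a for a in STANDARD_20 if a != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def reverse_db(db: SequenceDatabase, id_prefix: str = "rev_") -> SequenceDatabase:
    """Reverse every sequence; counts, lengths and compositions preserved."""
    out = SequenceDatabase(name=f"{db.name}_reversed")
    for rec in db:
        out.add(
            ProteinRecord(
                id=f"{id_prefix}{rec.id}",
                sequence=rec.sequence[::-1],
                description=rec.description,
                sources=rec.sources,
            )
        )
    return out


# Idealized alpha-helix parameters: 1.5 A rise and 100 degree twist per
# residue, CA at 2.3 A from the axis; backbone atoms are placed at
# approximate ideal offsets and one pseudo-side-chain CB points outward.
_HELIX_RISE = 1.5
_HELIX_TWIST = math.radians(100.0)
_CA_RADIUS = 2.3


def make_helix_structure(sequence: str, id: str = "helix") -> Structure:
    """Idealized alpha-helix with backbone N/CA/C/O plus a CB per residue.

    Coordinates are a deterministic function of the sequence length;
    the thin helix has no buried core, so every residue is a surface
    residue at the default cutoff.
    """
    if not sequence:
        raise ValueError("empty sequence")
    atoms_per_residue = []
    for i in range(len(sequence)):
        theta = i * _HELIX_TWIST
        z = i * _HELIX_RISE

        def cyl(r: float, ang: float, zz: float) -> tuple[float, float, float]:
            return (r * math.cos(ang), r * math.sin(ang), zz)

        ca = cyl(_CA_RADIUS, theta, z)
        n = cyl(1.6, theta - math.radians(28.0), z - 0.9)
        c = cyl(1.7, theta + math.radians(26.0), z + 1.0)
        o = (c[0] * (1.0 + 1.23 / 1.7), c[1] * (1.0 + 1.23 / 1.7), c[2] + 0.2)
        cb = cyl(3.6, theta, z + 0.4)
        atoms_per_residue.append(
            [
                ("N", "N", n),
                ("CA", "C", ca),
                ("C", "C", c),
                ("O", "O", o),
                ("CB", "C", cb),
            ]
        )
    return structure_from_coords(id, sequence.upper(), atoms_per_residue)


def make_buried_cluster(id: str = "buried") -> Structure:
    """A single central atom wrapped in three dense occluding shells.

    Residue 0 is the lone central atom; its distance to the accessible
    surface is far above the 2.55 A cutoff, making it the canonical
    "buried core" fixture.  Shell atoms form one residue per shell.
    """
    shells = []
    for radius in (3.0, 5.5, 8.0):
        n = int(math.ceil(4.0 * math.pi * radius**2 / 3.0))
        pts = _fibonacci(n) * radius
        shells.append(pts)
    atoms_per_residue = [[("C1", "C", (0.0, 0.0, 0.0))]]
    sequence = "G"
    for k, pts in enumerate(shells):
        atoms = [
            (f"C{j + 1}", "C", (float(p[0]), float(p[1]), float(p[2])))
            for j, p in enumerate(pts)
        ]
        atoms_per_residue.append(atoms)
        sequence += "G"
    return structure_from_coords(id, sequence, atoms_per_residue)


def _fibonacci(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    golden = (1.0 + 5.0 ** 0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def make_qrich_peptides(
    n: int,
    seed: int,
    length_range: tuple[int, int] = (9, 15),
    q_enrichment: float = 0.6,
    p_enrichment: float = 0.2,
) -> list[str]:
    """Seeded Q/P-enriched peptides standing in for a Celiac training set.

    ``q_enrichment`` 1.0 yields all-Q peptides; the remaining probability
    mass is spread uniformly over the other residues.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= q_enrichment <= 1.0 or not 0.0 <= p_enrichment <= 1.0:
        raise ValueError("enrichments must be in [0, 1]")
    if q_enrichment + p_enrichment > 1.0:
        raise ValueError("q_enrichment + p_enrichment must be <= 1")
    rng = np.random.default_rng(seed)
    rest = 1.0 - q_enrichment - p_enrichment
    others = [a for a in STANDARD_20 if a not in "QP"]
    weights = np.array(
        [
            q_enrichment if a == "Q" else p_enrichment if a == "P" else rest / len(others)
            for a in STANDARD_20
        ]
    )
    weights = weights / weights.sum()
    lo, hi = length_range
    if lo < 9:
        raise ValueError("peptides must be at least 9 residues")
    peptides = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        peptides.append("".join(rng.choice(_RESIDUES, size=length, p=weights)))
    return peptides


def build_synthetic_bundle(
    seed: int,
    n_allergens: int = 20,
    n_structures: int = 5,
    length_range: tuple[int, int] = (50, 120),
    n_peptides: int = 50,
    entropy_min: float = 0.34,
    structure_max_len: int = 120,
):
    """In-memory reference bundle built entirely from seeded fixtures.

    The first ``n_structures`` allergens double as structure
    representatives: each gets an idealized helix, a surface model and an
    epitope table (min size scaled down automatically for very short
    chains is NOT done -- chains shorter than the epitope minimum simply
    produce empty tables).
    """
    from allercat.workflow import ReferenceBundle

    spec = FixtureSpec(seed=seed, n_sequences=n_allergens, length_range=length_range,
                       id_prefix="alg")
    allergens = make_synthetic_db(spec, name="allergens")
    rep_sequences: dict[str, str] = {}
    tables: dict[str, EpitopeTable] = {}
    structures: dict[str, Structure] = {}
    for rec in list(allergens)[:n_structures]:
        seq = rec.sequence[:structure_max_len]
        sid = f"str_{rec.id}"
        helix = make_helix_structure(seq, id=sid)
        surf = surface_residues(helix, n_points=92)
        tables[sid] = build_epitope_table(helix, surf)
        rep_sequences[sid] = seq
        structures[sid] = helix
    model = train_fingerprint(make_qrich_peptides(n_peptides, seed=seed + 1))
    bundle = ReferenceBundle(
        allergens=allergens,
        rep_sequences=rep_sequences,
        epitope_tables=tables,
        qrepeat_model=model,
        entropy_min=entropy_min,
    )
    return bundle, structures


def make_demo_bundle(out_dir: str | Path, seed: int = 1, n_allergens: int = 12,
                     n_structures: int = 3, n_queries: int = 4) -> Path:
    """Write a complete on-disk demo bundle (FASTA + PDB + JSON + peptides).

    Layout::

        out_dir/
          allergens.fasta      reference allergen sequences
          queries.fasta        example queries (homolog, Q-repeat, random)
          celiac_peptides.txt  Q-repeat training peptides
          epitopes.json        pre-built epitope tables
          structures/*.pdb     helix structures for the representatives
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "structures").mkdir(exist_ok=True)

    bundle, structures = build_synthetic_bundle(
        seed=seed, n_allergens=n_allergens, n_structures=n_structures
    )
    write_fasta(bundle.allergens, out_dir / "allergens.fasta")
    for sid, structure in structures.items():
        write_pdb(structure, out_dir / "structures" / f"{sid}.pdb")
    save_epitope_tables(bundle.epitope_tables.values(), out_dir / "epitopes.json")

    peptides = make_qrich_peptides(50, seed=seed + 1)
    (out_dir / "celiac_peptides.txt").write_text("\n".join(peptides) + "\n")

    rng = np.random.default_rng(seed + 2)
    queries = SequenceDatabase(name="queries")
    first = bundle.allergens.records[0]
    queries.add(ProteinRecord(id="qry_verbatim", sequence=first.sequence,
                              description="verbatim copy of a reference allergen"))
    queries.add(
        ProteinRecord(
            id="qry_homolog",
            sequence=mutate_homolog(first.sequence, 0.8, seed=seed + 3),
            description="80%-identity homolog of a reference allergen",
        )
    )
    carrier = "".join(rng.choice(_RESIDUES, size=40))
    queries.add(
        ProteinRecord(
            id="qry_qrepeat",
            sequence=carrier[:20] + "QQPQQPQQQPQQ" + carrier[20:],
            description="Q-repeat peptide embedded in a random carrier",
        )
    )
    for i in range(max(0, n_queries - 3)):
        queries.add(
            ProteinRecord(
                id=f"qry_random{i + 1}",
                sequence="".join(rng.choice(_RESIDUES, size=60)),
                description="unrelated random sequence",
            )
        )
    write_fasta(queries, out_dir / "queries.fasta")
    return out_dir
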