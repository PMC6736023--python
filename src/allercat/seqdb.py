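"""Protein sequence collections: FASTA I/O, merging, deduplication, clustering.

A :class:`SequenceDatabase` is an ordered, id-indexed set of
:class:`ProteinRecord` objects.  Merging collapses byte-identical
sequences (100%-identity dedup) while accumulating provenance tags;
:func:`greedy_cluster` groups records at a global-identity threshold in
the style of greedy incremental clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "ProteinRecord",
    "SequenceDatabase",
    "ClusterSet",
    "read_fasta",
    "write_fasta",
    "merge_databases",
    "greedy_cluster",
    "FastaParseError",
]

#: The 20 standard amino acids.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes accepted on input (filtered downstream,
#: at the hexamer stage -- records themselves are never rejected for them).
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")

_ALLOWED = STANDARD_RESIDUES | AMBIGUOUS_RESIDUES


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input (with the offending line)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One named amino-acid sequence with source provenance.

    The sequence is normalized to uppercase at construction; the 20
    standard residues plus the ambiguity codes B, J, O, U, X, Z are
    accepted.
    """

    id: str
    sequence: str
    description: str = ""
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "sources", frozenset(self.sources))
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class SequenceDatabase:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    def __init__(self, records: Iterable[ProteinRecord] = (), name: str = "") -> None:
        self.name = name
        self._records: list[ProteinRecord] = []
        self._by_id: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.id in self._by_id:
            raise ValueError(f"duplicate record id {record.id!r}")
        self._records.append(record)
        self._by_id[record.id] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def __getitem__(self, record_id: str) -> ProteinRecord:
        return self._by_id[record_id]

    @property
    def records(self) -> tuple[ProteinRecord, ...]:
        return tuple(self._records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self._records)

    def sequences(self) -> set[str]:
        """Distinct sequence strings in the database."""
        return {r.sequence for r in self._records}

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"SequenceDatabase(name={self.name!r}, n={len(self)})"


def read_fasta(path: str | Path, name: str = "", source: str | None = None) -> SequenceDatabase:
    """Read a (possibly wrapped) FASTA file into a :class:`SequenceDatabase`.

    Sequences are uppercased; entry order is preserved.  Duplicate headers
    are disambiguated deterministically by appending ``.2``, ``.3``, ...
    An empty file yields an empty database.  Sequence data appearing
    before the first header raises :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    db = SequenceDatabase(name=name or path.stem)
    tag = frozenset([source]) if source else frozenset()
    seen_ids: dict[str, int] = {}

    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        rid, _, desc = header.partition(" ")
        n = seen_ids.get(rid, 0) + 1
        seen_ids[rid] = n
        if n > 1:
            rid = f"{rid}.{n}"
        db.add(ProteinRecord(id=rid, sequence=seq, description=desc.strip(), sources=tag))

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first '>' header at line {lineno}"
                    )
                chunks.append(line)
    flush()
    return db


def write_fasta(db: SequenceDatabase, path: str | Path, width: int = 60) -> None:
    """Write a database as wrapped FASTA (stable, round-trippable)."""
    with Path(path).open("w") as fh:
        for rec in db:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def merge_databases(dbs: Iterable[SequenceDatabase], name: str = "merged") -> SequenceDatabase:
    """Union of databases with 100%-identity dedup on the sequence string.

    Records with byte-identical sequences collapse into one record that
    keeps the first-seen id and description and unions all source tags.
    Ids never participate in dedup.
    """
    dbs = list(dbs)
    if not dbs:
        raise ValueError("merge_databases requires at least one input database")
    by_seq: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for db in dbs:
        for rec in db:
            prev = by_seq.get(rec.sequence)
            if prev is None:
                by_seq[rec.sequence] = rec
                order.append(rec.sequence)
            else:
                by_seq[rec.sequence] = ProteinRecord(
                    id=prev.id,
                    sequence=prev.sequence,
                    description=prev.description,
                    sources=prev.sources | rec.sources,
                )
    out = SequenceDatabase(name=name)
    used_ids: set[str] = set()
    for seq in order:
        rec = by_seq[seq]
        rid, n = rec.id, 1
        while rid in used_ids:
            n += 1
            rid = f"{rec.id}.{n}"
        used_ids.add(rid)
        if rid != rec.id:
            rec = ProteinRecord(rid, rec.sequence, rec.description, rec.sources)
        out.add(rec)
    return out


@dataclass
class ClusterSet:
    """Greedy identity clusters: representative record id -> member ids.

    Every database record belongs to exactly one cluster; each member has
    global identity >= ``identity_threshold`` to its representative.
    """

    clusters: dict[str, list[str]]
    identity_threshold: float

    @property
    def representative_ids(self) -> tuple[str, ...]:
        return tuple(self.clusters)

    def cluster_of(self, record_id: str) -> str:
        for rep, members in self.clusters.items():
            if record_id in members:
                return rep
        raise KeyError(record_id)

    def to_tsv(self, path: str | Path, db: SequenceDatabase) -> None:
        """Write ``representative_id<TAB>member_id<TAB>identity`` rows."""
        from allercat.align import global_align

        with Path(path).open("w") as fh:
            fh.write("representative_id\tmember_id\tidentity\n")
            for rep, members in self.clusters.items():
                for mid in members:
                    if mid == rep:
                        ident = 1.0
                    else:
                        ident = global_align(db[rep].sequence, db[mid].sequence).identity
                    fh.write(f"{rep}\t{mid}\t{ident:.4f}\n")


def greedy_cluster(db: SequenceDatabase, threshold: float = 0.70) -> ClusterSet:
    """cd-hit-style greedy incremental clustering by global identity.

    Records are visited in order of decreasing length (stable for ties);
    each record joins the first-founded cluster whose representative it
    matches at >= ``threshold`` global identity (identical columns over
    total alignment columns, gap columns included), else founds a new
    cluster.  Exact alignment replaces word heuristics: databases at this
    scale are small.
    """
    from allercat.align import global_align

    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(db, key=lambda r: -len(r.sequence))
    clusters: dict[str, list[str]] = {}
    for rec in order:
        placed = False
        for rep_id, members in clusters.items():
            rep_seq = db[rep_id].sequence
            if rec.sequence == rep_seq:
                members.append(rec.id)
                placed = True
                break
            if global_align(rec.sequence, rep_seq).identity >= threshold:
                members.append(rec.id)
                placed = True
                break
        if not placed:
            clusters[rec.id] = [rec.id]
    return ClusterSet(clusters=clusters, identity_threshold=threshold)
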