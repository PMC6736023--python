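"""The tiered decision cascade from query sequence to evidence call.

Stage order (first trigger wins):

1. Gluten-like Q-repeat fingerprint -> strong evidence, independent of
   every other feature.
2. Significant similarity to a 3D structure representative: the query is
   searched against the representative sequences and against the
   allergen database; the best epitope identity between query and best
   allergen (anchored on the representative) gives strong evidence at or
   above the 93% threshold, weak evidence below.  If the structure hit
   cannot be supported (no allergen hit, or an empty epitope table) the
   cascade falls through rather than emitting an unsupported call.
3. Linear-window rule (35% identity over 80 alignment columns) against
   the full allergen database -> strong evidence.
4. Entropy-filtered triple-hexamer sharing -> weak evidence.
5. Otherwise: no evidence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

from allercat import align as _align
from allercat import kmer as _kmer
from allercat import qrepeat as _qrepeat
from allercat.seqdb import ProteinRecord, SequenceDatabase
from allercat.structure import EpitopeTable

__all__ = [
    "WorkflowConfig",
    "EvidenceCall",
    "ReferenceBundle",
    "SelfScreenSummary",
    "assess",
    "run_batch",
    "self_screen",
    "CSV_HEADER",
]

CSV_HEADER = (
    "query_id,evidence,basis,best_allergen,best_structure,"
    "epitope_identity,window_identity,hexamer_hits,notes"
)

#: Queries shorter than this cannot trigger any stage reliably and are
#: reported as "too short" (a hexamer needs 6 residues).
MIN_QUERY_LENGTH = 6


@dataclass(frozen=True)
class WorkflowConfig:
    """Every numeric knob of the cascade, with production defaults."""

    entropy_min: float = 0.34
    kmer_k: int = 6
    kmer_min_hits: int = 3
    qrepeat_window: int = 9
    qrepeat_sd_multiplier: float = 1.0
    surface_cutoff: float = 2.55
    probe: float = 1.4
    epitope_radius: float = 12.0
    epitope_min_size: int = 13
    e_max: float = 0.001
    epitope_strong_identity: float = 0.93
    window_len: int = 80
    window_min_identity: float = 0.35
    cluster_identity: float = 0.70
    max_batch: int = 50

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        for name in ("epitope_strong_identity", "window_min_identity", "cluster_identity"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class EvidenceCall:
    """Final tiered verdict for one query."""

    query_id: str
    level: str                      # strong | weak | none
    basis: str                      # qrepeat | epitope3d | linear_window | kmer | none
    best_allergen: str = ""
    best_structure: str = ""
    epitope_identity: float | None = None
    window_identity: float | None = None
    hexamer_hits: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.level not in ("strong", "weak", "none"):
            raise ValueError(f"invalid level {self.level!r}")
        if self.basis not in ("qrepeat", "epitope3d", "linear_window", "kmer", "none"):
            raise ValueError(f"invalid basis {self.basis!r}")
        if (self.level == "none") != (self.basis == "none"):
            raise ValueError("level 'none' iff basis 'none'")
        if self.basis == "epitope3d" and self.epitope_identity is None:
            raise ValueError("epitope3d calls must carry an epitope identity")

    def to_csv_row(self) -> str:
        def fmt(x: float | None) -> str:
            return "" if x is None else f"{x:.4f}"

        notes = self.notes.replace(",", ";")
        return (
            f"{self.query_id},{self.level},{self.basis},{self.best_allergen},"
            f"{self.best_structure},{fmt(self.epitope_identity)},"
            f"{fmt(self.window_identity)},"
            f"{'' if self.hexamer_hits is None else self.hexamer_hits},{notes}"
        )


class ReferenceBundle:
    """Everything a query is assessed against.

    ``rep_sequences`` maps each structure id to the sequence of its
    representative; ``epitope_tables`` maps the same ids to pre-built
    :class:`EpitopeTable` objects.  The hexamer index is built from the
    allergen database on construction unless supplied.
    """

    def __init__(
        self,
        allergens: SequenceDatabase,
        rep_sequences: Mapping[str, str] | None = None,
        epitope_tables: Mapping[str, EpitopeTable] | None = None,
        qrepeat_model: _qrepeat.QRepeatModel | None = None,
        kmer_index: _kmer.KmerIndex | None = None,
        entropy_min: float = 0.34,
        kmer_k: int = 6,
    ) -> None:
        self.allergens = allergens
        self.rep_sequences = dict(rep_sequences or {})
        self.epitope_tables = dict(epitope_tables or {})
        self.qrepeat_model = qrepeat_model
        for sid, table in self.epitope_tables.items():
            if sid not in self.rep_sequences:
                raise ValueError(f"epitope table {sid!r} has no representative sequence")
        for sid, seq in self.rep_sequences.items():
            if not seq:
                raise ValueError(f"empty representative sequence for structure {sid!r}")
        self.kmer_index = kmer_index or _kmer.KmerIndex.from_database(
            allergens, k=kmer_k, entropy_min=entropy_min
        )
        self._rep_db = SequenceDatabase(
            (
                ProteinRecord(id=sid, sequence=seq)
                for sid, seq in sorted(self.rep_sequences.items())
            ),
            name="structure_representatives",
        )

    @property
    def structure_db(self) -> SequenceDatabase:
        return self._rep_db

    def without_record(self, record_id: str) -> "ReferenceBundle":
        """Jack-knife copy: the record (and structures sharing its exact
        sequence) removed from the reference side."""
        seq = self.allergens[record_id].sequence
        pruned = SequenceDatabase(
            (r for r in self.allergens if r.id != record_id),
            name=self.allergens.name,
        )
        reps = {sid: s for sid, s in self.rep_sequences.items() if s != seq}
        tables = {sid: t for sid, t in self.epitope_tables.items() if sid in reps}
        return ReferenceBundle(
            allergens=pruned,
            rep_sequences=reps,
            epitope_tables=tables,
            qrepeat_model=self.qrepeat_model,
            entropy_min=self.kmer_index.entropy_min,
            kmer_k=self.kmer_index.k,
        )


def assess(
    query: ProteinRecord,
    refs: ReferenceBundle,
    cfg: WorkflowConfig | None = None,
) -> EvidenceCall:
    """Run the full cascade for one query (see module docstring)."""
    cfg = cfg or WorkflowConfig()
    seq = query.sequence
    notes: list[str] = []

    if len(seq) < MIN_QUERY_LENGTH:
        return EvidenceCall(
            query_id=query.id,
            level="none",
            basis="none",
            notes=f"too short to be evaluated (length {len(seq)})",
        )

    # Stage 1: Q-repeat fingerprint shadows everything else.
    if refs.qrepeat_model is not None and len(seq) >= refs.qrepeat_model.window:
        qr = _qrepeat.qrepeat_hit(refs.qrepeat_model, seq, cfg.qrepeat_sd_multiplier)
        if qr.hit:
            return EvidenceCall(
                query_id=query.id,
                level="strong",
                basis="qrepeat",
                notes=(
                    f"Q-repeat window {qr.best_window!r} at {qr.best_position + 1} "
                    f"scores {qr.best_score:.2f} >= {qr.threshold:.2f}"
                ),
            )

    # Stage 2: structure representatives -> 3D epitope identity.
    struct_hits = _align.search_db(seq, refs.structure_db, cfg.e_max, query_id=query.id)
    if struct_hits:
        best_struct = struct_hits[0]
        allergen_hits = _align.search_db(seq, refs.allergens, cfg.e_max, query_id=query.id)
        table = refs.epitope_tables.get(best_struct.target_id)
        if allergen_hits and table:
            best_allergen = allergen_hits[0]
            mapping = _align.anchored_triple_map(
                seq,
                refs.rep_sequences[best_struct.target_id],
                refs.allergens[best_allergen.target_id].sequence,
            )
            result = _align.best_epitope_identity(mapping, table)
            if result is not None:
                strong = result.identity >= cfg.epitope_strong_identity
                return EvidenceCall(
                    query_id=query.id,
                    level="strong" if strong else "weak",
                    basis="epitope3d",
                    best_allergen=best_allergen.target_id,
                    best_structure=best_struct.target_id,
                    epitope_identity=result.identity,
                    notes=(
                        f"epitope center {result.center} size {result.size}: "
                        f"{result.n_identical}/{result.size} identical"
                    ),
                )
        if not allergen_hits:
            notes.append("structure hit without allergen hit; fell back")
        elif not table:
            notes.append("structure hit without epitope table; fell back")

    # Stage 3: classical linear-window rule over the full allergen DB.
    best_scan: _align.WindowScan | None = None
    best_scan_id = ""
    for rec in refs.allergens:
        scan = _align.linear_window_hit(
            seq, rec.sequence, cfg.window_len, cfg.window_min_identity
        )
        if (
            best_scan is None
            or scan.identity > best_scan.identity
            or (scan.identity == best_scan.identity and rec.id < best_scan_id)
        ):
            best_scan, best_scan_id = scan, rec.id
    if best_scan is not None and best_scan.hit:
        return EvidenceCall(
            query_id=query.id,
            level="strong",
            basis="linear_window",
            best_allergen=best_scan_id,
            window_identity=best_scan.identity,
            notes=(
                f"{best_scan.n_identical}/{best_scan.window} identical columns"
            ),
        )

    # Stage 4: triple-hexamer rule.
    hexamers = _kmer.valid_hexamers(seq, cfg.entropy_min, cfg.kmer_k)
    hit = _kmer.triple_hit(hexamers, refs.kmer_index, cfg.kmer_min_hits)
    if hit:
        return EvidenceCall(
            query_id=query.id,
            level="weak",
            basis="kmer",
            best_allergen=hit.best_id or "",
            hexamer_hits=hit.best_count,
            notes=f"{hit.best_count} shared hexamers",
        )

    return EvidenceCall(
        query_id=query.id,
        level="none",
        basis="none",
        notes="; ".join(notes),
    )


def run_batch(
    queries: SequenceDatabase,
    refs: ReferenceBundle,
    cfg: WorkflowConfig | None = None,
    out: str | Path | None = None,
) -> list[EvidenceCall]:
    """Assess every query in input order and (optionally) write the CSV.

    Rejects batches larger than ``cfg.max_batch`` before any output is
    written; identical inputs produce byte-identical CSV.
    """
    cfg = cfg or WorkflowConfig()
    if len(queries) == 0:
        raise ValueError("empty query set")
    if len(queries) > cfg.max_batch:
        raise ValueError(
            f"batch of {len(queries)} queries exceeds the limit of {cfg.max_batch}"
        )
    calls = [assess(q, refs, cfg) for q in queries]
    if out is not None:
        buf = io.StringIO()
        buf.write(CSV_HEADER + "\n")
        for call in calls:
            buf.write(call.to_csv_row() + "\n")
        Path(out).write_text(buf.getvalue())
    return calls


@dataclass(frozen=True)
class SelfScreenSummary:
    """Sensitivity summary of screening a bundle's own allergens."""

    counts: Mapping[str, int]           # level -> count
    missed: tuple[tuple[str, str], ...]  # (record id, reason)
    jackknife: bool

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def sensitivity(self) -> float:
        """Fraction of records called at level strong or weak."""
        hit = self.counts.get("strong", 0) + self.counts.get("weak", 0)
        return hit / self.n_total if self.n_total else 0.0


def self_screen(
    refs: ReferenceBundle,
    cfg: WorkflowConfig | None = None,
    jackknife: bool = False,
) -> SelfScreenSummary:
    """Assess every allergen in the bundle as a query against the bundle.

    In jack-knife mode the record under assessment (and structures whose
    representative shares its exact sequence) is removed from the
    reference side first, so self-matching cannot inflate sensitivity.
    """
    cfg = cfg or WorkflowConfig()
    counts: dict[str, int] = {"strong": 0, "weak": 0, "none": 0}
    missed: list[tuple[str, str]] = []
    for rec in refs.allergens:
        target = refs.without_record(rec.id) if jackknife else refs
        call = assess(rec, target, cfg)
        counts[call.level] += 1
        if call.level == "none":
            reason = call.notes or "no stage triggered"
            missed.append((rec.id, reason))
    return SelfScreenSummary(
        counts=counts, missed=tuple(missed), jackknife=jackknife
    )
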