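"""Pairwise alignment, significance-filtered search, window and epitope identity.

All alignment is done internally (no external BLASTP/MAFFT): global
Needleman-Wunsch and local Smith-Waterman with BLOSUM62 and affine gaps
(open 11, extend 1), with deterministic alignment selection.  Local-hit
significance uses Karlin-Altschul statistics, ``E = K*m*n*exp(-lambda*S)``
with the published gapped BLOSUM62 constants (lambda = 0.267, K = 0.041).
E-values therefore differ numerically from BLASTP's database-size-corrected
ones; the 0.001 cutoff is kept, so the hit set near the boundary may differ
from an external BLASTP run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

if TYPE_CHECKING:  # pragma: no cover
    from allercat.seqdb import SequenceDatabase
    from allercat.structure import EpitopeTable

__all__ = [
    "PairwiseAlignment",
    "AlignmentHit",
    "WindowScan",
    "EpitopeIdentityResult",
    "global_align",
    "local_align",
    "search_db",
    "linear_window_hit",
    "anchored_triple_map",
    "best_epitope_identity",
    "hits_to_tsv",
]

GAP_OPEN = 11
GAP_EXTEND = 1

#: Gapped BLOSUM62 Karlin-Altschul parameters (open 11 / extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

# BLOSUM62 covers B, Z, X but not J, O, U; fold those onto X for scoring
# (identity is still computed on the original residues).
_SANITIZE = str.maketrans({"J": "X", "O": "X", "U": "X"})


@lru_cache(maxsize=2)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    aligner.mode = mode
    return aligner


def _regap(gapped_sanitized: str, original: str) -> str:
    """Re-insert original residues into a gapped (sanitized) alignment row."""
    out = []
    it = iter(original)
    for c in gapped_sanitized:
        out.append("-" if c == "-" else next(it))
    return "".join(out)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment as two equal-length gapped strings plus score."""

    a_gapped: str
    b_gapped: str
    score: float

    @property
    def n_columns(self) -> int:
        return len(self.a_gapped)

    def identical_columns(self) -> list[bool]:
        """Per-column flags: both residues present and equal (gaps mismatch)."""
        return [
            x != "-" and y != "-" and x == y
            for x, y in zip(self.a_gapped, self.b_gapped)
        ]

    @property
    def n_identical(self) -> int:
        return sum(self.identical_columns())

    @property
    def identity(self) -> float:
        """Identical columns over total alignment columns (gaps included)."""
        return self.n_identical / self.n_columns if self.n_columns else 0.0


def global_align(a: str, b: str) -> PairwiseAlignment:
    """Global Needleman-Wunsch alignment (BLOSUM62, affine 11/1)."""
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    aln = _aligner("global").align(a.translate(_SANITIZE), b.translate(_SANITIZE))[0]
    return PairwiseAlignment(
        a_gapped=_regap(str(aln[0]), a),
        b_gapped=_regap(str(aln[1]), b),
        score=float(aln.score),
    )


@dataclass(frozen=True)
class AlignmentHit:
    """A scored local similarity match with significance estimate.

    Intervals are 1-based inclusive on the ungapped sequences.
    """

    query_id: str
    target_id: str
    score: float
    bit_score: float
    evalue: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    query_gapped: str
    target_gapped: str

    @property
    def identity(self) -> float:
        cols = [
            x != "-" and y != "-" and x == y
            for x, y in zip(self.query_gapped, self.target_gapped)
        ]
        return sum(cols) / len(cols) if cols else 0.0


def _karlin_altschul(score: float, m: int, n: int) -> tuple[float, float]:
    bit = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)
    evalue = KA_K * m * n * math.exp(-KA_LAMBDA * score)
    return bit, evalue


def local_align(
    query: str,
    target: str,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentHit | None:
    """Best local Smith-Waterman alignment, or None if nothing scores > 0."""
    if not query or not target:
        return None
    query, target = query.upper(), target.upper()
    aligner = _aligner("local")
    q, t = query.translate(_SANITIZE), target.translate(_SANITIZE)
    score = aligner.score(q, t)
    if score <= 0:
        return None
    aln = aligner.align(q, t)[0]
    qa, ta = aln.aligned
    if len(qa) == 0:
        return None
    bit, evalue = _karlin_altschul(score, len(query), len(target))
    qs, qe = int(qa[0][0]), int(qa[-1][1])
    ts, te = int(ta[0][0]), int(ta[-1][1])
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        score=float(score),
        bit_score=bit,
        evalue=evalue,
        query_start=qs + 1,
        query_end=qe,
        target_start=ts + 1,
        target_end=te,
        query_gapped=_regap(str(aln[0]), query[qs:qe]),
        target_gapped=_regap(str(aln[1]), target[ts:te]),
    )


def search_db(
    query: str,
    db: "SequenceDatabase",
    e_max: float = 0.001,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """Local-alignment search of ``query`` against every database record.

    Hits with ``E < e_max`` are returned ranked by E-value, then raw
    score, then target id; the first element is the best hit.
    """
    if e_max <= 0:
        raise ValueError(f"e_max must be > 0, got {e_max}")
    hits = []
    for rec in db:
        hit = local_align(query, rec.sequence, query_id=query_id, target_id=rec.id)
        if hit is not None and hit.evalue < e_max:
            hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, -h.score, h.target_id))
    return hits


@dataclass(frozen=True)
class WindowScan:
    """Best fixed-width window of a global alignment."""

    hit: bool
    identity: float
    n_identical: int
    window: int          # effective window width in alignment columns
    start_column: int    # 0-based leftmost maximizing window
    alignment: PairwiseAlignment


def linear_window_hit(
    query: str,
    allergen: str,
    window: int = 80,
    min_identity: float = 0.35,
) -> WindowScan:
    """FAO/WHO-style linear-window rule over global-alignment columns.

    A window of ``window`` alignment columns slides over the global
    alignment; per-window identity is identical columns / window width
    (gap columns count as mismatches).  Alignments shorter than
    ``window`` use all columns as a single window.  The hit test is
    inclusive (identity >= ``min_identity``).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if not 0.0 < min_identity <= 1.0:
        raise ValueError(f"min_identity must be in (0, 1], got {min_identity}")
    aln = global_align(query, allergen)
    ident = aln.identical_columns()
    w = min(window, len(ident))
    best_count, best_start = -1, 0
    count = sum(ident[:w])
    best_count, best_start = count, 0
    for start in range(1, len(ident) - w + 1):
        count += ident[start + w - 1] - ident[start - 1]
        if count > best_count:
            best_count, best_start = count, start
    identity = best_count / w
    return WindowScan(
        hit=identity >= min_identity,
        identity=identity,
        n_identical=best_count,
        window=w,
        start_column=best_start,
        alignment=aln,
    )


def anchored_triple_map(
    query: str,
    rep: str,
    allergen: str,
) -> list[tuple[str | None, str | None]]:
    """Map every structure-representative residue to query/allergen residues.

    Two global alignments (query vs rep, allergen vs rep) are merged with
    the representative as the coordinate anchor: element ``i`` of the
    result holds the query residue aligned to rep position ``i`` (or
    None for a gap) and likewise the allergen residue.
    """

    def rep_to_other(other: str) -> list[str | None]:
        aln = global_align(other, rep)
        out: list[str | None] = []
        for oc, rc in zip(aln.a_gapped, aln.b_gapped):
            if rc != "-":
                out.append(oc if oc != "-" else None)
        return out

    qmap = rep_to_other(query)
    amap = rep_to_other(allergen)
    return list(zip(qmap, amap))


@dataclass(frozen=True)
class EpitopeIdentityResult:
    """Identity of the best-matching surface patch between query and allergen."""

    structure_id: str
    center: int
    size: int
    n_identical: int

    @property
    def identity(self) -> float:
        return self.n_identical / self.size


def best_epitope_identity(
    mapping: Sequence[tuple[str | None, str | None]],
    table: "EpitopeTable",
) -> EpitopeIdentityResult | None:
    """Highest query/allergen identity over all epitope patches.

    A member counts as identical when its mapped query residue equals its
    mapped allergen residue (a gap on either side is a mismatch).  The
    denominator is the full epitope size, so unaligned surface dilutes
    identity.  Ties: larger epitope, then smaller center index.  Returns
    None for an empty table (caller falls back).
    """
    if not table:
        return None
    best: EpitopeIdentityResult | None = None
    for center in sorted(table.epitopes):
        members = table.epitopes[center]
        n_ident = 0
        for m in members:
            if m < len(mapping):
                q, a = mapping[m]
                if q is not None and a is not None and q == a:
                    n_ident += 1
        cand = EpitopeIdentityResult(
            structure_id=table.structure_id,
            center=center,
            size=len(members),
            n_identical=n_ident,
        )
        if (
            best is None
            or cand.identity > best.identity
            or (cand.identity == best.identity and cand.size > best.size)
        ):
            best = cand
    return best


def hits_to_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Export hits as TSV: query, target, score, bit score, E-value, identity."""
    with Path(path).open("w") as fh:
        fh.write("query_id\ttarget_id\tscore\tbit_score\tevalue\tidentity\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.score:.1f}\t{h.bit_score:.2f}"
                f"\t{h.evalue:.3g}\t{h.identity:.4f}\n"
            )
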