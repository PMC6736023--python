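"""Hexamer extraction, entropy/ambiguity filtering and the triple-hit rule.

A query shares evidence with a known allergen when at least
``min_hits`` (default 3) distinct valid hexamers occur in both.  A
hexamer is *valid* when it contains none of the ambiguity codes
B, J, O, U, X, Z and its within-k-mer Shannon entropy (base 2, computed
on the residue composition of the k-mer itself) reaches the configured
minimum, 0.34 bits by default.

At threshold 0.34 the entropy filter removes exactly the homopolymeric
hexamers (entropy 0): the next-lowest achievable hexamer entropy,
a 5+1 composition, is ~0.65 bits.  Three distinct hexamers shifted by
one position fit into a shared 8-residue stretch, so the triple-hit
rule acts as a relaxed 8-mer match.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from allercat.seqdb import AMBIGUOUS_RESIDUES, SequenceDatabase

__all__ = [
    "DEFAULT_K",
    "DEFAULT_ENTROPY_MIN",
    "kmer_entropy",
    "valid_hexamers",
    "KmerIndex",
    "TripleHitResult",
    "triple_hit",
]

DEFAULT_K = 6
DEFAULT_ENTROPY_MIN = 0.34


def kmer_entropy(kmer: str) -> float:
    """Shannon entropy (bits) of the residue composition of ``kmer``.

    ``H = -sum_a f_a * log2(f_a)`` over residues occurring in the k-mer.
    """
    if not kmer:
        raise ValueError("kmer_entropy: empty k-mer")
    n = len(kmer)
    h = 0.0
    for count in Counter(kmer).values():
        f = count / n
        h -= f * math.log2(f)
    return h


def valid_hexamers(
    sequence: str,
    entropy_min: float = DEFAULT_ENTROPY_MIN,
    k: int = DEFAULT_K,
) -> set[str]:
    """Distinct overlapping k-mers of ``sequence`` passing both filters.

    K-mers containing any of B, J, O, U, X, Z are removed, as are those
    with :func:`kmer_entropy` below ``entropy_min``.  Sequences shorter
    than ``k`` yield the empty set.
    """
    seen: set[str] = set()
    out: set[str] = set()
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        if kmer in seen:
            continue
        seen.add(kmer)
        if AMBIGUOUS_RESIDUES.intersection(kmer):
            continue
        if kmer_entropy(kmer) < entropy_min:
            continue
        out.add(kmer)
    return out


class KmerIndex:
    """Inverted index: valid hexamer -> set of allergen record ids.

    The database side is filtered with the same entropy/ambiguity rules
    as the query side (symmetric filtering), so a homopolymeric allergen
    region can never be hit.
    """

    def __init__(self, k: int = DEFAULT_K, entropy_min: float = DEFAULT_ENTROPY_MIN) -> None:
        self.k = k
        self.entropy_min = entropy_min
        self._map: dict[str, set[str]] = {}

    @classmethod
    def from_database(
        cls,
        db: SequenceDatabase,
        k: int = DEFAULT_K,
        entropy_min: float = DEFAULT_ENTROPY_MIN,
    ) -> "KmerIndex":
        index = cls(k=k, entropy_min=entropy_min)
        for rec in db:
            index.add_sequence(rec.id, rec.sequence)
        return index

    def add_sequence(self, record_id: str, sequence: str) -> None:
        for kmer in valid_hexamers(sequence, self.entropy_min, self.k):
            self._map.setdefault(kmer, set()).add(record_id)

    def lookup(self, kmer: str) -> frozenset[str]:
        return frozenset(self._map.get(kmer, ()))

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._map

    @property
    def hexamers(self) -> frozenset[str]:
        return frozenset(self._map)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as ``hexamer<TAB>id1,id2,...`` rows (sorted, for inspection)."""
        with Path(path).open("w") as fh:
            fh.write(f"#k={self.k}\tentropy_min={self.entropy_min}\n")
            for kmer in sorted(self._map):
                fh.write(f"{kmer}\t{','.join(sorted(self._map[kmer]))}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerIndex":
        with Path(path).open() as fh:
            head = fh.readline().strip()
            if not head.startswith("#k="):
                raise ValueError(f"{path}: not a k-mer index TSV")
            kpart, epart = head[1:].split("\t")
            index = cls(k=int(kpart.split("=")[1]), entropy_min=float(epart.split("=")[1]))
            for line in fh:
                kmer, _, ids = line.rstrip("\n").partition("\t")
                index._map[kmer] = set(ids.split(",")) if ids else set()
        return index


@dataclass(frozen=True)
class TripleHitResult:
    """Allergens sharing at least ``min_hits`` distinct hexamers with a query."""

    counts: Mapping[str, int]
    min_hits: int
    best_id: str | None = field(default=None)

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def best_count(self) -> int:
        return self.counts[self.best_id] if self.best_id is not None else 0


def triple_hit(
    query_hexamers: Iterable[str],
    index: KmerIndex,
    min_hits: int = 3,
) -> TripleHitResult:
    """Count distinct shared hexamers per allergen; keep counts >= ``min_hits``.

    "Distinct" counts hexamer strings, not occurrence positions.  The
    best hit has the highest count, ties broken by lexicographic id.
    """
    if min_hits < 1:
        raise ValueError(f"min_hits must be >= 1, got {min_hits}")
    tally: Counter[str] = Counter()
    for kmer in set(query_hexamers):
        for rid in index.lookup(kmer):
            tally[rid] += 1
    hits = {rid: c for rid, c in tally.items() if c >= min_hits}
    best = min(hits, key=lambda rid: (-hits[rid], rid)) if hits else None
    return TripleHitResult(counts=hits, min_hits=min_hits, best_id=best)
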