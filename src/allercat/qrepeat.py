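"""Gluten-like Q-repeat compositional fingerprint.

Glutamine/proline-rich repeat peptides are exactly what the hexamer
entropy filter discards, so they get a dedicated detector: a per-residue
log-odds fingerprint trained on a set of Celiac-associated peptides
against a background composition.  A query 9-mer window scoring within
one standard deviation of the training mean (one-sided: at or above
``mean - sd``) triggers a hit.

The score of a window is the sum of per-residue log-odds (base 2), so it
is a pure composition fingerprint: invariant under permutation of the
window's residues.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "QRepeatModel",
    "QRepeatHit",
    "BACKGROUND_COMPOSITION",
    "train_fingerprint",
    "score_window",
    "qrepeat_hit",
    "read_peptides",
]

logger = logging.getLogger(__name__)

STANDARD_20 = "ACDEFGHIKLMNPQRSTVWY"

# UniProtKB/Swiss-Prot-style average amino-acid composition (fractions;
# normalized exactly to 1 at import).  Any strictly positive table summing
# to 1 may be supplied instead.
_RAW_BACKGROUND = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}
_total = sum(_RAW_BACKGROUND.values())
BACKGROUND_COMPOSITION: Mapping[str, float] = {
    a: v / _total for a, v in _RAW_BACKGROUND.items()
}


@dataclass(frozen=True)
class QRepeatModel:
    """Trained compositional fingerprint.

    ``logodds`` maps each of the 20 standard residues to
    ``log2(f_train / f_background)`` bits; ``floor`` is the
    pseudocount-derived log-odds used for residues never seen in
    training and for non-standard residues in a query window.
    """

    window: int
    logodds: Mapping[str, float]
    train_mean: float
    train_sd: float
    pseudocount: float
    floor: float

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.train_sd < 0:
            raise ValueError("train_sd must be >= 0")
        missing = set(STANDARD_20) - set(self.logodds)
        if missing:
            raise ValueError(f"logodds missing residues: {sorted(missing)}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "window": self.window,
            "logodds": dict(sorted(self.logodds.items())),
            "train_mean": self.train_mean,
            "train_sd": self.train_sd,
            "pseudocount": self.pseudocount,
            "floor": self.floor,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "QRepeatModel":
        d = json.loads(Path(path).read_text())
        return cls(
            window=d["window"],
            logodds=d["logodds"],
            train_mean=d["train_mean"],
            train_sd=d["train_sd"],
            pseudocount=d["pseudocount"],
            floor=d["floor"],
        )


@dataclass(frozen=True)
class QRepeatHit:
    """Decision plus the maximal-scoring window (leftmost on ties)."""

    hit: bool
    best_score: float
    best_window: str
    best_position: int  # 0-based start; -1 when the sequence has no window
    threshold: float


def _validate_background(background: Mapping[str, float]) -> None:
    missing = set(STANDARD_20) - set(background)
    if missing:
        raise ValueError(f"background missing residues: {sorted(missing)}")
    if any(background[a] <= 0 for a in STANDARD_20):
        raise ValueError("background frequencies must be strictly positive")
    total = sum(background[a] for a in STANDARD_20)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"background frequencies must sum to 1 (got {total:.8f})")


def train_fingerprint(
    peptides: Iterable[str],
    background: Mapping[str, float] | None = None,
    window: int = 9,
    pseudocount: float | None = None,
) -> QRepeatModel:
    """Train the log-odds fingerprint from training peptides.

    Residue frequencies are pooled over every ``window``-length window of
    every peptide; peptides shorter than ``window`` are skipped with a
    warning.  A pseudocount of 0.5 observations per residue (frequency
    0.5 / total pooled residue count, overridable) keeps log-odds finite.
    ``train_mean`` / ``train_sd`` (population SD) summarize the scores of
    the training windows themselves under the trained model.
    """
    background = dict(background) if background is not None else dict(BACKGROUND_COMPOSITION)
    _validate_background(background)

    windows: list[str] = []
    for pep in peptides:
        pep = pep.strip().upper()
        if not pep:
            continue
        if len(pep) < window:
            logger.warning("skipping training peptide shorter than %d: %r", window, pep)
            continue
        windows.extend(pep[i : i + window] for i in range(len(pep) - window + 1))
    if not windows:
        raise ValueError(f"no training peptide provides a {window}-residue window")

    counts = {a: 0 for a in STANDARD_20}
    total = 0
    for w in windows:
        for a in w:
            if a in counts:
                counts[a] += 1
                total += 1
    if total == 0:
        raise ValueError("training windows contain no standard residues")

    # 0.5 extra observations per residue; as a frequency this is ~0.5/total.
    eps = pseudocount if pseudocount is not None else 0.5
    denom = total + eps * len(STANDARD_20)
    logodds = {
        a: math.log2(((counts[a] + eps) / denom) / background[a]) for a in STANDARD_20
    }
    floor = math.log2((eps / denom) / (1.0 / len(STANDARD_20)))

    model = QRepeatModel(
        window=window,
        logodds=logodds,
        train_mean=0.0,
        train_sd=0.0,
        pseudocount=eps,
        floor=floor,
    )
    scores = [score_window(model, w) for w in windows]
    mean = sum(scores) / len(scores)
    sd = math.sqrt(sum((s - mean) ** 2 for s in scores) / len(scores))
    return QRepeatModel(
        window=window,
        logodds=logodds,
        train_mean=mean,
        train_sd=sd,
        pseudocount=eps,
        floor=floor,
    )


def score_window(model: QRepeatModel, window: str) -> float:
    """Sum of per-residue log-odds over a window of length ``model.window``.

    Non-standard residues (B, J, O, U, X, Z) contribute the model floor.
    """
    if len(window) != model.window:
        raise ValueError(
            f"window length {len(window)} != model window {model.window}"
        )
    lo = model.logodds
    # summed in sorted residue order so permutations of a window score
    # bit-identically (pure composition fingerprint)
    return sum(lo.get(a, model.floor) for a in sorted(window.upper()))


def qrepeat_hit(
    model: QRepeatModel,
    sequence: str,
    sd_multiplier: float = 1.0,
) -> QRepeatHit:
    """Scan every window of ``sequence``; hit iff any scores >= mean - k*sd.

    The threshold is one-sided: windows scoring above the training mean
    are hits a fortiori.  Sequences shorter than the model window never
    hit.  The reported best window is the maximal-scoring one, leftmost
    on ties.
    """
    w = model.window
    threshold = model.train_mean - sd_multiplier * model.train_sd
    sequence = sequence.upper()
    if len(sequence) < w:
        return QRepeatHit(False, float("-inf"), "", -1, threshold)
    best_score = float("-inf")
    best_pos = 0
    for i in range(len(sequence) - w + 1):
        s = score_window(model, sequence[i : i + w])
        if s > best_score:
            best_score = s
            best_pos = i
    return QRepeatHit(
        hit=best_score >= threshold,
        best_score=best_score,
        best_window=sequence[best_pos : best_pos + w],
        best_position=best_pos,
        threshold=threshold,
    )


def read_peptides(path: str | Path) -> list[str]:
    """Read a plain peptide list: one peptide per line, blanks/# ignored."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.upper())
    return out
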