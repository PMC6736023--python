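"""Shared fixtures: small synthetic bundles and independent scoring oracles."""

from __future__ import annotations

import pytest

from allercat import fixtures as fx


@pytest.fixture(scope="session")
def small_bundle():
    """A 10-allergen bundle with 3 structures; cheap enough for many tests."""
    bundle, structures = fx.build_synthetic_bundle(
        seed=11, n_allergens=10, n_structures=3, length_range=(40, 90)
    )
    return bundle, structures


@pytest.fixture(scope="session")
def helix40():
    return fx.make_helix_structure("ACDEFGHIKLMNPQRSTVWY" * 2, id="helix40")


# ---------------------------------------------------------------------------
# Independent alignment oracles (Gotoh dynamic programming, pure Python).
# These deliberately share no code with allercat.align.
# ---------------------------------------------------------------------------

NEG = float("-inf")


def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def oracle_global_score(a: str, b: str, open_=11, ext=1) -> float:
    """Affine-gap Needleman-Wunsch score; gap of length L costs open+(L-1)*ext."""
    mat = _blosum62()
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -open_ - (i - 1) * ext
    for j in range(1, m + 1):
        Y[0][j] = -open_ - (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - ext, Y[i - 1][j] - open_)
            Y[i][j] = max(M[i][j - 1] - open_, Y[i][j - 1] - ext, X[i][j - 1] - open_)
    return max(M[n][m], X[n][m], Y[n][m])


def oracle_local_score(a: str, b: str, open_=11, ext=1) -> float:
    """Affine-gap Smith-Waterman best score (0 if nothing positive)."""
    mat = _blosum62()
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0.0,
                s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]),
            )
            X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - ext)
            Y[i][j] = max(M[i][j - 1] - open_, Y[i][j - 1] - ext)
            best = max(best, M[i][j])
    return best
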