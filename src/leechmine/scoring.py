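"""Substitution scoring and local-alignment statistics.

The default scheme is BLOSUM62 with BLAST-style affine gaps (a gap of length
L costs ``gap_open + gap_extend * L``) and the standard gapped Karlin-Altschul
parameters for BLOSUM62/11/1, lambda = 0.267 and K = 0.041.  Bit scores are
the usual normalisation S' = (lambda * S - ln K) / ln 2 and the expected
number of chance hits in an m x n search space is E = m * n * 2**(-S').

No composition-based statistics and no edge-effect length correction are
applied: m and n are raw sequence lengths.  This reproduces the familiar
BLASTp score scale at desk scale without re-estimating parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .records import ALPHABET

#: Index of each accepted letter in the score matrix.
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 over the package alphabet; X scores 0 against everything."""
    bl = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    m = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                m[i, j] = 0
            else:
                m[i, j] = int(bl[a, b])
    return m


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul parameters."""

    matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("matrix shape does not match alphabet")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        self._index = {aa: i for i, aa in enumerate(self.alphabet)}

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.fromiter((self._index[c] for c in seq), dtype=np.int64,
                               count=len(seq))
        except KeyError as exc:
            raise ValueError(f"letter {exc.args[0]!r} not in scoring alphabet") from exc

    def score(self, a: str, b: str) -> int:
        """Substitution score for a single residue pair."""
        return int(self.matrix[self._index[a], self._index[b]])

    def score_grid(self, a: str, b: str) -> np.ndarray:
        """len(a) x len(b) grid of substitution scores."""
        ia, ib = self.encode(a), self.encode(b)
        return self.matrix[np.ix_(ia, ib)].astype(np.float64)

    def gap_cost(self, length: int) -> int:
        """Total cost of one gap run of the given length (> 0)."""
        return self.gap_open + self.gap_extend * length


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    """Normalised score in bits: (lambda * S - ln K) / ln 2."""
    if raw_score < 0:
        raise ValueError("raw score must be non-negative")
    return (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2.0)


def expect_value(bits: float, m: int, n: int) -> float:
    """Expected chance hits at >= this bit score in an m x n search space."""
    if m <= 0 or n <= 0:
        raise ValueError("search-space dimensions must be positive")
    # 2**(-bits) can underflow for very strong hits; compute in log space.
    log10_e = math.log10(m) + math.log10(n) - bits * math.log10(2.0)
    if log10_e < -300:
        return 10.0 ** -300
    return 10.0 ** log10_e
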