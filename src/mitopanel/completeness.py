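"""Alignment completeness statistics.

Completeness treats a character as fully specified when it is one of
A, C, G or T; gaps and ambiguity codes count as unspecified.  The
overall score C_a is the fraction of specified characters in the whole
matrix, C_r and C_c are the per-sequence and per-column fractions, and
C_ij is, for a pair of sequences, the fraction of columns specified in
both.  For large alignments the pairwise scores are computed on a
seeded random subsample of pairs, since only min/max summaries are
typically reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import UNAMBIGUOUS, ReferenceAlignment

#: Below this many sequences all pairs are scored exhaustively.
EXHAUSTIVE_PAIR_LIMIT = 200


@dataclass
class CompletenessReport:
    """Completeness summary of an alignment."""

    c_a: float
    c_r: np.ndarray
    c_c: np.ndarray
    c_ij: np.ndarray          # scores for the evaluated pairs, i < j
    pair_indices: np.ndarray  # (n_pairs, 2) row indices of those pairs
    exhaustive_pairs: bool

    def summary(self) -> pd.DataFrame:
        rows = [
            ("n_sequences", len(self.c_r), ""),
            ("n_sites", len(self.c_c), ""),
            ("C_a", self.c_a, ""),
            ("C_r", self.c_r.min(), self.c_r.max()),
            ("C_c", self.c_c.min(), self.c_c.max()),
            ("C_ij", self.c_ij.min(), self.c_ij.max()),
        ]
        return pd.DataFrame(rows, columns=["feature", "value_or_min", "max"])


def completeness_scores(
    aln: ReferenceAlignment,
    pair_sample_size: int = 2000,
    seed: int | None = 0,
) -> CompletenessReport:
    """Compute C_a, per-sequence C_r, per-column C_c and pairwise C_ij.

    Pairwise scores are exhaustive when the alignment has at most
    :data:`EXHAUSTIVE_PAIR_LIMIT` sequences, otherwise a seeded random
    subsample of ``pair_sample_size`` distinct pairs is used.
    """
    n, L = aln.matrix.shape
    if n == 0 or L == 0:
        raise ValueError("cannot compute completeness of an empty alignment")
    S = np.isin(aln.matrix, sorted(UNAMBIGUOUS))
    c_r = S.mean(axis=1)
    c_c = S.mean(axis=0)
    c_a = float(S.mean())

    if n < 2:
        pairs = np.empty((0, 2), dtype=np.int64)
        c_ij = np.empty(0)
        exhaustive = True
    elif n <= EXHAUSTIVE_PAIR_LIMIT:
        joint = (S.astype(np.float64) @ S.T.astype(np.float64)) / L
        iu = np.triu_indices(n, k=1)
        pairs = np.column_stack(iu)
        c_ij = joint[iu]
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        n_pairs = min(pair_sample_size, n * (n - 1) // 2)
        seen: set[tuple[int, int]] = set()
        while len(seen) < n_pairs:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            seen.add((min(i, j), max(i, j)))
        pairs = np.array(sorted(seen), dtype=np.int64)
        c_ij = np.array([(S[i] & S[j]).mean() for i, j in pairs])
        exhaustive = False

    return CompletenessReport(
        c_a=c_a, c_r=c_r, c_c=c_c, c_ij=c_ij, pair_indices=pairs,
        exhaustive_pairs=exhaustive,
    )
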