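"""Pairwise global alignment and percent-identity matrices.

Homolog comparison starts from a residue correspondence. We compute optimal
global alignments under affine gap penalties (Needleman-Wunsch/Gotoh, via
Biopython's PairwiseAligner) with BLOSUM62 scoring, and summarize sets of
sequences as symmetric percent-identity matrices.

Conventions
-----------
* Gap cost: a run of L gapped columns costs ``gap_open + gap_extend*(L-1)``
  (the first gapped column pays the opening penalty). Defaults 11/1.
* 'X' (unknown residue) scores 0 against everything, including itself.
* Percent identity: identical aligned pairs over aligned (non-gap in both)
  columns — the usual "Clustal-method" denominator. Alternative denominators
  (shorter sequence, full alignment length) are selectable.
* Tie-breaking among co-optimal alignments is deterministic: reading the
  alignment left to right, a diagonal (match/mismatch) column is preferred,
  then a gap in B (consuming A), then a gap in A.

The alignment engine is a Gotoh three-state dynamic program written here
(the suffix formulation, so the deterministic tie-break can be applied while
tracing forward); Biopython's PairwiseAligner serves as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentMap", "global_align", "percent_identity", "identity_matrix",
    "default_substitution_matrix",
]


def default_substitution_matrix() -> substitution_matrices.Array:
    """BLOSUM62 with every score involving 'X' forced to 0."""
    mat = substitution_matrices.load("BLOSUM62").copy()
    for aa in mat.alphabet:
        mat["X", aa] = 0.0
        mat[aa, "X"] = 0.0
    return mat


@dataclass
class AlignmentMap:
    """Residue correspondence between two sequences.

    ``pairs`` lists aligned (non-gap) columns as 1-based positions
    ``(index_in_A, index_in_B)``; both index sequences are strictly
    increasing. ``identity_fraction`` uses the aligned-column denominator.
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)
    score: float = 0.0
    identity_fraction: float = 0.0
    seqA: str = ""
    seqB: str = ""

    def __post_init__(self) -> None:
        a_idx = [p[0] for p in self.pairs]
        b_idx = [p[1] for p in self.pairs]
        if any(x >= y for x, y in zip(a_idx, a_idx[1:])) or any(
            x >= y for x, y in zip(b_idx, b_idx[1:])
        ):
            raise ValueError("alignment indices must be strictly increasing")

    def transpose(self) -> "AlignmentMap":
        return AlignmentMap(
            pairs=[(j, i) for i, j in self.pairs],
            score=self.score,
            identity_fraction=self.identity_fraction,
            seqA=self.seqB,
            seqB=self.seqA,
        )

    @classmethod
    def identity(cls, n: int) -> "AlignmentMap":
        """The trivial self-correspondence of an n-residue sequence."""
        return cls(pairs=[(i, i) for i in range(1, n + 1)],
                   identity_fraction=1.0)

    def to_two_row_text(self) -> str:
        """Simple two-row rendering with '-' for gaps."""
        rows_a, rows_b = [], []
        ia = ib = 1
        for a, b in self.pairs:
            while ia < a:
                rows_a.append(self.seqA[ia - 1]); rows_b.append("-"); ia += 1
            while ib < b:
                rows_a.append("-"); rows_b.append(self.seqB[ib - 1]); ib += 1
            rows_a.append(self.seqA[a - 1]); rows_b.append(self.seqB[b - 1])
            ia, ib = a + 1, b + 1
        while ia <= len(self.seqA):
            rows_a.append(self.seqA[ia - 1]); rows_b.append("-"); ia += 1
        while ib <= len(self.seqB):
            rows_a.append("-"); rows_b.append(self.seqB[ib - 1]); ib += 1
        return "".join(rows_a) + "\n" + "".join(rows_b)


# DP states: previous alignment column type. The suffix tables are indexed
# [i][j][state] = best score of aligning A[i:] with B[j:] when the column
# just emitted was `state` (gap extension is cheaper than opening).
_START, _M, _IX, _IY = 0, 1, 2, 3


def _suffix_tables(
    sa: str, sb: str, sub: dict[tuple[str, str], float],
    gap_open: float, gap_extend: float,
) -> np.ndarray:
    n, m = len(sa), len(sb)
    neg = -np.inf
    best = np.full((n + 1, m + 1, 4), neg)
    best[n, m, :] = 0.0
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            for state in (_START, _M, _IX, _IY):
                cands = []
                if i < n and j < m:
                    cands.append(sub[sa[i], sb[j]] + best[i + 1, j + 1, _M])
                if i < n:  # gap in B, consume A
                    cost = gap_extend if state == _IX else gap_open
                    cands.append(-cost + best[i + 1, j, _IX])
                if j < m:  # gap in A, consume B
                    cost = gap_extend if state == _IY else gap_open
                    cands.append(-cost + best[i, j + 1, _IY])
                best[i, j, state] = max(cands)
    return best


def global_align(
    seqA: str,
    seqB: str,
    matrix: substitution_matrices.Array | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentMap:
    """Optimal global alignment of two one-letter sequences (Gotoh).

    The alignment maximizes the substitution score minus affine gap costs;
    among co-optimal alignments the deterministic front-to-back tie-break
    (diagonal, then gap-in-B, then gap-in-A) selects one. Raises
    ``ValueError`` on an empty sequence or a residue outside the
    substitution table's alphabet.
    """
    if not seqA or not seqB:
        raise ValueError("sequences must be nonempty")
    matrix = matrix if matrix is not None else default_substitution_matrix()
    alphabet = set(matrix.alphabet)
    for name, seq in (("A", seqA), ("B", seqB)):
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(f"sequence {name} contains letters outside the "
                             f"substitution alphabet: {sorted(bad)}")
    sub = {(a, b): float(matrix[a, b]) for a in set(seqA) for b in set(seqB)}

    best = _suffix_tables(seqA, seqB, sub, gap_open, gap_extend)
    n, m = len(seqA), len(seqB)
    score = float(best[0, 0, _START])

    # forward trace: at each cell take the first move (M, Ix, Iy) that is on
    # an optimal path — front-lexicographic deterministic tie-breaking
    pairs: list[tuple[int, int]] = []
    matches = 0
    i = j = 0
    state = _START
    tol = 1e-9
    while i < n or j < m:
        target = best[i, j, state]
        if (i < n and j < m
                and abs(sub[seqA[i], seqB[j]] + best[i + 1, j + 1, _M] - target) < tol):
            pairs.append((i + 1, j + 1))
            if seqA[i] == seqB[j]:
                matches += 1
            i, j, state = i + 1, j + 1, _M
            continue
        cost = gap_extend if state == _IX else gap_open
        if i < n and abs(-cost + best[i + 1, j, _IX] - target) < tol:
            i, state = i + 1, _IX
            continue
        cost = gap_extend if state == _IY else gap_open
        if j < m and abs(-cost + best[i, j + 1, _IY] - target) < tol:
            j, state = j + 1, _IY
            continue
        raise RuntimeError("traceback failed (inconsistent DP tables)")

    identity = matches / len(pairs) if pairs else 0.0
    return AlignmentMap(pairs=pairs, score=score,
                        identity_fraction=identity, seqA=seqA, seqB=seqB)


def percent_identity(
    m: AlignmentMap,
    seqA: str | None = None,
    seqB: str | None = None,
    denominator: str = "aligned",
) -> float:
    """Percent identity of an alignment, in [0, 100].

    denominator: ``aligned`` (non-gap-in-both columns, default),
    ``shorter`` (length of the shorter sequence), or ``alignment``
    (full alignment length including gapped columns).
    """
    seqA = seqA if seqA is not None else m.seqA
    seqB = seqB if seqB is not None else m.seqB
    matches = sum(1 for a, b in m.pairs if seqA[a - 1] == seqB[b - 1])
    if denominator == "aligned":
        denom = len(m.pairs)
    elif denominator == "shorter":
        denom = min(len(seqA), len(seqB))
    elif denominator == "alignment":
        denom = len(seqA) + len(seqB) - len(m.pairs)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * matches / denom if denom else 0.0


def identity_matrix(
    seqs: Sequence[tuple[str, str]],
    matrix: substitution_matrices.Array | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    denominator: str = "aligned",
) -> pd.DataFrame:
    """Symmetric percent-identity matrix of labelled sequences.

    ``seqs`` is a list of ``(label, sequence)``; duplicate labels are an
    error. The diagonal is exactly 100.0 and each off-diagonal entry comes
    from one global alignment of the pair.
    """
    labels = [label for label, _ in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    matrix = matrix if matrix is not None else default_substitution_matrix()
    n = len(seqs)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            m = global_align(seqs[i][1], seqs[j][1], matrix, gap_open, gap_extend)
            pid = percent_identity(m, denominator=denominator)
            out[i, j] = out[j, i] = pid
    return pd.DataFrame(out, index=labels, columns=labels)


def write_identity_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.2f")
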