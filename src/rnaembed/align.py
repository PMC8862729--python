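"""Global structural alignment over an embedding-derived score matrix.

The match score of positions (i, j) is the cosine similarity of the two
base embeddings (the Omega matrix); gaps are affine with an opening score
for the first column of a gap run and an extension score for each further
column (defaults -1 and -0.1). The optimum is found with the three-state
Gotoh dynamic program in O(nm) time, which is exact for these scores.

Alignment accuracy is measured over matched columns only: TP is the
number of predicted (i, j) pairs present in the reference, sensitivity
divides by the reference pair count, PPV by the predicted pair count and
F1 is their harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import PairwiseAlignment, RnaSequence

__all__ = [
    "GapParams",
    "AlignmentResult",
    "AlignmentMetrics",
    "nw_affine",
    "align_pair",
    "alignment_score",
    "alignment_metrics",
    "enumerate_alignments",
]

NEG = -1e30


@dataclass(frozen=True)
class GapParams:
    open: float = -1.0
    extend: float = -0.1

    def __post_init__(self):
        if self.open > 0 or self.extend > 0:
            raise ValueError("gap scores must be non-positive")

    def run_score(self, length: int) -> float:
        return self.open + self.extend * (length - 1) if length else 0.0


@dataclass
class AlignmentResult:
    alignment: PairwiseAlignment
    score: float
    aligned_rows: tuple[str, str] | None = None


@dataclass
class AlignmentMetrics:
    tp: int
    sensitivity: float
    ppv: float
    f1: float


def alignment_score(omega: np.ndarray, gaps: GapParams, y: PairwiseAlignment) -> float:
    """Sum of omega over matched columns plus affine gap-run scores."""
    omega = np.asarray(omega)
    n, m = omega.shape
    if y.n != n or y.m != m:
        raise ValueError("alignment does not fit the score matrix")
    total = 0.0
    run = 0  # 0 none, 1 gap in second seq (i,-), 2 gap in first (-,j)
    for i, j in y.columns:
        if i is not None and j is not None:
            total += omega[i - 1, j - 1]
            run = 0
        elif j is None:  # (i, -)
            total += gaps.extend if run == 1 else gaps.open
            run = 1
        else:  # (-, j)
            total += gaps.extend if run == 2 else gaps.open
            run = 2
    return total


def nw_affine(omega: np.ndarray, gaps: GapParams = GapParams()) -> AlignmentResult:
    """Optimal global alignment by the three-state Gotoh DP.

    States: M emits a matched column, X emits (i, -), Y emits (-, j).
    Ties are broken deterministically M > X > Y, both for the final state
    and in every traceback step.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.size == 0:
        raise ValueError("score matrix must be a non-empty 2-D array")
    n, m = omega.shape
    op, ex = gaps.open, gaps.extend

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    # backpointers: previous state index 0=M, 1=X, 2=Y (-1 at origin)
    bM = np.full((n + 1, m + 1), -1, dtype=np.int8)
    bX = np.full((n + 1, m + 1), -1, dtype=np.int8)
    bY = np.full((n + 1, m + 1), -1, dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gaps.run_score(i)
        bX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = gaps.run_score(j)
        bY[0, j] = 2 if j > 1 else 0

    def best(cands):
        # cands: list of (score, state_idx) in preference order M, X, Y
        s, b = cands[0]
        for sc, st in cands[1:]:
            if sc > s:
                s, b = sc, st
        return s, b

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s, b = best([(M[i - 1, j - 1], 0), (X[i - 1, j - 1], 1), (Y[i - 1, j - 1], 2)])
            M[i, j] = s + omega[i - 1, j - 1]
            bM[i, j] = b
            s, b = best([(M[i - 1, j] + op, 0), (X[i - 1, j] + ex, 1), (Y[i - 1, j] + op, 2)])
            X[i, j] = s
            bX[i, j] = b
            s, b = best([(M[i, j - 1] + op, 0), (X[i, j - 1] + op, 1), (Y[i, j - 1] + ex, 2)])
            Y[i, j] = s
            bY[i, j] = b

    score, state = best([(M[n, m], 0), (X[n, m], 1), (Y[n, m], 2)])
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            cols.append((i, j))
            state = bM[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            cols.append((i, None))
            state = bX[i, j]
            i -= 1
        else:
            cols.append((None, j))
            state = bY[i, j]
            j -= 1
    cols.reverse()
    return AlignmentResult(alignment=PairwiseAlignment(cols), score=float(score))


def align_pair(
    a: RnaSequence,
    b: RnaSequence,
    params: dict,
    config,
    gaps: GapParams = GapParams(),
) -> AlignmentResult:
    """Embed both sequences, build Omega and align."""
    from .sal import omega as omega_fn

    za = _embed(a, params, config)
    zb = _embed(b, params, config)
    result = nw_affine(omega_fn(za, zb), gaps)
    result.aligned_rows = result.alignment.to_gapped(a.residues, b.residues)
    return result


def _embed(seq: RnaSequence, params: dict, config) -> np.ndarray:
    from .model import embed

    return embed(seq, params, config)


def alignment_metrics(pred: PairwiseAlignment, ref: PairwiseAlignment) -> AlignmentMetrics:
    """Sensitivity, PPV and F1 over matched (i, j) pairs."""
    if pred.n != ref.n or pred.m != ref.m:
        raise ValueError("alignments cover different sequence pairs")
    p, r = pred.matched_pairs(), ref.matched_pairs()
    tp = len(p & r)
    sen = tp / len(r) if r else 0.0
    ppv = tp / len(p) if p else 0.0
    f1 = 2 * sen * ppv / (sen + ppv) if sen + ppv else 0.0
    return AlignmentMetrics(tp=tp, sensitivity=sen, ppv=ppv, f1=f1)


def enumerate_alignments(n: int, m: int):
    """Yield every global alignment of lengths n and m (test oracle).

    Exponential; intended only for tiny n, m.
    """

    def rec(i, j, prefix):
        if i == n and j == m:
            yield PairwiseAlignment(list(prefix))
            return
        if i < n and j < m:
            yield from rec(i + 1, j + 1, prefix + [(i + 1, j + 1)])
        if i < n:
            yield from rec(i + 1, j, prefix + [(i + 1, None)])
        if j < m:
            yield from rec(i, j + 1, prefix + [(None, j + 1)])

    yield from rec(0, 0, [])
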