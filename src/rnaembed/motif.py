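"""Sequence-motif calling from attention maps.

The attention map M assigns every position the total attention mass it
receives, summed over heads and query positions of one transformer layer
(the final layer by default). Positions whose mass exceeds
mean(M) + threshold_sd * sd(M) are salient; maximal runs of salient
positions of at least ``min_len`` bases are reported as motif calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import RnaSequence

__all__ = ["MotifCall", "call_motifs"]


@dataclass
class MotifCall:
    start: int  # 1-based inclusive
    end: int
    subsequence: str
    mean_salience: float


def call_motifs(
    seq: RnaSequence,
    attention: np.ndarray,
    min_len: int = 3,
    threshold_sd: float = 1.0,
) -> list[MotifCall]:
    """Report maximal high-attention runs of length >= min_len."""
    m = np.asarray(attention, dtype=float)
    n = len(seq)
    if len(m) != n:
        raise ValueError("attention map length does not match the sequence")
    cutoff = m.mean() + threshold_sd * m.std()
    flagged = m > cutoff
    calls: list[MotifCall] = []
    start = None
    for pos in range(n + 1):
        if pos < n and flagged[pos]:
            if start is None:
                start = pos
        elif start is not None:
            if pos - start >= min_len:
                calls.append(
                    MotifCall(
                        start=start + 1,
                        end=pos,
                        subsequence=seq.residues[start:pos],
                        mean_salience=float(m[start:pos].mean()),
                    )
                )
            start = None
    return calls
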