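"""Global affine-gap alignment of an element's two LTR copies.

The two LTRs of an intact element were identical at insertion, so a
standard global (end-gap penalized) alignment with affine gap costs is
the right comparison.  Scoring defaults mirror the common nucleotide
defaults of EMBOSS-style aligners: match +5, mismatch -4, gap opening
16 and gap extension 4, with a run of k gap positions costing
``gap_open + (k - 1) * gap_extend``.  Columns involving non-ACGT
characters score as mismatches and are excluded later from divergence
counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"
_ALPHABET = "ACGTURYSWKMBDHVN"


@dataclass(frozen=True)
class AlignParams:
    match_score: float = 5.0
    mismatch_score: float = -4.0
    gap_open: float = 16.0  # cost of the first gap position in a run
    gap_extend: float = 4.0  # cost of each additional gap position

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if not self.match_score > self.mismatch_score:
            raise ValueError("require match_score > mismatch_score")


@dataclass(frozen=True)
class AlignedPair:
    """Equal-length gapped rows; degapping each row recovers its input."""

    element_id: str
    aligned_left: str
    aligned_right: str
    score: float

    @property
    def aligned_columns(self) -> int:
        return len(self.aligned_left)


@lru_cache(maxsize=8)
def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    n = len(_ALPHABET)
    data = np.full((n, n), params.mismatch_score)
    matrix = substitution_matrices.Array(_ALPHABET, dims=2, data=data)
    for base in "ACGT":
        matrix[base, base] = params.match_score
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(
    left: str, right: str, params: AlignParams | None = None, element_id: str = ""
) -> AlignedPair:
    """Optimal global alignment of the two LTR sequences.

    Deterministic: among co-optimal alignments the aligner's canonical
    first traceback is reported.  Empty input is a hard error.
    """
    params = params or AlignParams()
    if not left or not right:
        raise ValueError(f"{element_id or '<element>'}: empty LTR sequence")
    left = left.upper()
    right = right.upper()
    aligner = _aligner(params)
    alignment = aligner.align(left, right)[0]
    aligned_left, aligned_right = str(alignment[0]), str(alignment[1])
    pair = AlignedPair(
        element_id=element_id,
        aligned_left=aligned_left,
        aligned_right=aligned_right,
        score=float(alignment.score),
    )
    assert pair.aligned_left.replace(GAP, "") == left
    assert pair.aligned_right.replace(GAP, "") == right
    return pair


def enumerate_best_score(left: str, right: str, params: AlignParams | None = None) -> float:
    """Best global score by exhaustive enumeration of all alignments.

    Walks every monotone path through the alignment grid, scoring gap
    runs as ``open + (k-1) * extend``.  Exponential — intended as an
    independent oracle for short sequences (length <= ~8) only.
    """
    params = params or AlignParams()

    def column_score(a: str, b: str) -> float:
        if a in "ACGT" and a == b:
            return params.match_score
        return params.mismatch_score

    best = -np.inf

    def walk(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if i == len(left) and j == len(right):
            best = max(best, score)
            return
        if i < len(left) and j < len(right):
            walk(i + 1, j + 1, score + column_score(left[i], right[j]), "M")
        if i < len(left):  # gap in right row
            cost = params.gap_extend if last == "D" else params.gap_open
            walk(i + 1, j, score - cost, "D")
        if j < len(right):  # gap in left row
            cost = params.gap_extend if last == "I" else params.gap_open
            walk(i, j + 1, score - cost, "I")

    walk(0, 0, 0.0, "M")
    return best
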