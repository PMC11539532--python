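"""Collapse near-duplicate intact-LTR records.

Structural LTR annotation output often contains several records for one
physical insertion.  Two records are duplicates when they lie on the
same scaffold, their left LTR intervals overlap, their right LTR
intervals overlap, and the sum of nonoverlapping bases — the symmetric
difference of the paired left intervals plus that of the paired right
intervals — is below a threshold (default 50 bp).  The duplicate
relation is closed transitively into connected components and, within
each component, the record with the byte-wise lexicographically
smallest element_id is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import LTRRecord


@dataclass(frozen=True)
class DedupConfig:
    nonoverlap_threshold: int = 50  # bases
    transitive: bool = True

    def __post_init__(self):
        if self.nonoverlap_threshold <= 0:
            raise ValueError("nonoverlap_threshold must be > 0")


def _intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def nonoverlap_bases(a: LTRRecord, b: LTRRecord) -> int:
    """Symmetric difference (bp) of the paired left and right LTR intervals."""
    return (
        abs(a.left_ltr_start - b.left_ltr_start)
        + abs(a.left_ltr_end - b.left_ltr_end)
        + abs(a.right_ltr_start - b.right_ltr_start)
        + abs(a.right_ltr_end - b.right_ltr_end)
    )


def records_are_duplicates(a: LTRRecord, b: LTRRecord, cfg: DedupConfig | None = None) -> bool:
    """True iff a and b represent the same physical insertion under cfg.

    Requires same scaffold, overlapping left LTRs, overlapping right
    LTRs, and total nonoverlap below the threshold.  Strand plays no
    part in the test.
    """
    cfg = cfg or DedupConfig()
    if a.seq_id != b.seq_id:
        return False
    if not _intervals_overlap(a.left_ltr_start, a.left_ltr_end, b.left_ltr_start, b.left_ltr_end):
        return False
    if not _intervals_overlap(a.right_ltr_start, a.right_ltr_end, b.right_ltr_start, b.right_ltr_end):
        return False
    return nonoverlap_bases(a, b) < cfg.nonoverlap_threshold


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def deduplicate(
    records: Sequence[LTRRecord], cfg: DedupConfig | None = None
) -> tuple[list[LTRRecord], list[tuple[str, str, int]]]:
    """Collapse duplicates; return (kept records, removal report).

    The removal report pairs each discarded element_id with the id of
    its component's keeper and their nonoverlap in bases.  Kept records
    preserve input order.  With ``transitive`` off, a greedy single-pass
    variant is used instead of connected components (sensitivity knob).
    """
    cfg = cfg or DedupConfig()
    ids = [r.element_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate element_id(s) on input: {dup}")

    n = len(records)
    if n == 0:
        return [], []

    # Candidate pairs restricted to same scaffold; n is annotation-sized
    # so all pairs within a scaffold is fine.
    by_scaffold: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_scaffold.setdefault(r.seq_id, []).append(i)

    if cfg.transitive:
        uf = _UnionFind(n)
        for idxs in by_scaffold.values():
            for ai in range(len(idxs)):
                for bi in range(ai + 1, len(idxs)):
                    i, j = idxs[ai], idxs[bi]
                    if records_are_duplicates(records[i], records[j], cfg):
                        uf.union(i, j)
        components: dict[int, list[int]] = {}
        for i in range(n):
            components.setdefault(uf.find(i), []).append(i)
        keeper_of: dict[int, int] = {}
        for members in components.values():
            keeper = min(members, key=lambda i: records[i].element_id.encode())
            for i in members:
                keeper_of[i] = keeper
    else:
        # Greedy, input-order: each record joins the first earlier keeper
        # it duplicates.
        keeper_of = {}
        keepers: list[int] = []
        for i in range(n):
            match = next(
                (k for k in keepers if records_are_duplicates(records[i], records[k], cfg)),
                None,
            )
            if match is None:
                keeper_of[i] = i
                keepers.append(i)
            else:
                keeper_of[i] = match

    kept = [records[i] for i in range(n) if keeper_of[i] == i]
    removed = [
        (
            records[i].element_id,
            records[keeper_of[i]].element_id,
            nonoverlap_bases(records[i], records[keeper_of[i]]),
        )
        for i in range(n)
        if keeper_of[i] != i
    ]
    return kept, removed


def write_dedup_report(removed: Sequence[tuple[str, str, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("removed_id\tkept_id\tnonoverlap_bases\n")
        for removed_id, kept_id, nov in removed:
            fh.write(f"{removed_id}\t{kept_id}\t{nov}\n")
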