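"""Input handling: genome FASTA, intact-LTR annotations, and clade tables.

Intact LTR retrotransposons arrive either as EDTA-style GFF3 (a parent
repeat feature with two ``long_terminal_repeat`` children) or as a
normalized TSV.  All coordinates are GFF3 convention: 1-based, closed
intervals.  Sequence extraction is always on the forward strand because
the divergence between an element's two LTRs is invariant under joint
reverse-complement.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

NORMALIZED_TSV_COLUMNS = [
    "element_id",
    "seq_id",
    "element_start",
    "element_end",
    "left_ltr_start",
    "left_ltr_end",
    "right_ltr_start",
    "right_ltr_end",
    "strand",
]

#: REXdb clades reported for plant Copia and Gypsy superfamilies.
COPIA_CLADES = ("Ale", "Gymco-I", "Gymco-II", "Ivana", "SIRE", "Tork")
GYPSY_CLADES = ("Athila", "CRM", "Ogre", "Reina", "TatII", "TatIII")


class GenomeSequences(Mapping[str, str]):
    """Upper-cased nucleotide scaffolds keyed by identifier, order preserved."""

    def __init__(self, entries: Mapping[str, str]):
        for name, seq in entries.items():
            if not name:
                raise ValueError("empty scaffold identifier")
            if not seq:
                raise ValueError(f"empty sequence for scaffold {name!r}")
        self._entries = {name: seq.upper() for name, seq in entries.items()}

    def __getitem__(self, key: str) -> str:
        return self._entries[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)


@dataclass(frozen=True)
class LTRRecord:
    """One intact element: element span plus its left/right LTR intervals.

    Coordinates are 1-based closed.  The ordering invariant is
    ``element_start <= left_ltr_start <= left_ltr_end < right_ltr_start
    <= right_ltr_end <= element_end``.
    """

    element_id: str
    seq_id: str
    element_start: int
    element_end: int
    left_ltr_start: int
    left_ltr_end: int
    right_ltr_start: int
    right_ltr_end: int
    strand: str = "."
    source_superfamily: str | None = None

    def validate(self) -> None:
        if not self.element_id:
            raise ValueError("empty element_id")
        if not self.seq_id:
            raise ValueError(f"{self.element_id}: empty seq_id")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.element_id}: bad strand {self.strand!r}")
        ok = (
            self.element_start
            <= self.left_ltr_start
            <= self.left_ltr_end
            < self.right_ltr_start
            <= self.right_ltr_end
            <= self.element_end
        )
        if not ok:
            raise ValueError(f"{self.element_id}: LTR/element coordinate ordering violated")
        if self.element_start < 1:
            raise ValueError(f"{self.element_id}: coordinates must be >= 1")

    @property
    def left_ltr_length(self) -> int:
        return self.left_ltr_end - self.left_ltr_start + 1

    @property
    def right_ltr_length(self) -> int:
        return self.right_ltr_end - self.right_ltr_start + 1

    @property
    def element_length(self) -> int:
        return self.element_end - self.element_start + 1


@dataclass(frozen=True)
class CladeAssignment:
    element_id: str
    superfamily: str  # "Copia", "Gypsy", or "other/unknown"
    clade: str = "others"


@dataclass
class AnnotationSet(Sequence):
    """Parsed annotation records plus parse bookkeeping.

    accepted + dropped = parents parsed; records failing the coordinate
    invariants are dropped with a warning, never fatal (structural
    annotation output is noisy).
    """

    records: list[LTRRecord] = field(default_factory=list)
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def n_parsed(self) -> int:
        return len(self.records) + self.n_dropped


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> GenomeSequences:
    """Read a (optionally gzipped) FASTA file into :class:`GenomeSequences`.

    The identifier is the header token before the first whitespace.
    Duplicate identifiers and empty files are hard errors.
    """
    entries: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in entries:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            entries[rec.id] = str(rec.seq).upper()
    if not entries:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequences(entries)


def _records_from_edta_gff3(path) -> AnnotationSet:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out = AnnotationSet()
    for parent in db.all_features():
        children = [
            c
            for c in db.children(parent, featuretype="long_terminal_repeat")
        ]
        if not children and parent.featuretype == "long_terminal_repeat":
            continue
        if parent.featuretype == "long_terminal_repeat":
            continue
        if not children:
            continue
        element_id = parent.id
        if len(children) != 2:
            logger.warning(
                "element %s has %d long_terminal_repeat children (expected 2); dropped",
                element_id,
                len(children),
            )
            out.n_dropped += 1
            continue
        children.sort(key=lambda c: (c.start, c.end))
        left, right = children
        rec = LTRRecord(
            element_id=element_id,
            seq_id=parent.seqid,
            element_start=parent.start,
            element_end=parent.end,
            left_ltr_start=left.start,
            left_ltr_end=left.end,
            right_ltr_start=right.start,
            right_ltr_end=right.end,
            strand=parent.strand if parent.strand in {"+", "-"} else ".",
            source_superfamily=parent.featuretype,
        )
        try:
            rec.validate()
        except ValueError as exc:
            logger.warning("dropping malformed record: %s", exc)
            out.n_dropped += 1
            continue
        out.records.append(rec)
    return out


def _records_from_normalized_tsv(path) -> AnnotationSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in NORMALIZED_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"normalized TSV {path} missing columns: {missing}")
    out = AnnotationSet()
    for row in df.itertuples(index=False):
        source = getattr(row, "source_superfamily", None)
        if pd.isna(source):
            source = None
        rec = LTRRecord(
            element_id=row.element_id,
            seq_id=row.seq_id,
            element_start=int(row.element_start),
            element_end=int(row.element_end),
            left_ltr_start=int(row.left_ltr_start),
            left_ltr_end=int(row.left_ltr_end),
            right_ltr_start=int(row.right_ltr_start),
            right_ltr_end=int(row.right_ltr_end),
            strand=row.strand,
            source_superfamily=source,
        )
        try:
            rec.validate()
        except ValueError as exc:
            logger.warning("dropping malformed record: %s", exc)
            out.n_dropped += 1
            continue
        out.records.append(rec)
    return out


def read_ltr_annotations(path, dialect: str = "edta_gff3") -> AnnotationSet:
    """Read intact-LTR annotations in the named dialect.

    ``edta_gff3``
        GFF3 where a parent repeat feature (any type, e.g.
        ``Copia_LTR_retrotransposon``) has exactly two
        ``long_terminal_repeat`` children referencing it via ``Parent``.
        The parent feature type is carried as ``source_superfamily``.
    ``normalized_tsv``
        Tab-separated table with header columns
        ``element_id seq_id element_start element_end left_ltr_start
        left_ltr_end right_ltr_start right_ltr_end strand``.

    The left LTR is always the child with the smaller start coordinate,
    regardless of file order.
    """
    if dialect == "edta_gff3":
        return _records_from_edta_gff3(path)
    if dialect == "normalized_tsv":
        return _records_from_normalized_tsv(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_normalized_tsv(records: Sequence[LTRRecord], path) -> None:
    """Write records as normalized TSV (round-trips with read_ltr_annotations)."""
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in NORMALIZED_TSV_COLUMNS}
        if r.source_superfamily is not None:
            row["source_superfamily"] = r.source_superfamily
        rows.append(row)
    cols = list(NORMALIZED_TSV_COLUMNS)
    if any("source_superfamily" in row for row in rows):
        cols.append("source_superfamily")
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def extract_ltr_pair(genome: GenomeSequences, record: LTRRecord) -> tuple[str, str]:
    """Return the forward-strand (left, right) LTR subsequences of a record."""
    if record.seq_id not in genome:
        raise KeyError(
            f"{record.element_id}: scaffold {record.seq_id!r} not in genome"
        )
    seq = genome[record.seq_id]
    if record.right_ltr_end > len(seq):
        raise ValueError(
            f"{record.element_id}: coordinates exceed scaffold "
            f"{record.seq_id} length {len(seq)}"
        )
    left = seq[record.left_ltr_start - 1 : record.left_ltr_end]
    right = seq[record.right_ltr_start - 1 : record.right_ltr_end]
    return left, right


def strip_classification_suffix(te_id: str) -> str:
    """TEsorter ids carry a '#classification' suffix; strip at the first '#'."""
    return te_id.split("#", 1)[0]


def read_clade_table(path) -> list[CladeAssignment]:
    """Read a TEsorter ``.cls.tsv`` classification table.

    Superfamilies other than Copia/Gypsy map to ``other/unknown``;
    missing or 'unknown' clades map to ``others``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lstrip("#"): c for c in df.columns}
    required = ["TE", "Superfamily", "Clade"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"clade table {path} missing columns: {missing}")
    out: list[CladeAssignment] = []
    for _, row in df.iterrows():
        element_id = strip_classification_suffix(str(row[cols["TE"]]))
        superfamily = str(row[cols["Superfamily"]])
        if superfamily not in {"Copia", "Gypsy"}:
            superfamily = "other/unknown"
        clade = row[cols["Clade"]]
        if pd.isna(clade) or not str(clade) or str(clade).lower() == "unknown":
            clade = "others"
        out.append(CladeAssignment(element_id, superfamily, str(clade)))
    return out


_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def remap_record_to_revcomp(record: LTRRecord, scaffold_length: int) -> LTRRecord:
    """Remap a record onto the reverse-complemented scaffold.

    Left and right LTRs swap roles; used to assert pipeline invariance
    under joint reverse-complement.
    """
    flip = lambda pos: scaffold_length - pos + 1
    strand = {"+": "-", "-": "+", ".": "."}[record.strand]
    return replace(
        record,
        element_start=flip(record.element_end),
        element_end=flip(record.element_start),
        left_ltr_start=flip(record.right_ltr_end),
        left_ltr_end=flip(record.right_ltr_start),
        right_ltr_start=flip(record.left_ltr_end),
        right_ltr_end=flip(record.left_ltr_start),
        strand=strand,
    )
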