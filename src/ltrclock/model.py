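"""Model/Results objects tying the pipeline stages together.

:class:`InsertionAgeModel` holds the data (genome, intact-LTR records,
optional clade assignments) and the estimation settings (dedup
threshold, alignment scoring, clock rate).  ``fit()`` runs
deduplication, LTR-pair extraction, global alignment, K2P divergence
and clock dating, and returns an :class:`InsertionAgeResults` carrying
the per-element table, the dedup report, stage counts and summary /
plotting methods.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import summary as summary_mod
from .align import AlignParams, global_align
from .dedup import DedupConfig, deduplicate, write_dedup_report
from .io import (
    AnnotationSet,
    CladeAssignment,
    GenomeSequences,
    LTRRecord,
    extract_ltr_pair,
    read_clade_table,
    read_fasta,
    read_ltr_annotations,
)
from .k2p import ClockConfig, date_element, estimate_divergence

logger = logging.getLogger(__name__)

PER_ELEMENT_COLUMNS = [
    "element_id", "seq_id", "element_length", "left_ltr_len", "right_ltr_len",
    "aligned_columns", "n_sites", "transitions", "transversions",
    "P", "Q", "k2p", "saturated", "age_years", "age_mya",
    "superfamily", "clade",
]


class InsertionAgeModel:
    """Insertion-age estimator for intact LTR retrotransposons.

    Parameters
    ----------
    genome
        Scaffold sequences the annotation coordinates refer to.
    records
        Intact-LTR records (element span + left/right LTR intervals).
    clades
        Optional clade assignments (e.g. from a TEsorter table).
    dedup_config, align_params, clock
        Estimation settings; defaults follow standard nucleotide
        alignment scoring and the C. japonica substitution rate
        0.59e-9 /site/year.
    species
        Label attached to every output row (used by multi-species
        comparisons).
    """

    def __init__(
        self,
        genome: GenomeSequences,
        records: Sequence[LTRRecord],
        clades: Sequence[CladeAssignment] | None = None,
        *,
        dedup_config: DedupConfig | None = None,
        align_params: AlignParams | None = None,
        clock: ClockConfig | None = None,
        species: str = "sample",
        n_dropped_on_parse: int = 0,
    ):
        self.genome = genome
        self.records = list(records)
        self.clades = list(clades) if clades is not None else []
        self.dedup_config = dedup_config or DedupConfig()
        self.align_params = align_params or AlignParams()
        self.clock = clock or ClockConfig()
        self.species = species
        self.n_dropped_on_parse = n_dropped_on_parse

    @classmethod
    def from_files(
        cls,
        genome_path,
        annotation_path,
        clade_path=None,
        *,
        dialect: str = "edta_gff3",
        **kwargs,
    ) -> "InsertionAgeModel":
        """Build a model from a FASTA, an annotation file and an
        optional TEsorter classification table."""
        genome = read_fasta(genome_path)
        annotations: AnnotationSet = read_ltr_annotations(annotation_path, dialect=dialect)
        clades = read_clade_table(clade_path) if clade_path else None
        if clade_path is None:
            logger.warning("no clade table given; all elements will be other/unknown")
        return cls(
            genome,
            annotations.records,
            clades,
            n_dropped_on_parse=annotations.n_dropped,
            **kwargs,
        )

    def fit(self, n_jobs: int = 1) -> "InsertionAgeResults":
        """Run dedup -> extract -> align -> K2P -> date -> clade join.

        ``n_jobs`` parallelizes the per-element alignment stage; results
        are sorted by element_id, so the value never changes outputs.
        """
        kept, removed = deduplicate(self.records, self.dedup_config)
        kept = sorted(kept, key=lambda r: r.element_id)

        def process(rec: LTRRecord) -> dict:
            left, right = extract_ltr_pair(self.genome, rec)
            pair = global_align(left, right, self.align_params, element_id=rec.element_id)
            est = estimate_divergence(pair)
            dated = date_element(est, self.clock)
            return dict(
                element_id=rec.element_id,
                seq_id=rec.seq_id,
                element_length=rec.element_length,
                left_ltr_len=rec.left_ltr_length,
                right_ltr_len=rec.right_ltr_length,
                aligned_columns=pair.aligned_columns,
                n_sites=est.n_sites,
                transitions=est.n_transitions,
                transversions=est.n_transversions,
                P=est.P,
                Q=est.Q,
                k2p=dated.K if dated.K is not None else np.nan,
                saturated=dated.saturated,
                age_years=dated.age_years if dated.age_years is not None else np.nan,
                age_mya=dated.age_mya if dated.age_mya is not None else np.nan,
                source_superfamily=rec.source_superfamily,
            )

        if n_jobs != 1:
            from joblib import Parallel, delayed

            rows = Parallel(n_jobs=n_jobs)(delayed(process)(r) for r in kept)
        else:
            rows = [process(r) for r in kept]

        per_element = pd.DataFrame(
            rows,
            columns=[c for c in PER_ELEMENT_COLUMNS if c not in ("superfamily", "clade")]
            + ["source_superfamily"],
        )
        per_element = summary_mod.join_classification(per_element, self.clades)
        per_element = per_element.drop(columns=["source_superfamily"])
        per_element.insert(0, "species", self.species)

        counts = dict(
            parsed=len(self.records) + self.n_dropped_on_parse,
            dropped_on_parse=self.n_dropped_on_parse,
            input_records=len(self.records),
            removed_as_duplicates=len(removed),
            deduplicated=len(kept),
            aligned=len(per_element),
            saturated=int(per_element["saturated"].sum()),
            dated=int((~per_element["saturated"].astype(bool)).sum()),
        )
        return InsertionAgeResults(self, per_element, removed, counts)


class InsertionAgeResults:
    """Fitted per-element insertion ages plus reporting utilities."""

    def __init__(self, model: InsertionAgeModel, table: pd.DataFrame,
                 dedup_removed: list, stage_counts: dict):
        self.model = model
        self.table = table
        self.dedup_removed = dedup_removed
        self.stage_counts = stage_counts

    def summary(self) -> pd.DataFrame:
        """Per-(superfamily, clade) counts, length and age statistics."""
        return summary_mod.summarize_by_clade(self.table)

    def age_histogram(self, bin_width: float = 5.0, max_age: float = 200.0) -> pd.DataFrame:
        return summary_mod.age_histogram(
            self.table, bin_width=bin_width, max_age=max_age,
            species_label=self.model.species,
        )

    def plot_age_landscape(self, path=None, **kwargs):
        return summary_mod.plot_age_landscape(
            self.age_histogram(**kwargs) if kwargs else self.age_histogram(), path=path
        )

    def manifest(self, input_paths: dict | None = None) -> dict:
        """Machine-readable run description: parameters, input
        checksums, stage counts."""
        checksums = {}
        for name, p in (input_paths or {}).items():
            if p and Path(p).exists():
                checksums[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        return dict(
            species=self.model.species,
            parameters=dict(
                dedup=asdict(self.model.dedup_config),
                align=asdict(self.model.align_params),
                clock=asdict(self.model.clock),
            ),
            input_checksums=checksums,
            stage_counts=self.stage_counts,
        )

    def save(self, outdir, input_paths: dict | None = None,
             bin_width: float = 5.0, max_age: float = 200.0) -> dict[str, Path]:
        """Write per-element TSV, dedup report, clade summary, histogram
        TSV, plots and the run manifest into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "per_element": outdir / "per_element.tsv",
            "dedup_report": outdir / "dedup_report.tsv",
            "clade_summary": outdir / "clade_summary.tsv",
            "age_histogram": outdir / "age_histogram.tsv",
            "manifest": outdir / "manifest.json",
        }
        self.table.to_csv(paths["per_element"], sep="\t", index=False)
        write_dedup_report(self.dedup_removed, paths["dedup_report"])
        self.summary().to_csv(paths["clade_summary"], sep="\t", index=False)
        hist = self.age_histogram(bin_width=bin_width, max_age=max_age)
        hist.to_csv(paths["age_histogram"], sep="\t", index=False)
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest(input_paths), fh, indent=2, sort_keys=True)
            fh.write("\n")
        plots = summary_mod.plot_age_landscape(hist, outdir / "age_landscape")
        for p in plots:
            paths[p.suffix.lstrip(".") + "_plot"] = p
        return paths
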