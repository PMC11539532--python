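"""Synthetic genomes with intact LTR elements of known insertion age.

The generator inverts the inference model: for each element an ancestral
LTR is drawn uniformly over ACGT, the element is laid out as
LTR-internal-LTR inside random background sequence, and the two LTR
copies evolve *independently* for ``r * t`` substitutions/site each
(rate r per site per year, true age t), so their expected pairwise
divergence is ``2 r t``.  Substitutions follow the Kimura two-parameter
process with transition/transversion rate ratio kappa, sampled from the
exact closed-form transition probabilities.  A truth table maps each
element to its true age, branch length, expected divergence and an
arbitrary clade label, so every pipeline stage can be validated against
known truth.  Optionally, near-duplicate annotation records with
jittered coordinates are injected to exercise deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    COPIA_CLADES,
    GYPSY_CLADES,
    CladeAssignment,
    GenomeSequences,
    LTRRecord,
    write_normalized_tsv,
)

_BASES = "AGCT"  # index: transition partner = index XOR 1
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}


def k2p_expected_proportions(branch_length: float, kappa: float) -> tuple[float, float]:
    """Closed-form expected (transition, transversion) difference
    proportions between sequence ends separated by ``branch_length``
    substitutions/site under K2P with ratio kappa."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta * branch_length)
    e2 = np.exp(-2.0 * (alpha + beta) * branch_length)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.5 - 0.5 * e1
    return float(p_ts), float(p_tv)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


def evolve_sequence(
    seq: str, branch_length: float, kappa: float = 2.0,
    rng: np.random.Generator | None = None, indel_rate: float = 0.0,
) -> str:
    """Evolve ``seq`` along one lineage of ``branch_length`` subs/site.

    Each site's end state is sampled independently from the exact K2P
    transition probabilities; length is preserved unless indel_rate > 0,
    in which case indel events (insertion/deletion equally likely,
    geometric lengths, mean 2) are applied after substitution.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    codes = np.array([_BASE_TO_CODE[b] for b in seq], dtype=np.int64)
    p_ts, p_tv = k2p_expected_proportions(branch_length, kappa)
    p_same = 1.0 - p_ts - p_tv
    u = rng.random(len(codes))
    out = codes.copy()
    ts_partner = codes ^ 1
    tv1 = np.where(codes < 2, 2, 0)  # first transversion target
    tv2 = tv1 + 1
    out = np.where(u < p_same, codes,
          np.where(u < p_same + p_ts, ts_partner,
          np.where(u < p_same + p_ts + p_tv / 2.0, tv1, tv2)))
    evolved = "".join(_BASES[c] for c in out)
    if indel_rate > 0:
        n_events = rng.binomial(len(evolved), indel_rate)
        for _ in range(n_events):
            pos = int(rng.integers(0, len(evolved) + 1))
            size = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                evolved = evolved[:pos] + random_sequence(size, rng) + evolved[pos:]
            else:
                evolved = evolved[:pos] + evolved[pos + size:]
        if not evolved:
            evolved = random_sequence(1, rng)
    return evolved


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    ``ages`` (MYA) are assigned to elements cyclically.  The defaults
    emulate plant intact LTR elements: kilobase-scale LTRs flanking a
    longer internal region, ages spanning recent to ancient conifer-like
    insertions, the C. japonica clock rate, kappa = 2.
    """

    n_elements: int = 20
    ltr_length: int = 1000
    internal_length: int = 3000
    ages: Sequence[float] = (1.0, 5.0, 10.0, 50.0, 100.0, 143.0)
    rate: float = 0.59e-9  # substitutions/site/year
    kappa: float = 2.0
    background_length: int = 300  # bp between/around elements
    indel_rate: float = 0.0
    duplicate_injection: int = 0
    duplicate_jitter_total: int = 20  # total coordinate jitter per injected record (bp)
    #: tie clade labels to the age cycle (one true age per clade) instead
    #: of drawing them at random; makes per-clade summary statistics
    #: directly comparable with the truth table
    clade_by_age: bool = False
    seed: int = 0
    scaffold_id: str = "scaffold_sim_1"

    def __post_init__(self):
        if min(self.ltr_length, self.internal_length, self.background_length) <= 0:
            raise ValueError("lengths must be > 0")
        if self.n_elements < 0 or any(a < 0 for a in self.ages):
            raise ValueError("n_elements and ages must be >= 0")
        if self.rate <= 0 or self.kappa <= 0:
            raise ValueError("rate and kappa must be > 0")


@dataclass
class SimulatedDataset:
    genome: GenomeSequences
    records: list[LTRRecord]  # genuine + injected near-duplicates
    clades: list[CladeAssignment]
    truth: pd.DataFrame  # element_id, true_age_mya, branch_length, expected_divergence, superfamily, clade, is_injected_duplicate
    config: SimConfig = field(repr=False, default=None)

    @property
    def genuine_ids(self) -> list[str]:
        return list(self.truth.loc[~self.truth.is_injected_duplicate, "element_id"])

    @property
    def injected_ids(self) -> list[str]:
        return list(self.truth.loc[self.truth.is_injected_duplicate, "element_id"])


def _jittered_duplicate(rec: LTRRecord, k: int, total_jitter: int,
                        rng: np.random.Generator) -> LTRRecord:
    # Shrink intervals inward by small deltas so overlap is kept and the
    # coordinate invariants survive; total symmetric difference stays
    # below the dedup threshold.
    deltas = rng.integers(0, max(2, total_jitter // 4 + 1), size=4)
    while int(deltas.sum()) >= max(total_jitter, 1):
        deltas = rng.integers(0, max(2, total_jitter // 4 + 1), size=4)
    d1, d2, d3, d4 = (int(x) for x in deltas)
    return LTRRecord(
        element_id=f"{rec.element_id}_dup{k}",
        seq_id=rec.seq_id,
        element_start=rec.element_start,
        element_end=rec.element_end,
        left_ltr_start=rec.left_ltr_start + d1,
        left_ltr_end=rec.left_ltr_end - d2,
        right_ltr_start=rec.right_ltr_start + d3,
        right_ltr_end=rec.right_ltr_end - d4,
        strand=rec.strand,
        source_superfamily=rec.source_superfamily,
    )


def simulate_genome(cfg: SimConfig) -> SimulatedDataset:
    """Generate genome, annotation records, clade labels and truth table.

    Deterministic: identical config (incl. seed) gives identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    chunks: list[str] = []
    pos = 0  # 0-based length so far
    records: list[LTRRecord] = []
    truth_rows: list[dict] = []
    clades: list[CladeAssignment] = []

    for i in range(cfg.n_elements):
        age_mya = float(cfg.ages[i % len(cfg.ages)])
        branch = cfg.rate * age_mya * 1e6  # substitutions/site per LTR copy
        element_id = f"elt{i + 1:05d}"
        if cfg.clade_by_age:
            age_idx = i % len(cfg.ages)
            superfamily = "Copia" if age_idx % 2 == 0 else "Gypsy"
            clade_pool = COPIA_CLADES if superfamily == "Copia" else GYPSY_CLADES
            clade = str(clade_pool[(age_idx // 2) % len(clade_pool)])
        else:
            superfamily = "Copia" if rng.random() < 0.5 else "Gypsy"
            clade_pool = COPIA_CLADES if superfamily == "Copia" else GYPSY_CLADES
            clade = str(clade_pool[rng.integers(0, len(clade_pool))])

        ancestral_ltr = random_sequence(cfg.ltr_length, rng)
        left = evolve_sequence(ancestral_ltr, branch, cfg.kappa, rng, cfg.indel_rate)
        right = evolve_sequence(ancestral_ltr, branch, cfg.kappa, rng, cfg.indel_rate)
        internal = random_sequence(cfg.internal_length, rng)
        background = random_sequence(cfg.background_length, rng)

        chunks.append(background)
        pos += cfg.background_length
        element_start = pos + 1
        left_start, left_end = pos + 1, pos + len(left)
        chunks.append(left)
        pos += len(left)
        chunks.append(internal)
        pos += len(internal)
        right_start, right_end = pos + 1, pos + len(right)
        chunks.append(right)
        pos += len(right)
        element_end = pos

        rec = LTRRecord(
            element_id=element_id,
            seq_id=cfg.scaffold_id,
            element_start=element_start,
            element_end=element_end,
            left_ltr_start=left_start,
            left_ltr_end=left_end,
            right_ltr_start=right_start,
            right_ltr_end=right_end,
            strand="+",
            source_superfamily=f"{superfamily}_LTR_retrotransposon",
        )
        rec.validate()
        records.append(rec)
        clades.append(CladeAssignment(element_id, superfamily, clade))
        truth_rows.append(dict(
            element_id=element_id,
            true_age_mya=age_mya,
            branch_length=branch,
            expected_divergence=2.0 * branch,
            superfamily=superfamily,
            clade=clade,
            is_injected_duplicate=False,
        ))

    chunks.append(random_sequence(cfg.background_length, rng))

    # Injected near-duplicates: annotation-level only, cycling over
    # genuine elements; ids sort after the original so dedup keeps it.
    for k in range(cfg.duplicate_injection):
        if not records[: cfg.n_elements]:
            raise ValueError("cannot inject duplicates without genuine elements")
        src = records[k % cfg.n_elements]
        dup = _jittered_duplicate(src, k + 1, cfg.duplicate_jitter_total, rng)
        dup.validate()
        records.append(dup)
        base = truth_rows[k % cfg.n_elements]
        truth_rows.append(dict(
            element_id=dup.element_id,
            true_age_mya=base["true_age_mya"],
            branch_length=base["branch_length"],
            expected_divergence=base["expected_divergence"],
            superfamily=base["superfamily"],
            clade=base["clade"],
            is_injected_duplicate=True,
        ))

    genome = GenomeSequences({cfg.scaffold_id: "".join(chunks)})
    truth = pd.DataFrame(
        truth_rows,
        columns=["element_id", "true_age_mya", "branch_length",
                 "expected_divergence", "superfamily", "clade",
                 "is_injected_duplicate"],
    )
    return SimulatedDataset(genome=genome, records=records, clades=clades,
                            truth=truth, config=cfg)


def write_simulated_dataset(sim: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write FASTA, GFF3 + normalized TSV annotation, TEsorter-dialect
    clade table and truth TSV; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "annotation_tsv": outdir / "annotation.tsv",
        "annotation_gff3": outdir / "annotation.gff3",
        "clades": outdir / "clades.cls.tsv",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for name, seq in sim.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    write_normalized_tsv(sim.records, paths["annotation_tsv"])

    with open(paths["annotation_gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sim.records:
            ptype = r.source_superfamily or "LTR_retrotransposon"
            fh.write(
                f"{r.seq_id}\tltrclock_sim\t{ptype}\t{r.element_start}\t"
                f"{r.element_end}\t.\t{r.strand}\t.\tID={r.element_id}\n"
            )
            for s, e in ((r.left_ltr_start, r.left_ltr_end),
                         (r.right_ltr_start, r.right_ltr_end)):
                fh.write(
                    f"{r.seq_id}\tltrclock_sim\tlong_terminal_repeat\t{s}\t{e}"
                    f"\t.\t{r.strand}\t.\tParent={r.element_id}\n"
                )

    with open(paths["clades"], "w") as fh:
        fh.write("#TE\tOrder\tSuperfamily\tClade\tComplete\tStrand\tDomains\n")
        for c in sim.clades:
            fh.write(f"{c.element_id}#LTR/{c.superfamily}\tLTR\t{c.superfamily}\t"
                     f"{c.clade}\tyes\t+\tnone\n")

    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def recovery_report(estimates: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per true-age accuracy of estimated ages against simulation truth.

    ``estimates`` needs columns element_id and age_mya; every estimate
    must match a truth row (unmatched ids are a hard error).  Returns
    one row per true age: n, mean/median estimate, bias, relative bias,
    RMSE.
    """
    merged = estimates.merge(
        truth[["element_id", "true_age_mya"]], on="element_id", how="left",
        validate="one_to_one",
    )
    unmatched = merged.loc[merged.true_age_mya.isna(), "element_id"].tolist()
    if unmatched:
        raise ValueError(f"estimates contain ids absent from truth: {unmatched[:5]}")
    rows = []
    for age, grp in merged.groupby("true_age_mya", sort=True):
        est = grp["age_mya"].astype(float)
        err = est - age
        rows.append(dict(
            true_age_mya=age,
            n=len(grp),
            mean_age_mya=est.mean(),
            median_age_mya=est.median(),
            bias_mya=err.mean(),
            relative_bias=err.mean() / age if age > 0 else float("nan"),
            rmse_mya=float(np.sqrt((err ** 2).mean())),
        ))
    return pd.DataFrame(rows)
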