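"""Per-clade summaries and age landscapes of dated elements.

Joins REXdb clade assignments onto the per-element table, computes
count/length/age statistics per (superfamily, clade) plus superfamily
totals, and bins non-saturated ages into half-open intervals for the
classic repeat age-landscape histogram.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CladeAssignment

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "superfamily", "clade", "count",
    "length_min", "length_max", "length_mean", "length_median",
    "age_min", "age_max", "age_mean", "age_median",
    "n_saturated",
]


def join_classification(
    dated: pd.DataFrame, clades: Sequence[CladeAssignment]
) -> pd.DataFrame:
    """Left-join clade assignments onto the per-element table.

    Elements without a classification get superfamily from the
    annotation's source feature type when it names Copia/Gypsy,
    otherwise "other/unknown"; clade falls back to "others".  Duplicate
    ids in the clade table: first occurrence wins, with a warning.
    """
    if dated["element_id"].duplicated().any():
        raise ValueError("duplicate element_id in dated table")
    seen: dict[str, CladeAssignment] = {}
    for c in clades:
        if c.element_id in seen:
            logger.warning("duplicate id %s in clade table; first occurrence wins",
                           c.element_id)
            continue
        seen[c.element_id] = c

    def fallback_superfamily(source) -> str:
        if isinstance(source, str):
            for name in ("Copia", "Gypsy"):
                if name.lower() in source.lower():
                    return name
        return "other/unknown"

    table = dated.copy()
    source = table["source_superfamily"] if "source_superfamily" in table else pd.Series(
        [None] * len(table), index=table.index)
    superfamilies, clade_labels = [], []
    n_matched = 0
    for eid, src in zip(table["element_id"], source):
        hit = seen.get(eid)
        if hit is not None:
            n_matched += 1
            superfamilies.append(hit.superfamily)
            clade_labels.append(hit.clade)
        else:
            superfamilies.append(fallback_superfamily(src))
            clade_labels.append("others")
    table["superfamily"] = superfamilies
    table["clade"] = clade_labels
    logger.info("clade join: %d matched, %d unmatched", n_matched, len(table) - n_matched)
    return table


def _stats(values: pd.Series) -> tuple[float, float, float, float]:
    v = values.astype(float)
    # median: midpoint of the two central values for even counts
    return float(v.min()), float(v.max()), float(v.mean()), float(v.median())


def summarize_by_clade(table: pd.DataFrame) -> pd.DataFrame:
    """One row per (superfamily, clade) plus a total row per superfamily.

    Ages (MYA) are computed over non-saturated elements only; lengths
    over all elements of the group.  Empty input gives an empty frame.
    """
    if table.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)

    def one_row(superfamily: str, clade: str, grp: pd.DataFrame) -> dict:
        datable = grp.loc[~grp["saturated"].astype(bool), "age_mya"].dropna()
        lmin, lmax, lmean, lmed = _stats(grp["element_length"])
        if len(datable):
            amin, amax, amean, amed = _stats(datable)
        else:
            amin = amax = amean = amed = float("nan")
        return dict(
            superfamily=superfamily, clade=clade, count=len(grp),
            length_min=lmin, length_max=lmax, length_mean=lmean, length_median=lmed,
            age_min=amin, age_max=amax, age_mean=amean, age_median=amed,
            n_saturated=int(grp["saturated"].astype(bool).sum()),
        )

    rows = []
    for (sf, clade), grp in table.groupby(["superfamily", "clade"], sort=True):
        rows.append(one_row(sf, clade, grp))
    for sf, grp in table.groupby("superfamily", sort=True):
        rows.append(one_row(sf, "ALL", grp))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def age_histogram(
    table: pd.DataFrame,
    bin_width: float = 5.0,
    max_age: float = 200.0,
    species_label: str | None = None,
) -> pd.DataFrame:
    """Bin non-saturated ages into half-open [k*w, (k+1)*w) bins.

    Returns a tidy frame (species, superfamily, bin_start, bin_end,
    count); counts sum to the number of non-saturated elements with
    age < max_age.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(np.ceil(max_age / bin_width))
    label = species_label if species_label is not None else (
        table["species"].iloc[0] if "species" in table and len(table) else "sample")
    rows = []
    for sf, grp in table.groupby("superfamily", sort=True):
        ages = grp.loc[~grp["saturated"].astype(bool), "age_mya"].dropna().astype(float)
        ages = ages[ages < max_age]
        idx = np.floor(ages.values / bin_width).astype(int)
        counts = np.bincount(idx, minlength=n_bins)[:n_bins]
        for k in range(n_bins):
            rows.append(dict(
                species=label, superfamily=sf,
                bin_start=k * bin_width, bin_end=(k + 1) * bin_width,
                count=int(counts[k]),
            ))
    return pd.DataFrame(rows, columns=["species", "superfamily", "bin_start",
                                       "bin_end", "count"])


REQUIRED_PER_ELEMENT_COLUMNS = [
    "species", "element_id", "element_length", "age_mya", "saturated",
    "superfamily", "clade",
]


def compare_runs(
    tables: Sequence[pd.DataFrame],
    bin_width: float = 5.0,
    max_age: float = 200.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-element tables from several runs (one species label
    each) into side-by-side histograms and a merged per-clade summary.

    Tables must share the per-element schema; a missing column is a
    hard error naming it.
    """
    for i, t in enumerate(tables):
        missing = [c for c in REQUIRED_PER_ELEMENT_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"table {i} missing required columns: {missing}")
    merged = pd.concat(list(tables), ignore_index=True) if tables else pd.DataFrame(
        columns=REQUIRED_PER_ELEMENT_COLUMNS)
    hists = []
    summaries = []
    for species, grp in merged.groupby("species", sort=True):
        hists.append(age_histogram(grp, bin_width=bin_width, max_age=max_age,
                                   species_label=str(species)))
        s = summarize_by_clade(grp)
        s.insert(0, "species", species)
        summaries.append(s)
    hist = pd.concat(hists, ignore_index=True) if hists else age_histogram(
        merged.assign(), bin_width=bin_width, max_age=max_age)
    summary = (pd.concat(summaries, ignore_index=True) if summaries
               else pd.DataFrame(columns=["species"] + SUMMARY_COLUMNS))
    return hist, summary


def plot_age_landscape(histograms: pd.DataFrame, path=None, title: str = "LTR insertion age landscape"):
    """One panel per superfamily, one trace per species label.

    ``histograms`` is the tidy output of :func:`age_histogram`
    (possibly concatenated across species).  Writes vector and raster
    files when ``path`` has no suffix, else the named file.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    superfamilies = sorted(histograms["superfamily"].unique())
    n = max(len(superfamilies), 1)
    fig, axes = plt.subplots(1, n, figsize=(5 * n, 4), squeeze=False)
    for ax, sf in zip(axes[0], superfamilies):
        panel = histograms[histograms["superfamily"] == sf]
        for species, grp in panel.groupby("species", sort=True):
            grp = grp.sort_values("bin_start")
            ax.bar(grp["bin_start"], grp["count"],
                   width=grp["bin_end"] - grp["bin_start"],
                   align="edge", alpha=0.5, label=str(species))
        ax.set_title(sf)
        ax.set_xlabel("insertion age (MYA)")
        ax.set_ylabel("elements")
        ax.legend(frameon=False)
    fig.suptitle(title)
    fig.tight_layout()
    written = []
    if path is not None:
        from pathlib import Path as _P
        p = _P(path)
        if p.suffix:
            fig.savefig(p)
            written.append(p)
        else:
            for ext in (".svg", ".png"):
                target = p.with_suffix(ext)
                fig.savefig(target)
                written.append(target)
        plt.close(fig)
        return written
    return fig
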