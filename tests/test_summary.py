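import numpy as np
import pandas as pd
import pytest

from ltrclock.io import CladeAssignment
from ltrclock.summary import (
    age_histogram,
    compare_runs,
    join_classification,
    summarize_by_clade,
)


def element_table(rows):
    defaults = dict(species="sample", seq_id="s1", element_length=5000,
                    saturated=False, age_mya=1.0, source_superfamily=None)
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestJoinClassification:
    def test_left_join_with_fallbacks(self):
        dated = element_table([
            dict(element_id="e1"),
            dict(element_id="e2"),
            dict(element_id="e3", source_superfamily="Gypsy_LTR_retrotransposon"),
        ])
        joined = join_classification(dated, [CladeAssignment("e1", "Copia", "SIRE")])
        by_id = joined.set_index("element_id")
        assert tuple(by_id.loc["e1", ["superfamily", "clade"]]) == ("Copia", "SIRE")
        assert tuple(by_id.loc["e2", ["superfamily", "clade"]]) == ("other/unknown", "others")
        # unmatched element falls back to the annotation's feature type
        assert tuple(by_id.loc["e3", ["superfamily", "clade"]]) == ("Gypsy", "others")

    def test_empty_clade_table(self):
        joined = join_classification(element_table([dict(element_id="e1")]), [])
        assert joined.loc[0, "superfamily"] == "other/unknown"

    def test_duplicate_clade_ids_first_wins(self):
        dated = element_table([dict(element_id="e1")])
        joined = join_classification(
            dated,
            [CladeAssignment("e1", "Copia", "Ale"), CladeAssignment("e1", "Gypsy", "Ogre")],
        )
        assert joined.loc[0, "clade"] == "Ale"

    def test_duplicate_dated_ids_rejected(self):
        dated = element_table([dict(element_id="e1"), dict(element_id="e1")])
        with pytest.raises(ValueError, match="duplicate element_id"):
            join_classification(dated, [])


class TestSummarizeByClade:
    def test_empty_table(self):
        assert summarize_by_clade(pd.DataFrame()).empty

    def test_hand_computed_median_and_mean(self):
        rows = [dict(element_id=f"e{i}", superfamily="Copia", clade="SIRE",
                     age_mya=a, element_length=1000 + i)
                for i, a in enumerate([1.0, 2.0, 3.0, 4.0, 100.0])]
        summary = summarize_by_clade(element_table(rows))
        clade_row = summary[(summary.clade == "SIRE")].iloc[0]
        assert clade_row["count"] == 5
        assert clade_row["age_median"] == 3.0
        assert clade_row["age_mean"] == 22.0

    def test_even_count_median_is_midpoint(self):
        rows = [dict(element_id=f"e{i}", superfamily="Copia", clade="Ale", age_mya=a)
                for i, a in enumerate([1.0, 3.0])]
        summary = summarize_by_clade(element_table(rows))
        assert summary[summary.clade == "Ale"].iloc[0]["age_median"] == 2.0

    def test_saturated_excluded_from_ages_but_counted(self):
        rows = [
            dict(element_id="e1", superfamily="Gypsy", clade="Ogre", age_mya=10.0),
            dict(element_id="e2", superfamily="Gypsy", clade="Ogre",
                 age_mya=np.nan, saturated=True),
        ]
        summary = summarize_by_clade(element_table(rows))
        row = summary[summary.clade == "Ogre"].iloc[0]
        assert row["count"] == 2 and row["n_saturated"] == 1
        assert row["age_median"] == 10.0

    def test_clade_counts_sum_to_superfamily_total(self):
        rng = np.random.default_rng(0)
        rows = [dict(element_id=f"e{i}",
                     superfamily=("Copia" if i % 2 else "Gypsy"),
                     clade=("SIRE", "Ale", "Ogre")[int(rng.integers(0, 3))],
                     age_mya=float(rng.uniform(0, 150)))
                for i in range(40)]
        summary = summarize_by_clade(element_table(rows))
        for sf in ("Copia", "Gypsy"):
            total = summary[(summary.superfamily == sf) & (summary.clade == "ALL")]
            parts = summary[(summary.superfamily == sf) & (summary.clade != "ALL")]
            assert parts["count"].sum() == total["count"].iloc[0]

    def test_statistics_match_independent_recomputation(self):
        rng = np.random.default_rng(8)
        rows = [dict(element_id=f"e{i}", superfamily="Copia", clade="Tork",
                     age_mya=float(rng.uniform(0, 150)),
                     element_length=int(rng.integers(1000, 25000)))
                for i in range(25)]
        table = element_table(rows)
        row = summarize_by_clade(table)
        row = row[row.clade == "Tork"].iloc[0]
        ages = np.array([r["age_mya"] for r in rows])
        lengths = np.array([r["element_length"] for r in rows])
        assert row["age_mean"] == pytest.approx(ages.mean())
        assert row["age_median"] == pytest.approx(np.median(ages))
        assert row["length_max"] == lengths.max()
        assert row["length_median"] == pytest.approx(np.median(lengths))


class TestAgeHistogram:
    def test_age_zero_lands_in_first_bin(self):
        table = element_table([dict(element_id="e1", superfamily="Copia",
                                    clade="Ale", age_mya=0.0)])
        hist = age_histogram(table, bin_width=10.0, max_age=30.0)
        assert hist.iloc[0]["count"] == 1 and hist["count"].sum() == 1

    def test_binning_arithmetic_and_half_open_edges(self):
        rows = [dict(element_id=f"e{i}", superfamily="Copia", clade="Ale", age_mya=a)
                for i, a in enumerate([5.0, 5.0, 15.0, 10.0])]
        hist = age_histogram(element_table(rows), bin_width=10.0, max_age=20.0)
        counts = dict(zip(hist.bin_start, hist["count"]))
        assert counts[0.0] == 2
        assert counts[10.0] == 2  # exact edge value 10 falls in [10, 20)

    def test_counts_sum_to_in_range_non_saturated(self):
        rows = [dict(element_id="e1", superfamily="Copia", clade="Ale", age_mya=3.0),
                dict(element_id="e2", superfamily="Copia", clade="Ale", age_mya=250.0),
                dict(element_id="e3", superfamily="Copia", clade="Ale",
                     age_mya=np.nan, saturated=True)]
        hist = age_histogram(element_table(rows), bin_width=10.0, max_age=200.0)
        assert hist["count"].sum() == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        rows = [dict(element_id=f"e{i}", superfamily="Gypsy", clade="Ogre",
                     age_mya=float(rng.uniform(0, 100))) for i in range(30)]
        t = element_table(rows)
        h1 = age_histogram(t, 5.0, 100.0)
        h2 = age_histogram(t.sample(frac=1, random_state=1), 5.0, 100.0)
        pd.testing.assert_frame_equal(h1.reset_index(drop=True), h2.reset_index(drop=True))

    def test_bin_width_validated(self):
        with pytest.raises(ValueError):
            age_histogram(element_table([]), bin_width=0.0)


class TestCompareRuns:
    def base_table(self, species, ages):
        return element_table([
            dict(element_id=f"{species}_{i}", species=species, superfamily="Copia",
                 clade="SIRE", age_mya=a)
            for i, a in enumerate(ages)
        ])

    def test_same_table_under_two_labels_gives_identical_histograms(self):
        a = self.base_table("A", [1.0, 12.0, 33.0])
        b = self.base_table("B", [1.0, 12.0, 33.0])
        hist, summary = compare_runs([a, b], bin_width=10.0, max_age=50.0)
        ha = hist[hist.species == "A"].drop(columns="species").reset_index(drop=True)
        hb = hist[hist.species == "B"].drop(columns="species").reset_index(drop=True)
        pd.testing.assert_frame_equal(ha, hb)
        assert set(summary.species) == {"A", "B"}

    def test_empty_plus_populated_does_not_crash(self):
        a = self.base_table("A", [])
        b = self.base_table("B", [5.0])
        a = a.reindex(columns=b.columns)
        hist, summary = compare_runs([a, b])
        assert hist[hist.species == "B"]["count"].sum() == 1

    def test_missing_column_is_hard_error_naming_it(self):
        bad = self.base_table("A", [1.0]).drop(columns=["age_mya"])
        with pytest.raises(ValueError, match="age_mya"):
            compare_runs([bad])
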