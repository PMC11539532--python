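import numpy as np
import pandas as pd
import pytest

from ltrclock.dedup import deduplicate
from ltrclock.simulate import (
    SimConfig,
    evolve_sequence,
    k2p_expected_proportions,
    random_sequence,
    recovery_report,
    simulate_genome,
    write_simulated_dataset,
)


class TestEvolveSequence:
    def test_zero_branch_is_identity(self):
        rng = np.random.default_rng(0)
        seq = random_sequence(500, rng)
        assert evolve_sequence(seq, 0.0, 2.0, rng) == seq

    def test_long_branch_approaches_stationary_mismatch(self):
        # at saturation 3/4 of sites differ; binomial 3 SE at L = 1e4
        rng = np.random.default_rng(1)
        L = 10_000
        seq = random_sequence(L, rng)
        out = evolve_sequence(seq, 10.0, 2.0, rng)
        mismatch = sum(a != b for a, b in zip(seq, out)) / L
        se = np.sqrt(0.75 * 0.25 / L)
        assert abs(mismatch - 0.75) <= 3 * se

    @pytest.mark.parametrize("branch", [0.01, 0.05, 0.2])
    def test_transition_transversion_fractions_match_closed_form(self, branch):
        rng = np.random.default_rng(42)
        L = 100_000
        seq = random_sequence(L, rng)
        out = evolve_sequence(seq, branch, 2.0, rng)
        ts = tv = 0
        for a, b in zip(seq, out):
            if a == b:
                continue
            if {a, b} in ({"A", "G"}, {"C", "T"}):
                ts += 1
            else:
                tv += 1
        p_ts, p_tv = k2p_expected_proportions(branch, 2.0)
        for observed, expected in ((ts / L, p_ts), (tv / L, p_tv)):
            se = np.sqrt(expected * (1 - expected) / L)
            assert abs(observed - expected) <= 3 * se

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence("ACGT", -0.1)

    def test_indels_change_length_but_keep_content_nucleotide(self):
        rng = np.random.default_rng(2)
        seq = random_sequence(2000, rng)
        out = evolve_sequence(seq, 0.02, 2.0, rng, indel_rate=0.005)
        assert set(out) <= set("ACGT")
        assert out != seq


class TestSimulateGenome:
    def test_age_zero_element_has_identical_ltrs(self):
        cfg = SimConfig(n_elements=1, ltr_length=200, internal_length=300,
                        ages=(0.0,), seed=3)
        sim = simulate_genome(cfg)
        from ltrclock.io import extract_ltr_pair

        left, right = extract_ltr_pair(sim.genome, sim.records[0])
        assert left == right

    def test_coordinates_recover_evolved_copies(self, small_sim):
        from ltrclock.io import extract_ltr_pair

        for rec in small_sim.records:
            left, right = extract_ltr_pair(small_sim.genome, rec)
            assert len(left) == rec.left_ltr_length
            assert len(right) == rec.right_ltr_length

    def test_injected_duplicates_removed_exactly(self, small_sim):
        kept, removed = deduplicate(small_sim.records)
        assert sorted(r for r, _, _ in removed) == sorted(small_sim.injected_ids)
        assert {r.element_id for r in kept} == set(small_sim.genuine_ids)

    def test_fixed_seed_runs_are_byte_identical(self, tmp_path):
        cfg = SimConfig(n_elements=4, ltr_length=150, internal_length=200,
                        duplicate_injection=1, seed=99)
        p1 = write_simulated_dataset(simulate_genome(cfg), tmp_path / "a")
        p2 = write_simulated_dataset(simulate_genome(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_truth_table_complete_and_clades_consistent(self, small_sim):
        assert len(small_sim.truth) == len(small_sim.records)
        assert set(small_sim.truth.element_id) == {r.element_id for r in small_sim.records}
        for c in small_sim.clades:
            assert c.superfamily in {"Copia", "Gypsy"}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(ltr_length=0)
        with pytest.raises(ValueError):
            SimConfig(ages=(-1.0,))


class TestRecoveryReport:
    def test_perfect_estimates_have_zero_bias_and_rmse(self):
        truth = pd.DataFrame(dict(element_id=["a", "b"], true_age_mya=[10.0, 10.0]))
        est = pd.DataFrame(dict(element_id=["a", "b"], age_mya=[10.0, 10.0]))
        rep = recovery_report(est, truth)
        assert rep.loc[0, "bias_mya"] == 0.0 and rep.loc[0, "rmse_mya"] == 0.0
        assert rep.loc[0, "n"] == 2

    def test_single_element_degenerates_to_its_error(self):
        truth = pd.DataFrame(dict(element_id=["a"], true_age_mya=[10.0]))
        est = pd.DataFrame(dict(element_id=["a"], age_mya=[12.0]))
        rep = recovery_report(est, truth)
        assert rep.loc[0, "bias_mya"] == pytest.approx(2.0)
        assert rep.loc[0, "rmse_mya"] == pytest.approx(2.0)
        assert rep.loc[0, "relative_bias"] == pytest.approx(0.2)

    def test_unmatched_ids_are_hard_error(self):
        truth = pd.DataFrame(dict(element_id=["a"], true_age_mya=[10.0]))
        est = pd.DataFrame(dict(element_id=["zzz"], age_mya=[12.0]))
        with pytest.raises(ValueError, match="absent from truth"):
            recovery_report(est, truth)
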