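import numpy as np
import pytest

import branchselex as bx
from branchselex.cluster import pairwise_identity
from branchselex.design import ConfigurationError
from branchselex.simulate import (
    AffinityModel,
    SimConfig,
    analytic_expected_ef,
    emit_pairs,
    make_affinity_model,
    make_truth_pool,
    sample_counts,
    select_round,
    simulate_run,
)

import pandas as pd


def neutral_model(pool):
    a = pd.DataFrame(1.0, index=range(len(pool.members)), columns=["wt"])
    return AffinityModel(a, background=0.0)


class TestTruthPool:
    def test_member_count_and_frequency_conservation(self):
        pool = make_truth_pool(n_families=5, family_size=20, n_background=1000, seed=4)
        assert len(pool.members) == 5 * 20 + 1000
        assert pool.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_under_seed(self):
        a = make_truth_pool(n_background=200, seed=9)
        b = make_truth_pool(n_background=200, seed=9)
        assert a.sequences == b.sequences
        assert np.array_equal(a.frequencies, b.frequencies)
        assert a.families.keys() == b.families.keys()

    def test_members_within_identity_threshold_of_master(self):
        pool = make_truth_pool(n_families=3, family_size=15, n_background=50, seed=11)
        for fid, fam in pool.families.items():
            for i in pool.family_members(fid):
                ident = pairwise_identity(pool.members[i].sequence, fam.master)
                assert ident >= 0.9

    def test_planted_motifs_present_in_all_members(self):
        pool = make_truth_pool(n_families=3, family_size=15, n_background=50, seed=11)
        for fid, fam in pool.families.items():
            for i in pool.family_members(fid):
                seq = pool.members[i].sequence
                for motif in fam.motifs:
                    assert motif in seq

    def test_lengths_within_library_bounds(self):
        pool = make_truth_pool(n_background=300, seed=2)
        assert all(25 <= len(m.sequence) <= 45 for m in pool.members)


class TestSelection:
    def test_total_capture_of_one_member(self):
        pool = make_truth_pool(n_families=1, family_size=1, n_background=1, seed=0,
                               master_weights=[0.5])
        a = pd.DataFrame({"wt": [1.0, 0.0]})
        out = select_round(pool, AffinityModel(a, background=0.0), "wt")
        assert np.allclose(out, [1.0, 0.0])

    def test_uniform_affinity_is_selection_neutral(self):
        pool = make_truth_pool(n_background=100, seed=5)
        out = select_round(pool, neutral_model(pool), "wt")
        assert np.allclose(out, pool.frequencies, rtol=1e-12)
        ef = analytic_expected_ef(pool, neutral_model(pool), "wt")
        assert np.allclose(ef, 1.0, rtol=1e-12)

    def test_matches_hand_normalisation(self, rng):
        pool = make_truth_pool(n_families=1, family_size=5, n_background=5, seed=6,
                               master_weights=[0.05])
        f = pool.frequencies
        a_col = rng.uniform(0, 2, size=len(f))
        model = AffinityModel(pd.DataFrame({"wt": a_col}), background=0.01)
        out = select_round(pool, model, "wt")
        hand = f * (a_col + 0.01)
        hand = hand / hand.sum()
        assert np.allclose(out, hand, atol=1e-15)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_affinity_is_error(self):
        pool = make_truth_pool(n_background=10, seed=1, n_families=1, family_size=2)
        a = pd.DataFrame({"wt": np.zeros(len(pool.members))})
        with pytest.raises(ConfigurationError):
            select_round(pool, AffinityModel(a, background=0.0), "wt")

    def test_analytic_ef_direct_substitution(self):
        # two members, f=(0.5,0.5), a=(1,0), b=0: sum f_j a_j = 0.5 -> EF = 2
        pool = make_truth_pool(n_families=1, family_size=1, n_background=1, seed=0,
                               master_weights=[0.5])
        model = AffinityModel(pd.DataFrame({"wt": [1.0, 0.0]}), background=0.0)
        assert analytic_expected_ef(pool, model, "wt", member=0) == pytest.approx(2.0)

    def test_affinity_model_fold_structure(self):
        pool = make_truth_pool(n_families=4, family_size=5, n_background=100, seed=7)
        model = make_affinity_model(pool, seed=7, fold_range=(4.0, 10.0))
        for fid, fam in pool.families.items():
            idx = pool.family_members(fid)
            for m in ("K71A", "R78A", "F116A"):
                vals = model.affinity.loc[idx, m]
                if m in fam.profile:
                    assert (vals <= 0.25).all()  # fold >= 4
                else:
                    assert (vals == 1.0).all()


class TestReadEmission:
    def test_multinomial_counts_track_frequencies(self, rng):
        freqs = np.array([0.5, 0.3, 0.15, 0.05])
        n = 100_000
        counts = sample_counts(freqs, n, rng)
        assert counts.sum() == n
        se = np.sqrt(n * freqs * (1 - freqs))
        assert np.all(np.abs(counts - n * freqs) <= 3 * se)

    def test_error_free_round_trip_through_readprep(self, design, sheet):
        config = SimConfig(design=design, sheet=sheet, n_reads=500,
                           error_rate=0.0, seed=13)
        entry = sheet.entries[1]
        seqs = ["ACGTTGCATGCA" * 3, "TTGACCGGTTAACCGGTTAACCGGTAG"]
        counts = np.array([300, 200])
        pairs = emit_pairs(seqs, counts, entry, config)
        assert len(pairs) == 500
        recovered = []
        for p in pairs:
            stripped = bx.ReadPair(
                p.read_id,
                p.fwd_seq[len(entry.barcode_fwd):], p.fwd_qual[len(entry.barcode_fwd):],
                p.rev_seq[len(entry.barcode_rev):], p.rev_qual[len(entry.barcode_rev):],
            )
            seq, reason = bx.pair_to_variable(stripped, design)
            assert reason is None
            recovered.append(seq)
        assert recovered.count(seqs[0]) == 300
        assert recovered.count(seqs[1]) == 200

    def test_two_samples_demultiplex_perfectly_without_errors(self, design, sheet):
        config = SimConfig(design=design, sheet=sheet, n_reads=1000,
                           error_rate=0.0, seed=21)
        pairs = []
        for entry in sheet.entries[:2]:
            pairs += emit_pairs(["ACGT" * 8], np.array([1000]), entry, config)
        assigned, report = bx.demultiplex(pairs, sheet)
        assert report.n_rejected == 0
        assert len(assigned[sheet.entries[0].sample_id]) == 1000
        assert len(assigned[sheet.entries[1].sample_id]) == 1000

    def test_emission_deterministic_under_seed(self, design, sheet):
        config = SimConfig(design=design, sheet=sheet, n_reads=200,
                           error_rate=0.01, seed=3)
        entry = sheet.entries[0]
        a = emit_pairs(["ACGT" * 8], np.array([200]), entry, config)
        b = emit_pairs(["ACGT" * 8], np.array([200]), entry, config)
        assert a == b

    def test_simulated_run_counts_shape(self, design, sheet):
        pool = make_truth_pool(n_background=100, seed=2)
        model = make_affinity_model(pool, seed=2)
        config = SimConfig(design=design, sheet=sheet, n_reads=2000,
                           error_rate=0.0, seed=2)
        run = simulate_run(pool, model, config, emit_reads=False)
        assert run.counts.shape == (len(pool.members), len(sheet))
        assert (run.counts.sum(axis=0) == 2000).all()
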