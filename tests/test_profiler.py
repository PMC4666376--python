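import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from branchselex.cluster import cluster_table_from_counts
from branchselex.design import BranchDescriptor, ConfigurationError
from branchselex.profiler import (
    BindingProfile,
    ProfilerParams,
    competition_call,
    conformation_call,
    hotspot_summary,
    infer_binding_profile,
    rank_by_ef,
    scan_profile_matches,
)
from branchselex.quantify import enrichment_from_clusters

PARAMS = ProfilerParams()


class TestInferBindingProfile:
    def test_alanine_scan_pattern(self):
        rel = {"K71A": 1.0, "R78A": 0.18, "Y81A": 0.9, "K82A": 0.19,
               "F116A": 0.17, "R120A": 0.20, "K124A": 0.7}
        profile = infer_binding_profile(rel, PARAMS)
        assert profile.residues == {"R78A", "K82A", "F116A", "R120A"}
        assert not profile.indeterminate

    def test_no_reduction_gives_empty_profile(self):
        rel = {m: 1.0 for m in ("R78A", "K82A")}
        assert infer_binding_profile(rel, PARAMS).residues == frozenset()

    def test_exact_twofold_reduction_excluded(self):
        # "more than two-fold" is strict: exactly 0.5 is not a call
        rel = {"R78A": 0.5, "K82A": 0.499}
        assert infer_binding_profile(rel, PARAMS).residues == {"K82A"}

    def test_undefined_value_makes_profile_indeterminate(self):
        for bad in (None, float("nan")):
            profile = infer_binding_profile({"R78A": 0.1, "K82A": bad}, PARAMS)
            assert profile.indeterminate
            assert profile.residues == frozenset()

    @given(
        st.dictionaries(
            st.sampled_from(["R78A", "K82A", "F116A"]),
            st.floats(0, 2, allow_nan=False),
            min_size=1,
        ),
        st.sampled_from(["R78A", "K82A", "F116A"]),
    )
    def test_monotone_in_rel_ef(self, rel, target):
        """Lowering any relative EF never removes a residue from the profile."""
        if target not in rel:
            return
        before = infer_binding_profile(rel, PARAMS).residues
        lowered = dict(rel)
        lowered[target] = rel[target] / 2
        after = infer_binding_profile(lowered, PARAMS).residues
        assert before <= after


class TestConformationAndCompetition:
    @pytest.mark.parametrize(
        "ef_active,ef_latent,label",
        [
            (1.5, 1.4, "binds_both"),
            (1.5, 0.1, "active_preferring"),
            (0.0, 0.0, "indeterminate"),
            (1.0, 3.0, "binds_both"),  # latent bound at least as well
        ],
    )
    def test_conformation_labels(self, ef_active, ef_latent, label):
        assert conformation_call(ef_active, ef_latent, PARAMS).label == label

    @pytest.mark.parametrize(
        "ef_ab,ef_cx,label",
        [
            (2.0, 0.2, "ligand_competed"),
            (2.0, 2.0, "complex_compatible"),
            (0.0, 5.0, "indeterminate"),
        ],
    )
    def test_competition_labels(self, ef_ab, ef_cx, label):
        assert competition_call(ef_ab, ef_cx, PARAMS).label == label

    @given(st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.1, 100))
    def test_calls_invariant_under_common_scaling(self, a, b, k):
        assert (
            conformation_call(a, b, PARAMS).label
            == conformation_call(k * a, k * b, PARAMS).label
        )
        assert (
            competition_call(a, b, PARAMS).label
            == competition_call(k * a, k * b, PARAMS).label
        )


def toy_enrichment(rng, n=8, seed_counts=None):
    """Small two-mode panel table with hand-set counts."""
    mutants = ("R78A", "K82A")
    samples = ["input"]
    metadata = {}
    for mode in ("poly_ab", "mono_ab"):
        metadata[f"wt_{mode}"] = BranchDescriptor("wt", mode)
        samples.append(f"wt_{mode}")
        for m in mutants:
            metadata[f"{m}_{mode}"] = BranchDescriptor(m, mode)
            samples.append(f"{m}_{mode}")
    seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 30)) for _ in range(n)]
    counts = seed_counts or {
        s: rng.integers(1, 1000, size=n) for s in samples
    }
    table = cluster_table_from_counts(seqs, counts)
    _fr, enr = enrichment_from_clusters(
        table, "input", {"poly_ab": "wt_poly_ab", "mono_ab": "wt_mono_ab"},
        {**metadata, "input": BranchDescriptor("input", "none")},
    )
    return table, enr


class TestScanAndRank:
    def test_scan_empty_reference_returns_unaffected_clusters(self, rng):
        n = 6
        base = rng.integers(100, 1000, size=n)
        counts = {"input": base}
        for mode in ("poly_ab", "mono_ab"):
            counts[f"wt_{mode}"] = base
            counts[f"R78A_{mode}"] = base
            counts[f"K82A_{mode}"] = base
        _table, enr = toy_enrichment(rng, n=n, seed_counts=counts)
        hits = scan_profile_matches(
            enr, frozenset(), ProfilerParams(min_copies=1),
            modes=("poly_ab", "mono_ab"), panel=("R78A", "K82A"),
        )
        assert len(hits) == n  # every cluster is unaffected by every mutant

    def test_scan_min_copies_filters_everything(self, rng):
        _table, enr = toy_enrichment(rng)
        hits = scan_profile_matches(
            enr, frozenset(), ProfilerParams(min_copies=10**9),
            modes=("poly_ab",), panel=("R78A", "K82A"),
        )
        assert hits == []

    def test_scan_missing_mode_is_configuration_error(self, rng):
        _table, enr = toy_enrichment(rng)
        with pytest.raises(ConfigurationError):
            scan_profile_matches(
                enr, frozenset(), PARAMS, modes=("vitronectin",),
                panel=("R78A", "K82A"),
            )

    def test_rank_by_ef_orders_descending_undefined_last(self, rng):
        counts = {
            "input": [10, 10, 10, 0],
            "wt_poly_ab": [6750, 4700, 10, 5],
            "R78A_poly_ab": [1, 1, 1, 1],
            "K82A_poly_ab": [1, 1, 1, 1],
            "wt_mono_ab": [1, 1, 1, 1],
            "R78A_mono_ab": [1, 1, 1, 1],
            "K82A_mono_ab": [1, 1, 1, 1],
        }
        table, enr = toy_enrichment(rng, n=4, seed_counts=counts)
        ranking = rank_by_ef(enr, "wt_poly_ab")
        efs = [enr.ef_series("wt_poly_ab")[c] for c in ranking]
        assert np.isnan(efs[-1])  # undefined input fraction sorts last
        assert efs[0] > efs[1] > efs[2]

    def test_rank_ties_broken_by_input_abundance(self, rng):
        counts = {
            "input": [100, 900, 500],
            "wt_poly_ab": [100, 900, 500],   # all EF = 1
            "R78A_poly_ab": [1, 1, 1],
            "K82A_poly_ab": [1, 1, 1],
            "wt_mono_ab": [1, 1, 1],
            "R78A_mono_ab": [1, 1, 1],
            "K82A_mono_ab": [1, 1, 1],
        }
        table, enr = toy_enrichment(rng, n=3, seed_counts=counts)
        ranking = rank_by_ef(enr, "wt_poly_ab")
        assert [int(table.to_frame().loc[c, "input"]) for c in ranking] == [900, 500, 100]


class TestHotspot:
    def test_top_n_one_gives_binary_fractions(self, rng):
        # the abundant binder is enriched on wt, collapses 10-fold on R78A
        counts = {
            "input": [900, 100],
            "wt_poly_ab": [950, 50],
            "R78A_poly_ab": [10, 100],
            "K82A_poly_ab": [900, 100],
            "wt_mono_ab": [950, 50],
            "R78A_mono_ab": [10, 100],
            "K82A_mono_ab": [900, 100],
        }
        _t, enr = toy_enrichment(rng, n=2, seed_counts=counts)
        hs = hotspot_summary(
            enr, "poly_ab", panel=("R78A", "K82A"),
            params=ProfilerParams(top_n=1),
        )
        assert set(hs.fraction_reduced.index) == {"R78A", "K82A"}
        assert set(hs.fraction_reduced.unique()) <= {0.0, 1.0}
        assert hs.fraction_reduced["R78A"] == 1.0
        assert hs.fraction_reduced["K82A"] == 0.0
        assert hs.fraction_unaffected == 0.0
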