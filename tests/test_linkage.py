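"""Consensus/recoding/QC, pairwise linkage statistics, LOD grouping and the
ordering heuristic, validated by simulation recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from lenspipe import linkage as lk
from lenspipe import simdata as sd


class TestKosambi:
    def test_zero_and_monotone(self):
        assert lk.kosambi(0.0) == 0.0
        r = np.linspace(0, 0.49, 50)
        d = lk.kosambi(r)
        assert (np.diff(d) > 0).all()

    def test_spot_value(self):
        assert float(lk.kosambi(0.2)) == pytest.approx(25 * np.log(1.4 / 0.6))
        assert float(lk.kosambi(0.2)) == pytest.approx(21.18, abs=0.005)

    @given(st.floats(0.0, 0.499))
    @settings(max_examples=200, deadline=None)
    def test_inverse_round_trips(self, r):
        assert float(lk.kosambi_inverse(lk.kosambi(r))) == pytest.approx(
            r, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            lk.kosambi(0.5)
        with pytest.raises(ValueError):
            lk.kosambi_inverse(-1.0)


class TestConsensus:
    def test_missing_filled_conflicts_masked(self):
        m = pd.DataFrame(
            {"P1": list("AAA"), "P2": list("BBB"), "r1": list("AUA"),
             "r2": list("ABU"), "r3": list("UUU")},
            index=["m1", "m2", "m3"])
        out = lk.consensus_haplotype(m, {"m1": "c", "m2": "c", "m3": "c"})
        assert out.loc["c"].to_dict() == {
            "P1": "A", "P2": "B", "r1": "A", "r2": "U", "r3": "U"}

    def test_single_marker_contig_unchanged(self):
        m = pd.DataFrame({"P1": ["A"], "P2": ["B"], "r1": ["H"]}, index=["m1"])
        out = lk.consensus_haplotype(m, {"m1": "c"})
        assert out.loc["c"].to_dict() == {"P1": "A", "P2": "B", "r1": "H"}


class TestDominantRecoding:
    def test_null_follows_null_parent(self):
        m = pd.DataFrame({"P1": ["NULL"], "P2": ["PRESENT"],
                          "r1": ["NULL"], "r2": ["PRESENT"]}, index=["m1"])
        out = lk.recode_dominant(m)
        assert out.loc["m1", "r1"] == "A"
        assert out.loc["m1", "r2"] == "B"

    def test_indistinguishable_parents_dropped(self):
        m = pd.DataFrame({"P1": ["PRESENT"], "P2": ["PRESENT"],
                          "r1": ["NULL"]}, index=["m1"])
        assert len(lk.recode_dominant(m)) == 0

    def test_recoded_matrix_matches_truth_at_zero_error(self):
        spec = sd.RILSpec(n_lg=1, markers_per_lg=10, lg_length_cM=50,
                          n_ril=200, missing_rate=0.0, seed=13)
        res = sd.simulate_ril_population(sd.make_marker_map(spec), spec)
        truth = res.truth_calls
        # B allele fails to amplify: B -> NULL, A -> PRESENT, H amplifies
        dom = truth.replace({"B": "NULL", "A": "PRESENT", "H": "PRESENT"})
        out = lk.recode_dominant(dom)
        hom = truth.isin(["A", "B"])
        agree = (out[hom] == truth[hom]).to_numpy()
        assert np.nanmean(agree.astype(float)) >= 0.99


class TestQC:
    def test_counts_match_recount(self):
        rng = np.random.default_rng(2)
        calls = rng.choice(list("ABU"), p=[0.45, 0.45, 0.1], size=(50, 144))
        calls[:, :5] = "U"      # five individuals with (almost) no data
        m = pd.DataFrame(calls, columns=[f"R{i}" for i in range(144)])
        m.insert(0, "P1", "A")
        m.insert(1, "P2", "B")
        kept, report = lk.qc_individuals(m, 0.5)
        assert report.removed.sum() == 5
        assert kept.shape[1] == 2 + 139

    def test_threshold_one_removes_nobody(self):
        m = pd.DataFrame({"P1": ["A"], "P2": ["B"], "r1": ["U"]})
        kept, _ = lk.qc_individuals(m, 1.0)
        assert kept.shape[1] == 3

    def test_all_removed_is_an_error(self):
        m = pd.DataFrame({"P1": ["A"], "P2": ["B"], "r1": ["U"], "r2": ["U"]})
        with pytest.raises(ValueError):
            lk.qc_individuals(m, 0.5)


class TestPairwise:
    def _pair_matrix(self, row1, row2):
        cols = {f"r{i}": [a, b] for i, (a, b) in enumerate(zip(row1, row2))}
        m = pd.DataFrame(cols, index=["m1", "m2"])
        m.insert(0, "P1", "A")
        m.insert(1, "P2", "B")
        return m

    def test_identical_rows_lod(self):
        m = self._pair_matrix("AB" * 10, "AB" * 10)
        p = lk.pairwise_linkage(m)
        assert p.k[0, 1] == 0
        assert p.lod[0, 1] == pytest.approx(20 * np.log10(2))  # ~6.02

    def test_ril_correction_closed_form(self):
        # R_hat = 0.4 -> r_hat = 0.4 / (2 * 0.6) = 1/3
        row1 = "A" * 10
        row2 = "B" * 4 + "A" * 6
        p = lk.pairwise_linkage(self._pair_matrix(row1, row2))
        assert p.R[0, 1] == pytest.approx(0.4)
        assert p.r[0, 1] == pytest.approx(1 / 3)

    def test_independent_rows_zero_lod(self):
        row1 = "A" * 5 + "B" * 5
        row2 = "B" * 10    # mismatch at half the individuals: R_hat = 0.5
        p = lk.pairwise_linkage(self._pair_matrix(row1, row2))
        assert p.R[0, 1] == pytest.approx(0.5)
        assert p.lod[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_h_and_u_calls_are_uninformative(self):
        m = self._pair_matrix("ABHU", "ABAB")
        p = lk.pairwise_linkage(m)
        assert p.n[0, 1] == 2


class TestGrouping:
    def test_infinite_threshold_isolates_markers(self):
        spec = sd.RILSpec(n_lg=2, markers_per_lg=5, lg_length_cM=40,
                          n_ril=50, seed=3)
        res = sd.simulate_ril_population(sd.make_marker_map(spec), spec)
        pairs = lk.pairwise_linkage(res.matrix)
        groups = lk.group_markers(pairs, lod_threshold=np.inf)
        assert all(len(g) == 1 for g in groups)

    def test_raising_threshold_refines_partition(self):
        spec = sd.RILSpec(n_lg=3, markers_per_lg=8, lg_length_cM=60,
                          n_ril=80, seed=4)
        res = sd.simulate_ril_population(sd.make_marker_map(spec), spec)
        pairs = lk.pairwise_linkage(res.matrix)
        for lo, hi in [(3, 6), (6, 10)]:
            coarse = {frozenset(g) for g in lk.group_markers(pairs, lo)}
            fine = lk.group_markers(pairs, hi)
            for g in fine:
                assert any(set(g) <= c for c in coarse)

    def test_recovers_true_linkage_groups(self):
        spec = sd.RILSpec(n_lg=4, markers_per_lg=15, lg_length_cM=80,
                          n_ril=139, missing_rate=0.02, seed=5)
        mm = sd.make_marker_map(spec)
        res = sd.simulate_ril_population(mm, spec)
        pairs = lk.pairwise_linkage(res.matrix)
        groups = lk.group_markers(pairs, 6.0)
        groups = [g for g in groups if len(g) > 1]
        truth = {frozenset(grp.marker) for _, grp in mm.groupby("lg")}
        assert {frozenset(g) for g in groups} == truth


class TestOrdering:
    def test_zero_r_pair_is_zero_cm_apart(self):
        m = pd.DataFrame({"P1": ["A", "A"], "P2": ["B", "B"],
                          **{f"r{i}": ["A", "A"] if i < 10 else ["B", "B"]
                             for i in range(20)}}, index=["m1", "m2"])
        pairs = lk.pairwise_linkage(m)
        lg = lk.order_and_space(["m1", "m2"], pairs)
        assert lg.positions[-1] == pytest.approx(0.0)

    def test_map_length_invariant_under_reversal(self):
        spec = sd.RILSpec(n_lg=1, markers_per_lg=12, lg_length_cM=60,
                          n_ril=139, seed=6)
        res = sd.simulate_ril_population(sd.make_marker_map(spec), spec)
        pairs = lk.pairwise_linkage(res.matrix)
        markers = list(res.matrix.index)
        a = lk.order_and_space(markers, pairs)
        b = lk.order_and_space(markers[::-1], pairs)
        assert a.length_cM == pytest.approx(b.length_cM, rel=1e-9)

    def test_simulated_group_order_recovered(self):
        spec = sd.RILSpec(n_lg=2, markers_per_lg=25, lg_length_cM=100,
                          n_ril=139, missing_rate=0.02, seed=7)
        mm = sd.make_marker_map(spec)
        res = sd.simulate_ril_population(mm, spec)
        groups = lk.build_map(res.matrix, lod_threshold=6.0)
        assert len(groups) == 2
        truth = mm.set_index("marker")
        for g in groups:
            cms = truth.loc[g.markers, "cm"].to_numpy()
            rho = spearmanr(cms, np.arange(len(cms))).statistic
            assert abs(rho) >= 0.95
            assert (np.diff(g.positions) >= 0).all()
            assert g.positions[0] == 0.0
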