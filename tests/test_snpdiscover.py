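"""SNP calling, merging, summaries and SSR detection against oracles and
planted truth."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lenspipe import simdata as sd
from lenspipe import snpdiscover as snp


def _site(contig, pos, ref_counts, seq="A" * 100, **alt_counts):
    counts = {b: 0 for b in "ACGT"}
    counts.update(alt_counts)
    counts[seq[pos - 1]] = ref_counts
    depth = sum(counts.values())
    return pd.DataFrame([{"contig": contig, "pos": pos, "depth": depth, **counts}])


@pytest.fixture
def one_contig():
    return {"c1": snp.ReferenceContig("c1", "A" * 100)}


class TestFilterReference:
    def test_length_boundary_and_repeat_flags(self):
        contigs = {
            "short": snp.ReferenceContig("short", "A" * 199),
            "edge": snp.ReferenceContig("edge", "A" * 200),
            "rep": snp.ReferenceContig("rep", "A" * 500, repeat_class=True),
        }
        kept, log = snp.filter_reference(contigs)
        assert set(kept) == {"edge"}
        assert set(log.reason) == {"length<200", "repeat_class"}

    def test_removal_count(self):
        contigs = {f"c{i}": snp.ReferenceContig(f"c{i}", "A" * 300,
                                                repeat_class=i < 3)
                   for i in range(10)}
        kept, _ = snp.filter_reference(contigs)
        assert len(kept) == 7


class TestCallThresholds:
    @pytest.mark.parametrize("ref_n,alt_n,expected", [
        (0, 2, "BELOW_THRESHOLD"),   # 100% alt but <3 reads
        (10, 0, None),               # pure reference: no record
        (1, 9, "ALT"),               # 90%, >=3 reads
        (3, 7, "BELOW_THRESHOLD"),   # 70% < 80%
        (2, 8, "ALT"),               # exactly 80% passes
    ])
    def test_confidence_rule(self, one_contig, ref_n, alt_n, expected):
        pile = _site("c1", 10, ref_n, G=alt_n)
        out = snp.call_snps_per_genotype(pile, one_contig)
        if expected is None:
            assert len(out) == 0
        else:
            assert list(out.status) == [expected]
            assert list(out.alt) == ["G"]

    def test_row_order_invariance(self, clean_pileups, ref_contigs):
        pile = clean_pileups["wild01"]
        shuffled = pile.sample(frac=1.0, random_state=0)
        a = snp.call_snps_per_genotype(pile, ref_contigs)
        b = snp.call_snps_per_genotype(shuffled, ref_contigs)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_contig_is_an_error(self, one_contig):
        pile = _site("cX", 5, 0, T=5)
        with pytest.raises(ValueError, match="cX"):
            snp.call_snps_per_genotype(pile, one_contig)

    @given(st.integers(1, 6), st.floats(0.5, 0.95))
    @settings(max_examples=25, deadline=None)
    def test_relaxing_thresholds_never_shrinks_call_set(
            self, min_reads, min_fraction):
        rng = np.random.default_rng(42)
        contig = {"c1": snp.ReferenceContig("c1", "A" * 200)}
        counts = rng.integers(0, 6, size=(200, 4))
        pile = pd.DataFrame({"contig": "c1", "pos": np.arange(1, 201),
                             "depth": counts.sum(axis=1),
                             **{b: counts[:, i] for i, b in enumerate("ACGT")}})
        pile = pile[pile.depth > 0]
        strict = snp.call_snps_per_genotype(pile, contig, min_reads, min_fraction)
        loose = snp.call_snps_per_genotype(pile, contig,
                                           max(min_reads - 1, 1),
                                           min_fraction - 0.1)
        strict_alt = set(map(tuple, strict[strict.status == "ALT"]
                             [["contig", "pos"]].itertuples(index=False)))
        loose_alt = set(map(tuple, loose[loose.status == "ALT"]
                            [["contig", "pos"]].itertuples(index=False)))
        assert strict_alt <= loose_alt


class TestMerge:
    def test_shared_snp_collapses_to_one_record(self, one_contig):
        pile = _site("c1", 10, 1, G=9)
        empty = pile.iloc[:0]
        calls = {g: snp.call_snps_per_genotype(pile, one_contig)
                 for g in ["g1", "g2", "g3"]}
        table = snp.merge_nonredundant(calls, {g: pile for g in calls}, one_contig)
        assert len(table) == 1
        assert all(table.frame.iloc[0][g] == "ALT" for g in calls)

    def test_below_threshold_only_sites_are_absent(self, one_contig):
        low = _site("c1", 10, 8, G=2)     # 2 reads: below threshold
        calls = {"g1": snp.call_snps_per_genotype(low, one_contig)}
        table = snp.merge_nonredundant(calls, {"g1": low}, one_contig)
        assert len(table) == 0

    def test_disjoint_sets_union(self, one_contig):
        piles = {}
        for g, positions in [("g1", range(1, 6)), ("g2", range(50, 55))]:
            piles[g] = pd.concat([_site("c1", p, 0, C=10) for p in positions])
        calls = {g: snp.call_snps_per_genotype(piles[g], one_contig)
                 for g in piles}
        table = snp.merge_nonredundant(calls, piles, one_contig)
        assert len(table) == 10
        # the other genotype has no reads at those sites -> MISSING
        assert (table.frame.loc[table.frame.g1 == "ALT", "g2"] == "MISSING").all()

    def test_statuses_against_planted_truth(self, snp_table, small_panel):
        """Error-free full-coverage panel: every planted variant is a
        confident ALT, nothing else is called."""
        truth = set(map(tuple, small_panel.truth
                        [["genotype", "contig", "pos", "alt"]]
                        .itertuples(index=False)))
        called = set()
        for g in snp_table.genotypes:
            sub = snp_table.frame[snp_table.frame[g] == "ALT"]
            called |= {(g, r.contig, r.pos, r.alt)
                       for r in sub.itertuples(index=False)}
        assert called == truth


class TestTsTv:
    def test_exhaustive_enumeration(self):
        classes = [snp.classify_ts_tv(a, b)
                   for a, b in itertools.permutations("ACGT", 2)]
        assert classes.count("transition") == 4
        assert classes.count("transversion") == 8
        assert snp.classify_ts_tv("A", "G") == "transition"
        assert snp.classify_ts_tv("C", "A") == "transversion"

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            snp.classify_ts_tv("N", "A")
        with pytest.raises(ValueError):
            snp.classify_ts_tv("A", "A")

    def test_called_transition_fraction_tracks_generator_ratio(self, snp_table,
                                                               small_panel):
        ratio = small_panel.spec.ts_tv_ratio
        expected = ratio / (1 + ratio)
        n = len(snp_table)
        frac = (snp_table.frame["class"] == "transition").mean()
        assert abs(frac - expected) < 4 * np.sqrt(expected * (1 - expected) / n)


class TestAlleleFrequency:
    def _table(self, rows, genotypes):
        frame = pd.DataFrame(rows)
        return snp.SNPTable(frame, genotypes)

    def test_single_snp_fraction(self):
        rows = [{"contig": "c", "pos": 1, "ref": "A", "alt": "G",
                 "class": "transition",
                 **{f"g{i}": ("ALT" if i == 0 else "REF") for i in range(9)}}]
        t = self._table(rows, [f"g{i}" for i in range(9)])
        assert snp.allele_frequency_summary(t, t.genotypes) == pytest.approx(0.1)

    def test_mean_over_snps(self):
        genos = [f"g{i}" for i in range(4)]
        rows = [
            {"contig": "c", "pos": 1, "ref": "A", "alt": "G",
             "class": "transition", "g0": "ALT", "g1": "REF", "g2": "REF",
             "g3": "REF"},                                        # 1/5 = 0.2
            {"contig": "c", "pos": 2, "ref": "A", "alt": "C",
             "class": "transversion", "g0": "ALT", "g1": "ALT", "g2": "MISSING",
             "g3": "MISSING"},                                    # 2/3
        ]
        t = self._table(rows, genos)
        assert snp.allele_frequency_summary(t, genos) == pytest.approx(
            (0.2 + 2 / 3) / 2)

    def test_matches_truth_oracle(self, snp_table, small_panel):
        """On clean data the summary equals a brute-force recomputation from
        the planted truth list."""
        carriers = small_panel.truth.groupby(
            ["contig", "pos", "alt"]).genotype.apply(set).to_dict()
        site_alt = {(r.contig, r.pos): {} for r in
                    small_panel.truth.itertuples(index=False)}
        for r in small_panel.truth.itertuples(index=False):
            site_alt[(r.contig, r.pos)][r.genotype] = r.alt
        n_g = len(snp_table.genotypes)
        freqs = []
        for r in snp_table.frame.itertuples(index=False):
            k = len(carriers[(r.contig, r.pos, r.alt)])
            # a genotype carrying a different alt at a multi-allelic site is
            # non-informative on this record
            other = sum(1 for g, a in site_alt[(r.contig, r.pos)].items()
                        if a != r.alt)
            freqs.append(k / (n_g + 1 - other))
        expected = float(np.mean(freqs))
        got = snp.allele_frequency_summary(snp_table, snp_table.genotypes)
        assert got == pytest.approx(expected)

    def test_empty_subset_rejected(self, snp_table):
        with pytest.raises(ValueError):
            snp.allele_frequency_summary(snp_table, [])


class TestSSR:
    def test_simple_dinucleotide(self):
        [ssr] = snp.find_ssrs("G" * 5 + "ACACACACACAC" + "T" * 5,
                              min_total_len=12)
        assert (ssr.motif, ssr.copies) == ("AC", 6)
        assert (ssr.start, ssr.end) == (5, 17)

    def test_below_copy_threshold_not_reported(self):
        assert snp.find_ssrs("G" * 5 + "AT" * 5 + "C" * 5) == []

    def test_composite_motifs_collapse_to_primitive_period(self):
        out = snp.find_ssrs("ACACACACACACACAC")
        assert len(out) == 1 and out[0].motif == "AC"

    def test_planted_ssrs_all_recovered(self, small_ref):
        found = snp.find_ssrs_in_contigs(small_ref.contigs)
        assert len(small_ref.ssrs) > 5
        for t in small_ref.ssrs.itertuples(index=False):
            hit = found[(found.contig == t.contig) & (found.start - 1 < t.end)
                        & (found.end > t.start)]
            assert len(hit) >= 1, f"planted SSR missed: {t}"


class TestVCF:
    def test_round_trip_through_pysam(self, snp_table, ref_contigs, tmp_path):
        pysam = pytest.importorskip("pysam")
        path = tmp_path / "out.vcf"
        snp.write_vcf(snp_table, ref_contigs, path)
        recs = list(pysam.VariantFile(str(path)))
        assert len(recs) == len(snp_table)
        r0 = recs[0]
        row0 = snp_table.frame.iloc[0]
        assert (r0.chrom, r0.pos, r0.ref, r0.alts[0]) == (
            row0.contig, row0.pos, row0.ref, row0.alt)
        for g in snp_table.genotypes:
            ft = r0.samples[g]["FT"]
            assert ft in ("PASS", "LOWCONF", "MISSING")
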