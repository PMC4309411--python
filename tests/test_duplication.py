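import numpy as np
import pytest

from pericompart import duplication as dup
from pericompart.io_formats import GeneMapEntry, SimilarityHit


def hit(q, s, bit=500.0, ident=90.0, length=600, evalue=1e-50):
    return SimilarityHit(q, s, ident, length, 10, 0, 1, length, 1, length,
                         evalue, bit)


def pp(a, b, a_idx, b_idx, chrom_a="1H", chrom_b="2H", **kw):
    return dup.PositionedPair(dup.ParalogPair(a, b, kw.get("bit", 500.0),
                                              kw.get("ident", 90.0),
                                              kw.get("length", 600)),
                              chrom_a, a_idx, chrom_b, b_idx)


class TestBestNonselfHits:
    def test_self_hits_discarded_best_kept(self):
        hits = [hit("q", "q", bit=2000), hit("q", "b", bit=900),
                hit("q", "c", bit=500)]
        (pair,) = dup.best_nonself_hits(hits)
        assert {pair.gene_a, pair.gene_b} == {"b", "q"}

    def test_tie_broken_by_evalue_then_id(self):
        hits = [hit("q", "b", bit=900, evalue=1e-40),
                hit("q", "c", bit=900, evalue=1e-50)]
        (pair,) = dup.best_nonself_hits(hits)
        assert {pair.gene_a, pair.gene_b} == {"c", "q"}
        hits = [hit("q", "b", bit=900), hit("q", "c", bit=900)]
        (pair,) = dup.best_nonself_hits(hits)
        assert {pair.gene_a, pair.gene_b} == {"b", "q"}

    def test_only_self_hit_emits_nothing(self):
        assert dup.best_nonself_hits([hit("q", "q")]) == []

    def test_multiple_hsps_collapsed(self):
        hits = [hit("q", "b", bit=300), hit("q", "b", bit=800),
                hit("q", "c", bit=500)]
        (pair,) = dup.best_nonself_hits(hits)
        assert pair.bit_score == 800

    def test_rank_two(self):
        hits = [hit("q", "b", bit=900), hit("q", "c", bit=500)]
        (pair,) = dup.best_nonself_hits(hits, rank=2)
        assert {pair.gene_a, pair.gene_b} == {"c", "q"}


class TestFilterParalogPairs:
    @pytest.mark.parametrize("bit,ident,length,kept", [
        (8500, 92.0, 900, False),   # bit-score ceiling
        (250, 90.0, 400, False),    # weak and short
        (250, 90.0, 600, True),     # weak but long enough
        (400, 90.0, 400, True),     # short but strong enough
        (500, 100.0, 250, False),   # perfect identity over >200 bp
        (500, 100.0, 150, True),    # perfect identity but short
        (7999, 90.0, 900, True),
    ])
    def test_rules(self, bit, ident, length, kept):
        p = dup.ParalogPair("a", "b", bit, ident, length)
        assert (dup.filter_paralog_pairs([p]) == [p]) is kept


class TestReorderByReference:
    def test_local_shuffle_restored_to_reference_order(self):
        genes = ["g1", "g2", "g3", "g4"]
        anchors = {"g1": 10, "g2": 12, "g3": 11, "g4": 13}
        out, dropped = dup.reorder_by_reference(genes, anchors, [genes])
        assert out == ["g1", "g3", "g2", "g4"]
        assert dropped == 0

    def test_remote_anchor_dropped(self):
        genes = ["g1", "g2", "g3"]
        anchors = {"g1": 10, "g2": 520, "g3": 11}
        out, dropped = dup.reorder_by_reference(genes, anchors, [genes])
        assert out == ["g1", "g3"]
        assert dropped == 1

    def test_collinear_input_unchanged(self):
        genes = [f"g{i}" for i in range(10)]
        anchors = {g: i * 3 for i, g in enumerate(genes)}
        out, dropped = dup.reorder_by_reference(genes, anchors, [genes])
        assert out == genes and dropped == 0

    def test_unanchored_gene_dropped_and_counted(self):
        genes = ["g1", "g2", "g3"]
        anchors = {"g1": 1, "g3": 2}
        out, dropped = dup.reorder_by_reference(genes, anchors, [genes])
        assert out == ["g1", "g3"] and dropped == 1


class TestRemoveMapOutliers:
    def entries(self, cms):
        return [GeneMapEntry(f"g{i}", "1H", cm, (i + 1) * 1000)
                for i, cm in enumerate(cms)]

    def test_monotone_map_untouched(self):
        es = self.entries(np.linspace(0, 100, 200))
        assert dup.remove_map_outliers(es) == es

    def test_single_displaced_gene_removed(self):
        cms = list(np.linspace(0, 100, 200))
        cms[100] += 50.0
        es = self.entries(cms)
        out = dup.remove_map_outliers(es)
        assert len(out) == 199
        assert all(e.gene_id != "g100" for e in out)

    def test_mad_zero_guard(self):
        es = self.entries([5.0] * 100)
        assert dup.remove_map_outliers(es) == es


class TestDetectCollinearRegions:
    def test_perfect_diagonal(self):
        pairs = [pp(f"a{i}", f"b{i}", i + 1, i + 101) for i in range(12)]
        (region,) = dup.detect_collinear_regions(pairs)
        assert region.strength == 12
        assert region.orientation == "same"

    def test_rerouted_pair_excluded(self):
        pairs = [pp(f"a{i}", f"b{i}", i + 1, i + 101) for i in range(12)]
        pairs[5] = pp("a5", "b5", 6, 500)
        (region,) = dup.detect_collinear_regions(pairs, min_pairs=9)
        assert region.strength == 11
        assert region.strength == dup.brute_force_best_chain(pairs)

    def test_inverted_diagonal(self):
        pairs = [pp(f"a{i}", f"b{i}", i + 1, 200 - i) for i in range(12)]
        (region,) = dup.detect_collinear_regions(pairs)
        assert region.strength == 12
        assert region.orientation == "inverted"

    def test_gap_rule_splits_chain(self):
        pairs = ([pp(f"a{i}", f"b{i}", i + 1, i + 1) for i in range(10)]
                 + [pp(f"c{i}", f"d{i}", i + 100, i + 100) for i in range(10)])
        regions = dup.detect_collinear_regions(pairs, min_pairs=9, max_gap=25)
        assert sorted(r.strength for r in regions) == [10, 10]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        pairs = [pp(f"a{i}", f"b{i}", int(rng.integers(1, 40)),
                    int(rng.integers(1, 40))) for i in range(n)]
        regions = dup.detect_collinear_regions(pairs, min_pairs=1, max_gap=25)
        best = max((r.strength for r in regions), default=0)
        assert best == dup.brute_force_best_chain(pairs, max_gap=25)


class TestNg86:
    def test_identical_sequences(self):
        ka, ks, kk = dup.ng86_ka_ks("ATGGGG", "ATGGGG")
        assert ka == 0.0 and ks == 0.0 and kk is None

    def test_hand_computed_synonymous_example(self):
        a = "GGG" * 9 + "TTT"
        b = "GGG" * 9 + "TTC"
        ka, ks, kk = dup.ng86_ka_ks(a, b)
        assert ka == 0.0
        assert ks == pytest.approx(0.1156, abs=1e-4)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        from pericompart.synthetic_data import _diverge_pair
        a, b = _diverge_pair(rng, 50, ks=0.8, ka=0.1)
        assert dup.ng86_ka_ks(a, b) == dup.ng86_ka_ks(b, a)

    def test_site_counts_conserve_total(self):
        from pericompart.variant_diversity import codon_site_fractions
        for codon in ("GGG", "TTT", "ATG", "TGG", "CGA"):
            s, n = codon_site_fractions(codon)
            assert s + n == pytest.approx(3.0)

    def test_pure_synonymous_divergence_gives_zero_ka(self):
        rng = np.random.default_rng(1)
        from pericompart.synthetic_data import _diverge_pair
        a, b = _diverge_pair(rng, 100, ks=1.0, ka=0.0)
        ka, ks, kk = dup.ng86_ka_ks(a, b)
        assert ka == 0.0 and ks > 0.5

    def test_saturation_flagged(self):
        # maximally divergent third positions everywhere: ps beyond JC range
        a = "GGG" * 60
        b = "GGA" * 20 + "GGC" * 20 + "GGT" * 20
        ka, ks, kk = dup.ng86_ka_ks(a, b)
        assert ks is None and kk is None

    def test_length_contract(self):
        with pytest.raises(ValueError):
            dup.ng86_ka_ks("ATG", "ATGGGG")
        with pytest.raises(ValueError):
            dup.ng86_ka_ks("ATGA", "ATGA")


class TestTrimOhnologPairs:
    def _op(self, a, b, ks, region=""):
        return dup.OhnologPair(dup.ParalogPair(a, b, 500, 70, 600),
                               ka=0.2, ks=ks, ka_ks=None, region_id=region)

    def _region(self, rid, pairs, chrom_a="1H", chrom_b="2H", start=0):
        members = [pp(p.pair.gene_a, p.pair.gene_b, start + i, start + i,
                      chrom_a, chrom_b) for i, p in enumerate(pairs)]
        return dup.OhnologRegion(rid, chrom_a, chrom_b, members, "same")

    def test_high_ks_removed(self):
        pairs = [self._op(f"a{i}", f"b{i}", ks=1.0) for i in range(9)]
        pairs.append(self._op("x", "y", ks=3.2))
        regions = [self._region("R1", pairs)]
        final, counts = dup.trim_ohnolog_pairs(pairs, regions)
        assert counts["ks"] == 1
        assert all(p.pair.gene_a != "x" for p in final)

    def test_multi_pair_genes_both_removed(self):
        pairs = [self._op(f"a{i}", f"b{i}", ks=1.0) for i in range(10)]
        pairs.append(self._op("a0", "zz", ks=1.0))  # a0 now in two pairs
        regions = [self._region("R1", pairs)]
        final, counts = dup.trim_ohnolog_pairs(pairs, regions)
        assert counts["multi_pair_gene"] == 2
        genes = {g for p in final for g in (p.pair.gene_a, p.pair.gene_b)}
        assert "a0" not in genes and "zz" not in genes

    def test_small_region_removed(self):
        pairs = [self._op(f"a{i}", f"b{i}", ks=1.0) for i in range(8)]
        regions = [self._region("R1", pairs)]
        final, counts = dup.trim_ohnolog_pairs(pairs, regions)
        assert final == [] and counts["weak_region"] == 8

    def test_overlapping_weaker_region_removed(self):
        strong = [self._op(f"a{i}", f"b{i}", ks=1.0) for i in range(12)]
        weak = [self._op(f"c{i}", f"d{i}", ks=1.0) for i in range(9)]
        regions = [self._region("RS", strong, start=0),
                   self._region("RW", weak, start=5)]  # overlapping spans
        final, counts = dup.trim_ohnolog_pairs(strong + weak, regions)
        assert counts["overlap"] == 9
        assert {p.region_id for p in final} == {"RS"}

    def test_final_set_one_pair_per_gene(self):
        pairs = [self._op(f"a{i}", f"b{i}", ks=1.0) for i in range(12)]
        regions = [self._region("R1", pairs)]
        final, _ = dup.trim_ohnolog_pairs(pairs, regions)
        genes = [g for p in final for g in (p.pair.gene_a, p.pair.gene_b)]
        assert len(genes) == len(set(genes))


class TestLocalDuplicates:
    def entries(self):
        # chromosome of length ~100 Mbp
        es = [GeneMapEntry("q", "1H", 0.0, 10_000_000),
              GeneMapEntry("near", "1H", 0.1, 11_500_000),
              GeneMapEntry("edge", "1H", 0.2, 12_000_000),
              GeneMapEntry("far", "1H", 0.3, 13_000_000),
              GeneMapEntry("end", "1H", 1.0, 100_000_000)]
        return es

    def test_distance_rule(self):
        es = self.entries()
        local, trans, skipped = dup.call_local_duplicates(
            [hit("q", "near")], es)
        assert len(local) == 1 and trans == [] and skipped == 0

    def test_remote_hit_is_translocation(self):
        es = self.entries()
        local, trans, _ = dup.call_local_duplicates([hit("q", "far")], es)
        assert local == [] and len(trans) == 1

    def test_exactly_two_percent_is_local(self):
        es = self.entries()
        local, trans, _ = dup.call_local_duplicates([hit("q", "edge")], es)
        assert len(local) == 1 and trans == []

    def test_unmapped_gene_skipped(self):
        es = self.entries()
        local, trans, skipped = dup.call_local_duplicates(
            [hit("q", "unknown")], es)
        assert skipped == 1 and local == [] and trans == []


class TestCompartmentTables:
    def test_expected_ohnolog_gene_counts(self):
        t = dup.ohnolog_gene_table(477, 103, 26445, 8688)
        assert round(t.exp_lr) == 143
        assert round(t.exp_hr) == 437
        assert t.lr_share_pct == pytest.approx(17.8, abs=0.1)

    def test_expected_pair_counts(self):
        t = dup.ohnolog_pair_table({"HR-HR": 187, "LR-HR": 103, "LR-LR": 0},
                                   8688 / 35133)
        assert round(t.exp["LR-LR"]) == 18
        assert round(t.exp["HR-HR"]) == 164
        assert round(t.exp["LR-HR"]) == 108

    def test_depletion_row(self):
        row = dup.local_dup_table(6082, 1297, 26445, 8688)
        assert row.ratio == pytest.approx(0.71, abs=0.005)
        assert row.depletion_pct == pytest.approx(29, abs=0.5)


class TestClockRate:
    def test_formula(self):
        assert dup.clock_rate(1.2, 60e6).rate == pytest.approx(1.0e-8)
        assert dup.clock_rate(0.0, 60e6).rate == 0.0
        assert dup.clock_rate(1.290, 60e6).rate == pytest.approx(1.075e-8,
                                                                 abs=1e-11)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            dup.clock_rate(1.0, 0.0)
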