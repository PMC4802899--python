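"""Motif scanning and set enrichment: IUPAC matching on both strands, the
raw-p + min-promoter significance rule, and BH-controlled GO-slim testing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drynet.motifs import (EnrichmentResult, MotifHitIndex, build_hit_index,
                           go_slim_enrichment, motif_enrichment, scan_promoter)
from drynet.simulate import IUPACMotif, PromoterSet, reverse_complement
from drynet.stats import hypergeometric_upper_tail

DNA = st.text(alphabet="ACGT", min_size=12, max_size=60)
MOTIF = st.text(alphabet="ACGTRYMKSWBDHVN", min_size=3, max_size=8)


class TestScan:
    def test_single_planted_degenerate_site(self):
        m = IUPACMotif("DRE", "RCCGAC")
        assert scan_promoter("AACCGACGG", m, both_strands=False) == 1

    def test_palindrome_counts_twice_on_both_strands(self):
        m = IUPACMotif("GBOX", "CACGTG")
        seq = "TTTCACGTGTTT"
        assert scan_promoter(seq, m, both_strands=False) == 1
        assert scan_promoter(seq, m, both_strands=True) == 2

    def test_fully_degenerate_window_count(self):
        m = IUPACMotif("ANY", "NNNN")
        assert scan_promoter("ACGTACGTAC", m, both_strands=False) == 7

    def test_overlapping_matches_all_count(self):
        m = IUPACMotif("AA", "AA")
        assert scan_promoter("AAAA", m, both_strands=False) == 3

    def test_sequence_N_matches_only_motif_N(self):
        assert scan_promoter("AANAA", IUPACMotif("x", "ANA"), both_strands=False) == 1
        assert scan_promoter("AANAA", IUPACMotif("y", "AAA"), both_strands=False) == 0

    def test_sequence_shorter_than_motif(self):
        with pytest.raises(ValueError):
            scan_promoter("ACG", IUPACMotif("m", "ACGT"))

    @given(DNA, MOTIF)
    def test_strand_symmetry(self, seq, cons):
        """Both-strand counts are invariant under reverse complementing the
        scanned sequence."""
        m = IUPACMotif("m", cons)
        if len(seq) < len(cons):
            return
        rc_seq = reverse_complement(seq)
        assert scan_promoter(seq, m, both_strands=True) == \
            scan_promoter(rc_seq, m, both_strands=True)


class TestHitIndex:
    def test_universal_motif_hits_everything(self):
        prom = PromoterSet({"g1": "ACGT" * 5, "g2": "TTAA" * 5})
        idx = build_hit_index(prom, [IUPACMotif("any", "N")])
        assert idx.hits["any"] == {"g1", "g2"}
        assert idx.background_size == 2

    def test_impossible_motif_empty(self):
        prom = PromoterSet({"g1": "ATATATATATATAT", "g2": "TTTTAAAATTTTAA"})
        idx = build_hit_index(prom, [IUPACMotif("gc", "CCCCCCCCCCCC")])
        assert idx.hits["gc"] == set()

    def test_empty_promoter_set_rejected(self):
        with pytest.raises(ValueError):
            build_hit_index(PromoterSet({}), [IUPACMotif("m", "ACGT")])


def _index(hits, background):
    return MotifHitIndex(hits=hits, background_size=len(background),
                         background=set(background))


class TestMotifEnrichment:
    def test_score_is_neg_log10_p(self):
        genes = [f"g{i}" for i in range(100)]
        idx = _index({"m": set(genes[:30])}, genes)
        (res,) = motif_enrichment(set(genes[:20]), idx, min_promoters=1)
        assert res.score == pytest.approx(-np.log10(res.p))
        assert res.p == pytest.approx(
            hypergeometric_upper_tail(res.k, res.K, res.n, res.N))

    def test_min_promoter_rule_blocks_small_k(self):
        genes = [f"g{i}" for i in range(1000)]
        idx = _index({"m": set(genes[:9])}, genes)
        (res,) = motif_enrichment(set(genes[:20]), idx,
                                  alpha=0.01, min_promoters=10)
        assert res.k == 9 and res.p < 1e-6
        assert res.significant is False  # fails the >=10-promoter rule

    def test_significance_thresholds_match_score_scale(self):
        # p = 0.01 <-> score 2; p = 1e-4 <-> score 4 (the heatmap convention)
        assert -np.log10(0.01) == pytest.approx(2.0)
        genes = [f"g{i}" for i in range(200)]
        idx = _index({"m": set(genes[:80])}, genes)
        (res,) = motif_enrichment(set(genes[:40]), idx, min_promoters=10)
        assert res.significant == (res.p < 0.01 and res.k >= 10)

    def test_unknown_gene_named_in_error(self):
        idx = _index({"m": {"g1"}}, ["g1", "g2"])
        with pytest.raises(ValueError, match="ghost"):
            motif_enrichment({"ghost"}, idx)

    def test_results_sorted_by_p(self):
        genes = [f"g{i}" for i in range(300)]
        idx = _index({"strong": set(genes[:50]), "weak": set(genes[:150])}, genes)
        res = motif_enrichment(set(genes[:40]), idx, min_promoters=1)
        assert [r.p for r in res] == sorted(r.p for r in res)


class TestGoSlim:
    def test_planted_category_has_minimum_p(self):
        background = {f"g{i}" for i in range(200)}
        term_map = {
            "planted": {f"g{i}" for i in range(30)},
            "other1": {f"g{i}" for i in range(100, 140)},
            "other2": {f"g{i}" for i in range(140, 180)},
        }
        res = go_slim_enrichment({f"g{i}" for i in range(20)}, background, term_map)
        assert res[0].id == "planted" and res[0].significant

    def test_gene_set_equal_background_certain(self):
        background = {f"g{i}" for i in range(50)}
        term_map = {"t": {f"g{i}" for i in range(10)}}
        res = go_slim_enrichment(background, background, term_map)
        assert all(r.p == pytest.approx(1.0) for r in res)

    def test_empty_term_map_warns_and_returns_empty(self):
        assert go_slim_enrichment({"g1"}, {"g1", "g2"}, {}) == []

    def test_gene_set_outside_background_rejected(self):
        with pytest.raises(ValueError):
            go_slim_enrichment({"gX"}, {"g1"}, {"t": {"g1"}})

    def test_bh_family_rate_under_null(self):
        """~20 null terms at FDR 0.05: any-significant rate stays near or
        below nominal over 200 simulated families."""
        n_genes, n_terms = 150, 20
        genes = np.array([f"g{i}" for i in range(n_genes)])
        background = set(genes)
        any_sig = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            gene_set = set(rng.choice(genes, size=25, replace=False))
            term_map = {f"t{j}": set(rng.choice(genes, size=30, replace=False))
                        for j in range(n_terms)}
            res = go_slim_enrichment(gene_set, background, term_map, fdr=0.05)
            any_sig += any(r.significant for r in res)
        assert any_sig / 200 <= 0.10  # 0.05 nominal + Monte-Carlo slack
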