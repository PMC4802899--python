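"""Metabolite-transcript integration: sample alignment, top-k correlators,
overlap Venn counts against a brute-force oracle, pathway edge tallies."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drynet.integrate import (GeneMetaboliteLink, align_samples,
                              build_gene_metabolite_network, overlap_summary,
                              pathway_edge_summary, top_correlators)
from drynet.simulate import generate_metabolite_matrix, generate_transcript_matrix
from drynet.containers import OmicsMatrix


class TestAlignment:
    def test_replicate_pairing_default_design(self, default_dataset):
        merged = align_samples(default_dataset.metabolites,
                               default_dataset.transcripts)
        assert merged.values.shape[1] == 18  # 3 shared stages x 3 reps x 2
        assert set(merged.origin) == {"metabolite", "transcript"}
        assert merged.values.shape[0] == 74 + 2000

    def test_stage_means_default_design(self, default_dataset):
        merged = align_samples(default_dataset.metabolites,
                               default_dataset.transcripts,
                               strategy="stage_means")
        assert merged.values.shape[1] == 6  # 3 stages x 2 treatments

    def test_stage_means_averages_replicates(self, default_dataset):
        merged = align_samples(default_dataset.metabolites,
                               default_dataset.transcripts,
                               strategy="stage_means")
        metab = default_dataset.metabolites
        cols = metab.samples_for(treatment="C", stage_daa=41)
        expected = metab.values.loc["met_001", cols].mean()
        assert merged.values.loc["met_001", "C_41_mean"] == pytest.approx(expected)

    def test_disjoint_stages_rejected(self, default_dataset):
        trans = default_dataset.transcripts
        shifted = trans.metadata.copy()
        shifted["stage_daa"] = shifted["stage_daa"] + 1
        bad = OmicsMatrix(values=trans.values.copy(), metadata=shifted)
        with pytest.raises(ValueError):
            align_samples(default_dataset.metabolites, bad)


class TestTopCorrelators:
    @pytest.fixture(scope="class")
    def noise_free_merged(self, small_noise_free_config):
        cfg = small_noise_free_config
        matrix, truth = generate_metabolite_matrix(cfg)
        trans = generate_transcript_matrix(cfg, truth)
        return align_samples(matrix, trans), truth

    def test_planted_gene_is_rank_one_with_perfect_r(self, noise_free_merged):
        merged, truth = noise_free_merged
        gene, met = sorted(truth.planted_gene_metabolite_links)[0]
        links = top_correlators(merged, met, k=5, B=1999, seed=0)
        assert links and links[0].rank == 1
        assert {l.gene_id for l in links if abs(l.r) > 0.999} >= {gene}

    def test_underfilled_list_keeps_contiguous_ranks(self, noise_free_merged):
        merged, _ = noise_free_merged
        links = top_correlators(merged, merged.metabolite_ids[0], k=100,
                                B=1999, seed=0)
        assert len(links) < 100
        assert [l.rank for l in links] == list(range(1, len(links) + 1))
        assert all(l.p < 0.001 for l in links)

    def test_unknown_metabolite_and_bad_k(self, noise_free_merged):
        merged, _ = noise_free_merged
        with pytest.raises(ValueError):
            top_correlators(merged, "not_a_metabolite", B=10, seed=0)
        with pytest.raises(ValueError):
            top_correlators(merged, merged.metabolite_ids[0], k=0, B=10, seed=0)

    def test_deterministic_given_seed(self, noise_free_merged):
        merged, _ = noise_free_merged
        met = merged.metabolite_ids[1]
        a = top_correlators(merged, met, B=499, seed=5)
        b = top_correlators(merged, met, B=499, seed=5)
        assert a == b


class TestOverlap:
    def test_hand_enumerable_example(self):
        sets = {"A": {"g1", "g2", "g3"}, "B": {"g2", "g3"}, "C": {"g3"}}
        s = overlap_summary(sets)
        assert s.per_metabolite_specific == {"A": 1, "B": 0, "C": 0}
        assert s.pairwise_shared[("A", "B")] == 1  # g2 in exactly A and B
        assert s.pairwise_shared[("A", "C")] == 0
        assert s.shared_by_all == 1  # g3

    def test_identical_sets(self):
        sets = {"A": {"g1", "g2"}, "B": {"g1", "g2"}}
        s = overlap_summary(sets)
        assert s.per_metabolite_specific == {"A": 0, "B": 0}
        assert s.shared_by_all == 2

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            overlap_summary({"A": {"g"}})

    @given(st.lists(st.sets(st.integers(0, 40)), min_size=2, max_size=4))
    def test_inclusion_exclusion_against_brute_force(self, raw_sets):
        sets = {f"M{i}": {f"g{v}" for v in s} for i, s in enumerate(raw_sets)}
        s = overlap_summary(sets)
        universe = set().union(*sets.values())
        names = sorted(sets)
        for m in names:
            expected = sum(1 for g in universe
                           if {n for n in names if g in sets[n]} == {m})
            assert s.per_metabolite_specific[m] == expected
        assert s.shared_by_all == len(set.intersection(*sets.values())) \
            if all(sets.values()) else True
        # every gene is counted in exactly one exclusive cell
        total_cells = sum(s.per_metabolite_specific.values()) + \
            sum(s.pairwise_shared.values())
        exclusive_up_to_pairs = sum(
            1 for g in universe
            if len({n for n in names if g in sets[n]}) in (1, 2))
        assert total_cells == exclusive_up_to_pairs


class TestPathwaySummary:
    def _links(self, spec):
        return [GeneMetaboliteLink(gene_id=g, metabolite_id="m", r=r, p=0.0005,
                                   rank=i + 1)
                for i, (g, r) in enumerate(spec)]

    def test_counts_by_sign(self):
        links = self._links([("g1", 0.9), ("g2", 0.8), ("g3", 0.7),
                             ("g4", -0.9), ("g5", -0.8)])
        pmap = {f"g{i}": "terpenoid" for i in range(1, 6)}
        (s,) = pathway_edge_summary(links, pmap)
        assert (s.pathway, s.n_positive, s.n_negative) == ("terpenoid", 3, 2)

    def test_all_positive_and_unannotated_bucket(self):
        links = self._links([("g1", 0.9), ("g2", 0.8)])
        out = pathway_edge_summary(links, {"g1": "phenylpropanoid"})
        by = {s.pathway: s for s in out}
        assert by["phenylpropanoid"].n_negative == 0
        assert by["unannotated"].n_positive == 1


class TestBipartiteNetwork:
    def test_disjoint_top_lists_union(self):
        links = {
            f"met{i}": [GeneMetaboliteLink(gene_id=f"g{i}{j}", metabolite_id=f"met{i}",
                                           r=0.9, p=0.0005, rank=j + 1)
                        for j in range(2)]
            for i in range(3)
        }
        g = build_gene_metabolite_network(links, de_flags={"g00"})
        genes = [n for n, d in g.nodes(data=True) if d["kind"] == "transcript"]
        assert len(genes) == 6
        assert g.nodes["g00"]["is_de"] is True
        assert g.number_of_edges() == 6
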