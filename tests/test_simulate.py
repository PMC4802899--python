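"""Synthetic-data generator: design shapes, determinism, positivity, planted
correlation structure, and promoter motif planting."""

import numpy as np
import pytest

from drynet.simulate import (IUPACMotif, ModuleSpec, SynthConfig, SynthConfigError,
                             default_motif_library, generate_dataset,
                             generate_metabolite_matrix, generate_promoters,
                             generate_transcript_matrix)
from drynet.motifs import scan_promoter
from drynet.stats import pearson


class TestDesignShape:
    def test_default_design_dimensions(self, default_dataset):
        ds = default_dataset
        assert ds.metabolites.values.shape == (74, 48)   # 2 x 6 stages x 4 reps
        assert ds.transcripts.values.shape == (2000, 18)  # 2 x 3 stages x 3 reps
        assert len(ds.promoters) == 2000
        assert all(len(s) == 1000 for s in ds.promoters.sequences.values())

    def test_metadata_matches_factorial_design(self, default_dataset):
        meta = default_dataset.metabolites.metadata
        counts = meta.groupby(["treatment", "stage_daa"]).size()
        assert len(counts) == 12 and set(counts) == {4}
        meta_t = default_dataset.transcripts.metadata
        counts_t = meta_t.groupby(["treatment", "stage_daa"]).size()
        assert len(counts_t) == 6 and set(counts_t) == {3}

    def test_positivity(self, default_dataset):
        assert (default_dataset.metabolites.values.to_numpy() > 0).all()
        assert (default_dataset.transcripts.values.to_numpy() > 0).all()


class TestDeterminism:
    def test_identical_config_bit_identical(self):
        cfg = SynthConfig(seed=5, n_metabolites=20, n_genes=40, regulon_size=10,
                          modules=(ModuleSpec("m", 5, linked_gene_count=6),))
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert a.metabolites.values.equals(b.metabolites.values)
        assert a.transcripts.values.equals(b.transcripts.values)
        assert a.promoters.sequences == b.promoters.sequences
        assert a.truth.planted_gene_metabolite_links == b.truth.planted_gene_metabolite_links
        assert a.de_flags == b.de_flags

    def test_seed_changes_output(self):
        base = dict(n_metabolites=20, n_genes=40, regulon_size=10,
                    modules=(ModuleSpec("m", 5, linked_gene_count=6),))
        a = generate_dataset(SynthConfig(seed=1, **base))
        b = generate_dataset(SynthConfig(seed=2, **base))
        assert not a.metabolites.values.equals(b.metabolites.values)

    def test_gene_count_does_not_perturb_metabolites(self):
        """Named substreams: adding genes leaves metabolite draws unchanged."""
        a, _ = generate_metabolite_matrix(SynthConfig(seed=3, n_genes=100))
        b, _ = generate_metabolite_matrix(SynthConfig(seed=3, n_genes=500))
        assert a.values.equals(b.values)


class TestPlantedCorrelation:
    def test_noise_free_module_is_perfectly_correlated(self, small_noise_free_config):
        matrix, truth = generate_metabolite_matrix(small_noise_free_config)
        members = [m for m, mod in truth.module_membership.items() if mod == "m1"]
        for cond in ("C", "D"):
            cols = matrix.samples_for(treatment=cond)
            sub = matrix.values.loc[members, cols].to_numpy()
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    assert pearson(sub[i], sub[j]) == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_linked_gene_tracks_metabolite(self, small_noise_free_config):
        cfg = small_noise_free_config
        matrix, truth = generate_metabolite_matrix(cfg)
        trans = generate_transcript_matrix(cfg, truth)
        gene, met = sorted(truth.planted_gene_metabolite_links)[0]
        # align on the shared (treatment, stage, replicate) cells
        shared = [s for s in trans.sample_ids if s in set(matrix.sample_ids)]
        r = pearson(matrix.values.loc[met, shared], trans.values.loc[gene, shared])
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_decoupled_config_has_no_links(self):
        cfg = SynthConfig(seed=2, n_metabolites=10, n_genes=30, regulon_size=5,
                          modules=(ModuleSpec("m", 4, linked_gene_count=0),))
        _, truth = generate_metabolite_matrix(cfg)
        assert truth.planted_gene_metabolite_links == set()

    def test_planted_pairs_exceed_study_gate(self):
        """Default noise level: planted within-module |PCC| > 0.8 for nearly
        all pairs, per condition, across seeds."""
        total = passed = 0
        for seed in range(6):
            cfg = SynthConfig(seed=seed)
            matrix, truth = generate_metabolite_matrix(cfg)
            for cond in ("C", "D"):
                cols = matrix.samples_for(treatment=cond)
                vals = matrix.values[cols]
                for a, b in truth.planted_edges[cond]:
                    total += 1
                    if abs(pearson(vals.loc[a], vals.loc[b])) > 0.8:
                        passed += 1
        assert passed / total >= 0.95

    def test_coupling_monotone_in_loading(self):
        """Stronger loading never weakens expected within-module |PCC|."""
        def mean_abs_pcc(loading: float) -> float:
            out = []
            for seed in range(4):
                cfg = SynthConfig(seed=seed, n_metabolites=8, n_genes=10,
                                  regulon_size=4,
                                  modules=(ModuleSpec("m", 5, loading=loading),))
                matrix, truth = generate_metabolite_matrix(cfg)
                cols = matrix.samples_for(treatment="C")
                vals = matrix.values[cols]
                out.extend(abs(pearson(vals.loc[a], vals.loc[b]))
                           for a, b in truth.planted_edges["C"])
            return float(np.mean(out))
        assert mean_abs_pcc(0.9) > mean_abs_pcc(0.5) > mean_abs_pcc(0.2)


class TestPromoters:
    def test_extreme_plant_rates(self):
        cfg = SynthConfig(seed=4, n_metabolites=10, n_genes=60, regulon_size=20,
                          motif_plant_rate_regulon=1.0,
                          motif_plant_rate_background=0.0,
                          modules=(ModuleSpec("m", 4, linked_gene_count=10),))
        _, truth = generate_metabolite_matrix(cfg)
        promoters, library = generate_promoters(cfg, truth)
        planted = [m for m in library if m.motif_id in truth.planted_motif_ids]
        for gene in truth.regulon_genes:
            assert any(scan_promoter(promoters[gene], m) >= 1 for m in planted)

    def test_spontaneous_match_rate_matches_closed_form(self):
        """A fully specified 6-mer in 1-kb uniform-random sequence scanned on
        both strands appears 2*(1000-6+1)/4^6 ~ 0.486 times on average."""
        cfg = SynthConfig(seed=9, n_metabolites=5, n_genes=1200, regulon_size=5,
                          gc_content=0.5, motif_plant_rate_regulon=0.0,
                          motif_plant_rate_background=0.0, modules=())
        _, truth = generate_metabolite_matrix(cfg)
        promoters, _ = generate_promoters(cfg, truth)
        motif = IUPACMotif("PROBE", "ACGTAC")
        counts = [scan_promoter(seq, motif, both_strands=True)
                  for seq in promoters.sequences.values()]
        expected = 2 * (1000 - 6 + 1) * 0.25 ** 6
        assert np.mean(counts) == pytest.approx(expected, abs=0.06)

    def test_gc_content_respected(self):
        cfg = SynthConfig(seed=8, n_metabolites=5, n_genes=300, regulon_size=5,
                          gc_content=0.35, motif_plant_rate_regulon=0.0,
                          motif_plant_rate_background=0.0, modules=())
        _, truth = generate_metabolite_matrix(cfg)
        promoters, _ = generate_promoters(cfg, truth)
        joined = "".join(promoters.sequences.values())
        gc = (joined.count("G") + joined.count("C")) / len(joined)
        assert gc == pytest.approx(0.35, abs=0.01)


class TestConfigErrors:
    def test_module_sizes_exceed_features(self):
        with pytest.raises(SynthConfigError):
            SynthConfig(n_metabolites=4, modules=(ModuleSpec("m", 6),)).validate()

    def test_negative_noise(self):
        with pytest.raises(SynthConfigError):
            SynthConfig(noise_sd=-0.1).validate()

    def test_transcript_stages_not_subset(self):
        with pytest.raises(SynthConfigError):
            SynthConfig(stages_trans=(40,)).validate()

    def test_motif_longer_than_promoter(self):
        cfg = SynthConfig(seed=0, n_metabolites=5, n_genes=5, regulon_size=2,
                          promoter_length=6, modules=())
        _, truth = generate_metabolite_matrix(cfg)
        with pytest.raises(SynthConfigError):
            generate_promoters(cfg, truth)

    def test_invalid_iupac_motif(self):
        with pytest.raises(ValueError):
            IUPACMotif("BAD", "ACGTX")
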