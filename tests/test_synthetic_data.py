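import numpy as np
import pandas as pd
import pytest

from siphonatlas.assembly_stats import read_lengths
from siphonatlas.cross_species import intersection_chisq, null_distribution
from siphonatlas.enrichment import hypergeom_enrich
from siphonatlas.io_formats import DEFAULT_ORGANS
from siphonatlas.synthetic_data import (
    DEFAULT_PROTOTYPES,
    generate_atlas,
    generate_foreign_atlas_and_homologs,
    generate_go_and_lengths,
    write_fasta,
    write_simulated_inputs,
)

from conftest import matched_agreement


class TestGenerateAtlas:
    def test_design_shape_and_replicates(self, atlas):
        cm, truth = atlas
        assert cm.counts.shape == (2000, 29)
        reps = {o: len(s) for o, s in cm.organ_samples().items()}
        assert reps == {"apex": 5, "pinnule": 5, "rachis": 5,
                        "frond_base": 5, "stolon": 5, "holdfast": 4}

    def test_determinism(self):
        cm1, t1 = generate_atlas(seed=4, n_transcripts=200)
        cm2, t2 = generate_atlas(seed=4, n_transcripts=200)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_series_equal(t1.node_labels, t2.node_labels)

    def test_poisson_limit_moments(self):
        cm, truth = generate_atlas(seed=5, n_transcripts=500, frac_null=1.0,
                                   dispersion=0.0)
        # null genes, dispersion 0: per-gene variance ≈ mean across replicates
        apex = cm.counts[[s for s in cm.sample_ids if s.startswith("apex")]]
        ratio = (apex.var(axis=1) / apex.mean(axis=1).clip(lower=1)).mean()
        assert 0.7 <= ratio <= 1.3

    def test_planted_fold_visible_in_normalized_means(self):
        # raw per-organ proportions carry a library-composition bias; the
        # planted fold is read off TMM-normalized CPM, which corrects it
        from siphonatlas.normalization import cpm, tmm_factors

        folds = []
        for seed in range(3):
            cm, truth = generate_atlas(seed=seed, n_transcripts=600,
                                       mean_depth=1e6)
            vals = cpm(cm, tmm_factors(cm)).values
            apex = [s for s in cm.sample_ids if s.startswith("apex")]
            hold = [s for s in cm.sample_ids if s.startswith("holdfast")]
            apex_genes = truth.node_labels[truth.node_labels == 0].index
            ratio = vals.loc[apex_genes, apex].mean(axis=1) \
                / vals.loc[apex_genes, hold].mean(axis=1).clip(lower=1e-9)
            folds.append(float(ratio.median()))
        assert all(3.0 <= f <= 5.3 for f in folds)

    def test_prototypes_distinct_after_scaling(self):
        p = DEFAULT_PROTOTYPES
        scaled = (p - p.mean(1, keepdims=True)) / p.std(1, ddof=1, keepdims=True)
        d = ((scaled[:, None] - scaled[None]) ** 2).sum(-1) ** 0.5
        off = d[~np.eye(len(p), dtype=bool)]
        assert off.min() > 1.0

    def test_invalid_replicates_rejected(self):
        with pytest.raises(ValueError):
            generate_atlas(replicates=(5, 5, 5, 5, 5))
        with pytest.raises(ValueError):
            generate_atlas(replicates=(5, 5, 5, 5, 5, 0))


class TestForeignAtlasAndHomologs:
    def test_identity_association_detected(self, rng):
        cm, truth = generate_atlas(seed=8, n_transcripts=900, frac_null=0.0)
        identity = np.eye(6, 9).copy()
        identity[:, 6:] = 0
        identity /= identity.sum(1, keepdims=True)
        membership, hits, _ = generate_foreign_atlas_and_homologs(
            truth, association=identity, seed=9)
        from siphonatlas.cross_species import assign_foreign_nodes

        table, _ = assign_foreign_nodes(
            hits, membership, source_nodes=truth.node_labels.to_dict())
        summary, _ = intersection_chisq(table, null_distribution(membership))
        assert (summary["p_value"] < 0.01).all()

    def test_unassociated_transcripts_follow_null(self):
        # unstructured source transcripts draw homolog nodes from the foreign
        # atlas's own realized distribution: the χ² test sees the exact null
        cm, truth = generate_atlas(seed=10, n_transcripts=900, frac_null=1.0)
        membership, hits, _ = generate_foreign_atlas_and_homologs(truth, seed=11)
        from siphonatlas.cross_species import assign_foreign_nodes

        table, _ = assign_foreign_nodes(
            hits, membership, source_nodes=truth.node_labels.to_dict())
        summary, _ = intersection_chisq(table, null_distribution(membership))
        assert (summary["p_value"] > 1e-3).all()

    def test_evalues_below_ceiling(self, atlas):
        cm, truth = atlas
        membership, hits, _ = generate_foreign_atlas_and_homologs(truth, seed=2)
        assert (hits["e_value"] <= 1e-5).all()

    def test_bad_association_rows_rejected(self, atlas):
        cm, truth = atlas
        with pytest.raises(ValueError, match="sum"):
            generate_foreign_atlas_and_homologs(
                truth, association=np.full((6, 9), 0.2))


class TestGoAndLengths:
    def test_planted_term_recovered_at_fdr(self):
        cm, truth = generate_atlas(seed=12, n_transcripts=1200, frac_null=0.0)
        ann, lengths, planted = generate_go_and_lengths(truth, planted_odds=8.0,
                                                        seed=13)
        universe = list(truth.node_labels.index)
        node0 = list(truth.node_labels.index[truth.node_labels == 0])
        res = hypergeom_enrich(node0, universe, ann).set_index("term")
        assert bool(res.loc[planted[0], "significant"])

    def test_odds_one_not_significant(self):
        hits = 0
        for seed in range(10):
            cm, truth = generate_atlas(seed=seed, n_transcripts=600,
                                       frac_null=0.0)
            ann, lengths, planted = generate_go_and_lengths(
                truth, planted_odds=1.0, seed=100 + seed)
            universe = list(truth.node_labels.index)
            node0 = list(truth.node_labels.index[truth.node_labels == 0])
            res = hypergeom_enrich(node0, universe, ann).set_index("term")
            hits += bool(res.loc[planted[0], "significant"])
        assert hits <= 1

    def test_fasta_round_trip_matches_lengths(self, tmp_path, atlas):
        cm, truth = atlas
        ann, lengths, _ = generate_go_and_lengths(truth, seed=3)
        small = dict(list(lengths.items())[:50])
        write_fasta(small, tmp_path / "c.fasta", seed=4)
        assert read_lengths(tmp_path / "c.fasta") == small


class TestEndToEnd:
    def test_full_pipeline_recovers_planted_nodes(self, pipeline_products):
        agreement = matched_agreement(
            pipeline_products["som"].assignment,
            pipeline_products["truth"].node_labels)
        assert agreement >= 0.90

    def test_write_simulated_inputs_round_trip(self, tmp_path):
        meta = write_simulated_inputs(tmp_path / "sim", seed=3,
                                      n_transcripts=150)
        assert (tmp_path / "sim" / "counts.tsv").exists()
        from siphonatlas.io_formats import read_best_hits, read_count_matrix

        cm = read_count_matrix(tmp_path / "sim" / "counts.tsv",
                               tmp_path / "sim" / "sheet.tsv")
        assert cm.counts.shape[0] == 150
        hits = read_best_hits(tmp_path / "sim" / "blast.tsv")
        assert not hits.empty
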