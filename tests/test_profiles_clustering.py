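import numpy as np
import pandas as pd
import pytest

from siphonatlas.profiles_clustering import (
    average_replicates,
    node_summary,
    pca,
    scale_rows,
    train_som,
    _unit_distances,
)

from conftest import matched_agreement


def frame(arr, prefix="g"):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"v{j}" for j in range(arr.shape[1])])


class TestAverageReplicates:
    def test_single_sample_per_organ_is_identity(self):
        values = frame([[1, 2], [3, 4]])
        values.columns = ["a1", "b1"]
        sheet = pd.Series({"a1": "apex", "b1": "stolon"})
        avg = average_replicates(values, sheet)
        assert np.allclose(avg.to_numpy(), values.to_numpy())

    def test_unequal_replicate_counts(self):
        values = frame([[2, 4, 6, 10]])
        values.columns = ["a1", "a2", "h1", "h2"]
        sheet = pd.Series({"a1": "apex", "a2": "apex",
                           "h1": "holdfast", "h2": "holdfast"})
        avg = average_replicates(values, sheet)
        assert avg.loc["g0", "apex"] == 3
        assert avg.loc["g0", "holdfast"] == 8


class TestScaleRows:
    def test_mean_zero_variance_one(self):
        spm = scale_rows(frame([[1, 2, 3, 4, 5, 6]]))
        row = spm.values.iloc[0]
        assert abs(row.mean()) < 1e-9
        assert abs(row.var(ddof=1) - 1) < 1e-9

    def test_constant_rows_dropped_and_reported(self):
        spm = scale_rows(frame([[1, 1, 1], [1, 2, 3]]))
        assert spm.dropped == ["g0"]
        assert list(spm.values.index) == ["g1"]

    def test_idempotent(self):
        m = frame(np.random.default_rng(0).normal(size=(20, 6)))
        once = scale_rows(m).values
        twice = scale_rows(once).values
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            scale_rows(frame([[2, 2, 2]]))


class TestPca:
    def test_full_rank_reconstruction(self, rng):
        m = frame(rng.normal(size=(30, 5)))
        res = pca(m)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T \
            + res.means.to_numpy()
        assert np.allclose(recon, m.to_numpy(), atol=1e-9)

    def test_variance_ratios_non_increasing_and_recovered(self, rng):
        # axis-aligned Gaussians with known variances under a rotation
        var = np.array([9.0, 4.0, 1.0, 0.25])
        x = rng.normal(size=(4000, 4)) * np.sqrt(var)
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        res = pca(frame(x @ q))
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()
        assert np.allclose(res.explained_variance_ratio,
                           var / var.sum(), atol=0.02)

    def test_row_scaled_matrix_rank_deficient(self, rng):
        spm = scale_rows(frame(rng.normal(size=(100, 6))))
        res = pca(spm.values)
        # mean-0 rows leave at most 5 informative PCs of 6
        assert res.explained_variance_ratio[5] < 1e-9

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pca(frame([[1, 2, 3]]))


class TestHexGrid:
    def test_hex_distances_3x2(self):
        d = _unit_distances(3, 2, "hexagonal")
        assert d.max() == 2.0
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_unknown_topology_rejected(self):
        with pytest.raises(ValueError):
            _unit_distances(2, 2, "toroidal")


class TestTrainSom:
    def test_six_well_separated_families_each_captured(self):
        # six distinct prototype profiles with modest within-family spread:
        # every unit captures one family (label-matched agreement ~1) and the
        # assigned distances are small relative to the profile norm sqrt(5)
        from siphonatlas.synthetic_data import DEFAULT_PROTOTYPES, _profile_matrix

        protos = np.log(_profile_matrix(DEFAULT_PROTOTYPES, 4.0))
        agreements = []
        for seed in (0, 1, 2):
            g = np.random.default_rng(seed)
            data = np.repeat(protos, 40, axis=0) + g.normal(0, 0.15, (240, 6))
            spm = scale_rows(frame(data))
            model = train_som(spm, seed=seed)
            fam = pd.Series(np.arange(240) // 40, index=spm.values.index)
            agreements.append(matched_agreement(model.assignment, fam))
            assert model.distance.mean() < 0.6
        assert np.median(agreements) >= 0.95

    def test_two_blob_partition_matches_kmeans_oracle(self, rng):
        from sklearn.cluster import KMeans

        blob1 = rng.normal([5, 0, 0, 0, 0, 1], 0.5, size=(150, 6))
        blob2 = rng.normal([-5, 0, 1, 0, 0, 0], 0.5, size=(150, 6))
        data = frame(np.vstack([blob1, blob2]))
        model = train_som(data, grid=(1, 2), seed=3)
        km = KMeans(2, n_init=10, random_state=0).fit_predict(data.to_numpy())
        agreement = matched_agreement(
            model.assignment, pd.Series(km, index=data.index))
        assert agreement >= 0.98

    def test_3x2_grid_produces_six_labels(self, pipeline_products):
        model = pipeline_products["som"]
        assert model.assignment.nunique() == 6

    def test_partition_property(self, pipeline_products):
        model = pipeline_products["som"]
        spm = pipeline_products["spm"]
        assert len(model.assignment) == len(spm.values)
        assert model.assignment.index.equals(spm.values.index)

    def test_planted_node_recovery(self, pipeline_products):
        agreement = matched_agreement(
            pipeline_products["som"].assignment,
            pipeline_products["truth"].node_labels)
        assert agreement >= 0.90

    def test_mean_distance_decreases(self, pipeline_products):
        trace = pipeline_products["som"].mean_distance_per_iteration
        assert trace[-1] < trace[0]

    def test_determinism(self, rng):
        data = frame(rng.normal(size=(60, 6)))
        m1 = train_som(data, seed=11, n_restarts=2)
        m2 = train_som(data, seed=11, n_restarts=2)
        assert m1.assignment.equals(m2.assignment)
        assert np.allclose(m1.codebook, m2.codebook)

    def test_grid_larger_than_data_rejected(self, rng):
        with pytest.raises(ValueError):
            train_som(frame(rng.normal(size=(4, 6))), grid=(3, 2))


class TestNodeSummary:
    def test_counts_partition_and_above_zero_labels(self, pipeline_products):
        model = pipeline_products["som"]
        spm = pipeline_products["spm"]
        summ = node_summary(model, spm)
        assert summ["n_members"].sum() == len(spm.values)
        for unit, row in summ.iterrows():
            labels = set(row["organs_above_zero"].split(",")) \
                if row["organs_above_zero"] else set()
            medians = {o: row[f"median_{o}"] for o in spm.organ_labels}
            assert labels == {o for o, v in medians.items() if v > 0}
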