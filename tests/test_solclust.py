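import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from sporesol import solclust
from sporesol.errors import ParameterError, ValidationError
from sporesol.synthetic import ARCHETYPES, SolubilitySimConfig, gen_solubility_dataset
from sporesol import pindex as pm

TIME_POINTS = ["0h", "1h", "3h", "6h", "veg"]


def mean_matrix_from_synthetic(cfg):
    table, truth = gen_solubility_dataset(cfg)
    filtered, _ = pm.apply_detection_filters(table)
    mean, _ = pm.summarize_replicates(pm.pindex_long(filtered), time_order=TIME_POINTS)
    return mean, truth


class TestClusterTrajectories:
    def test_identical_trajectories_cannot_split(self):
        matrix = pd.DataFrame(
            np.tile([0.5, 0.5, 0.5, 0.5, 0.5], (10, 1)),
            index=[f"P{i}" for i in range(10)], columns=TIME_POINTS,
        )
        with pytest.raises(ParameterError, match="tied merge heights"):
            solclust.cluster_trajectories(matrix, n_clusters=5)

    def test_n_clusters_exceeding_proteins_errors(self):
        matrix = pd.DataFrame(
            np.random.default_rng(0).uniform(size=(3, 5)), columns=TIME_POINTS
        )
        with pytest.raises(ParameterError):
            solclust.cluster_trajectories(matrix, n_clusters=5)

    def test_missing_cells_rejected(self):
        matrix = pd.DataFrame([[0.1, np.nan]], index=["A"], columns=["0h", "1h"])
        with pytest.raises(ValidationError):
            solclust.cluster_trajectories(matrix, n_clusters=1)

    def test_two_obvious_groups(self):
        rng = np.random.default_rng(1)
        low = rng.uniform(0.0, 0.1, size=(5, 5))
        high = rng.uniform(0.9, 1.0, size=(5, 5))
        matrix = pd.DataFrame(np.vstack([low, high]), columns=TIME_POINTS,
                              index=[f"P{i}" for i in range(10)])
        assignments, profiles, _ = solclust.cluster_trajectories(matrix, n_clusters=2)
        ids = assignments["cluster_id"].to_numpy()
        assert len(set(ids[:5])) == 1 and len(set(ids[5:])) == 1
        assert ids[0] != ids[5]
        assert sum(p.size for p in profiles) == 10

    def test_planted_recovery_ari(self):
        cfg = SolubilitySimConfig(
            class_counts={label: 100 for label in solclust.CLASS_LABELS},
            noise_sd=0.05, seed=1,
        )
        mean, truth = mean_matrix_from_synthetic(cfg)
        assignments, _, _ = solclust.cluster_trajectories(mean, n_clusters=5)
        merged = assignments.merge(truth, on="protein_id")
        assert adjusted_rand_score(merged["truth_class"], merged["cluster_id"]) >= 0.9

    def test_order_invariance(self):
        cfg = SolubilitySimConfig(
            class_counts={label: 20 for label in solclust.CLASS_LABELS},
            noise_sd=0.05, seed=2,
        )
        mean, _ = mean_matrix_from_synthetic(cfg)
        a1, _, _ = solclust.cluster_trajectories(mean, n_clusters=5)
        perm = mean.sample(frac=1.0, random_state=11)
        a2, _, _ = solclust.cluster_trajectories(perm, n_clusters=5)
        merged = a1.merge(a2, on="protein_id", suffixes=("_a", "_b"))
        assert adjusted_rand_score(merged["cluster_id_a"], merged["cluster_id_b"]) == 1.0

    def test_dendrogram_serializable(self):
        import json

        matrix = pd.DataFrame(
            np.random.default_rng(4).uniform(size=(6, 5)), columns=TIME_POINTS,
            index=[f"P{i}" for i in range(6)],
        )
        _, _, tree = solclust.cluster_trajectories(matrix, n_clusters=2)
        text = json.dumps(tree)
        assert tree["count"] == 6
        assert "leaf" in text


class TestClassLabels:
    def test_mostly_pellet(self):
        assert solclust.classify_profile([0.85] * 5) == "mostly_pellet"

    def test_mostly_supernatant(self):
        assert solclust.classify_profile([0.15] * 5) == "mostly_supernatant"

    def test_transient_interior_dip(self):
        assert solclust.classify_profile([0.80, 0.20, 0.70, 0.80, 0.80]) == \
            "transient_solubilization"

    def test_gradual_solubilization_monotone_decrease(self):
        assert solclust.classify_profile([0.80, 0.65, 0.50, 0.35, 0.20]) == \
            "gradual_solubilization"

    def test_gradual_desolubilization(self):
        assert solclust.classify_profile([0.20, 0.35, 0.50, 0.65, 0.80]) == \
            "gradual_desolubilization"

    def test_ambiguous_double_label_errors(self):
        profiles = [
            solclust.ClusterProfile(1, np.array([0.85] * 5), 3),
            solclust.ClusterProfile(2, np.array([0.9] * 5), 3),
        ]
        with pytest.raises(ValidationError, match="both classify"):
            solclust.assign_class_labels(profiles)

    def test_archetypes_get_planted_labels(self):
        profiles = [
            solclust.ClusterProfile(i + 1, np.array(traj), 1)
            for i, traj in enumerate(ARCHETYPES.values())
        ]
        labels = solclust.assign_class_labels(profiles)
        assert list(labels.values()) == list(ARCHETYPES.keys())

    @settings(max_examples=200, deadline=None)
    @given(
        label=st.sampled_from(sorted(ARCHETYPES)),
        noise=st.lists(st.floats(-0.05, 0.05), min_size=5, max_size=5),
    )
    def test_labels_stable_under_small_median_noise(self, label, noise):
        perturbed = np.clip(np.array(ARCHETYPES[label]) + np.array(noise), 0, 1)
        assert solclust.classify_profile(perturbed) == label


class TestChangingSet:
    def _assign(self, labels):
        return pd.DataFrame(
            {"protein_id": [f"P{i}" for i in range(len(labels))],
             "cluster_id": 1, "class_label": labels}
        )

    def test_toy_sizes(self):
        flat = (["mostly_pellet"] * 3 + ["mostly_supernatant"] * 4 +
                ["transient_solubilization", "gradual_desolubilization",
                 "gradual_solubilization"])
        out = solclust.extract_changing_set(self._assign(flat))
        assert len(out) == 3

    def test_all_static_empty(self):
        out = solclust.extract_changing_set(self._assign(["mostly_pellet"] * 5))
        assert out == []

    def test_input_order_preserved(self):
        df = self._assign(["gradual_solubilization", "mostly_pellet", "transient_solubilization"])
        assert solclust.extract_changing_set(df) == ["P0", "P2"]

    def test_planted_changing_set_size_111(self):
        cfg = SolubilitySimConfig(noise_sd=0.05, seed=3)  # default preset 15/17/79 dynamic
        mean, truth = mean_matrix_from_synthetic(cfg)
        assignments, profiles, _ = solclust.cluster_trajectories(mean, n_clusters=5)
        labels = solclust.assign_class_labels(profiles)
        assignments["class_label"] = assignments["cluster_id"].map(labels)
        changing = solclust.extract_changing_set(assignments)
        assert len(changing) == 111


class TestPCA:
    def test_perfectly_correlated_features(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        props = pd.DataFrame({"f1": a, "f2": 2 * a + 1})
        out = solclust.pca_protein_properties(props)
        assert out["explained_variance_ratio"].iloc[0] == pytest.approx(1.0)

    def test_independent_features_equal_variance(self):
        rng = np.random.default_rng(3)
        props = pd.DataFrame(rng.normal(size=(10000, 4)), columns=list("abcd"))
        out = solclust.pca_protein_properties(props)
        np.testing.assert_allclose(out["explained_variance_ratio"], 0.25, atol=0.05 * 0.25 * 4)

    def test_duplicated_rows_identical_scores(self):
        rng = np.random.default_rng(5)
        base = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        props = pd.concat([base, base.iloc[[0]]], ignore_index=True)
        out = solclust.pca_protein_properties(props)
        np.testing.assert_allclose(out["scores"].iloc[0], out["scores"].iloc[10], atol=1e-10)

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(6)
        props = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20), "c": 1.0})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = solclust.pca_protein_properties(props)
        assert "c" not in out["loadings"].index

    def test_variance_fractions_sum_and_order(self):
        rng = np.random.default_rng(7)
        props = pd.DataFrame(rng.normal(size=(30, 5)) * [1, 2, 3, 4, 5])
        out = solclust.pca_protein_properties(props)
        evr = out["explained_variance_ratio"].to_numpy()
        assert evr.sum() == pytest.approx(1.0)
        assert (np.diff(evr) <= 1e-12).all()

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(8)
        props = pd.DataFrame(rng.normal(size=(40, 4)))
        load = solclust.pca_protein_properties(props)["loadings"].to_numpy()
        np.testing.assert_allclose(load.T @ load, np.eye(4), atol=1e-10)

    def test_sign_convention(self):
        rng = np.random.default_rng(9)
        props = pd.DataFrame(rng.normal(size=(40, 3)))
        load = solclust.pca_protein_properties(props)["loadings"].to_numpy()
        for j in range(load.shape[1]):
            assert load[np.argmax(np.abs(load[:, j])), j] > 0


class TestInteractionPairs:
    def test_basic(self):
        assert solclust.interaction_pairs(["A", "B", "C"], [("A", "B"), ("A", "D")]) == [("A", "B")]

    def test_empty_edges(self):
        assert solclust.interaction_pairs(["A", "B"], []) == []

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        proteins = [f"P{i}" for i in range(200)]
        changing = list(rng.choice(proteins, size=100, replace=False))
        edges = []
        for _ in range(500):
            a, b = rng.choice(proteins, size=2, replace=False)
            edges.append((a, b))
        result = solclust.interaction_pairs(changing, edges)
        # independent oracle: double loop over the deduplicated edge set
        members = set(changing)
        expected = set()
        for a, b in edges:
            if a in members and b in members:
                expected.add(tuple(sorted((a, b))))
        assert set(result) == expected
        assert len(result) == len(set(result))
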