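"""Ordination, supplementary projection, Ward clustering and attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import dungprint as dp
from dungprint.source_attribution import load_model, save_model


def frame(arr, prefix="v"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"obs{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


def eig_pca_oracle(X, standardize=True):
    """Independent PCA oracle: eigendecomposition of the covariance matrix."""
    X = np.asarray(X, dtype=float)
    Z = X - X.mean(axis=0)
    if standardize:
        Z = Z / X.std(axis=0, ddof=0)
    cov = Z.T @ Z / (len(X) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # Same sign convention as the implementation (tie-tolerant argmax).
    for j in range(evecs.shape[1]):
        mag = np.abs(evecs[:, j])
        i = int(np.flatnonzero(mag >= mag.max() * (1 - 1e-9))[0])
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
    return evals, evecs, Z @ evecs


def ward_heights_oracle(points):
    """Exhaustive greedy Ward: at each step merge the pair whose merge
    minimally increases total within-cluster sum of squares; heights in the
    Euclidean (square-root) form used by the implementation."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pa, pb = points[clusters[a]], points[clusters[b]]
                na, nb = len(pa), len(pb)
                delta = (
                    na * nb / (na + nb)
                    * float(((pa.mean(axis=0) - pb.mean(axis=0)) ** 2).sum())
                )
                if best is None or delta < best[0]:
                    best = (delta, a, b)
        delta, a, b = best
        heights.append(np.sqrt(2.0 * delta))
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return np.array(heights)


class TestFitPca:
    def test_collinear_points_put_all_variance_on_pc1(self):
        X = frame([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        model = dp.fit_pca(X, n_components=1)
        assert model.explained_variance[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle_on_toy_matrix(self):
        rng = np.random.default_rng(7)
        X = frame(rng.normal(size=(4, 3)))
        model = dp.fit_pca(X, n_components=3)
        evals, evecs, scores = eig_pca_oracle(X.to_numpy())
        assert np.allclose(model.loadings, evecs, atol=1e-8)
        assert np.allclose(model.training_scores.to_numpy(), scores, atol=1e-8)
        assert np.allclose(
            model.explained_variance, evals / evals.sum(), atol=1e-10
        )

    @given(
        X=arrays(
            float,
            (10, 4),
            elements=st.floats(min_value=-50, max_value=50, allow_nan=False),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_oracle_on_random_matrices(self, X):
        if np.any(X.std(axis=0, ddof=0) == 0):
            # Constant columns are rejected, not mis-fit.
            with pytest.raises(ValueError):
                dp.fit_pca(frame(X), n_components=4)
            return
        if np.any(X.std(axis=0, ddof=0) < 1e-6):
            return  # near-degenerate scaling: numerically ambiguous comparison
        evals, evecs, scores = eig_pca_oracle(X)
        if np.min(np.abs(np.diff(evals))) < 1e-6:
            return  # tied eigenvalues: component directions are not unique
        model = dp.fit_pca(frame(X), n_components=4)
        assert np.max(np.abs(model.training_scores.to_numpy() - scores)) < 1e-8
        assert np.max(np.abs(model.loadings - evecs)) < 1e-8

    def test_constant_variable_named_in_error(self):
        X = frame([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(ValueError, match="v0"):
            dp.fit_pca(X)

    def test_component_count_bounds(self):
        X = frame(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError, match="n_components"):
            dp.fit_pca(X, n_components=4)

    def test_sklearn_cross_check(self, dung_library):
        from sklearn.decomposition import PCA

        profiles = dp.zoostanol_profiles(dung_library)
        model = dp.fit_pca(profiles, n_components=4)
        Z = (profiles - profiles.mean()) / profiles.std(ddof=0)
        sk = PCA(n_components=4).fit(Z.to_numpy())
        # Compare up to sign per component.
        for j in range(4):
            ours, theirs = model.loadings[:, j], sk.components_[j]
            assert min(
                np.abs(ours - theirs).max(), np.abs(ours + theirs).max()
            ) < 1e-8


class TestProjectSupplementary:
    def test_training_samples_reproduce_training_scores(self, dung_library):
        profiles = dp.zoostanol_profiles(dung_library)
        model = dp.fit_pca(profiles, n_components=4)
        projected = dp.project_supplementary(model, profiles)
        assert np.max(np.abs(projected.to_numpy() - model.training_scores.to_numpy())) < 1e-9

    def test_center_vector_projects_to_origin(self, dung_library):
        profiles = dp.zoostanol_profiles(dung_library)
        model = dp.fit_pca(profiles, n_components=4)
        center = pd.DataFrame(
            [model.center_vector], columns=model.variable_names, index=["center"]
        )
        assert np.allclose(dp.project_supplementary(model, center).to_numpy(), 0.0, atol=1e-12)

    def test_hand_computed_projection(self):
        # Orthonormal 4x2 loading matrix picked by hand.
        loadings = np.array(
            [[0.5, 0.5], [0.5, -0.5], [0.5, 0.5], [0.5, -0.5]]
        )
        model = dp.OrdinationModel(
            variable_names=["a", "b", "c", "d"],
            center_vector=np.array([1.0, 1.0, 1.0, 1.0]),
            scale_vector=np.array([2.0, 2.0, 2.0, 2.0]),
            loadings=loadings,
            explained_variance=np.array([0.6, 0.4]),
            training_scores=pd.DataFrame(columns=["PC1", "PC2"]),
            n_components=2,
        )
        new = pd.DataFrame([[3.0, 1.0, 5.0, 1.0]], columns=list("abcd"), index=["x"])
        # standardized: (2,0,4,0)/2 = (1,0,2,0); scores = (1.5, 1.5)
        out = dp.project_supplementary(model, new)
        assert np.allclose(out.loc["x"], [1.5, 1.5])

    def test_variable_mismatch_lists_names(self, dung_library):
        profiles = dp.zoostanol_profiles(dung_library)
        model = dp.fit_pca(profiles, n_components=2)
        bad = profiles.rename(columns={"coprostanol": "something_else"})
        with pytest.raises(ValueError, match="coprostanol"):
            dp.project_supplementary(model, bad)


class TestHcpc:
    def test_two_separated_clouds_auto_k(self):
        rng = np.random.default_rng(3)
        cloud_a = rng.normal(0.0, 0.1, size=(8, 2))
        cloud_b = rng.normal(5.0, 0.1, size=(8, 2)) + np.array([0.0, 5.0])
        scores = frame(np.vstack([cloud_a, cloud_b]), prefix="PC")
        scores.columns = ["PC1", "PC2"]
        model = dp.hcpc_cluster(scores)
        assert model.k == 2
        labels = model.assignments.to_numpy()
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[-1]

    @given(
        pts=arrays(
            float,
            (4, 2),
            elements=st.floats(min_value=-10, max_value=10, allow_nan=False),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_four_point_dendrogram_matches_exhaustive_ward(self, pts):
        # Skip near-coincident points where merge order is numerically ambiguous.
        from scipy.spatial.distance import pdist

        if np.min(pdist(pts)) < 1e-3:
            return
        scores = frame(pts, prefix="PC")
        scores.columns = ["PC1", "PC2"]
        model = dp.hcpc_cluster(scores, k=2)
        assert np.allclose(
            np.sort(model.merge_history[:, 2]),
            np.sort(ward_heights_oracle(pts)),
            rtol=1e-8,
        )

    def test_k_bounds(self):
        scores = frame(np.random.default_rng(0).normal(size=(5, 2)), prefix="PC")
        scores.columns = ["PC1", "PC2"]
        with pytest.raises(ValueError):
            dp.hcpc_cluster(scores, k=1)
        with pytest.raises(ValueError):
            dp.hcpc_cluster(scores, k=5)

    def test_singleton_centroid_equals_its_score(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0]])
        scores = frame(pts, prefix="PC")
        scores.columns = ["PC1", "PC2"]
        model = dp.hcpc_cluster(scores, k=2)
        singleton = model.assignments.value_counts().idxmin()
        member = model.assignments[model.assignments == singleton].index[0]
        assert np.allclose(model.centroids.loc[singleton], scores.loc[member])

    def test_reference_library_forms_three_species_groups(self, dung_library, reference_model):
        _, clusters = reference_model
        species = dung_library.species_labels()
        by_cluster = {
            cid: set(species[clusters.assignments == cid].unique())
            for cid in range(1, 4)
        }
        groups = sorted(by_cluster.values(), key=lambda s: sorted(s))
        assert groups == sorted(
            [{"bison", "elk"}, {"moose"}, {"mule_deer", "pronghorn"}],
            key=lambda s: sorted(s),
        )


class TestAttribution:
    def test_sample_at_centroid_has_zero_distance(self, dung_library, reference_model):
        model, clusters = reference_model
        # Invert the standardization to place a profile exactly on a centroid.
        target = clusters.centroids.loc[2].to_numpy()
        profile = model.center_vector + model.scale_vector * (
            model.loadings @ target
        )
        sed = pd.DataFrame([profile], columns=model.variable_names, index=["at_c2"])
        out = dp.attribute_sediments(model, clusters, sed)
        assert out.loc["at_c2", "dist_to_cluster_2"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc["at_c2", "nearest_cluster"] == 2

    def test_three_four_five_distance(self):
        scores = frame([[1.0, 2.0], [4.0, 6.0]], prefix="PC")
        scores.columns = ["PC1", "PC2"]
        d = np.linalg.norm(scores.iloc[0] - scores.iloc[1])
        assert d == pytest.approx(5.0)

    def test_distances_invariant_to_global_sign_flip(self, dung_library, reference_model):
        model, clusters = reference_model
        sed, _ = dp.generate_sediment_core(dp.CoreScenario(seed=5))
        prof = dp.zoostanol_profiles(sed)
        base = dp.attribute_sediments(model, clusters, prof)
        flipped_model = dp.OrdinationModel(
            variable_names=model.variable_names,
            center_vector=model.center_vector,
            scale_vector=model.scale_vector,
            loadings=-model.loadings,
            explained_variance=model.explained_variance,
            training_scores=-model.training_scores,
            n_components=model.n_components,
        )
        flipped_clusters = dp.ClusterModel(
            merge_history=clusters.merge_history,
            k=clusters.k,
            assignments=clusters.assignments,
            centroids=-clusters.centroids,
        )
        flipped = dp.attribute_sediments(flipped_model, flipped_clusters, prof)
        dist_cols = [c for c in base.columns if c.startswith("dist_")]
        assert np.allclose(base[dist_cols], flipped[dist_cols], atol=1e-9)
        assert (base["nearest_cluster"] == flipped["nearest_cluster"]).all()

    def test_empty_sediment_set_gives_empty_series(self, reference_model):
        model, clusters = reference_model
        empty = pd.DataFrame(columns=model.variable_names)
        out = dp.attribute_sediments(model, clusters, empty)
        assert len(out) == 0
        assert "nearest_cluster" in out.columns

    def test_default_scenario_attributes_to_bison_elk_cluster(
        self, dung_library, reference_model
    ):
        model, clusters = reference_model
        species = dung_library.species_labels()
        bison_elk = clusters.assignments[species == "bison"].mode()[0]
        sed, am = dp.generate_sediment_core(dp.CoreScenario(seed=9))
        out = dp.attribute_sediments(
            model, clusters, dp.zoostanol_profiles(sed),
            age_model=am, depths=sed.meta["depth_cm"],
        )
        assert (out["nearest_cluster"] == bison_elk).all()
        assert out["age_cal_BP"].is_monotonic_increasing


class TestModelPersistence:
    def test_save_load_roundtrip_preserves_attribution(self, tmp_path, reference_model):
        model, clusters = reference_model
        path = tmp_path / "model.txt"
        save_model(model, clusters, path)
        model2, clusters2 = load_model(path)
        sed, _ = dp.generate_sediment_core(dp.CoreScenario(seed=21))
        prof = dp.zoostanol_profiles(sed)
        a = dp.attribute_sediments(model, clusters, prof)
        b = dp.attribute_sediments(model2, clusters2, prof)
        pd.testing.assert_frame_equal(a, b)
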