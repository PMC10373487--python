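"""PCA map fitting, loadings, correlation, graphs, charts, classification."""

import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cgslatm import (
    SelectivityMap,
    SelectivityMapResults,
    build_interaction_graph,
    default_cg_registry,
    write_dot,
    write_graphml,
)

def keys_for(d):
    return tuple((f"X{i}", f"X{i}") for i in range(d))


def fit(X, d, seed=0, **kw):
    return SelectivityMap(X, keys_for(X.shape[1]), **kw).fit(d, seed=seed)


class TestFitPca:
    def test_rank_one_data_explains_everything_first(self, rng):
        direction = rng.normal(size=5)
        X = np.outer(rng.normal(size=30), direction)
        res = fit(X, 2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_2d_gaussian_variance_ratio_4_to_1(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(10000, 2)) * [2.0, 1.0]
        res = fit(X, 2)
        assert res.explained_variance_ratio[0] == pytest.approx(0.8, abs=0.02)
        assert res.explained_variance_ratio[1] == pytest.approx(0.2, abs=0.02)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(12, 6))
        res = fit(X, 6)
        np.testing.assert_allclose(res.reconstruct(), X, atol=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit(np.ones((5, 3)), 2)

    def test_explained_ratios_sum_to_one_at_full_rank(self, rng):
        X = rng.normal(size=(20, 4))
        res = fit(X, 4)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scores_have_zero_column_means(self, rng):
        X = rng.normal(size=(40, 8))
        res = fit(X, 4)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_eigenvectors_orthonormal(self, rng):
        X = rng.normal(size=(30, 6))
        res = fit(X, 5)
        np.testing.assert_allclose(
            res.components @ res.components.T, np.eye(5), atol=1e-10
        )

    def test_covariance_backtransform_identity(self, rng):
        # cov(X_c, Y_k) = lambda_k * v_kc on synthetic data
        X = rng.normal(size=(300, 5)) @ rng.normal(size=(5, 5))
        res = fit(X, 5)
        Xc = X - X.mean(axis=0)
        for k in range(5):
            cov = (Xc * res.scores[:, [k]]).sum(axis=0) / (len(X) - 1)
            np.testing.assert_allclose(
                cov, res.eigenvalues[k] * res.components[k], atol=1e-8
            )

    def test_determinism_bit_identical_model_files(self, rng, tmp_path):
        X = rng.normal(size=(50, 30))
        fit(X, 6, seed=7).save(tmp_path / "a.json")
        fit(X, 6, seed=7).save(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_randomized_solver_is_seeded_and_sign_fixed(self, rng):
        X = rng.normal(size=(60, 40))
        a = SelectivityMap(X, keys_for(40)).fit(3, seed=5, svd_solver="randomized")
        b = SelectivityMap(X, keys_for(40)).fit(3, seed=5, svd_solver="randomized")
        np.testing.assert_array_equal(a.components, b.components)
        for k in range(3):
            j = np.argmax(np.abs(a.components[k]))
            assert a.components[k, j] > 0


class TestProject:
    def test_training_rows_project_to_stored_scores(self, rng):
        X = rng.normal(size=(15, 6))
        res = fit(X, 4)
        np.testing.assert_allclose(res.project(X), res.scores, atol=1e-10)

    def test_column_means_project_to_origin(self, rng):
        X = rng.normal(size=(15, 6))
        res = fit(X, 4)
        np.testing.assert_allclose(res.project(X.mean(axis=0)), 0.0, atol=1e-10)

    def test_held_out_vector_matches_dense_oracle(self, rng):
        X = rng.normal(size=(15, 6))
        res = fit(X, 3)
        new = rng.normal(size=6)
        want = res.components @ (new - X.mean(axis=0))
        np.testing.assert_allclose(res.project(new), want, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        res = fit(rng.normal(size=(10, 4)), 2)
        with pytest.raises(ValueError, match="dimension"):
            res.project(np.ones(5))


class TestScaledLoadings:
    def test_unit_eigenvalue_leaves_loadings_raw(self, rng):
        X = rng.normal(size=(2000, 3))  # unit variances: lambda ~ 1
        res = fit(X, 3)
        tab = res.scaled_loadings(0)
        ratio = tab["scaled_loading"] / tab["loading"]
        np.testing.assert_allclose(
            ratio, np.sqrt(res.eigenvalues[0]), rtol=1e-12
        )

    def test_hand_built_model_scaled_loadings(self):
        res = SelectivityMapResults(
            model=SelectivityMap(np.zeros((2, 3)), ("a", "b", "c")),
            column_means=np.zeros(3),
            eigenvalues=np.array([4.0]),
            components=np.array([[0.6, 0.0, 0.8]]),
            scores=np.zeros((2, 1)),
            explained_variance_ratio=np.array([1.0]),
        )
        tab = res.scaled_loadings(0)
        assert list(tab["channel"]) == ["c", "a", "b"]  # by |v * sqrt(4)|
        assert list(tab["scaled_loading"]) == [1.6, 1.2, 0.0]

    def test_equal_magnitudes_tie_break_lexicographic(self):
        res = SelectivityMapResults(
            model=SelectivityMap(np.zeros((2, 3)), ("b", "a", "c")),
            column_means=np.zeros(3),
            eigenvalues=np.array([1.0]),
            components=np.array([[0.5, 0.5, 0.5]]),
            scores=np.zeros((2, 1)),
            explained_variance_ratio=np.array([1.0]),
        )
        assert list(res.scaled_loadings(0)["channel"]) == ["a", "b", "c"]


class TestCorrelate:
    def test_proportional_descriptor_r2_one(self, rng):
        X = rng.normal(size=(50, 4))
        res = fit(X, 2)
        corr = res.correlate(0, 3.0 * res.scores[:, 0])
        assert corr.r2 == pytest.approx(1.0, abs=1e-12)
        assert corr.slope > 0

    def test_orthogonal_descriptor_r2_zero(self, rng):
        X = rng.normal(size=(60, 4))
        res = fit(X, 2)
        y = rng.normal(size=60)
        s = res.scores[:, 0]
        y -= y.mean() + (y - y.mean()) @ s / (s @ s) * 0  # center only
        y_orth = y - (y @ s) / (s @ s) * s
        assert res.correlate(0, y_orth).r2 == pytest.approx(0.0, abs=1e-12)

    def test_noise_to_signal_quarter_gives_r2_point8(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        noise = rng.normal(size=5000) * 1.0  # var(noise)/var(2x) = 1/4
        X = np.column_stack([x, rng.normal(size=5000) * 0.01])
        res = fit(X, 1)
        sgn = np.sign(res.components[0, 0])
        y = 2 * sgn * x + noise
        assert res.correlate(0, y).r2 == pytest.approx(0.8, abs=0.03)

    def test_zero_variance_descriptor_rejected(self, rng):
        res = fit(rng.normal(size=(10, 3)), 2)
        with pytest.raises(ValueError, match="variance"):
            res.correlate(0, np.ones(10))


class TestDominantInteractions:
    @staticmethod
    def planted_results():
        comps = np.zeros((1, 4))
        comps[0] = [0.05, -0.9, 0.1, 0.42]
        comps[0] /= np.linalg.norm(comps[0])
        return SelectivityMapResults(
            model=SelectivityMap(
                np.zeros((2, 4)),
                (("T1", "T1"), ("Q0", "Nda"), ("T2", "P4"), ("T3", "T4")),
            ),
            column_means=np.zeros(4),
            eigenvalues=np.array([9.0]),
            components=comps,
            scores=np.zeros((2, 1)),
            explained_variance_ratio=np.array([1.0]),
        )

    def test_planted_negative_loading_found(self):
        res = self.planted_results()
        assert res.dominant_interactions(0, sign="negative") == [("Q0", "Nda")]

    def test_high_threshold_empty(self):
        res = self.planted_results()
        assert res.dominant_interactions(0, threshold=100.0) == []

    def test_both_signs_sorted_by_magnitude(self):
        res = self.planted_results()
        got = res.dominant_interactions(0, threshold=1.0, sign="both")
        assert got[0] == ("Q0", "Nda")
        assert ("T3", "T4") in got


class TestInteractionGraph:
    def test_single_two_body_channel(self):
        g = build_interaction_graph([("Q0", "Nda")], default_cg_registry())
        assert g.number_of_edges() == 1
        assert g["Q0"]["Nda"]["weight"] == 1
        assert g.nodes["Q0"]["category"] == "solute"
        assert g["Q0"]["Nda"]["kind"] == "solute-environment"

    def test_three_body_projects_onto_center_edges(self):
        reg = default_cg_registry()
        g = build_interaction_graph(
            [("Q0", "Nda"), ("Nda", ("Q0", "T3"))], reg
        )
        assert g["Q0"]["Nda"]["weight"] == 2
        assert g["Nda"]["T3"]["weight"] == 1
        assert not g.has_edge("Q0", "T3")
        g2 = build_interaction_graph(
            [("Nda", ("Q0", "T3"))], reg, include_pair_leg=True
        )
        assert g2.has_edge("Q0", "T3")

    def test_empty_channel_list_empty_graph(self):
        g = build_interaction_graph([], default_cg_registry())
        assert g.number_of_nodes() == 0

    def test_unknown_type_rejected(self):
        with pytest.raises(KeyError):
            build_interaction_graph([("ZZ", "Nda")], default_cg_registry())

    def test_exports(self, tmp_path):
        g = build_interaction_graph(
            [("Q0", "Nda"), ("POL", ("Q0", "Q0"))], default_cg_registry()
        )
        write_graphml(g, tmp_path / "g.graphml")
        write_dot(g, tmp_path / "g.dot")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_edges() == g.number_of_edges()
        assert "penwidth" in (tmp_path / "g.dot").read_text()


class TestChartMap:
    def test_default_six_arrows_two_body_only(self, rng):
        d = 10
        keys = tuple(
            [("A", "B")] * 0
            + [(f"T{i}", f"T{i}") for i in range(1, 6)]
            + [(f"T{i}", (f"T{i}", f"T{i}")) for i in range(1, 6)]
        )
        X = rng.normal(size=(30, d))
        res = SelectivityMap(X, keys).fit(3, seed=0)
        bundle = res.chart_map(0, 1)
        assert len(bundle["arrows"]) <= 6
        assert all("|" not in c for c in bundle["arrows"]["channel"])
        assert bundle["points"]["x"].min() == pytest.approx(-1.0)
        assert bundle["points"]["x"].max() == pytest.approx(1.0)

    def test_symmetric_data_symmetric_scaled_scores(self, rng):
        half = rng.normal(size=(20, 5))
        X = np.vstack([half, -half])
        res = fit(X, 2)
        bundle = res.chart_map(0, 1)
        xs = np.sort(bundle["points"]["x"].to_numpy())
        np.testing.assert_allclose(xs + xs[::-1], 0.0, atol=1e-10)

    def test_same_axis_rejected(self, rng):
        res = fit(rng.normal(size=(10, 4)), 2)
        with pytest.raises(ValueError):
            res.chart_map(1, 1)

    def test_degenerate_axis_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        res = fit(X, 3)
        res.scores[:, 2] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            res.chart_map(0, 2)


class TestClassifyNew:
    @staticmethod
    def basins(n=40, gap=4.0, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([[-gap, 0.0], [gap, 0.0]])
        labels = np.repeat(["selective", "non-selective"], n // 2)
        pts = np.vstack(
            [
                centers[0] + rng.normal(scale=0.4, size=(n // 2, 2)),
                centers[1] + rng.normal(scale=0.4, size=(n // 2, 2)),
            ]
        )
        # embed the 2-D basins into a 5-channel space
        emb = np.zeros((n, 5))
        emb[:, 1] = pts[:, 0]
        emb[:, 3] = pts[:, 1]
        emb += rng.normal(scale=0.01, size=emb.shape)
        return emb, labels

    def test_separable_basins_recover_all_training_labels(self):
        X, labels = self.basins()
        res = fit(X, 2)
        got, coords, coef = res.classify_new(0, 1, labels, X)
        assert (got == labels).all()

    def test_training_point_classifies_as_itself(self):
        X, labels = self.basins()
        res = fit(X, 2)
        lab, coord, _ = res.classify_new(0, 1, labels, X[0])
        assert lab == labels[0]
        np.testing.assert_allclose(coord, res.scores[0, :2], atol=1e-10)

    def test_boundary_point_is_non_selective(self):
        X, labels = self.basins()
        res = fit(X, 2)
        _, _, coef = res.classify_new(0, 1, labels, X[0])
        # construct a vector projecting exactly onto the boundary (h = 0)
        a, b, c = coef
        y = np.array([0.0, 0.0])
        y[0] = -c / a if a != 0 else 0.0
        vec = res.column_means + y @ res.components[:2]
        lab, _, _ = res.classify_new(0, 1, labels, vec)
        assert lab == "non-selective"

    def test_single_class_rejected(self):
        X, labels = self.basins()
        res = fit(X, 2)
        with pytest.raises(ValueError, match="single class"):
            res.classify_new(0, 1, ["selective"] * len(X), X[0])


class TestSummaryAndPersistence:
    def test_summary_mentions_dimensions_and_descriptors(self, rng):
        X = rng.normal(size=(25, 6))
        desc = pd.DataFrame({"ddG": rng.normal(size=25)})
        res = SelectivityMap(X, keys_for(6), descriptors=desc).fit(3, seed=0)
        text = res.summary()
        assert "compounds: 25" in text
        assert "ddG" in text

    def test_save_load_roundtrip(self, rng, tmp_path):
        X = rng.normal(size=(12, 5))
        res = fit(X, 3, seed=2)
        res.save(tmp_path / "m.json")
        back = SelectivityMapResults.load(tmp_path / "m.json")
        np.testing.assert_array_equal(back.components, res.components)
        np.testing.assert_array_equal(back.scores, res.scores)
        assert back.seed == 2

    def test_one_body_share_diagnostic(self):
        res = SelectivityMapResults(
            model=SelectivityMap(np.zeros((2, 3)), ("T1", ("T1", "T1"), ("T1", ("T1", "T1")))),
            column_means=np.zeros(3),
            eigenvalues=np.array([1.0]),
            components=np.array([[0.1, 0.7, 0.7071067]]),
            scores=np.zeros((2, 1)),
            explained_variance_ratio=np.array([1.0]),
        )
        assert res.one_body_share(0) == pytest.approx(0.01, abs=1e-3)
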