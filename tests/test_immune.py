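"""Immune-state modeling: fractions, clustering, labels, change rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from imd.immune import (
    STATE_RANK,
    assign_state_labels,
    build_immune_feature_matrix,
    classify_immune_change,
    cluster_immune_states,
    estimate_cell_fractions,
    immune_profile,
)
from imd.io import ExpressionMatrix


@pytest.fixture()
def signature_matrix():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(60)]
    S = pd.DataFrame(rng.uniform(0, 1, size=(60, 3)), index=genes,
                     columns=["typeA", "typeB", "typeC"])
    # distinct marker blocks keep the matrix well conditioned
    S.iloc[:20, 0] += 50
    S.iloc[20:40, 1] += 50
    S.iloc[40:, 2] += 50
    return S


class TestCellFractions:
    def test_pure_signature_column_gets_fraction_one(self, signature_matrix):
        bulk = ExpressionMatrix(signature_matrix[["typeB"]].rename(
            columns={"typeB": "s"}), scale="linear")
        frac = estimate_cell_fractions(bulk, signature_matrix)
        assert frac.loc["s", "typeB"] == pytest.approx(1.0, abs=1e-6)
        assert frac.loc["s", ["typeA", "typeC"]].abs().max() < 1e-6

    def test_even_mixture_recovered(self, signature_matrix):
        mix = 0.5 * signature_matrix["typeA"] + 0.5 * signature_matrix["typeC"]
        bulk = ExpressionMatrix(mix.to_frame("s"), scale="linear")
        frac = estimate_cell_fractions(bulk, signature_matrix)
        assert frac.loc["s", "typeA"] == pytest.approx(0.5, abs=1e-6)
        assert frac.loc["s", "typeC"] == pytest.approx(0.5, abs=1e-6)

    def test_signal_free_bulk_is_all_other(self, signature_matrix):
        sig = signature_matrix.copy()
        sig.iloc[50:] = 0.0  # leave genes the signatures do not explain
        bulk_vals = pd.Series(0.0, index=sig.index)
        bulk_vals.iloc[50:] = 100.0
        bulk = ExpressionMatrix(bulk_vals.to_frame("s"), scale="linear")
        frac = estimate_cell_fractions(bulk, sig)
        assert frac.loc["s", ["typeA", "typeB", "typeC"]].sum() < 1e-6
        assert frac.loc["s", "other"] == pytest.approx(1.0, abs=1e-6)

    def test_fraction_sums_bounded_by_one(self, default_cohort):
        expr, _, truth = default_cohort
        frac = estimate_cell_fractions(expr.to_linear(), truth.signature_matrix)
        cell_cols = [c for c in frac.columns if c != "other"]
        assert (frac[cell_cols].sum(axis=1) <= 1 + 1e-9).all()
        assert (frac >= 0).all().all()

    def test_rank_deficient_signatures_rejected(self, signature_matrix):
        sig = signature_matrix.copy()
        sig["typeC"] = sig["typeA"] * 2.0
        bulk = ExpressionMatrix(signature_matrix[["typeA"]].rename(
            columns={"typeA": "s"}), scale="linear")
        with pytest.raises(ValueError, match="typeA.*typeC|typeC.*typeA"):
            estimate_cell_fractions(bulk, sig)


class TestFeatureMatrix:
    def test_concatenation_and_standardization(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(8)]
        fractions = pd.DataFrame(rng.uniform(size=(8, 2)), index=samples,
                                 columns=["A", "B"])
        scores = pd.DataFrame(rng.normal(size=(3, 8)),
                              index=["x", "y", "z"], columns=samples)
        feats = build_immune_feature_matrix(fractions, scores)
        assert feats.shape == (8, 5)
        assert np.abs(feats.mean()).max() < 1e-12
        assert np.allclose(feats.std(ddof=1), 1.0, atol=1e-9)

    def test_constant_feature_dropped(self, caplog):
        samples = ["a", "b", "c", "d"]
        fractions = pd.DataFrame({"A": [0.5] * 4, "B": [0.1, 0.2, 0.3, 0.4]},
                                 index=samples)
        scores = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["x"],
                              columns=samples)
        with caplog.at_level("WARNING", logger="imd"):
            feats = build_immune_feature_matrix(fractions, scores)
        assert list(feats.columns) == ["frac_B", "sig_x"]

    def test_disjoint_samples_rejected(self):
        fractions = pd.DataFrame({"A": [1.0]}, index=["s1"])
        scores = pd.DataFrame([[1.0]], index=["x"], columns=["s2"])
        with pytest.raises(ValueError, match="no sample ids"):
            build_immune_feature_matrix(fractions, scores)


class TestClustering:
    def _blobs(self, seed=0, sep=6.0, n_per=40):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0, 0], [sep, 0, 0], [0, sep, 0]], dtype=float)
        X = np.vstack([c + rng.normal(size=(n_per, 3)) for c in centers])
        labels = np.repeat([0, 1, 2], n_per)
        idx = [f"s{i}" for i in range(len(X))]
        return pd.DataFrame(X, index=idx), pd.Series(labels, index=idx)

    def test_recovers_three_separated_classes(self):
        X, labels = self._blobs()
        model = cluster_immune_states(X, k_range=(2, 3, 4, 5, 6), n_latent=3,
                                      seed=0)
        assert model.n_clusters == 3
        assert adjusted_rand_score(labels, model.assignments) == 1.0

    def test_identical_points_select_smallest_k(self):
        X = pd.DataFrame(np.zeros((30, 3)), index=[f"s{i}" for i in range(30)])
        model = cluster_immune_states(X, k_range=(2, 3), seed=0)
        assert model.n_clusters == 2

    def test_seed_determinism(self):
        X, _ = self._blobs(seed=3)
        a = cluster_immune_states(X, seed=4)
        b = cluster_immune_states(X, seed=4)
        assert a.assignments.equals(b.assignments)

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError, match="too few"):
            cluster_immune_states(X, k_range=(2, 6))

    def test_invalid_k_rejected(self):
        X, _ = self._blobs()
        with pytest.raises(ValueError, match="k >= 1"):
            cluster_immune_states(X, k_range=(0, 3))


class TestLabels:
    def _model_with_assignments(self, assign, k):
        from imd.immune import ClusteringModel
        probs = pd.DataFrame(0.0, index=assign.index, columns=range(k))
        for s, c in assign.items():
            probs.loc[s, c] = 1.0
        return ClusteringModel(k, assign, probs, {k: 0.0}, np.zeros((k, 2)), 0)

    def test_score_ordering_defines_cold_warm_hot(self):
        assign = pd.Series([0, 1, 2, 0, 1, 2],
                           index=[f"s{i}" for i in range(6)])
        score = pd.Series([-1, 0, 2, -1, 0, 2.0],
                          index=[f"s{i}" for i in range(6)])
        labels = assign_state_labels(self._model_with_assignments(assign, 3), score)
        assert labels.loc["s0", "state"] == "cold"
        assert labels.loc["s1", "state"] == "warm"
        assert labels.loc["s2", "state"] == "hot"

    def test_labeling_invariant_to_cluster_relabeling(self):
        assign = pd.Series([0, 1, 2, 0, 1, 2],
                           index=[f"s{i}" for i in range(6)])
        score = pd.Series([-1, 0, 2, -1, 0, 2.0], index=assign.index)
        base = assign_state_labels(self._model_with_assignments(assign, 3), score)
        relabeled = assign.map({0: 2, 1: 0, 2: 1})
        out = assign_state_labels(
            self._model_with_assignments(relabeled, 3), score)
        assert (out["state"] == base["state"]).all()

    def test_k4_uses_generic_state_names(self):
        assign = pd.Series([0, 1, 2, 3] * 2, index=[f"s{i}" for i in range(8)])
        score = pd.Series([0.0, 1, 2, 3] * 2, index=assign.index)
        labels = assign_state_labels(self._model_with_assignments(assign, 4), score)
        assert set(labels["state"]) == {"state_1", "state_2", "state_3", "state_4"}

    def test_tied_means_broken_by_size_with_warning(self, caplog):
        assign = pd.Series([0, 0, 0, 1, 1, 2],
                           index=[f"s{i}" for i in range(6)])
        score = pd.Series([1.0, 1.0, 1.0, 1.0, 1.0, 5.0], index=assign.index)
        with caplog.at_level("WARNING", logger="imd"):
            labels = assign_state_labels(
                self._model_with_assignments(assign, 3), score)
        assert any("tie" in r.message.lower() for r in caplog.records)
        # the larger of the tied clusters ranks higher
        assert labels.loc["s0", "state"] == "warm"
        assert labels.loc["s3", "state"] == "cold"


class TestChangeRule:
    def test_exhaustive_truth_table(self):
        expected = {
            ("cold", "cold"): "negative",
            ("cold", "warm"): "positive",
            ("cold", "hot"): "positive",
            ("warm", "cold"): "negative",
            ("warm", "warm"): "positive",
            ("warm", "hot"): "positive",
            ("hot", "cold"): "negative",
            ("hot", "warm"): "negative",
            ("hot", "hot"): "positive",
        }
        for (pre, later), want in expected.items():
            assert classify_immune_change(pre, later) == want

    def test_total_on_all_label_pairs(self):
        for pre, later in itertools.product(STATE_RANK, repeat=2):
            assert classify_immune_change(pre, later) in ("negative", "positive")

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            classify_immune_change("cold", "lukewarm")


class TestEndToEnd:
    def test_default_cohort_recovery(self, default_cohort):
        expr, _, truth = default_cohort
        profile, model = immune_profile(
            expr, truth.signature_matrix, truth.immune_signatures,
            activation_set="adaptive_immune", seed=7)
        assert model.n_clusters == 3
        ari = adjusted_rand_score(
            truth.samples["immune_class"],
            profile.labels.reindex(truth.samples.index))
        assert ari >= 0.9
        # the hot label lands on the class with the highest simulated
        # immune-signature expression
        sig = truth.immune_signatures["adaptive_immune"]
        means = expr.values.loc[sig].mean().groupby(
            profile.labels.reindex(truth.samples.index)).mean()
        assert means.idxmax() == "hot"
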