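"""Association layer: mixed models, ANOVA, correlations, k-core pruning."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from imd.simulate import simulate_interaction_cohort, simulate_longitudinal_scores
from imd.stats import (
    correlation_network,
    fit_longitudinal_lmem,
    fit_state_interaction_lmem,
    k_core_prune,
    spearman_matrix,
    two_way_anova_interaction,
)


class TestInteractionLmem:
    def test_recovers_negative_interaction(self):
        df = simulate_interaction_cohort(beta1=-0.4, n_patients=60, seed=1)
        res = fit_state_interaction_lmem(df)
        assert res.coefficients["_M"] < 0
        assert res.p_values["_M"] < 0.01
        assert res.random_intercept_var >= 0
        assert res.lrt_stat >= 0

    def test_label_and_numeric_encodings_agree(self):
        df = simulate_interaction_cohort(beta1=-0.3, n_patients=20, seed=2)
        coded = fit_state_interaction_lmem(df)
        lab = df.copy()
        lab["metabolic_state"] = lab["metabolic_state"].map(
            {-1: "down", 0: "neutral", 1: "up"})
        labeled = fit_state_interaction_lmem(lab)
        assert labeled.coefficients["_M"] == pytest.approx(
            coded.coefficients["_M"], abs=1e-8)

    def test_single_observation_per_patient_falls_back_to_ols(self, caplog):
        df = simulate_interaction_cohort(beta1=-0.3, n_patients=40,
                                         n_timepoints=1, seed=3)
        with caplog.at_level("WARNING", logger="imd"):
            res = fit_state_interaction_lmem(df)
        assert res.fallback_ols
        # matches a plain least-squares fit
        import statsmodels.formula.api as smf
        df2 = df.rename(columns={"immune_state": "I", "metabolic_state": "M"})
        ols = smf.ols("I ~ M + C(subtype)", df2).fit()
        assert res.coefficients["_M"] == pytest.approx(ols.params["M"], abs=1e-6)

    def test_zero_random_effect_estimated_near_zero(self):
        df = simulate_interaction_cohort(beta1=0.0, n_patients=60,
                                         random_intercept_sd=0.0, seed=4)
        res = fit_state_interaction_lmem(df)
        assert res.random_intercept_var < 0.05

    def test_cellularity_adjustment_accepted(self):
        df = simulate_interaction_cohort(beta1=-0.3, n_patients=20, seed=5)
        df["cellularity"] = np.random.default_rng(0).uniform(0.2, 0.8, len(df))
        res = fit_state_interaction_lmem(df, cellularity_col="cellularity")
        assert "cellularity" in res.coefficients.index


class TestLongitudinalLmem:
    def test_time_effect_detected_by_lrt(self):
        df = simulate_longitudinal_scores(beta_time=0.5, n_patients=60, seed=1)
        res = fit_longitudinal_lmem(df)
        assert res.lrt_df == 1
        assert res.lrt_p < 0.05

    def test_time_effect_power_at_stated_scale(self):
        hits = 0
        for seed in range(20):
            df = simulate_longitudinal_scores(beta_time=0.5, n_patients=60,
                                              seed=seed)
            hits += fit_longitudinal_lmem(df).lrt_p < 0.05
        assert hits / 20 >= 0.8

    def test_identical_scores_give_zero_lrt(self):
        df = simulate_longitudinal_scores(seed=2)
        df["score"] = 1.0
        res = fit_longitudinal_lmem(df)
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-6)

    def test_pre_is_reference_level(self):
        df = simulate_longitudinal_scores(seed=3)
        res = fit_longitudinal_lmem(df)
        assert res.encoding["time_levels"][0] == "pre"
        assert not any("pre" in c and "T.pre" in c
                       for c in res.coefficients.index)


class TestAnova:
    def test_pure_interaction_detected(self):
        rows = []
        rng = np.random.default_rng(0)
        for g in ("neg", "pos"):
            for t in ("pre", "on"):
                effect = 1.0 if (g == "pos") == (t == "on") else -1.0
                for _ in range(10):
                    rows.append({"score": effect + rng.normal(0, 0.3),
                                 "group": g, "time": t})
        res = two_way_anova_interaction(pd.DataFrame(rows))
        assert res["p"] < 0.01

    def test_additive_only_data_not_flagged(self):
        rng = np.random.default_rng(1)
        ps = []
        for rep in range(30):
            rows = []
            for g in ("neg", "pos"):
                for t in ("pre", "on"):
                    mu = (g == "pos") * 1.0 + (t == "on") * 0.5
                    for _ in range(8):
                        rows.append({"score": mu + rng.normal(0, 0.5),
                                     "group": g, "time": t})
            ps.append(two_way_anova_interaction(pd.DataFrame(rows))["p"])
        # roughly uniform: around 5% of replicates under 0.05
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_constant_data_yields_f_zero_p_one(self):
        rows = [{"score": 2.0, "group": g, "time": t}
                for g in "ab" for t in "xy" for _ in range(3)]
        res = two_way_anova_interaction(pd.DataFrame(rows))
        assert res["F"] == 0.0
        assert res["p"] == 1.0

    def test_empty_cell_named_in_error(self):
        rows = [{"score": 1.0, "group": g, "time": t}
                for g, t in [("a", "x"), ("a", "x"), ("a", "y"), ("a", "y"),
                             ("b", "x"), ("b", "x")]]
        with pytest.raises(ValueError, match="b.*y"):
            two_way_anova_interaction(pd.DataFrame(rows))


class TestSpearman:
    def test_monotone_relations(self):
        x = np.linspace(-2, 2, 20)
        feats = pd.DataFrame({"x": x, "lin": x, "cube": -(x ** 3)})
        rho, p = spearman_matrix(feats)
        assert rho.loc["x", "lin"] == pytest.approx(1.0)
        assert rho.loc["x", "cube"] == pytest.approx(-1.0)
        assert (np.diag(rho) == 1.0).all()

    def test_tied_data_matches_midrank_oracle(self):
        x = pd.Series([1, 2, 2, 3, 3, 3, 4, 5, 5, 6.0])
        y = pd.Series([2, 1, 3, 3, 5, 4, 4, 6, 7, 7.0])
        feats = pd.DataFrame({"x": x, "y": y})
        rho, _ = spearman_matrix(feats)
        # Spearman = Pearson on midranks
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(oracle, abs=1e-12)

    def test_spearman_equals_pearson_on_ranks_random(self):
        rng = np.random.default_rng(2)
        feats = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        rho, _ = spearman_matrix(feats)
        for i, j in itertools.combinations("abc", 2):
            oracle = np.corrcoef(sps.rankdata(feats[i]),
                                 sps.rankdata(feats[j]))[0, 1]
            assert rho.loc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_constant_feature_reported_missing(self):
        feats = pd.DataFrame({"x": [1, 2, 3, 4.0], "c": [5, 5, 5, 5.0]})
        rho, p = spearman_matrix(feats)
        assert np.isnan(rho.loc["c", "x"])
        assert np.isnan(rho.loc["c", "c"])


class TestNetwork:
    def test_perfect_correlation_edge(self):
        x = np.arange(10.0)
        mat = pd.DataFrame({"s" + str(i): [x[i], 2 * x[i], -5.0]
                            for i in range(10)},
                           index=["f1", "f2", "const"])
        g = correlation_network(mat, threshold=0.3)
        assert g.has_edge("f1", "f2")
        assert g.edges["f1", "f2"]["r"] == pytest.approx(1.0)
        assert g.degree["const"] == 0

    def test_impossible_threshold_gives_empty_edges(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(4, 20)))
        g = correlation_network(mat, threshold=1.01)
        assert g.number_of_edges() == 0

    def test_null_edge_density_matches_theory(self):
        # independent gaussians, n = 200: P(|r| >= 0.3) from the exact
        # null distribution of the correlation coefficient
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(40, 200)))
        g = correlation_network(mat, threshold=0.3)
        n_pairs = 40 * 39 / 2
        density = g.number_of_edges() / n_pairs
        nu = 200 - 2
        t_crit = 0.3 * np.sqrt(nu / (1 - 0.09))
        p_theory = 2 * sps.t.sf(t_crit, nu)
        assert density == pytest.approx(p_theory, abs=0.005)


def kcore_oracle(graph, k):
    """Union of all vertex subsets whose induced subgraph has min degree k
    (the maximal such subset, found by brute force)."""
    nodes = list(graph.nodes)
    best: set = set()
    for r in range(len(nodes), 0, -1):
        for subset in itertools.combinations(nodes, r):
            sub = graph.subgraph(subset)
            if len(sub) and min(dict(sub.degree).values(), default=0) >= k:
                return set(subset)
    return best


class TestKCore:
    def test_triangle_survives_two_core(self):
        g = nx.cycle_graph(3)
        assert set(k_core_prune(g, 2).nodes) == {0, 1, 2}

    def test_star_collapses_to_empty(self):
        g = nx.star_graph(5)
        assert len(k_core_prune(g, 2)) == 0

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1e6)))
            pruned = set(k_core_prune(g, 2).nodes)
            assert pruned == kcore_oracle(g, 2)

    def test_independent_of_node_order(self):
        g = nx.gnp_random_graph(12, 0.3, seed=9)
        h = nx.Graph()
        h.add_nodes_from(reversed(list(g.nodes)))
        h.add_edges_from(reversed(list(g.edges)))
        assert set(k_core_prune(g, 2).nodes) == set(k_core_prune(h, 2).nodes)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            k_core_prune(nx.path_graph(3), -1)
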