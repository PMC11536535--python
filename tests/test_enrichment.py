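"""Global test, pathway impact and over-representation statistics."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tcellomics as tc
from tcellomics.enrichment import autoscale, global_test_statistic


def _data(n=20, p=30, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     index=[f"s{i}" for i in range(n)],
                     columns=[f"f{j}" for j in range(p)])
    y = np.repeat([0.0, 1.0], n // 2)
    return X, y


class TestGlobalTest:
    def test_single_member_reduces_to_squared_covariance(self):
        X, y = _data(seed=1)
        Xs = autoscale(X)
        q = global_test_statistic(Xs[["f0"]].to_numpy(), y)
        yc = y - y.mean()
        brute = float((Xs["f0"].to_numpy() @ yc) ** 2)
        assert q == pytest.approx(brute)

    def test_quadratic_form_matches_brute_force_small_sets(self):
        """Q equals elementwise evaluation of (y-ybar)' X X' (y-ybar)/m on
        pathways of <= 5 members."""
        X, y = _data(seed=2)
        Xs = autoscale(X)
        yc = y - y.mean()
        for members in [["f0"], ["f1", "f2"], ["f3", "f4", "f5", "f6", "f7"]]:
            M = Xs[members].to_numpy()
            q = global_test_statistic(M, y)
            outer = M @ M.T
            brute = sum(yc[i] * outer[i, j] * yc[j]
                        for i in range(len(y)) for j in range(len(y)))
            assert q == pytest.approx(brute / len(members))

    def test_member_order_invariance(self):
        X, y = _data(seed=3)
        Xs = autoscale(X)
        q1 = global_test_statistic(Xs[["f0", "f1", "f2"]].to_numpy(), y)
        q2 = global_test_statistic(Xs[["f2", "f0", "f1"]].to_numpy(), y)
        assert q1 == pytest.approx(q2)

    def test_permutation_pvalues_on_grid_and_minimal_under_separation(self):
        # unbalanced phenotype (as in the study design): no permutation can
        # reproduce the labeling via its complement, so complete separation
        # attains the minimal grid value exactly
        X, _ = _data(seed=4)
        y = np.r_[np.zeros(12), np.ones(8)]
        X.loc[:, ["f0", "f1", "f2"]] += y[:, None] * 10.0
        db = tc.PathwayDB(sets={"hit": ["f0", "f1", "f2"],
                                "null": ["f10", "f11"]})
        res = tc.global_test_qea(X, y, db, n_perm=199, seed=0)
        grid = np.arange(1, 201) / 200
        assert all(np.isclose(p, grid).any() for p in res["p"])
        assert res.set_index("pathway").loc["hit", "p"] == pytest.approx(1 / 200)

    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for rep in range(30):
            X, y = _data(n=16, p=10, seed=50 + rep)
            db = tc.PathwayDB(sets={"pw": ["f0", "f1", "f2", "f3"]})
            res = tc.global_test_qea(X, y, db, n_perm=99, seed=rep)
            pvals.append(res["p"].iloc[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_unmatched_pathway_dropped(self):
        X, y = _data(seed=5)
        db = tc.PathwayDB(sets={"gone": ["zz1", "zz2"], "ok": ["f0", "f1"]})
        res = tc.global_test_qea(X, y, db, n_perm=49, seed=0)
        assert list(res["pathway"]) == ["ok"]


class TestKNNImpute:
    def test_complete_matrix_unchanged(self):
        X, _ = _data(seed=6)
        pd.testing.assert_frame_equal(tc.knn_impute_features(X), X)

    def test_correlated_features_donate_values(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=30)
        m = pd.DataFrame({
            "a": base, "b": base + rng.normal(0, 0.01, 30),
            "c": rng.normal(size=30)},
            index=[f"s{i}" for i in range(30)])
        m.loc["s3", "a"] = np.nan
        out = tc.knn_impute_features(m, k=1)
        assert out.loc["s3", "a"] == pytest.approx(m.loc["s3", "b"], abs=0.05)


class TestPathwayImpact:
    def test_all_nodes_hit_gives_one_empty_gives_zero(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        db = tc.PathwayDB(sets={"pw": ["a", "b", "c"]}, graphs={"pw": g})
        assert tc.pathway_impact(db, {"a", "b", "c"}).loc["pw", "impact"] == 1.0
        assert tc.pathway_impact(db, set()).loc["pw", "impact"] == 0.0

    def test_chain_out_degree_hand_example(self):
        # a->b->c: out-degrees 1,1,0 -> importances 0.5,0.5,0 -> hit {a} = 0.5
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        db = tc.PathwayDB(sets={"pw": ["a", "b", "c"]}, graphs={"pw": g})
        assert tc.pathway_impact(db, {"a"}).loc["pw", "impact"] == 0.5

    def test_missing_graph_reports_missing_not_zero(self):
        db = tc.PathwayDB(sets={"pw": ["a"]})
        assert np.isnan(tc.pathway_impact(db, {"a"}).loc["pw", "impact"])


class TestORA:
    def test_hypergeometric_tail_matches_enumeration(self):
        """On a background of <= 20 the hypergeometric tail equals the
        exhaustive count of draws with at least the observed overlap."""
        background = {f"x{i}" for i in range(12)}
        members = [f"x{i}" for i in range(5)]
        hits = {f"x{i}" for i in range(4)} | {"x7"}
        db = tc.PathwayDB(sets={"pw": members})
        res = tc.ora_enrich(hits, background, db).set_index("pathway")
        k_obs = len(hits & set(members))
        total = hit = 0
        for draw in itertools.combinations(sorted(background), len(hits)):
            total += 1
            if len(set(draw) & set(members)) >= k_obs:
                hit += 1
        assert res.loc["pw", "p"] == pytest.approx(hit / total)

    def test_empty_hits_give_p_one(self):
        db = tc.PathwayDB(sets={"pw": ["a", "b"]})
        res = tc.ora_enrich(set(), {"a", "b", "c"}, db)
        assert (res["p"] == 1.0).all()

    def test_hits_outside_background_rejected(self):
        db = tc.PathwayDB(sets={"pw": ["a"]})
        with pytest.raises(ValueError, match="not in background"):
            tc.ora_enrich({"zz"}, {"a", "b"}, db)

    def test_null_hits_significant_at_nominal_rate(self):
        rng = np.random.default_rng(8)
        background = [f"g{i}" for i in range(200)]
        db = tc.PathwayDB(sets=tc.simulate_pathways(background, 40, 15,
                                                    seed=9))
        raw_sig = []
        for rep in range(20):
            hits = set(rng.choice(background, size=20, replace=False))
            res = tc.ora_enrich(hits, set(background), db, p_cut=0.05)
            raw_sig.append((res["p"] < 0.05).mean())
        assert np.mean(raw_sig) < 0.12
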