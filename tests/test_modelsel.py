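import numpy as np
import pandas as pd
import pytest

from batlife.trees import covariance
from batlife.modelsel import (aicc, akaike_weights, enumerate_models, dredge,
                              split_analysis, averaged_frame)
from batlife.simulate import sim_tree, sim_continuous, sim_binary_threshold


class TestAICcArithmetic:
    def test_hand_computed_value(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)
        assert aicc(0.0, 2, 10) == pytest.approx(5.7143, abs=1e-4)

    def test_large_n_limit_is_aic(self):
        assert aicc(-3.0, 4, 10 ** 9) == pytest.approx(6 + 8, abs=1e-6)

    def test_denominator_zero_errors(self):
        with pytest.raises(ValueError):
            aicc(0.0, 9, 10)

    def test_weights_equal_for_equal_aicc(self):
        assert np.allclose(akaike_weights([3.0, 3.0, 3.0]), 1 / 3)

    def test_weights_delta_two(self):
        w = akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)))

    def test_weights_sum_to_one(self):
        w = akaike_weights(np.random.default_rng(0).uniform(0, 50, 20))
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weights_stable_for_huge_values(self):
        w = akaike_weights([1e6, 1e6 + 2])
        assert np.isfinite(w).all() and w.sum() == pytest.approx(1.0)


class TestEnumeration:
    def test_three_mains(self):
        assert len(enumerate_models(["M", "H", "L"])) == 8

    def test_marginality_constrained_interaction(self):
        models = enumerate_models(["M", "H", "L"], ["H:L"])
        assert len(models) == 10
        for mains, inters in models:
            for a, b in inters:
                assert a in mains and b in mains

    def test_single_main(self):
        assert len(enumerate_models(["v"])) == 2

    def test_unknown_interaction_main_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            enumerate_models(["M"], ["M:Z"])


def _dataset(n=40, seed=6, beta_m=0.5):
    tree = sim_tree(n, seed)
    rng = np.random.default_rng(seed + 1)
    df = pd.DataFrame({
        "species": tree.tip_labels,
        "M": sim_continuous(tree, 1.0, 1.0, 0.0, seed + 2),
        "H": sim_binary_threshold(tree, 0.5, seed + 3),
        "L": rng.normal(size=n),
    })
    df["y"] = 0.3 + beta_m * df.M + sim_continuous(tree, 0.05, 1.0, 0.0, seed + 4)
    return tree, df


def _oracle_ml_stats(tree, df, terms):
    """Independent AICc for one model: explicit matrix-inverse GLS + grid
    search over lambda, no calls into the fitting path."""
    y = df["y"].to_numpy()
    X = np.column_stack([np.ones(len(df))] + [df[t].to_numpy() for t in terms])
    C, _ = covariance(tree, 1.0)
    best = -np.inf
    for lam in np.linspace(0, 1, 2001):
        V = lam * C + (1 - lam) * np.diag(np.diag(C))
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        n = len(y)
        s2 = (r @ Vi @ r) / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + n + np.linalg.slogdet(V)[1])
        best = max(best, ll)
    k = X.shape[1] + 1
    return -2 * best + 2 * k + 2 * k * (k + 1) / (len(y) - k - 1)


class TestDredge:
    def test_two_model_set_matches_stepwise_oracle(self):
        tree, df = _dataset(n=12, seed=9)
        mset, avg = dredge(tree, df, "y", ["M"])
        assert len(mset.records) == 2
        by_label = {r.label: r for r in mset.records}
        a_null = _oracle_ml_stats(tree, df, [])
        a_m = _oracle_ml_stats(tree, df, ["M"])
        assert by_label["(intercept)"].aicc == pytest.approx(a_null, abs=2e-3)
        assert by_label["M"].aicc == pytest.approx(a_m, abs=2e-3)
        # weights and deltas follow from the AICcs by definition
        aiccs = np.array([r.aicc for r in mset.records])
        assert np.allclose([r.weight for r in mset.records], akaike_weights(aiccs))
        assert mset.records[0].delta == 0.0

    def test_candidate_set_of_one_model(self):
        tree, df = _dataset(n=40, seed=6, beta_m=2.0)  # M overwhelmingly wins
        mset, avg = dredge(tree, df, "y", ["M"], delta_threshold=0.0)
        assert len(mset.candidates) == 1
        best = mset.records[0]
        est = {a.variable: a for a in avg}
        for term in best.fit.terms:
            assert est[term].estimate == pytest.approx(
                best.fit.beta[best.fit.terms.index(term)], abs=1e-12)
            assert est[term].importance == pytest.approx(1.0)

    def test_weights_sum_to_one_over_full_enumeration(self):
        tree, df = _dataset()
        mset, _ = dredge(tree, df, "y", ["M", "H", "L"])
        assert sum(r.weight for r in mset.records) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_rerun(self):
        tree, df = _dataset()
        f1 = dredge(tree, df, "y", ["M", "H", "L"], ["H:L"])
        f2 = dredge(tree, df, "y", ["M", "H", "L"], ["H:L"])
        pd.testing.assert_frame_equal(f1[0].to_frame(), f2[0].to_frame())
        pd.testing.assert_frame_equal(averaged_frame(f1[1]), averaged_frame(f2[1]))

    def test_removing_variable_preserves_other_aiccs(self):
        tree, df = _dataset()
        full = {r.label: r.aicc for r in dredge(tree, df, "y", ["M", "H", "L"])[0].records}
        reduced = {r.label: r.aicc for r in dredge(tree, df, "y", ["M", "H"])[0].records}
        for label, a in reduced.items():
            assert full[label] == pytest.approx(a, abs=1e-10)

    def test_importance_one_when_in_every_candidate(self):
        tree, df = _dataset(n=60, seed=6, beta_m=2.0)
        mset, avg = dredge(tree, df, "y", ["M", "H"])
        assert all("M" in r.fit.terms for r in mset.candidates)
        m = {a.variable: a for a in avg}["M"]
        assert m.importance == pytest.approx(1.0, abs=1e-9)

    def test_unconditional_se_burnham_anderson(self):
        tree, df = _dataset()
        mset, avg = dredge(tree, df, "y", ["M", "H"])
        cand = [r for r in mset.candidates if "M" in r.fit.terms]
        w = np.array([r.weight for r in cand])
        w = w / (sum(r.weight for r in mset.candidates))
        w = w / w.sum()
        betas = np.array([r.fit.beta[r.fit.terms.index("M")] for r in cand])
        ses = np.array([r.fit.se[r.fit.terms.index("M")] for r in cand])
        est = w @ betas
        se_u = w @ np.sqrt(ses ** 2 + (betas - est) ** 2)
        m = {a.variable: a for a in avg}["M"]
        assert m.estimate == pytest.approx(est, abs=1e-12)
        assert m.unconditional_se == pytest.approx(se_u, abs=1e-12)


class TestSplit:
    def test_split_bookkeeping(self):
        tree, df = _dataset(n=60, seed=15)
        out = split_analysis(tree, df, "y", "H",
                             variables_by_level={0: ["M", "L"], 1: ["M", "L"]})
        n0, n1 = out[0][2], out[1][2]
        assert n0 + n1 == 60
        assert n0 == int((df.H == 0).sum())

    def test_small_stratum_errors(self):
        tree, df = _dataset(n=20, seed=30)
        df["H"] = 0.0
        df.loc[:2, "H"] = 1.0
        with pytest.raises(ValueError, match="stratum"):
            split_analysis(tree, df, "y", "H",
                           variables_by_level={0: ["M", "L"], 1: ["M", "L"]})

    def test_split_variable_excluded_from_candidates(self):
        tree, df = _dataset(n=60, seed=15)
        with pytest.raises(ValueError, match="split variable"):
            split_analysis(tree, df, "y", "H",
                           variables_by_level={0: ["M", "H"], 1: ["M"]})
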