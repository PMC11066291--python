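"""Tree pruning, phylogenetic covariance, Pagel's λ ML, PGLS, trends."""

import numpy as np
import pandas as pd
import pytest

from repeatphylo import comparative, simulate, trees


class TestPrune:
    def test_keep_all_is_identity(self, tree10):
        pruned = comparative.prune(tree10, set(trees.tip_labels(tree10)))
        assert trees.tip_labels(pruned) == trees.tip_labels(tree10)
        D0 = trees.path_distance_matrix(tree10)
        D1 = trees.path_distance_matrix(pruned)
        assert np.allclose(D0.to_numpy(), D1.loc[D0.index, D0.columns].to_numpy())

    def test_two_tips_single_path(self, tree10):
        pruned = comparative.prune(tree10, {"a1", "d3"})
        D = trees.path_distance_matrix(pruned)
        full = trees.path_distance_matrix(tree10)
        assert D.loc["a1", "d3"] == pytest.approx(full.loc["a1", "d3"])

    def test_path_lengths_preserved(self, tree10):
        keep = ["a1", "b2", "c1", "d1", "d3"]
        pruned = comparative.prune(tree10, keep)
        D0 = trees.path_distance_matrix(tree10).loc[keep, keep]
        D1 = trees.path_distance_matrix(pruned).loc[keep, keep]
        assert np.allclose(D0.to_numpy(), D1.to_numpy())

    def test_unknown_tip_rejected(self, tree10):
        with pytest.raises(KeyError):
            comparative.prune(tree10, {"a1", "nope"})


class TestPhyloVcv:
    def test_two_tip_tree_diagonal(self):
        t = trees.tree_from_newick("[&R] (x:0.3,y:0.7);")
        C = comparative.phylo_vcv(t).matrix
        assert np.allclose(C.to_numpy(), [[0.3, 0.0], [0.0, 0.7]])

    def test_sister_offdiagonal_is_stem(self):
        t = trees.tree_from_newick("[&R] ((a:0.2,b:0.2):0.5,c:0.7);")
        C = comparative.phylo_vcv(t).matrix
        assert C.loc["a", "b"] == pytest.approx(0.5)
        assert C.loc["a", "c"] == 0.0

    def test_ultrametric_tree_constant_diagonal(self, tree10):
        C = comparative.phylo_vcv(tree10).matrix.to_numpy()
        assert np.allclose(np.diag(C), 1.0)


class TestLambdaTransform:
    def test_identity_at_one(self, tree10):
        C = comparative.phylo_vcv(tree10).matrix.to_numpy()
        assert np.allclose(comparative.lambda_transform(C, 1.0), C)

    def test_diagonal_at_zero(self, tree10):
        C = comparative.phylo_vcv(tree10).matrix.to_numpy()
        out = comparative.lambda_transform(C, 0.0)
        assert np.allclose(out, np.diag(np.diag(C)))

    def test_out_of_range_rejected(self, tree10):
        C = comparative.phylo_vcv(tree10).matrix.to_numpy()
        with pytest.raises(ValueError):
            comparative.lambda_transform(C, 1.2)

    def test_positive_semidefinite_on_random_ultrametric_trees(self, rng):
        for _ in range(10):
            sizes = rng.integers(2, 4, size=3)
            clades = {
                f"K{i}": [f"K{i}x{j}" for j in range(sizes[i])] for i in range(3)
            }
            t = trees.clade_tree(clades)
            C = comparative.phylo_vcv(t).matrix.to_numpy()
            for lam in (0.0, 0.3, 0.7, 1.0):
                w = np.linalg.eigvalsh(comparative.lambda_transform(C, lam))
                assert w.min() > -1e-10


class TestFitLambda:
    def test_star_tree_reports_zero_by_convention(self):
        t = trees.tree_from_newick("[&R] (a:1.0,b:1.0,c:1.0,d:1.0,e:1.0);")
        t.is_rooted = True
        y = pd.Series({"a": 0.3, "b": -1.2, "c": 0.5, "d": 2.0, "e": -0.1})
        fit = comparative.fit_lambda(y, t)
        assert fit.lambda_hat == 0.0
        assert fit.lrt == pytest.approx(0.0, abs=1e-9)

    def test_constant_trait_rejected(self, tree13):
        y = pd.Series(1.0, index=trees.tip_labels(tree13))
        with pytest.raises(ValueError, match="zero-variance"):
            comparative.fit_lambda(y, tree13)

    def test_matches_dense_grid_search(self, tree13):
        C = comparative.phylo_vcv(tree13).matrix.to_numpy()
        tips = trees.tip_labels(tree13)
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        for rep in range(20):
            y = simulate.simulate_trait(
                tree13, lam=(rep % 5) / 4.0, sigma2=1.0, seed=500 + rep
            ).iloc[0]
            fit = comparative.fit_lambda(y, tree13)
            yv = np.array([y[t] for t in tips])
            lnls = np.array([
                comparative._gls_profile(yv, comparative.lambda_transform(C, l))[0]
                for l in grid
            ])
            lam_grid = grid[int(np.argmax(lnls))]
            assert abs(fit.lambda_hat - lam_grid) < 1e-3
            assert fit.lnl >= lnls.max() - 1e-8

    def test_invariant_to_shift_and_equivariant_to_scale(self, tree13):
        y = simulate.simulate_trait(tree13, lam=0.8, sigma2=1.0, seed=9).iloc[0]
        base = comparative.fit_lambda(y, tree13)
        shifted = comparative.fit_lambda(y + 100.0, tree13)
        scaled = comparative.fit_lambda(y * 10.0, tree13)
        assert shifted.lambda_hat == pytest.approx(base.lambda_hat, abs=1e-5)
        assert scaled.lambda_hat == pytest.approx(base.lambda_hat, abs=1e-5)
        assert scaled.sigma2_hat == pytest.approx(base.sigma2_hat * 100.0, rel=1e-6)

    def test_agrees_with_phytools_reference(self, tree13, tmp_path):
        """Frozen cross-check against R phytools::phylosig on one dataset."""
        y = simulate.simulate_trait(tree13, lam=0.7, sigma2=1.0, seed=42).iloc[0]
        fit = comparative.fit_lambda(y, tree13)
        # reference values computed with phytools 2.5 phylosig(..., method="lambda")
        assert fit.lambda_hat == pytest.approx(0.674487, abs=2e-4)
        assert fit.lnl == pytest.approx(-16.405199, abs=1e-4)
        assert fit.lnl0 == pytest.approx(-17.382598, abs=1e-4)
        assert fit.pvalue == pytest.approx(0.162071, abs=1e-4)


class TestPGLS:
    def test_identity_covariance_matches_ols(self):
        # star tree with equal branches => GLS == OLS
        t = trees.tree_from_newick("[&R] (a:1.0,b:1.0,c:1.0,d:1.0,e:1.0,f:1.0);")
        t.is_rooted = True
        rng = np.random.default_rng(5)
        tips = trees.tip_labels(t)
        x = pd.Series(rng.normal(size=6), index=tips)
        y = 1.5 * x + pd.Series(rng.normal(scale=0.3, size=6), index=tips)
        fit = comparative.pgls(y, x, t, mode="BM")
        slope, intercept = np.polyfit(x[tips], y[tips], 1)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_exact_linear_relation(self, tree13):
        tips = trees.tip_labels(tree13)
        x = pd.Series(np.linspace(0, 1, len(tips)), index=tips)
        y = 2.0 * x
        for mode in ("BM", "lambda"):
            fit = comparative.pgls(y, x, tree13, mode=mode)
            assert fit.slope == pytest.approx(2.0, abs=1e-8)
            assert fit.adj_r2 == pytest.approx(1.0, abs=1e-8)

    def test_self_regression(self, tree13):
        tips = trees.tip_labels(tree13)
        x = pd.Series(np.arange(len(tips), dtype=float), index=tips)
        fit = comparative.pgls(x, x, tree13, mode="BM")
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_constant_predictor_rejected(self, tree13):
        tips = trees.tip_labels(tree13)
        x = pd.Series(1.0, index=tips)
        y = pd.Series(np.arange(len(tips), dtype=float), index=tips)
        with pytest.raises(ValueError):
            comparative.pgls(y, x, tree13)


class TestClassifyTrend:
    def _order(self, tree):
        score = {}
        for tip in trees.tip_labels(tree):
            score[tip] = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}[tip[0]]
        return pd.Series(score)

    def test_constant_abundance_none(self, tree10):
        y = pd.Series(5.0, index=trees.tip_labels(tree10))
        assert comparative.classify_trend(y, tree10, self._order(tree10)) == "none"

    def test_clade_graded_abundance_increasing(self, tree10):
        order = self._order(tree10)
        y = order * 10.0  # strictly clade-graded => strong signal, positive slope
        assert comparative.classify_trend(y, tree10, order) == "increasing"

    def test_negated_series_decreasing(self, tree10):
        order = self._order(tree10)
        y = order * -10.0
        assert comparative.classify_trend(y, tree10, order) == "decreasing"

    def test_missing_score_rejected(self, tree10):
        y = self._order(tree10) * 2.0
        with pytest.raises(KeyError):
            comparative.classify_trend(y, tree10, pd.Series({"a1": 1.0}))


def test_lrt_type_one_error_controlled(tree13):
    """Independent (λ=0) traits analysed on a structured tree reject H0
    at no more than 7% at nominal α = 5% (boundary effects make the χ²₁
    reference conservative)."""
    null = simulate.simulate_trait(tree13, lam=0.0, sigma2=1.0, seed=12, size=1000)
    rej = sum(
        comparative.fit_lambda(null.iloc[i], tree13).pvalue < 0.05 for i in range(1000)
    )
    assert rej / 1000 <= 0.07
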