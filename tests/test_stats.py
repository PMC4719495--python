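"""Statistical toolkit: oracle equivalence and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cardiopop.stats import (mann_whitney, partial_correlation, pearson,
                             significance_stars)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 3) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        # cov = 3, var_x = var_y = 5  =>  r = 0.6
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    @given(a=st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
           b=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_sign_of_affine_map(self, a, b):
        x = np.array([0.3, 1.1, 2.5, 4.0, 5.2])
        assert pearson(x, a * x + b) == pytest.approx(np.sign(a))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialCorrelation:
    def test_single_driver_recovered(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 2, size=(1000, 11))
        y = 3.0 * X[:, 4] + rng.normal(0, 0.1, 1000)
        pcc, pval = partial_correlation(X, y)
        assert pcc[4] > 0.95
        others = np.delete(np.abs(pcc), 4)
        assert np.all(others < 0.15)
        assert pval[4] < 1e-6

    def test_reduces_to_pearson_with_one_parameter(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = 0.7 * x + rng.normal(size=50)
        pcc, _ = partial_correlation(x[:, None], y)
        assert pcc[0] == pytest.approx(pearson(x, y), abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 4))
        y = X @ np.array([1.0, -0.5, 0.0, 0.2]) + rng.normal(size=80)
        pcc, pval = partial_correlation(X, y)
        df = pd.DataFrame(X, columns=list("abcd"))
        df["y"] = y
        for j, name in enumerate("abcd"):
            ref = pingouin.partial_corr(
                df, x=name, y="y",
                covar=[c for c in "abcd" if c != name])
            assert pcc[j] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
            assert pval[j] == pytest.approx(float(ref["p_val"].iloc[0]),
                                            rel=1e-3, abs=1e-9)

    def test_orthogonal_design_signs_match_marginal(self):
        rng = np.random.default_rng(5)
        from cardiopop.population import lhs_sample
        X = lhs_sample(400, seed=5)
        beta = rng.uniform(0.5, 1.5, 11) * rng.choice([-1, 1], 11)
        y = X @ beta + rng.normal(0, 0.3, 400)
        pcc, _ = partial_correlation(X, y)
        marginal = np.array([pearson(X[:, j], y) for j in range(11)])
        assert np.all(np.sign(pcc) == np.sign(marginal))

    def test_collinear_design_named(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        X = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            partial_correlation(X, X[:, 1])

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="observations"):
            partial_correlation(np.ones((5, 11)), np.ones(5))


class TestMannWhitney:
    def test_separated_groups_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0
        assert res["p"] == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res["p"] == pytest.approx(1.0)

    def test_symmetry(self):
        a = [1.2, 3.4, 2.2, 8.0]
        b = [0.5, 2.9, 7.7]
        assert mann_whitney(a, b)["p"] == pytest.approx(
            mann_whitney(b, a)["p"])

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (3, 4), (5, 5), (4, 8)])
    def test_exact_matches_scipy_enumeration(self, n_a, n_b):
        """Tie-free samples: exact p equals scipy's exact distribution."""
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(5):
            a = rng.permutation(np.arange(1.0, n_a + n_b + 1))[:n_a]
            b = np.setdiff1d(np.arange(1.0, n_a + n_b + 1), a)
            ours = mann_whitney(a, b)["p"]
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue
            assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.8, 1, 40)
        ours = mann_whitney(a, b)["p"]
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic").pvalue
        assert ours == pytest.approx(float(ref))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def test_significance_stars():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
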