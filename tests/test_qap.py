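import numpy as np
import pandas as pd
import pytest

from spanet.containers import DistanceMatrix, DirectedNetwork, DyadMatrix
from spanet.qap import (
    MRQAP,
    QAPCorrelation,
    binary_network_as_dyads,
    difference_matrix,
    proximity_matrix,
    qap_correlation,
    qap_regression,
)
from spanet.synthetic import generate_dyadic_design


def _noise_dyad(n, seed, labels=None):
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((n, n))
    np.fill_diagonal(m, 0.0)
    return DyadMatrix(labels or [f"N{i}" for i in range(n)], m)


class TestMatrixConstruction:
    def test_difference_matrix_values(self):
        dm = difference_matrix(pd.Series([1.0, 3.0, 6.0], index=list("abc")))
        expected = np.array([[0, 2, 5], [2, 0, 3], [5, 3, 0]], dtype=float)
        np.testing.assert_allclose(dm.m, expected)

    def test_constant_vector_gives_zero_matrix(self):
        dm = difference_matrix(pd.Series([4.0] * 5, index=list("abcde")))
        assert (dm.m == 0).all()

    def test_scaling_homogeneity(self):
        v = pd.Series([1.0, 2.0, 5.0], index=list("abc"))
        np.testing.assert_allclose(
            difference_matrix(-3 * v).m, 3 * difference_matrix(v).m
        )

    def test_missing_value_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            difference_matrix(pd.Series([1.0, np.nan], index=list("ab")))

    def test_inverse_distance(self):
        d = DistanceMatrix(list("ab"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        pm = proximity_matrix(d, "inverse_distance")
        assert pm.m[0, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(pm.m, pm.m.T)

    def test_border_adjacency(self):
        d = DistanceMatrix(list("abc"), np.array(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float))
        pm = proximity_matrix(d, "border_adjacency", border_pairs={("a", "b")})
        assert pm.m[0, 1] == pm.m[1, 0] == 1.0
        assert pm.m.sum() == 2.0
        empty = proximity_matrix(d, "border_adjacency", border_pairs=set())
        assert (empty.m == 0).all()
        with pytest.raises(ValueError, match="border_pairs"):
            proximity_matrix(d, "border_adjacency")

    def test_network_round_trips_as_dyads(self):
        rng = np.random.default_rng(0)
        a = (rng.random((6, 6)) < 0.4).astype(int)
        np.fill_diagonal(a, 0)
        net = DirectedNetwork([f"v{i}" for i in range(6)], a)
        dm = binary_network_as_dyads(net)
        np.testing.assert_array_equal(dm.m, net.a)
        assert dm.offdiag().shape == (30,)


class TestQapCorrelation:
    def test_self_correlation(self):
        a = _noise_dyad(12, 1)
        res = qap_correlation(a, a, n_perm=500, seed=0)
        assert res.coefficient == pytest.approx(1.0)
        assert res.p_ge <= 0.05

    def test_negated_matrix(self):
        a = _noise_dyad(12, 2)
        b = DyadMatrix(a.labels, -a.m)
        res = qap_correlation(a, b, n_perm=200, seed=0)
        assert res.coefficient == pytest.approx(-1.0)

    def test_tail_conventions(self):
        a, b = _noise_dyad(10, 3), _noise_dyad(10, 4)
        res = qap_correlation(a, b, n_perm=999, seed=5)
        assert res.p_ge + res.p_le >= 1.0  # ties count in both tails
        assert res.sig == min(res.p_ge, res.p_le)
        assert res.perm_min <= res.perm_mean <= res.perm_max

    def test_deterministic_under_seed(self):
        a, b = _noise_dyad(10, 6), _noise_dyad(10, 7)
        r1 = qap_correlation(a, b, n_perm=500, seed=11)
        r2 = qap_correlation(a, b, n_perm=500, seed=11)
        assert r1 == r2

    def test_observed_r_invariant_under_joint_relabeling(self):
        a, b = _noise_dyad(9, 8), _noise_dyad(9, 9)
        rng = np.random.default_rng(1)
        perm = rng.permutation(9)
        ap = DyadMatrix(a.labels, a.m[np.ix_(perm, perm)])
        bp = DyadMatrix(b.labels, b.m[np.ix_(perm, perm)])
        r1 = qap_correlation(a, b, n_perm=10, seed=0).coefficient
        r2 = qap_correlation(ap, bp, n_perm=10, seed=0).coefficient
        assert r1 == pytest.approx(r2)

    def test_symmetric_matrices_equal_unordered_pair_correlation(self):
        rng = np.random.default_rng(3)
        s1 = rng.standard_normal((8, 8))
        s2 = rng.standard_normal((8, 8))
        s1, s2 = s1 + s1.T, s2 + s2.T
        np.fill_diagonal(s1, 0), np.fill_diagonal(s2, 0)
        labels = [f"N{i}" for i in range(8)]
        r = qap_correlation(
            DyadMatrix(labels, s1), DyadMatrix(labels, s2), n_perm=10, seed=0
        ).coefficient
        iu = np.triu_indices(8, 1)
        assert r == pytest.approx(np.corrcoef(s1[iu], s2[iu])[0, 1])

    def test_zero_variance_rejected(self):
        flat = DyadMatrix(list("abcd"), np.ones((4, 4)))
        with pytest.raises(ValueError, match="variance"):
            qap_correlation(flat, _noise_dyad(4, 0, list("abcd")), n_perm=10)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            qap_correlation(_noise_dyad(5, 0), _noise_dyad(5, 1, list("abcde")),
                            n_perm=10)


class TestMrqap:
    def test_noiseless_exact_fit(self):
        y, xs = generate_dyadic_design(8, 1, betas=[2.0], noise_sd=0.0, seed=0)
        res = qap_regression(y, xs, n_perm=100, seed=0)
        assert res.table["coefficient"].iloc[0] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.adj_r_squared <= res.r_squared

    def test_named_covariates_and_sign_side_significance(self):
        y, xs = generate_dyadic_design(
            15, 2, betas=[1.5, -1.5], noise_sd=0.3, seed=2
        )
        model = MRQAP(n_perm=500, seed=3).fit({"up": xs[0], "down": xs[1]}, y)
        assert model.names_ == ["up", "down"]
        np.testing.assert_allclose(
            model.sig_,
            np.where(model.coef_ >= 0, model.p_ge_, model.p_le_),
        )

    def test_standardized_coefficients_scale_free(self):
        y, xs = generate_dyadic_design(12, 1, betas=[2.0], noise_sd=0.5, seed=4)
        scaled = [DyadMatrix(xs[0].labels, 1000.0 * xs[0].m)]
        m1 = MRQAP(n_perm=50, seed=0).fit(xs, y)
        m2 = MRQAP(n_perm=50, seed=0).fit(scaled, y)
        assert m2.coef_[0] == pytest.approx(m1.coef_[0] / 1000.0)
        assert m2.std_coef_[0] == pytest.approx(m1.std_coef_[0])
        assert m2.r_squared_ == pytest.approx(m1.r_squared_)

    def test_deterministic_under_seed(self):
        y, xs = generate_dyadic_design(10, 2, betas=[1, 1], noise_sd=1, seed=5)
        r1 = qap_regression(y, xs, n_perm=300, seed=21)
        r2 = qap_regression(y, xs, n_perm=300, seed=21)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_collinear_covariates_named(self):
        y, xs = generate_dyadic_design(8, 1, betas=[1.0], noise_sd=0.1, seed=6)
        dup = DyadMatrix(xs[0].labels, 2.0 * xs[0].m)
        with pytest.raises(ValueError, match="a ~ b"):
            qap_regression(y, {"a": xs[0], "b": dup}, n_perm=10)

    def test_constant_covariate_named(self):
        y, xs = generate_dyadic_design(8, 1, betas=[1.0], noise_sd=0.1, seed=7)
        flat = DyadMatrix(xs[0].labels, np.full((8, 8), 3.0))
        with pytest.raises(ValueError, match="flat"):
            qap_regression(y, {"x": xs[0], "flat": flat}, n_perm=10)

    def test_estimator_params_round_trip(self):
        model = MRQAP(n_perm=123, seed=9)
        assert MRQAP(**model.get_params()).get_params() == model.get_params()
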