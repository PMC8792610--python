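"""Connectivity estimation, proportional thresholding and graph assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msgcn import (TimeSeriesMatrix, assemble_multiscale, build_graph, pearson_fcn,
                   proportional_threshold, sparse_representation_fcn)
from msgcn.errors import DataError
from msgcn.fcn import ConnectivityMatrix

from conftest import random_connectivity


def naive_pearson(values):
    """Double-loop centered-dot-product correlation (independent oracle)."""
    t, n = values.shape
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            si = values[:, i] - values[:, i].mean()
            sj = values[:, j] - values[:, j].mean()
            out[i, j] = (si @ sj) / np.sqrt((si @ si) * (sj @ sj))
    return out


class TestPearson:
    def test_identical_and_negated_columns(self):
        s = np.random.default_rng(0).normal(size=20)
        ts = TimeSeriesMatrix(np.column_stack([s, s, -s]))
        e = pearson_fcn(ts).values
        assert e[0, 1] == pytest.approx(1.0)
        assert e[0, 2] == pytest.approx(-1.0)

    def test_orthogonal_after_centering(self):
        # centered (1,0,1) is orthogonal to centered (1,2,3)
        ts = TimeSeriesMatrix(np.array([[1.0, 1.0], [2.0, 0.0], [3.0, 1.0]]))
        assert pearson_fcn(ts).values[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            ts = TimeSeriesMatrix(rng.normal(size=(30, 8)))
            e = pearson_fcn(ts).values
            np.testing.assert_allclose(e, naive_pearson(ts.values), atol=1e-12)
            assert np.allclose(np.diag(e), 1.0)

    def test_zero_variance_column_names_roi(self):
        vals = np.random.default_rng(0).normal(size=(10, 3))
        vals[:, 2] = 4.2
        with pytest.raises(DataError, match="2"):
            pearson_fcn(TimeSeriesMatrix(vals))

    @given(a=st.floats(0.1, 50.0), b=st.floats(-10.0, 10.0),
           col=st.integers(0, 3))
    @settings(max_examples=25, deadline=None)
    def test_affine_rescaling_invariance(self, a, b, col):
        vals = np.random.default_rng(99).normal(size=(25, 4))
        e0 = pearson_fcn(TimeSeriesMatrix(vals)).values
        vals2 = vals.copy()
        vals2[:, col] = a * vals2[:, col] + b
        e1 = pearson_fcn(TimeSeriesMatrix(vals2)).values
        np.testing.assert_allclose(e0, e1, atol=1e-10)


def l1_regression_oracle(y, x, lam):
    """Split-variable convex formulation solved by L-BFGS-B (u, v >= 0)."""
    from scipy.optimize import minimize

    p = x.shape[1]

    def obj(uv):
        w = uv[:p] - uv[p:]
        r = y - x @ w
        return 0.5 * r @ r + lam * uv.sum()

    def grad(uv):
        w = uv[:p] - uv[p:]
        g = x.T @ (x @ w - y)
        return np.concatenate([g + lam, -g + lam])

    res = minimize(obj, np.zeros(2 * p), jac=grad, method="L-BFGS-B",
                   bounds=[(0, None)] * 2 * p,
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return res.x[:p] - res.x[p:]


class TestSparseRepresentation:
    def test_full_shrinkage_at_large_lambda(self, rng):
        ts = TimeSeriesMatrix(rng.normal(size=(40, 5)))
        c = sparse_representation_fcn(ts, lam=1e6)
        off = c.values[~np.eye(5, dtype=bool)]
        assert np.all(off == 0.0)
        assert c.method == "sparse_representation"

    def test_recovers_dependent_roi(self, rng):
        s1 = rng.normal(size=80)
        s2 = rng.normal(size=80)  # independent noise
        s3 = s1 + 0.05 * rng.normal(size=80)
        ts = TimeSeriesMatrix(np.column_stack([s1, s2, s3]))
        w = sparse_representation_fcn(ts, lam=5.0).values
        assert w[0, 2] > 10 * w[1, 2]

    def test_sparsity_monotone_in_lambda(self, rng):
        ts = TimeSeriesMatrix(rng.normal(size=(50, 6)))
        frac = [np.mean(sparse_representation_fcn(ts, lam).values == 0)
                for lam in (0.5, 2.0, 10.0, 1e5)]
        assert all(a <= b + 1e-12 for a, b in zip(frac, frac[1:]))

    def test_matches_convex_solver_oracle(self, rng):
        ts = TimeSeriesMatrix(rng.normal(size=(40, 5)))
        lam = 2.0
        got = sparse_representation_fcn(ts, lam).values
        s = (ts.values - ts.values.mean(0)) / ts.values.std(0)
        w = np.zeros((5, 5))
        for i in range(5):
            others = np.delete(np.arange(5), i)
            w[i, others] = l1_regression_oracle(s[:, i], s[:, others], lam)
        expected = (np.abs(w) + np.abs(w.T)) / 2
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(got, expected, atol=1e-4)


class TestProportionalThreshold:
    def test_identity_at_full_retention(self, rng):
        c = ConnectivityMatrix(random_connectivity(rng, 10), method="pearson")
        out = proportional_threshold(c, 1.0)
        np.testing.assert_array_equal(out.values, c.values)

    def test_keeps_top_edges_by_magnitude(self):
        c = np.eye(4)
        weights = {(0, 1): 0.9, (0, 2): -0.8, (0, 3): 0.1,
                   (1, 2): 0.5, (1, 3): -0.05, (2, 3): 0.02}
        for (i, j), w in weights.items():
            c[i, j] = c[j, i] = w
        out = proportional_threshold(ConnectivityMatrix(c, "pearson"), 0.5).values
        iu, ju = np.triu_indices(4, k=1)
        kept = set(map(tuple, np.argwhere(out != 0)))
        assert sum(out[iu, ju] != 0) == 3
        assert {(0, 1), (0, 2), (1, 2)} <= kept
        np.testing.assert_array_equal(np.diag(out), np.diag(c))

    @pytest.mark.parametrize("frac", [0.6, 0.7, 0.8, 0.9, 1.0])
    def test_retained_count_closed_form(self, rng, frac):
        n = 15
        c = ConnectivityMatrix(random_connectivity(rng, n), method="pearson")
        out = proportional_threshold(c, frac).values
        iu, ju = np.triu_indices(n, k=1)
        m = iu.size
        assert (out[iu, ju] != 0).sum() == int(np.ceil(frac * m))
        np.testing.assert_array_equal(out, out.T)
        assert np.all(np.abs(out) <= np.abs(c.values) + 1e-15)

    def test_tied_weights_thresholded_deterministically(self):
        c = np.eye(5)
        iu, ju = np.triu_indices(5, k=1)
        c[iu, ju] = c[ju, iu] = 0.5  # every off-diagonal tied
        cm = ConnectivityMatrix(c, "pearson")
        a = proportional_threshold(cm, 0.5).values
        b = proportional_threshold(cm, 0.5).values
        np.testing.assert_array_equal(a, b)
        # stable order prefers low row, then low column indices
        assert a[0, 1] != 0 and a[3, 4] == 0

    @pytest.mark.parametrize("frac", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, rng, frac):
        c = ConnectivityMatrix(random_connectivity(rng, 4), method="pearson")
        with pytest.raises(DataError):
            proportional_threshold(c, frac)


class TestGraphAssembly:
    def test_signed_features_absolute_adjacency(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = -0.5
        g = build_graph(ConnectivityMatrix(c, "pearson"), label=1)
        assert g.X[0, 1] == -0.5
        assert g.A[0, 1] == 0.5
        assert g.label == 1

    def test_all_positive_matrix_gives_equal_x_and_a(self, rng):
        c = np.abs(random_connectivity(rng, 6))
        g = build_graph(ConnectivityMatrix(c, "pearson"), label=0)
        np.testing.assert_array_equal(g.X, g.A)

    def test_l1_norm_preserved(self, rng):
        c = random_connectivity(rng, 8)
        g = build_graph(ConnectivityMatrix(c, "pearson"), label=0)
        assert np.abs(g.X).sum() == pytest.approx(g.A.sum())
        assert g.A.min() >= 0
        np.testing.assert_allclose(np.diag(g.X), 1.0)

    def test_asymmetric_input_rejected(self):
        c = np.eye(3)
        c[0, 1] = 0.5
        with pytest.raises(DataError):
            ConnectivityMatrix(c, "pearson")

    def test_multiscale_bundle_counts(self, tiny_samples, tiny_cohort):
        assert len(tiny_samples) == tiny_cohort.n_subjects
        total_graphs = sum(len(s.graphs) for s in tiny_samples)
        assert total_graphs == 2 * tiny_cohort.n_subjects
        for s in tiny_samples:
            assert s.scales == ["coarse", "fine"]

    def test_three_scale_bundle(self, rng):
        from msgcn.fcn import SubjectGraph
        graphs = [SubjectGraph(np.eye(n), np.eye(n), label=1, scale=f"s{n}",
                               subject_id="x") for n in (4, 5, 6)]
        sample = assemble_multiscale(graphs)
        assert len(sample.graphs) == 3

    def test_label_mismatch_rejected(self):
        from msgcn.fcn import SubjectGraph
        g1 = SubjectGraph(np.eye(3), np.eye(3), label=0, scale="a", subject_id="x")
        g2 = SubjectGraph(np.eye(4), np.eye(4), label=1, scale="b", subject_id="x")
        with pytest.raises(DataError):
            assemble_multiscale([g1, g2])
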