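"""VAR fitting, BIC order selection and Granger/Pearson connectivity
against closed forms and brute-force regression oracles."""

from dataclasses import replace

import numpy as np
import pytest
from statsmodels.tsa.api import VAR as SmVAR

from grangernet.connectivity import (
    ConnectivityMatrix,
    aggregate_epochs,
    average_connection_strength,
    fit_var,
    granger_pairwise,
    normalize_weights,
    pearson_matrix,
    select_order_bic,
)
from grangernet.simulate import SimulationSpec, order5_benchmark_spec, simulate_mvar
from grangernet.timeseries import ROITimeSeries


def _ts(data, fs=500.0):
    data = np.asarray(data, dtype=float)
    return ROITimeSeries(data, [f"R{i}" for i in range(data.shape[0])], fs)


def _ar1(phi, n, seed=0, sigma=1.0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n + 200)
    e = rng.standard_normal(n + 200) * sigma
    for t in range(1, n + 200):
        x[t] = phi * x[t - 1] + e[t]
    return x[200:]


def brute_force_ols(data, order, targets, predictors, offset=None):
    """Explicitly assembled regression: RSS of each target channel on the
    p lags of the predictor channels."""
    n, t = data.shape
    offset = order if offset is None else offset
    y = data[targets, offset:].T
    cols = []
    for k in range(1, order + 1):
        for j in predictors:
            cols.append(data[j, offset - k : t - k])
    x = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, resid


class TestFitVar:
    def test_independent_white_noise_cross_terms_near_zero(self):
        rng = np.random.default_rng(1)
        ts = _ts(rng.standard_normal((2, 5000)))
        m = fit_var(ts, 1)
        # standard error of a VAR(1) coefficient on white noise ~ 1/sqrt(n)
        se = 1 / np.sqrt(m.n_effective)
        assert abs(m.coeff_matrices[0][0, 1]) < 4 * se
        assert abs(m.coeff_matrices[0][1, 0]) < 4 * se

    def test_ar1_gain_recovered(self):
        ts = _ts(_ar1(0.5, 5000, seed=2)[None, :])
        m = fit_var(ts, 1)
        assert m.coeff_matrices[0][0, 0] == pytest.approx(0.5, abs=0.05)
        assert m.n_effective == 4999

    def test_matches_bruteforce_normal_equations(self):
        rng = np.random.default_rng(3)
        ts = _ts(rng.standard_normal((3, 200)))
        m = fit_var(ts, 2)
        beta, resid = brute_force_ols(ts.data, 2, [0, 1, 2], [0, 1, 2])
        # beta rows: (lag, channel) blocks -> A_k[i, j] = beta[(k-1)*3 + j, i]
        for k in range(2):
            for i in range(3):
                for j in range(3):
                    assert m.coeff_matrices[k][i, j] == pytest.approx(
                        beta[k * 3 + j, i], abs=1e-10)
        assert np.allclose(m.resid_cov, resid.T @ resid / resid.shape[0], atol=1e-12)

    def test_matches_statsmodels_var(self):
        """Independent implementation check (no-constant VAR OLS)."""
        rng = np.random.default_rng(4)
        ts = _ts(rng.standard_normal((3, 400)))
        m = fit_var(ts, 2)
        sm = SmVAR(ts.data.T).fit(maxlags=2, trend="n")
        assert np.allclose(
            np.stack([sm.coefs[k] for k in range(2)]), m.coeff_matrices, atol=1e-8
        )

    def test_duplicated_channel_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(300)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_var(_ts(np.vstack([x, x])), 2)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="identify"):
            fit_var(_ts(np.random.default_rng(0).standard_normal((5, 12))), 3)


class TestOrderSelection:
    def test_white_noise_prefers_order_one(self):
        picks = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            picks.append(select_order_bic(_ts(rng.standard_normal((3, 500))), 1, 6))
        assert np.mean(np.asarray(picks) == 1) >= 0.8

    def test_modal_order_five_on_order5_process(self):
        picks = []
        for seed in range(20):
            ts = simulate_mvar(replace(order5_benchmark_spec(), seed=seed))
            picks.append(select_order_bic(ts, 1, 10))
        vals, counts = np.unique(picks, return_counts=True)
        assert vals[np.argmax(counts)] == 5

    def test_singleton_candidate_returned(self, small_series):
        assert select_order_bic(small_series, 3, 3) == 3

    def test_order2_process_recovered(self):
        a = np.zeros((2, 3, 3))
        a[0] = 0.3 * np.eye(3)
        a[1] = -0.45 * np.eye(3)
        a[1, 0, 1] = 0.3
        spec = SimulationSpec(3, 2, a, np.eye(3), 1000)
        picks = []
        for seed in range(20):
            picks.append(select_order_bic(simulate_mvar(replace(spec, seed=seed)), 1, 6))
        vals, counts = np.unique(picks, return_counts=True)
        assert vals[np.argmax(counts)] == 2


class TestGranger:
    def test_independent_channels_have_tiny_f(self):
        rng = np.random.default_rng(6)
        f = granger_pairwise(_ts(rng.standard_normal((2, 10000))), 1)
        assert f.weights[0, 1] < 0.01 and f.weights[1, 0] < 0.01

    def test_closed_form_unidirectional_coupling(self):
        # x_t = 0.9 y_{t-1} + e_t with unit noises: reduced variance 1.81,
        # full variance 1 -> F = ln(1.81)
        rng = np.random.default_rng(7)
        n = 20000
        y = rng.standard_normal(n + 1)
        x = 0.9 * y[:-1] + rng.standard_normal(n)
        f = granger_pairwise(_ts(np.vstack([x, y[1:]])), 1)
        assert f.weights[1, 0] == pytest.approx(np.log(1.81), abs=0.03)
        assert f.weights[0, 1] == pytest.approx(0.0, abs=0.01)

    def test_matches_bruteforce_pairwise_regressions(self):
        rng = np.random.default_rng(8)
        ts = _ts(rng.standard_normal((4, 300)))
        order = 3
        f = granger_pairwise(ts, order)
        for x in range(4):
            _, r_red = brute_force_ols(ts.data, order, [x], [x])
            rss_red = float((r_red**2).sum())
            for y in range(4):
                if y == x:
                    continue
                _, r_full = brute_force_ols(ts.data, order, [x], [x, y])
                rss_full = float((r_full**2).sum())
                assert f.weights[y, x] == pytest.approx(
                    np.log(rss_red / rss_full), abs=1e-9)

    def test_nonnegative_and_asymmetric_on_coupled_system(self):
        rng = np.random.default_rng(9)
        n = 3000
        y = rng.standard_normal(n + 1)
        x = 0.6 * y[:-1] + rng.standard_normal(n)
        f = granger_pairwise(_ts(np.vstack([x, y[1:]])), 2)
        assert np.all(f.weights >= 0)
        assert f.weights[1, 0] > 10 * f.weights[0, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegativity_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        f = granger_pairwise(_ts(rng.standard_normal((5, 400))), 2)
        assert np.all(f.weights >= 0)
        assert np.allclose(np.diag(f.weights), 0)


class TestPearson:
    def test_affine_and_sign_relations(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(500)
        ts = _ts(np.vstack([x, 2 * x + 3, -x + 1]))
        r = pearson_matrix(ts)
        assert r.weights[0, 1] == pytest.approx(1.0)
        assert r.weights[0, 2] == pytest.approx(-1.0)
        assert np.allclose(r.weights, r.weights.T)

    def test_matches_direct_formula(self, small_series):
        r = pearson_matrix(small_series)
        d = small_series.data
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert r.weights[i, j] == 0
                    continue
                num = np.mean((d[i] - d[i].mean()) * (d[j] - d[j].mean()))
                assert r.weights[i, j] == pytest.approx(
                    num / (d[i].std() * d[j].std()), abs=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_matrix(_ts(np.vstack([np.ones(50), np.arange(50.0)])))


class TestNormalizeAndStrength:
    def test_max_scaling(self):
        w = ConnectivityMatrix(np.array([[0, 4.0], [2.0, 0]]), True, "GCA", ["a", "b"])
        nw = normalize_weights(w)
        assert nw.weights[0, 1] == 1.0 and nw.weights[1, 0] == 0.5
        assert np.allclose(normalize_weights(nw).weights, nw.weights)

    def test_pcc_rectified_before_scaling(self):
        m = np.array([[0, -0.8, 0.4], [-0.8, 0, 0.0], [0.4, 0.0, 0]])
        w = ConnectivityMatrix(m, False, "PCC", ["a", "b", "c"])
        nw = normalize_weights(w)
        assert nw.weights[0, 1] == pytest.approx(1.0)
        assert nw.weights[0, 2] == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        w = ConnectivityMatrix(np.zeros((3, 3)), True, "GCA", list("abc"))
        with pytest.raises(ValueError, match="all-zero"):
            normalize_weights(w)

    def test_average_strength_conventions(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 0)
        w = ConnectivityMatrix(m, True, "GCA", list("abc"))
        assert average_connection_strength(w) == pytest.approx(0.5)
        single = np.zeros((3, 3))
        single[0, 1] = 1.0
        w1 = ConnectivityMatrix(single, True, "GCA", list("abc"))
        assert average_connection_strength(w1) == pytest.approx(1 / 6)

    def test_permutation_invariance_of_strength(self):
        rng = np.random.default_rng(11)
        m = np.abs(rng.standard_normal((5, 5)))
        np.fill_diagonal(m, 0)
        w = ConnectivityMatrix(m, True, "GCA", [f"R{i}" for i in range(5)])
        perm = rng.permutation(5)
        wp = ConnectivityMatrix(m[np.ix_(perm, perm)], True, "GCA",
                                [f"R{i}" for i in perm])
        assert average_connection_strength(w) == pytest.approx(
            average_connection_strength(wp), abs=1e-14)


class TestAggregateEpochs:
    def test_mean_and_identity(self):
        a = np.zeros((3, 3))
        b = np.ones((3, 3)) - np.eye(3)
        wa = ConnectivityMatrix(a, True, "GCA", list("abc"))
        wb = ConnectivityMatrix(b, True, "GCA", list("abc"))
        assert np.allclose(aggregate_epochs([wa, wb]).weights, b / 2)
        assert np.allclose(aggregate_epochs([wb, wb]).weights, b)

    def test_bruteforce_mean_of_five(self):
        rng = np.random.default_rng(12)
        mats = []
        raw = []
        for _ in range(5):
            m = np.abs(rng.standard_normal((4, 4)))
            np.fill_diagonal(m, 0)
            raw.append(m)
            mats.append(ConnectivityMatrix(m, True, "GCA", list("abcd")))
        assert np.allclose(aggregate_epochs(mats).weights, np.mean(raw, axis=0))

    def test_heterogeneous_rejected(self):
        wa = ConnectivityMatrix(np.zeros((3, 3)), True, "GCA", list("abc"))
        wb = ConnectivityMatrix(np.zeros((4, 4)), True, "GCA", list("abcd"))
        with pytest.raises(ValueError, match="differ"):
            aggregate_epochs([wa, wb])
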