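"""Directed (Granger) and undirected (Pearson) connectivity estimation.

The directed measure is time-domain pairwise Granger causality.  For an
ordered region pair (Y, X) two autoregressions of order p are fitted by
least squares on the same effective window (the first p samples are
dropped from the targets so both models see identical observations):

* full:    X_t regressed on p lags of X and p lags of Y;
* reduced: X_t regressed on p lags of X only.

With maximum-likelihood residual variances (divisor = number of fitted
time points) the influence of Y on X is

    F_{Y->X} = ln( var'_X / var_X )

where var'_X is the reduced and var_X the full residual variance.  Because
the reduced regressors are a subset of the full ones over a common window,
F >= 0 up to floating-point round-off.

The lag order is chosen by the Bayesian Information Criterion

    BIC(p) = n_eff * ln det(Sigma_p) + k * ln(n_eff),    k = p * n_regions**2

minimized over a candidate range, with every candidate evaluated on the
same effective window (targets start after max_order samples) so the
criteria are comparable.  No intercept is fitted: signals are expected to
be standardized (see :func:`grangernet.timeseries.zscore`) or zero-mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .timeseries import ROITimeSeries

__all__ = [
    "MVARModel",
    "ConnectivityMatrix",
    "fit_var",
    "select_order_bic",
    "granger_pairwise",
    "pearson_matrix",
    "normalize_weights",
    "average_connection_strength",
    "aggregate_epochs",
]

# round-off guard on the nested-model log variance ratio
_F_NEG_TOL = 1e-8


@dataclass
class MVARModel:
    """Least-squares vector-autoregression fit.

    ``coeff_matrices[k][i, j]`` is the gain of channel j at lag k+1 in the
    equation for channel i.  ``resid_cov`` uses the maximum-likelihood
    divisor (1 / n_effective).
    """

    order: int
    coeff_matrices: np.ndarray  # (p, n, n)
    resid_cov: np.ndarray  # (n, n)
    n_effective: int
    bic: float

    def __post_init__(self) -> None:
        p, n, m = self.coeff_matrices.shape
        if p != self.order or n != m:
            raise ValueError("coefficient array must have shape (order, n, n)")
        if not np.allclose(self.resid_cov, self.resid_cov.T):
            raise ValueError("residual covariance must be symmetric")
        if np.any(np.diag(self.resid_cov) < 0):
            raise ValueError("residual variances must be non-negative")


@dataclass
class ConnectivityMatrix:
    """n x n weighted connectivity; ``weights[i, j]`` = influence of region i
    on region j (row = source, column = target).  ``method`` is ``"GCA"``
    (directed, non-negative) or ``"PCC"`` (undirected, symmetric)."""

    weights: np.ndarray
    directed: bool
    method: str
    region_labels: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got {w.shape}")
        if not np.allclose(np.diag(w), 0):
            raise ValueError("diagonal must be zero")
        if self.method == "GCA":
            if np.any(w < 0):
                raise ValueError("GCA weights must be non-negative")
        elif self.method == "PCC":
            if np.any(np.abs(w) > 1 + 1e-12):
                raise ValueError("PCC weights must lie in [-1, 1]")
            if not np.allclose(w, w.T):
                raise ValueError("PCC matrix must be symmetric")
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.weights = w
        self.region_labels = [str(l) for l in self.region_labels]
        if len(self.region_labels) != w.shape[0]:
            raise ValueError("label count must equal matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def _lag_matrix(data: np.ndarray, order: int, offset: int | None = None):
    """Targets and lagged-predictor design for a no-intercept VAR fit.

    Targets are ``data[:, offset:]`` (offset defaults to ``order``); the
    predictor block for lag k holds ``data[:, offset-k : T-k]``.  Column
    ``(k-1)*n + j`` of the design is channel j at lag k.
    """
    n, t = data.shape
    if offset is None:
        offset = order
    if offset < order:
        raise ValueError("offset must be >= order")
    y = data[:, offset:].T  # (n_eff, n)
    n_eff = t - offset
    if n_eff < 1:
        raise ValueError("series too short for requested order")
    lags = np.empty((n_eff, n * order))
    for k in range(1, order + 1):
        lags[:, (k - 1) * n : k * n] = data[:, offset - k : t - k].T
    return y, lags


def fit_var(ts: ROITimeSeries, order: int) -> MVARModel:
    """Fit a full multivariate autoregression of the given order by OLS."""
    if order < 1:
        raise ValueError("order must be >= 1")
    n, t = ts.data.shape
    if t <= order * n + 1:
        raise ValueError(
            f"{t} samples cannot identify a VAR({order}) on {n} channels "
            f"(need > {order * n + 1})"
        )
    y, lags = _lag_matrix(ts.data, order)
    coeffs, _, rank, sv = np.linalg.lstsq(lags, y, rcond=None)
    if rank < lags.shape[1]:
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        raise ValueError(
            f"rank-deficient design (rank {rank} < {lags.shape[1]}, cond {cond:.3g}); "
            "check for duplicated or constant channels"
        )
    n_eff = y.shape[0]
    resid = y - lags @ coeffs
    resid_cov = resid.T @ resid / n_eff
    # coeffs[(k-1)*n + j, i] -> A_k[i, j]
    coeff_matrices = np.stack(
        [coeffs[k * n : (k + 1) * n, :].T for k in range(order)]
    )
    bic = _bic(resid_cov, n_eff, order * n * n)
    return MVARModel(order, coeff_matrices, 0.5 * (resid_cov + resid_cov.T), n_eff, bic)


def _bic(resid_cov: np.ndarray, n_eff: int, k: int) -> float:
    sign, logdet = np.linalg.slogdet(np.atleast_2d(resid_cov))
    if sign <= 0:
        raise ValueError("singular residual covariance: degenerate channels")
    return float(n_eff * logdet + k * np.log(n_eff))


def select_order_bic(ts: ROITimeSeries, min_order: int = 1, max_order: int = 10) -> int:
    """Return the BIC-minimizing lag order over the inclusive candidate range.

    All candidates are scored on the same effective window (targets start
    at sample ``max_order``) so the criteria are directly comparable; ties
    resolve to the smaller order.
    """
    if not 1 <= min_order <= max_order:
        raise ValueError("need 1 <= min_order <= max_order")
    n, t = ts.data.shape
    if t - max_order <= max_order * n + 1:
        raise ValueError("series too short to identify the maximal candidate order")
    best_order, best_bic = None, np.inf
    for p in range(min_order, max_order + 1):
        y, lags = _lag_matrix(ts.data, p, offset=max_order)
        coeffs, _, rank, _ = np.linalg.lstsq(lags, y, rcond=None)
        if rank < lags.shape[1]:
            raise ValueError(f"rank-deficient design at order {p}")
        resid = y - lags @ coeffs
        n_eff = y.shape[0]
        bic = _bic(resid.T @ resid / n_eff, n_eff, p * n * n)
        if bic < best_bic:
            best_order, best_bic = p, bic
    return best_order


def granger_pairwise(ts: ROITimeSeries, order: int) -> ConnectivityMatrix:
    """Pairwise-bivariate Granger causality matrix at a fixed lag order.

    Entry [y, x] is F_{y->x}; the diagonal is zero.  Residual variances are
    obtained from the Gram matrix of the shared lagged design via Schur
    complements — algebraically identical to explicit per-pair least
    squares, which the test suite verifies against a brute-force oracle.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    n, t = ts.data.shape
    if t - order <= 2 * order + 1:
        raise ValueError("series too short for bivariate fits at this order")
    y, lags = _lag_matrix(ts.data, order)
    gram = lags.T @ lags
    cross = lags.T @ y
    sq = (y**2).sum(axis=0)

    def rss(target: int, pred_idx: np.ndarray) -> float:
        g = gram[np.ix_(pred_idx, pred_idx)]
        c = cross[pred_idx, target]
        try:
            sol = np.linalg.solve(g, c)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"singular design for target region {ts.region_labels[target]}; "
                "check for duplicated or constant channels"
            )
        return float(sq[target] - c @ sol)

    f = np.zeros((n, n))
    own_idx = [np.arange(order) * n + x for x in range(n)]
    rss_reduced = [rss(x, own_idx[x]) for x in range(n)]
    for x in range(n):
        for src in range(n):
            if src == x:
                continue
            full_idx = np.concatenate([own_idx[x], np.arange(order) * n + src])
            rss_full = rss(x, full_idx)
            if rss_full <= 0:
                raise ValueError(
                    f"zero full-model residual variance for region "
                    f"{ts.region_labels[x]} given {ts.region_labels[src]}: "
                    "deterministic channel"
                )
            val = np.log(rss_reduced[x] / rss_full)
            if val < 0:
                if val < -_F_NEG_TOL:
                    raise ValueError(
                        f"negative GC value {val:.3g} for "
                        f"{ts.region_labels[src]}->{ts.region_labels[x]}: "
                        "numerical breakdown"
                    )
                val = 0.0
            f[src, x] = val
    return ConnectivityMatrix(f, directed=True, method="GCA", region_labels=ts.region_labels)


def pearson_matrix(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between all region pairs, diagonal zeroed."""
    sd = ts.data.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"constant signal in region(s): {[ts.region_labels[i] for i in flat]}"
        )
    r = np.corrcoef(ts.data)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, directed=False, method="PCC", region_labels=ts.region_labels)


def normalize_weights(w: ConnectivityMatrix) -> ConnectivityMatrix:
    """Rescale weights to [0, 1] by the maximum off-diagonal magnitude.

    Pearson weights are rectified by absolute value first, because the
    downstream proportional threshold needs a non-negative strength
    ordering.  The diagonal stays zero; the strongest connection maps to 1.
    """
    vals = np.abs(w.weights) if w.method == "PCC" else w.weights.copy()
    mx = vals.max()
    if mx == 0:
        raise ValueError("all-zero connectivity matrix cannot be normalized")
    return replace(w, weights=vals / mx)


def average_connection_strength(w: ConnectivityMatrix) -> float:
    """Mean off-diagonal weight: all n(n-1) ordered pairs if directed, the
    upper triangle if undirected."""
    n = w.n_regions
    if w.directed:
        mask = ~np.eye(n, dtype=bool)
    else:
        mask = np.triu(np.ones((n, n), dtype=bool), k=1)
    return float(w.weights[mask].mean())


def aggregate_epochs(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean of per-epoch connectivity matrices."""
    if not matrices:
        raise ValueError("no matrices to aggregate")
    first = matrices[0]
    for m in matrices[1:]:
        if (
            m.weights.shape != first.weights.shape
            or m.method != first.method
            or m.directed != first.directed
            or m.region_labels != first.region_labels
        ):
            raise ValueError("matrices differ in shape, method or labels")
    mean = np.mean([m.weights for m in matrices], axis=0)
    if first.method == "PCC":
        mean = 0.5 * (mean + mean.T)
    np.fill_diagonal(mean, 0.0)
    return replace(first, weights=mean)
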