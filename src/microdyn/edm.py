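"""Empirical dynamic modeling: Takens embedding, simplex projection, S-map.

Each taxon's z-standardized abundance series is embedded with time-delay
coordinates z(t) = (x(t), x(t-1), ..., x(t-E+1)), tau = 1.  Forecasting at
horizon p uses a cross-replicate reference database: embedding vectors
never span a replicate boundary, and a target replicate never appears in
its own reference set.

Simplex projection predicts from the E+1 nearest reference neighbors with
weights exp(-d/d_min).  The S-map fits, for each query point, a locally
weighted linear map with weights w(d) = exp(-theta d / dbar) (dbar = mean
distance from the query to all reference points) solved by SVD least
squares; theta = 0 reduces to one global linear regression, and theta is
selected on a fixed grid by forecast RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_X_y

THETA_GRID = (0.0, 0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 4.0, 8.0)
E_RANGE = tuple(range(1, 21))


class EdmError(RuntimeError):
    pass


def zstandardize(series) -> tuple[np.ndarray, float, float, bool]:
    """Zero-mean unit-variance transform of one (taxon, replicate) series.

    Returns (z, mean, sd, constant_flag); a constant series maps to zeros
    with the flag set instead of dividing by zero.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    mu = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd == 0:
        return np.zeros_like(x), mu, 0.0, True
    return (x - mu) / sd, mu, sd, False


def destandardize(z, mean: float, sd: float) -> np.ndarray:
    return np.asarray(z, dtype=float) * sd + mean


def embed_series(x: np.ndarray, E: int, tau: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Delay embedding of one series: rows (x[t], x[t-tau], ..., x[t-(E-1)tau]).

    Returns (vectors, t_indices) where t_indices are positions in ``x``.
    """
    x = np.asarray(x, dtype=float)
    t0 = (E - 1) * tau
    if len(x) <= t0:
        raise EdmError(f"series of length {len(x)} too short for E={E}")
    ts = np.arange(t0, len(x))
    vecs = np.column_stack([x[ts - j * tau] for j in range(E)])
    return vecs, ts


@dataclass
class Embedding:
    """Reference database of embedded points with p-step futures.

    ``X`` holds embedding vectors, ``y`` the corresponding future values of
    the first coordinate, and ``block`` the (replicate, t) identity of each
    point.  No vector mixes samples from two replicates.
    """

    X: np.ndarray
    y: np.ndarray
    block: list

    @classmethod
    def from_series(
        cls, series_by_replicate: dict, E: int, p: int, tau: int = 1
    ) -> "Embedding":
        xs, ys, blocks = [], [], []
        for rep, x in series_by_replicate.items():
            x = np.asarray(x, dtype=float)
            try:
                vecs, ts = embed_series(x, E, tau)
            except EdmError:
                continue
            ok = ts + p < len(x)
            xs.append(vecs[ok])
            ys.append(x[ts[ok] + p])
            blocks.extend((rep, int(t)) for t in ts[ok])
        if not xs:
            raise EdmError("no replicate long enough for this embedding")
        return cls(np.vstack(xs), np.concatenate(ys), blocks)


class SimplexProjection(BaseEstimator, RegressorMixin):
    """Nearest-neighbor forecasting in embedded state space.

    Uses the ``n_neighbors`` = E+1 nearest reference points with weights
    exp(-d/d_min); zero-distance neighbors share uniform weight and exclude
    all others.
    """

    def __init__(self, n_neighbors: int | None = None):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.X_, self.y_ = X, y
        k = self.n_neighbors if self.n_neighbors is not None else X.shape[1] + 1
        if len(X) < k:
            raise EdmError(f"reference has {len(X)} points; need >= {k} neighbors")
        self.k_ = k
        return self

    def predict(self, X) -> np.ndarray:
        X = check_array(X)
        preds = np.empty(len(X))
        for i, q in enumerate(X):
            d = np.linalg.norm(self.X_ - q, axis=1)
            nn = np.argsort(d, kind="stable")[: self.k_]
            d_min = d[nn[0]]
            if d_min == 0:
                zero = nn[d[nn] == 0]
                preds[i] = self.y_[zero].mean()
            else:
                w = np.exp(-d[nn] / d_min)
                preds[i] = float(w @ self.y_[nn] / w.sum())
        return preds


class SMap(BaseEstimator, RegressorMixin):
    """Sequential locally weighted global linear maps.

    For each query z(t*) the model solves b = A C by SVD least squares with
    b_i = w_i y_i, A_i = w_i [1, z_ref(t'_i)], w_i = exp(-theta d_i / dbar),
    dbar the mean distance from the query to all reference points.  The
    prediction is C_0 + sum_j C_j z_j(t*); the coefficient rows (without
    intercept) estimate the local Jacobian of the map.
    """

    def __init__(self, theta: float = 0.0):
        self.theta = theta

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")
        self.X_, self.y_ = X, y
        return self

    def _solve(self, q: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(self.X_ - q, axis=1)
        dbar = d.mean()
        if dbar == 0:
            raise EdmError("degenerate reference: all points coincide with the query")
        w = np.exp(-self.theta * d / dbar)
        A = w[:, None] * np.column_stack([np.ones(len(self.X_)), self.X_])
        b = w * self.y_
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        return coef  # (C0, C1..CE)

    def local_coefficients(self, X) -> np.ndarray:
        """Per-query coefficient vectors (C0, C1..CE)."""
        X = check_array(X)
        return np.vstack([self._solve(q) for q in X])

    def predict(self, X) -> np.ndarray:
        X = check_array(X)
        C = self.local_coefficients(X)
        return C[:, 0] + np.einsum("ij,ij->i", C[:, 1:], X)


# ---------------------------------------------------------------------------
# E and theta selection
# ---------------------------------------------------------------------------

def _forecast_rmse(
    target: np.ndarray,
    reference: dict,
    E: int,
    p: int,
    method: str = "simplex",
    theta: float = 0.0,
) -> float:
    ref = Embedding.from_series(reference, E, p)
    vecs, ts = embed_series(np.asarray(target, dtype=float), E)
    ok = ts + p < len(target)
    if not ok.any():
        raise EdmError("target series too short for this E and p")
    obs = np.asarray(target, dtype=float)[ts[ok] + p]
    if method == "simplex":
        model = SimplexProjection().fit(ref.X, ref.y)
    elif method == "smap":
        model = SMap(theta=theta).fit(ref.X, ref.y)
    else:
        raise ValueError(f"unknown method {method!r}")
    pred = model.predict(vecs[ok])
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def select_embedding_dimension(
    target,
    reference: dict,
    E_range=E_RANGE,
    p: int = 1,
    method: str = "simplex",
) -> int:
    """E minimizing pre-run forecast RMSE; ties go to the smallest E."""
    best_e, best_rmse = None, np.inf
    for E in E_range:
        try:
            rmse = _forecast_rmse(target, reference, E, p, method=method)
        except EdmError:
            continue
        if rmse < best_rmse - 1e-12:
            best_e, best_rmse = E, rmse
    if best_e is None:
        raise EdmError("series too short for any embedding dimension in range")
    return best_e


def optimize_theta(
    target,
    reference: dict,
    E: int,
    grid=THETA_GRID,
    p: int = 1,
) -> float:
    """Grid member minimizing S-map forecast RMSE; ties go to smaller theta."""
    best_t, best_rmse = None, np.inf
    for theta in grid:
        rmse = _forecast_rmse(target, reference, E, p, method="smap", theta=theta)
        if rmse < best_rmse - 1e-12:
            best_t, best_rmse = theta, rmse
    return best_t


def nonlinearity_fraction(thetas) -> float:
    """Fraction of (taxon, replicate) fits with optimal theta > 0."""
    t = np.asarray(list(thetas), dtype=float)
    if t.size == 0:
        raise ValueError("no theta values supplied")
    return float((t > 0).mean())
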