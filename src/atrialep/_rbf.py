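"""Gaussian radial-basis-function interpolation with LOOCV hyperparameter search.

Both the LAT and CV surface maps use the same engine: a Gaussian kernel
``exp(-(eps*r)**2)`` with a ridge ("smoothing") term on the kernel diagonal.
The shape parameter ``eps`` and the smoothing ``lam`` are selected by exact
leave-one-out cross-validation, which for a ridge-regularised kernel system
``(K + lam*I) c = y`` has the closed form ``e_i = c_i / (K + lam*I)^{-1}_{ii}``
— one factorisation per candidate instead of n refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist


@dataclass
class RbfModel:
    points: np.ndarray          # (n, d) data sites
    coefs: np.ndarray           # (n,) kernel weights
    epsilon: float              # kernel shape parameter, 1/mm
    smoothing: float            # ridge added to the kernel diagonal
    loocv_rmse: float           # LOO error of the selected hyperparameters
    support_radius: float       # queries farther than this from all data -> NaN

    def __call__(self, query: np.ndarray) -> np.ndarray:
        query = np.atleast_2d(np.asarray(query, dtype=float))
        K = np.exp(-(self.epsilon * cdist(query, self.points)) ** 2)
        out = K @ self.coefs
        if np.isfinite(self.support_radius):
            d, _ = cKDTree(self.points).query(query)
            out[d > self.support_radius] = np.nan
        return out


def _loo_rmse(K: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    A = K + lam * np.eye(len(K))
    try:
        c, low = cho_factor(A)
        Ainv = cho_solve((c, low), np.eye(len(K)))
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(len(K))
    coefs = Ainv @ y
    diag = np.diag(Ainv)
    if np.any(diag <= 0):
        return np.inf, coefs
    resid = coefs / diag
    return float(np.sqrt(np.mean(resid ** 2))), coefs


def fit_rbf(points: np.ndarray, values: np.ndarray,
            eps_grid: np.ndarray | None = None,
            smoothing_grid: np.ndarray | None = None,
            support_radius: float = 10.0) -> RbfModel:
    """Fit a Gaussian RBF to scattered data, selecting eps and smoothing by LOOCV.

    Parameters
    ----------
    points : (n, d) data sites in mm, n >= 4
    values : (n,) measurements
    eps_grid : candidate shape parameters (1/mm).  Default: a logarithmic
        grid scaled to the median nearest-neighbour spacing of the data.
    smoothing_grid : candidate ridge values.  Default ``{1e-8 .. 1e-1}``.
    support_radius : mm; evaluations farther than this from every data
        site return NaN (regions with insufficient data stay undefined).
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if len(points) < 4:
        raise ValueError("RBF interpolation requires at least 4 data points")
    if len(points) != len(values):
        raise ValueError("points and values length mismatch")

    # collapse exact duplicate sites (averaging their values) so the kernel
    # matrix cannot be trivially singular
    _, idx, inv = np.unique(np.round(points, 9), axis=0,
                            return_index=True, return_inverse=True)
    if len(idx) < len(points):
        agg = np.zeros(len(idx))
        cnt = np.zeros(len(idx))
        np.add.at(agg, inv, values)
        np.add.at(cnt, inv, 1.0)
        points = np.round(points, 9)[idx]
        values = agg / cnt
        if len(points) < 4:
            raise ValueError("fewer than 4 unique data points")

    if eps_grid is None:
        d, _ = cKDTree(points).query(points, k=2)
        h = float(np.median(d[:, 1]))
        h = max(h, 1e-6)
        eps_grid = np.geomspace(0.1 / h, 2.0 / h, 6)
    if smoothing_grid is None:
        smoothing_grid = np.geomspace(1e-8, 1e-1, 8)

    r = cdist(points, points)
    best = (np.inf, None, None, None)
    for eps in np.atleast_1d(eps_grid):
        K = np.exp(-(eps * r) ** 2)
        for lam in np.atleast_1d(smoothing_grid):
            rmse, coefs = _loo_rmse(K, values, lam)
            if rmse < best[0]:
                best = (rmse, eps, lam, coefs)

    rmse, eps, lam, coefs = best
    if eps is None:
        # every candidate system was singular: fall back to a heavy ridge
        eps = float(np.atleast_1d(eps_grid)[0])
        lam = 1e-2
        K = np.exp(-(eps * r) ** 2)
        coefs = solve(K + lam * np.eye(len(K)), values)
        rmse = np.inf
    return RbfModel(points=points, coefs=coefs, epsilon=float(eps),
                    smoothing=float(lam), loocv_rmse=rmse,
                    support_radius=float(support_radius))
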