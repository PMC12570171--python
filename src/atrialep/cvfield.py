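"""Conduction-velocity vector fields from local activation times.

At every recording point a quadratic polynomial surface T(u, v) is fitted
by least squares to the LATs of its spatial neighbourhood, expressed in a
local tangent plane.  The CV vector is the inverse gradient of that
surface, v = g / |g|^2, so the speed is 1/|g|.  Wavefront-collision sites
produce artificially high apparent speeds; they are located as points
where the divergence of the CV field falls below -1.5 1/s and are
excluded before interpolation and summary statistics.

Units: coordinates mm, LAT ms, so a LAT gradient in ms/mm equals s/m and
its inverse is directly in m/s; divergence is converted to 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._rbf import RbfModel, fit_rbf
from .mesh import SurfaceMesh


@dataclass
class CvConfig:
    fit_radius_mm: float = 5.0
    min_neighbors: int = 8
    poly_degree: int = 2
    div_threshold_per_s: float = -1.5
    max_physiological_cv: float = 2.0    # m/s QC gate on magnitudes
    min_gradient_ms_per_mm: float = 1e-3  # below this, activation is treated
                                          # as simultaneous and CV undefined
    support_radius_mm: float = 10.0
    histogram_bin_m_per_s: float = 0.05


@dataclass
class CvField:
    point_xyz: np.ndarray          # (n, 3) mm
    cv_vectors: np.ndarray         # (n, 3) m/s, NaN rows where undefined
    cv_magnitude: np.ndarray       # (n,) m/s
    divergence: np.ndarray         # (n,) 1/s, NaN where not computable
    collision_mask: np.ndarray     # True where excluded as a collision site
    defined_mask: np.ndarray       # True where a CV vector exists
    interpolated_magnitude: np.ndarray | None = None   # per mesh vertex
    model: RbfModel | None = None
    condition_numbers: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def retained_mask(self) -> np.ndarray:
        return self.defined_mask & ~self.collision_mask

    @property
    def retained_magnitudes(self) -> np.ndarray:
        return self.cv_magnitude[self.retained_mask]


def _tangent_basis(centered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis (e1, e2) from PCA of centred neighbour
    coordinates; works on meshes and raw point clouds alike."""
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0], vt[1]


def fit_local_surface(point: np.ndarray, neighbors_xyz: np.ndarray,
                      neighbors_lat: np.ndarray,
                      cfg: CvConfig | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Least-squares polynomial fit of LAT over the tangent plane at a point.

    Returns ``(gradient, e1, e2, cond)``: the in-plane LAT gradient
    (ms/mm) evaluated at the point, the tangent basis vectors, and the
    condition number of the design matrix.  Raises on a rank-deficient
    design (e.g. collinear electrodes).
    """
    cfg = cfg or CvConfig()
    point = np.asarray(point, dtype=float)
    xyz = np.asarray(neighbors_xyz, dtype=float)
    lat = np.asarray(neighbors_lat, dtype=float)
    deg = cfg.poly_degree
    n_coef = (deg + 1) * (deg + 2) // 2
    if len(xyz) < n_coef:
        raise ValueError(f"need >= {n_coef} neighbors for degree {deg}")
    centered = xyz - point
    e1, e2 = _tangent_basis(centered)
    u = centered @ e1
    v = centered @ e2
    cols = [np.ones_like(u)]
    for total in range(1, deg + 1):
        for j in range(total + 1):
            cols.append(u ** (total - j) * v ** j)
    A = np.column_stack(cols)
    cond = float(np.linalg.cond(A))
    coef, _, rank, _ = np.linalg.lstsq(A, lat, rcond=None)
    if rank < n_coef:
        raise np.linalg.LinAlgError("rank-deficient design (collinear points)")
    grad = np.array([coef[1], coef[2]])   # dT/du, dT/dv at the point
    return grad, e1, e2, cond


def cv_from_gradient(gradient: np.ndarray, e1: np.ndarray | None = None,
                     e2: np.ndarray | None = None,
                     cfg: CvConfig | None = None) -> np.ndarray | None:
    """CV vector as the inverse gradient: v = g/|g|^2 (m/s).

    With ``e1``/``e2`` given, the in-plane vector is mapped back to 3-D.
    Returns None when the gradient is too small (near-simultaneous
    activation, CV undefined).
    """
    cfg = cfg or CvConfig()
    g = np.asarray(gradient, dtype=float)
    g2 = float(g @ g)
    if np.sqrt(g2) < cfg.min_gradient_ms_per_mm:
        return None
    v = g / g2                     # mm/ms == m/s
    if e1 is None:
        return v
    return v[0] * e1 + v[1] * e2


def estimate_cv_field(point_xyz: np.ndarray, lats: np.ndarray,
                      cfg: CvConfig | None = None) -> CvField:
    """CV vectors, divergence and collision mask at every recording point."""
    cfg = cfg or CvConfig()
    pts = np.asarray(point_xyz, dtype=float)
    lats = np.asarray(lats, dtype=float)
    finite = np.isfinite(lats)
    n = len(pts)
    tree = cKDTree(pts[finite])
    fin_idx = np.nonzero(finite)[0]

    vectors = np.full((n, 3), np.nan)
    conds = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    for i in range(n):
        if not finite[i]:
            continue
        nb = tree.query_ball_point(pts[i], cfg.fit_radius_mm)
        if len(nb) < max(cfg.min_neighbors, 6):
            k = min(max(cfg.min_neighbors, 6), len(fin_idx))
            _, nb = tree.query(pts[i], k=k)
            nb = np.atleast_1d(nb)
        nb_global = fin_idx[np.asarray(nb, dtype=int)]
        if len(nb_global) < 6:
            continue
        try:
            grad, e1, e2, cond = fit_local_surface(pts[i], pts[nb_global],
                                                   lats[nb_global], cfg)
        except (ValueError, np.linalg.LinAlgError):
            continue
        conds[i] = cond
        v = cv_from_gradient(grad, e1, e2, cfg)
        if v is None:
            continue
        vectors[i] = v
        defined[i] = True

    div = divergence(pts, vectors, defined, cfg)
    collision = exclude_collisions(div, cfg)
    mag = np.linalg.norm(vectors, axis=1)
    return CvField(point_xyz=pts, cv_vectors=vectors, cv_magnitude=mag,
                   divergence=div, collision_mask=collision,
                   defined_mask=defined, condition_numbers=conds)


def divergence(point_xyz: np.ndarray, cv_vectors: np.ndarray,
               defined_mask: np.ndarray | None = None,
               cfg: CvConfig | None = None) -> np.ndarray:
    """Per-point divergence of the CV field (1/s).

    In the local tangent plane the two CV components are each fitted with
    a linear model over the neighbourhood; the divergence is
    d(v_u)/du + d(v_v)/dv, converted from (m/s)/mm to 1/s.  Points with
    fewer than 6 CV-bearing neighbours get NaN (they are never
    auto-excluded on that account).
    """
    cfg = cfg or CvConfig()
    pts = np.asarray(point_xyz, dtype=float)
    vec = np.asarray(cv_vectors, dtype=float)
    if defined_mask is None:
        defined_mask = np.all(np.isfinite(vec), axis=1)
    n = len(pts)
    out = np.full(n, np.nan)
    def_idx = np.nonzero(defined_mask)[0]
    if len(def_idx) < 6:
        return out
    tree = cKDTree(pts[def_idx])
    for i in range(n):
        if not defined_mask[i]:
            continue
        nb = tree.query_ball_point(pts[i], cfg.fit_radius_mm)
        nb_global = def_idx[np.asarray(nb, dtype=int)]
        if len(nb_global) < 6:
            continue
        centered = pts[nb_global] - pts[i]
        e1, e2 = _tangent_basis(centered)
        u = centered @ e1
        v = centered @ e2
        A = np.column_stack([np.ones_like(u), u, v])
        vu = vec[nb_global] @ e1
        vv = vec[nb_global] @ e2
        try:
            cu, _, rank, _ = np.linalg.lstsq(A, vu, rcond=None)
            cv_, _, rank2, _ = np.linalg.lstsq(A, vv, rcond=None)
        except np.linalg.LinAlgError:
            continue
        if rank < 3 or rank2 < 3:
            continue
        out[i] = (cu[1] + cv_[2]) * 1000.0   # (m/s)/mm -> 1/s
    return out


def exclude_collisions(div: np.ndarray,
                       cfg: CvConfig | None = None) -> np.ndarray:
    """Collision mask: divergence strictly below the threshold (-1.5 1/s).

    The boundary value itself is retained; NaN divergence is retained.
    """
    cfg = cfg or CvConfig()
    div = np.asarray(div, dtype=float)
    with np.errstate(invalid="ignore"):
        return div < cfg.div_threshold_per_s


def interpolate_cv(mesh: SurfaceMesh, point_xyz: np.ndarray,
                   magnitudes: np.ndarray,
                   retained_mask: np.ndarray | None = None,
                   cfg: CvConfig | None = None
                   ) -> tuple[np.ndarray, RbfModel]:
    """Gaussian-RBF CV-magnitude map on the mesh; unsupported regions NaN."""
    cfg = cfg or CvConfig()
    pts = np.asarray(point_xyz, dtype=float)
    mag = np.asarray(magnitudes, dtype=float)
    if retained_mask is None:
        retained_mask = np.isfinite(mag)
    if int(retained_mask.sum()) < 4:
        raise ValueError("CV interpolation requires at least 4 retained points")
    model = fit_rbf(pts[retained_mask], mag[retained_mask],
                    support_radius=cfg.support_radius_mm)
    return model(mesh.vertices), model


def cv_summary(magnitudes: np.ndarray, cfg: CvConfig | None = None) -> dict:
    """Median/mean/IQR and a fixed-bin histogram of retained CV magnitudes.

    Magnitudes above the physiological QC gate are excluded and counted.
    """
    cfg = cfg or CvConfig()
    mag = np.asarray(magnitudes, dtype=float)
    mag = mag[np.isfinite(mag)]
    if len(mag) == 0:
        raise ValueError("no CV magnitudes to summarize")
    over = mag > cfg.max_physiological_cv
    n_gated = int(over.sum())
    mag = mag[~over]
    if len(mag) == 0:
        raise ValueError("all CV magnitudes exceeded the physiological gate")
    q25, q75 = np.percentile(mag, [25, 75])
    edges = np.arange(0.0, cfg.max_physiological_cv + 1e-9,
                      cfg.histogram_bin_m_per_s)
    hist, _ = np.histogram(mag, bins=edges)
    return {"n": int(len(mag)), "n_gated": n_gated,
            "median": float(np.median(mag)), "mean": float(np.mean(mag)),
            "iqr": float(q75 - q25), "q25": float(q25), "q75": float(q75),
            "hist_counts": hist, "hist_edges": edges}
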