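"""Unipolar electrogram analysis: LAT detection, mapping and TAAT.

Local activation time (LAT) is the instant of maximum negative slope of
the unipolar voltage, expressed relative to a coronary-sinus (CS)
reference.  Electrode LATs are projected onto the nearest vertex of the
chamber's surface mesh, screened with a 2-mm neighbourhood outlier check,
and interpolated over the mesh with a Gaussian-kernel RBF whose shape and
smoothing hyperparameters are selected by leave-one-out cross-validation.
Total atrial activation time (TAAT) is the interval from the earliest
right-atrial LAT to the activation detected at the distal CS electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.spatial import cKDTree

from ._rbf import RbfModel, fit_rbf
from .mesh import SurfaceMesh


@dataclass
class EgmConfig:
    sg_order: int = 2
    sg_span: int = 201               # samples
    bp_order: int = 5
    bp_low_hz: float = 2.0
    bp_high_hz: float = 100.0
    projection_gate_mm: float = 5.0
    neighborhood_radius_mm: float = 2.0
    outlier_tol_ms: float = 10.0
    support_radius_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.sg_span % 2 == 0:
            raise ValueError("sg_span must be odd")
        if not self.bp_low_hz < self.bp_high_hz:
            raise ValueError("bp_low_hz must be below bp_high_hz")


@dataclass
class EgmDataset:
    """Unipolar electrograms with geometry.

    signals : (n_electrodes, n_samples) mV
    fs : Hz (clinical systems export at 953.6 Hz)
    electrode_xyz : (n_electrodes, 3) mm
    mesh : chamber surface
    cs_reference_time_ms : activation time on the CS reference channel
    """

    signals: np.ndarray
    fs: float
    electrode_xyz: np.ndarray
    mesh: SurfaceMesh
    cs_reference_time_ms: float = 0.0
    cs_signal: np.ndarray | None = None
    chamber_label: str = "RA"

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        self.electrode_xyz = np.asarray(self.electrode_xyz, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.electrode_xyz) != len(self.signals):
            raise ValueError("electrode_xyz must match number of signals")

    @property
    def n_electrodes(self) -> int:
        return len(self.signals)


@dataclass
class LatMap:
    vertex_lat: np.ndarray           # ms per mesh vertex, NaN where unsupported
    source_vertices: np.ndarray      # indices of vertices carrying data
    source_lats: np.ndarray          # measured (projected) LATs at those vertices
    valid_mask: np.ndarray           # per-source-vertex: survived outlier check
    isolated_mask: np.ndarray = field(default_factory=lambda: np.array([], bool))
    model: RbfModel | None = None
    n_dropped_electrodes: int = 0

    @property
    def earliest_ms(self) -> float:
        vals = self.source_lats[self.valid_mask]
        if len(vals) == 0:
            raise ValueError("LAT map has no valid points")
        return float(np.min(vals))


# ---------------------------------------------------------------------------

def condition(signals: np.ndarray, fs: float,
              cfg: EgmConfig | None = None) -> np.ndarray:
    """Detrend by subtracting a Savitzky–Golay smoothed trend (order 2,
    span 201) and band-pass with a zero-phase fifth-order Butterworth."""
    cfg = cfg or EgmConfig()
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if x.shape[1] <= cfg.sg_span:
        raise ValueError(
            f"signals of {x.shape[1]} samples are shorter than the "
            f"Savitzky-Golay span of {cfg.sg_span}")
    trend = sps.savgol_filter(x, cfg.sg_span, cfg.sg_order, axis=1)
    x = x - trend
    high = min(cfg.bp_high_hz, 0.45 * fs)
    sos = sps.butter(cfg.bp_order, [cfg.bp_low_hz, high], btype="band",
                     fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, x, axis=1)
    return out if np.asarray(signals).ndim > 1 else out[0]


def detect_lat(egm_signal: np.ndarray, cs_time_ms: float, fs: float
               ) -> tuple[float, bool]:
    """LAT = time of maximum negative dV/dt minus the CS reference time.

    The derivative is a central difference; the minimum is refined to
    sub-sample precision by a parabolic fit through its neighbours.
    Returns ``(lat_ms, edge_flag)`` — the flag marks low confidence when
    the extremum sits at the window edge (no deflection to anchor on).
    """
    if not np.isfinite(cs_time_ms):
        raise ValueError("cs_time_ms must be finite")
    x = np.asarray(egm_signal, dtype=float)
    if len(x) < 5:
        raise ValueError("signal too short for LAT detection")
    dt = 1000.0 / fs
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) / (2 * dt)
    d[0], d[-1] = d[1], d[-2]
    i = int(np.argmin(d[1:-1])) + 1
    edge = i <= 1 or i >= len(x) - 2
    # no distinct downstroke: trough depth indistinguishable from the bulk
    med = float(np.median(d))
    mad = float(np.median(np.abs(d - med)))
    if med - d[i] <= 5.0 * mad + 1e-12:
        edge = True
    t = i * dt
    if not edge:
        y0, y1, y2 = d[i - 1], d[i], d[i + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-15:
            t += dt * 0.5 * (y0 - y2) / denom
    return float(t - cs_time_ms), bool(edge)


def detect_lat_all(ds: EgmDataset, cfg: EgmConfig | None = None,
                   conditioned: bool = False
                   ) -> tuple[np.ndarray, np.ndarray]:
    """LATs (ms, relative to the CS reference) for every electrode."""
    cfg = cfg or EgmConfig()
    sig = ds.signals if conditioned else condition(ds.signals, ds.fs, cfg)
    lats = np.empty(ds.n_electrodes)
    flags = np.empty(ds.n_electrodes, dtype=bool)
    for k in range(ds.n_electrodes):
        lats[k], flags[k] = detect_lat(sig[k], ds.cs_reference_time_ms, ds.fs)
    return lats, flags


def project_to_mesh(electrode_xyz: np.ndarray, lats: np.ndarray,
                    mesh: SurfaceMesh, gate_mm: float = 5.0
                    ) -> tuple[np.ndarray, np.ndarray, int]:
    """Assign each LAT to the nearest mesh vertex; co-located LATs are
    arithmetically averaged; electrodes beyond ``gate_mm`` are dropped.

    Returns ``(vertex_lats, counts, n_dropped)`` where ``vertex_lats`` is
    NaN at vertices that received no electrode.
    """
    electrode_xyz = np.asarray(electrode_xyz, dtype=float)
    lats = np.asarray(lats, dtype=float)
    tree = cKDTree(mesh.vertices)
    dist, vidx = tree.query(electrode_xyz)
    ok = dist <= gate_mm
    n_dropped = int(np.sum(~ok))
    acc = np.zeros(mesh.n_vertices)
    counts = np.zeros(mesh.n_vertices)
    np.add.at(acc, vidx[ok], lats[ok])
    np.add.at(counts, vidx[ok], 1.0)
    out = np.full(mesh.n_vertices, np.nan)
    has = counts > 0
    if not has.any():
        raise ValueError("no electrode lies within the projection gate")
    out[has] = acc[has] / counts[has]
    return out, counts.astype(int), n_dropped


def exclude_outliers(vertex_lats: np.ndarray, mesh: SurfaceMesh,
                     cfg: EgmConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """2-mm neighbourhood check on populated vertices.

    A vertex is excluded when at least 2 other populated vertices lie
    within ``neighborhood_radius_mm`` (Euclidean, a good geodesic proxy at
    this scale) and its LAT deviates from their median by more than
    ``outlier_tol_ms``.  Vertices with fewer neighbours are retained but
    flagged isolated.  Returns ``(valid_mask, isolated_mask)`` over the
    populated vertices in index order.
    """
    cfg = cfg or EgmConfig()
    pop = np.nonzero(np.isfinite(vertex_lats))[0]
    if len(pop) < 4:
        raise ValueError("need at least 4 populated vertices")
    pts = mesh.vertices[pop]
    vals = vertex_lats[pop]
    tree = cKDTree(pts)
    pairs = tree.query_ball_tree(tree, cfg.neighborhood_radius_mm + 1e-9)
    valid = np.ones(len(pop), dtype=bool)
    isolated = np.zeros(len(pop), dtype=bool)
    for i, nb in enumerate(pairs):
        others = [j for j in nb if j != i]
        if len(others) < 2:
            isolated[i] = True
            continue
        if abs(vals[i] - np.median(vals[others])) > cfg.outlier_tol_ms:
            valid[i] = False
    return valid, isolated


def interpolate_lat(mesh: SurfaceMesh, vertex_lats: np.ndarray,
                    valid_mask: np.ndarray | None = None,
                    cfg: EgmConfig | None = None) -> LatMap:
    """Gaussian-RBF LAT map over all mesh vertices (NaN outside support)."""
    cfg = cfg or EgmConfig()
    pop = np.nonzero(np.isfinite(vertex_lats))[0]
    if valid_mask is None:
        valid_mask = np.ones(len(pop), dtype=bool)
    if int(valid_mask.sum()) < 4:
        raise ValueError("RBF LAT interpolation requires at least 4 valid points")
    src = pop[valid_mask]
    model = fit_rbf(mesh.vertices[src], vertex_lats[src],
                    support_radius=cfg.support_radius_mm)
    vmap = model(mesh.vertices)
    return LatMap(vertex_lat=vmap, source_vertices=pop,
                  source_lats=vertex_lats[pop], valid_mask=valid_mask,
                  model=model)


def build_lat_map(ds: EgmDataset, cfg: EgmConfig | None = None) -> LatMap:
    """Full chain: condition, detect, project, screen, interpolate."""
    cfg = cfg or EgmConfig()
    lats, _ = detect_lat_all(ds, cfg)
    vlats, _, n_dropped = project_to_mesh(ds.electrode_xyz, lats, ds.mesh,
                                          gate_mm=cfg.projection_gate_mm)
    valid, isolated = exclude_outliers(vlats, ds.mesh, cfg)
    lm = interpolate_lat(ds.mesh, vlats, valid, cfg)
    lm.isolated_mask = isolated
    lm.n_dropped_electrodes = n_dropped
    return lm


def compute_taat(ra_map: LatMap | np.ndarray,
                 cs_distal_time_ms: float) -> tuple[float, bool]:
    """TAAT = CS-distal activation time minus the earliest valid RA LAT.

    Returns ``(taat_ms, physiological)``; the flag is False when the CS
    distal activation precedes the earliest RA activation (non-physiologic
    for sinus rhythm, the value is still reported).
    """
    if not np.isfinite(cs_distal_time_ms):
        raise ValueError("cs_distal_time_ms must be finite")
    if isinstance(ra_map, LatMap):
        earliest = ra_map.earliest_ms
    else:
        vals = np.asarray(ra_map, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError("empty LAT map")
        earliest = float(np.min(vals))
    taat = float(cs_distal_time_ms - earliest)
    return taat, taat > 0
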