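"""Triangulated surface meshes used by the mapping and synthesis modules.

Coordinates are millimetres throughout.  The container is a thin wrapper
around ``(vertices, faces)`` arrays; heavier geometric queries (surface
sampling, nearest-point projection) delegate to :mod:`trimesh`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh


@dataclass
class SurfaceMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def validate(self, min_area: float = 1e-9) -> None:
        """Raise on degenerate (zero-area) triangles."""
        areas = self.face_areas()
        if np.any(areas <= min_area):
            bad = int(np.argmin(areas))
            raise ValueError(f"mesh contains a degenerate triangle (face {bad})")

    def save_ply(self, path) -> None:
        self.as_trimesh().export(path, encoding="ascii")


def flat_rectangle(width_mm: float = 40.0, height_mm: float = 40.0,
                   spacing_mm: float = 2.0) -> SurfaceMesh:
    """Regular triangulated rectangle in the z = 0 plane, corner at origin."""
    nx = int(round(width_mm / spacing_mm)) + 1
    ny = int(round(height_mm / spacing_mm)) + 1
    xs = np.linspace(0.0, width_mm, nx)
    ys = np.linspace(0.0, height_mm, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return SurfaceMesh(vertices, np.array(faces))


def spherical_cap(radius_mm: float = 30.0, half_angle_deg: float = 45.0,
                  n_rings: int = 12) -> SurfaceMesh:
    """Spherical cap centred on the +z pole of a sphere of given radius.

    Used to exercise tangent-plane projection in CV fitting on a curved
    surface; triangulated as concentric rings around the pole.
    """
    half = np.deg2rad(half_angle_deg)
    verts = [np.array([0.0, 0.0, radius_mm])]
    ring_start = [0]
    for r in range(1, n_rings + 1):
        theta = half * r / n_rings
        n_on_ring = max(6, int(round(2 * np.pi * np.sin(theta) / (half / n_rings))))
        ring_start.append(len(verts))
        phis = 2 * np.pi * np.arange(n_on_ring) / n_on_ring
        for phi in phis:
            verts.append(radius_mm * np.array([
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(theta),
            ]))
    ring_start.append(len(verts))
    vertices = np.array(verts)

    faces = []
    # pole fan
    first = ring_start[1]
    n1 = ring_start[2] - first
    for k in range(n1):
        faces.append([0, first + k, first + (k + 1) % n1])
    # stitch consecutive rings greedily by angle
    for r in range(1, n_rings):
        a0, a1 = ring_start[r], ring_start[r + 1]
        b0, b1 = ring_start[r + 1], ring_start[r + 2]
        na, nb = a1 - a0, b1 - b0
        ang_a = np.arctan2(vertices[a0:a1, 1], vertices[a0:a1, 0])
        ang_b = np.arctan2(vertices[b0:b1, 1], vertices[b0:b1, 0])
        i = j = 0
        # walk both rings once, always advancing the ring whose next angle is smaller
        while i < na or j < nb:
            ai, aj = a0 + i % na, b0 + j % nb
            adv_a = j >= nb or (i < na and
                                ang_a[i % na] <= ang_b[j % nb])
            if adv_a:
                faces.append([ai, b0 + j % nb, a0 + (i + 1) % na])
                i += 1
            else:
                faces.append([ai, b0 + j % nb, b0 + (j + 1) % nb])
                j += 1
    m = SurfaceMesh(vertices, np.array(faces))
    # drop any numerically degenerate stitch triangles
    keep = m.face_areas() > 1e-9
    return SurfaceMesh(vertices, m.faces[keep])
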