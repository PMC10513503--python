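"""Triangulated surface meshes, solid-angle kernels and electrode montages.

All meshes are closed, consistently outward-oriented triangle surfaces with
coordinates in millimetres, right-handed axes and the torso long axis along z.
Vertex indices are 0-based throughout. Solid angles follow the convention in
which a closed outward-oriented surface subtends -4*pi at an interior
observation point and 0 at an exterior one.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "ElectrodeMontage",
    "MeshError",
    "OpenSurfaceError",
    "OrientationError",
    "SingularGeometryError",
    "load_mesh",
    "write_mesh",
    "triangle_solid_angle",
    "mesh_solid_angles",
    "solid_angle_sum",
    "points_inside",
    "place_electrode_strips",
    "load_montage",
    "write_montage",
]


class MeshError(ValueError):
    """A surface mesh violates a structural invariant."""


class OpenSurfaceError(MeshError):
    """The surface is not closed (an edge is not shared by exactly 2 triangles)."""


class OrientationError(MeshError):
    """Triangle winding is inconsistent and could not be repaired."""


class SingularGeometryError(ValueError):
    """An observation point lies on (or numerically on) a source triangle."""


@dataclass(frozen=True)
class TriMesh:
    """A closed, outward-oriented triangulated surface.

    Parameters
    ----------
    vertices : (N, 3) float array, millimetres.
    triangles : (F, 3) int array of 0-based vertex indices.
    name : label used in provenance and error messages.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    name: str = "surface"

    def __post_init__(self):
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=np.float64))
        object.__setattr__(self, "triangles", np.asarray(self.triangles, dtype=np.int64))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"{self.name}: vertices must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError(f"{self.name}: triangles must be (F, 3)")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    def signed_volume(self) -> float:
        """Signed enclosed volume via the divergence theorem (positive = outward)."""
        v = self.vertices[self.triangles]
        return float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2]))) / 6.0

    def diameter(self) -> float:
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def mean_edge_length(self) -> float:
        e = np.concatenate(
            [
                self.vertices[self.triangles[:, 1]] - self.vertices[self.triangles[:, 0]],
                self.vertices[self.triangles[:, 2]] - self.vertices[self.triangles[:, 1]],
                self.vertices[self.triangles[:, 0]] - self.vertices[self.triangles[:, 2]],
            ]
        )
        return float(np.linalg.norm(e, axis=1).mean())

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def validate(self) -> "TriMesh":
        """Check all invariants, repairing orientation where possible.

        Returns a mesh that passes every invariant (possibly with repaired
        triangle winding) or raises a specific :class:`MeshError` subclass.
        """
        t = self.triangles
        if t.size and (t.min() < 0 or t.max() >= self.n_vertices):
            raise MeshError(f"{self.name}: triangle index out of range")
        areas = self.triangle_areas()
        scale = self.diameter()
        if np.any(areas <= 1e-14 * scale**2):
            bad = int(np.argmin(areas))
            raise MeshError(f"{self.name}: degenerate (zero-area) triangle {bad}")
        # closedness: each undirected edge in exactly two triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        und = np.sort(edges, axis=1)
        _, counts = np.unique(und, axis=0, return_counts=True)
        if np.any(counts != 2):
            raise OpenSurfaceError(
                f"{self.name}: open surface ({int(np.sum(counts != 2))} edges not shared by 2 triangles)"
            )
        mesh = self._repair_orientation()
        if mesh.signed_volume() <= 0:
            raise OrientationError(f"{self.name}: non-positive signed volume after repair")
        return mesh

    def _repair_orientation(self) -> "TriMesh":
        """Make winding consistent by breadth-first flip propagation, then
        flip globally if the signed volume is negative."""
        t = self.triangles.copy()
        # map undirected edge -> incident triangles
        tm = _trimesh.Trimesh(vertices=self.vertices, faces=t, process=False)
        adj = tm.face_adjacency
        n_f = t.shape[0]
        neighbors = [[] for _ in range(n_f)]
        for a, b in adj:
            neighbors[a].append(b)
            neighbors[b].append(a)

        def directed_edges(tri):
            return {(tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])}

        visited = np.zeros(n_f, dtype=bool)
        for start in range(n_f):
            if visited[start]:
                continue
            visited[start] = True
            queue = [start]
            while queue:
                f = queue.pop()
                de_f = directed_edges(t[f])
                for g in neighbors[f]:
                    if visited[g]:
                        continue
                    de_g = directed_edges(t[g])
                    # consistent orientation: shared edge traversed oppositely,
                    # i.e. no directed edge in common
                    if de_f & de_g:
                        t[g] = t[g][::-1]
                    visited[g] = True
                    queue.append(g)
        out = TriMesh(self.vertices, t, self.name)
        if out.signed_volume() < 0:
            out = TriMesh(self.vertices, t[:, ::-1], self.name)
        # verify consistency: no directed edge repeated
        te = out.triangles
        de = np.concatenate([te[:, [0, 1]], te[:, [1, 2]], te[:, [2, 0]]])
        _, c = np.unique(de, axis=0, return_counts=True)
        if np.any(c != 1):
            raise OrientationError(f"{self.name}: inconsistent orientation (non-orientable patch)")
        return out


_FORMATS = ("ply", "off", "stl")


def load_mesh(path: str | os.PathLike, fmt: str | None = None, name: str | None = None) -> TriMesh:
    """Read a PLY, OFF or STL surface and validate it as a closed oriented mesh.

    ``fmt`` defaults to the file extension. STL stores no shared vertex table,
    so identical corner coordinates are merged on load.
    """
    path = os.fspath(path)
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    tm = _trimesh.load(path, file_type=fmt, process=False, force="mesh")
    if fmt == "stl":
        tm.merge_vertices()
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), name).validate()


def write_mesh(mesh: TriMesh, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a mesh to PLY, OFF or STL (format from extension by default)."""
    path = os.fspath(path)
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(path, file_type=fmt)


def triangle_solid_angle(tri_vertices: np.ndarray, obs: np.ndarray, tol: float | None = None) -> float:
    """Signed solid angle (sr) of one oriented triangle seen from ``obs``.

    Uses the analytic plane-triangle (van Oosterom-Strackee) formula with the
    sign convention of this package: an outward-oriented closed surface sums
    to -4*pi from inside. Raises :class:`SingularGeometryError` when ``obs``
    lies in the triangle plane inside the triangle.
    """
    tri = np.asarray(tri_vertices, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    R = tri - obs
    l = np.linalg.norm(R, axis=1)
    if tol is None:
        tol = 1e-9 * max(np.linalg.norm(tri.max(0) - tri.min(0)), 1.0)
    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    nn = np.linalg.norm(n)
    if nn > 0:
        dist = abs(np.dot(obs - tri[0], n / nn))
        if dist < tol:
            # in-plane: singular only if the projection falls inside the triangle
            if _point_in_triangle(obs, tri):
                raise SingularGeometryError("observation point lies on the triangle")
            return 0.0
    N = np.dot(R[0], np.cross(R[1], R[2]))
    D = l[0] * l[1] * l[2] + np.dot(R[0], R[1]) * l[2] + np.dot(R[0], R[2]) * l[1] + np.dot(R[1], R[2]) * l[0]
    return float(-2.0 * np.arctan2(N, D))


def _point_in_triangle(p, tri) -> bool:
    # barycentric test of the in-plane projection
    a, b, c = tri
    v0, v1, v2 = c - a, b - a, p - a
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d20, d21 = v2 @ v0, v2 @ v1
    den = d00 * d11 - d01 * d01
    if den == 0:
        return False
    u = (d11 * d20 - d01 * d21) / den
    v = (d00 * d21 - d01 * d20) / den
    return u >= -1e-12 and v >= -1e-12 and u + v <= 1 + 1e-12


def mesh_solid_angles(mesh: TriMesh, obs: np.ndarray, skip: np.ndarray | None = None) -> np.ndarray:
    """Per-triangle solid angles of ``mesh`` from a single observation point.

    ``skip`` marks triangles whose contribution is set to zero (used by the
    BEM assembly for triangles incident to the collocation vertex, where the
    analytic formula degenerates to 0/0).
    """
    V = mesh.vertices[mesh.triangles]  # (F, 3, 3)
    R = V - np.asarray(obs, dtype=np.float64)
    l = np.linalg.norm(R, axis=2)  # (F, 3)
    N = np.einsum("ij,ij->i", R[:, 0], np.cross(R[:, 1], R[:, 2]))
    D = (
        l[:, 0] * l[:, 1] * l[:, 2]
        + np.einsum("ij,ij->i", R[:, 0], R[:, 1]) * l[:, 2]
        + np.einsum("ij,ij->i", R[:, 0], R[:, 2]) * l[:, 1]
        + np.einsum("ij,ij->i", R[:, 1], R[:, 2]) * l[:, 0]
    )
    with np.errstate(invalid="ignore"):
        omega = -2.0 * np.arctan2(N, D)
    omega = np.where(np.isfinite(omega), omega, 0.0)
    if skip is not None:
        omega = np.where(skip, 0.0, omega)
    return omega


def solid_angle_sum(mesh: TriMesh, obs: np.ndarray) -> float:
    """Total solid angle of the closed surface from ``obs`` (-4*pi inside, 0 outside)."""
    return float(mesh_solid_angles(mesh, obs).sum())


def points_inside(mesh: TriMesh, points: np.ndarray) -> np.ndarray:
    """Boolean mask of points strictly inside a closed outward-oriented mesh."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = np.empty(points.shape[0], dtype=bool)
    for i, p in enumerate(points):
        out[i] = solid_angle_sum(mesh, p) < -2.0 * np.pi
    return out


# ---------------------------------------------------------------------------
# electrode montage


@dataclass(frozen=True)
class ElectrodeMontage:
    """M electrodes as distinct vertex indices on a torso mesh.

    Emulates strip-based body-surface-potential-mapping hardware: electrodes
    come in vertical adhesive strips, ``strip_of[i]`` giving the strip of
    electrode i and ``labels[i]`` encoding (strip, level).
    """

    vertex_ids: np.ndarray
    labels: tuple
    strip_of: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "vertex_ids", np.asarray(self.vertex_ids, dtype=np.int64))
        object.__setattr__(self, "strip_of", np.asarray(self.strip_of, dtype=np.int64))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.vertex_ids.tolist())) != self.vertex_ids.size:
            raise ValueError("montage vertex_ids must be distinct")
        if self.vertex_ids.size < 4:
            raise ValueError("montage needs at least 4 electrodes")
        if not (len(self.labels) == self.vertex_ids.size == self.strip_of.size):
            raise ValueError("labels/strip_of/vertex_ids length mismatch")

    @property
    def n_electrodes(self) -> int:
        return int(self.vertex_ids.size)

    def positions(self, torso: TriMesh) -> np.ndarray:
        return torso.vertices[self.vertex_ids]


def place_electrode_strips(
    torso: TriMesh,
    n_strips: int = 16,
    per_strip: int = 8,
    z_range: tuple[float, float] = (0.2, 0.8),
) -> ElectrodeMontage:
    """Build a strip montage of ``n_strips`` azimuthal lines x ``per_strip`` levels.

    Nominal sites sit on equally spaced azimuths around the torso long axis (z)
    and equally spaced axial levels inside the fractional ``z_range`` of the
    torso's z extent; each site is snapped to its nearest torso vertex in a
    cylindrical metric. When two sites contend for one vertex, the later site
    takes the nearest still-unused vertex, so the montage size is exactly
    ``n_strips * per_strip``.
    """
    m_total = n_strips * per_strip
    if torso.n_vertices < m_total:
        raise ValueError(f"torso has {torso.n_vertices} vertices < {m_total} electrodes")
    if not (0.0 <= z_range[0] < z_range[1] <= 1.0):
        raise ValueError("z_range must be an increasing interval inside [0, 1]")
    v = torso.vertices
    c = torso.centroid()
    zmin, zmax = v[:, 2].min(), v[:, 2].max()
    z_levels = zmin + (z_range[0] + (z_range[1] - z_range[0]) * np.linspace(0, 1, per_strip)) * (zmax - zmin)
    azimuths = 2.0 * np.pi * np.arange(n_strips) / n_strips
    theta_v = np.arctan2(v[:, 1] - c[1], v[:, 0] - c[0])
    r_mean = float(np.hypot(v[:, 0] - c[0], v[:, 1] - c[1]).mean())

    used = np.zeros(torso.n_vertices, dtype=bool)
    ids, labels, strips = [], [], []
    for s in range(n_strips):
        for lev in range(per_strip):
            dth = np.angle(np.exp(1j * (theta_v - azimuths[s])))
            d2 = (r_mean * dth) ** 2 + (v[:, 2] - z_levels[lev]) ** 2
            order = np.argsort(d2, kind="stable")
            pick = order[0] if not used[order[0]] else order[~used[order]][0]
            used[pick] = True
            ids.append(int(pick))
            labels.append(f"S{s + 1:02d}E{lev + 1}")
            strips.append(s)
    if len(set(ids)) != m_total:
        raise ValueError("electrode snapping produced duplicate vertices")
    return ElectrodeMontage(np.array(ids), labels, np.array(strips))


def write_montage(montage: ElectrodeMontage, path: str | os.PathLike) -> None:
    """Write a montage as CSV with columns label,strip,level,vertex_id."""
    levels = [int(lab.split("E")[1]) - 1 if "E" in lab else i for i, lab in enumerate(montage.labels)]
    df = pd.DataFrame(
        {
            "label": list(montage.labels),
            "strip": montage.strip_of,
            "level": levels,
            "vertex_id": montage.vertex_ids,
        }
    )
    df.to_csv(path, index=False)


def load_montage(path: str | os.PathLike) -> ElectrodeMontage:
    df = pd.read_csv(path)
    return ElectrodeMontage(
        df["vertex_id"].to_numpy(), [str(x) for x in df["label"]], df["strip"].to_numpy()
    )
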