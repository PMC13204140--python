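"""3D morphometry of triangulated object surfaces.

Computes the radiomic shape descriptors used for airway-hazard
assessment: exact closed-mesh volume (signed tetrahedra), surface area,
PCA principal frame with projection-span extents, elongation / flatness /
sphericity, convexity ratio, and the sharp-edge dihedral census.
All lengths are millimetres.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh
from scipy.spatial import ConvexHull, QhullError

from .errors import (
    DegenerateGeometryError,
    EmptyInputError,
    MeshParseError,
    UndefinedDescriptorError,
)

__all__ = [
    "TriMesh",
    "PrincipalFrame",
    "Shape3DDescriptors",
    "load_stl",
    "signed_volume",
    "divergence_volume",
    "surface_area",
    "principal_frame",
    "inertia_frame",
    "dimensionless_shape",
    "sphericity",
    "convexity_ratio",
    "dihedral_sharpness",
    "describe_3d",
]

_DEGENERATE_AREA = 1e-12  # mm^2; faces thinner than this are dropped


@dataclass
class TriMesh:
    """Triangulated surface in mm with deduplicated vertices.

    ``watertight`` is true iff every edge is shared by exactly two faces.
    Faces are oriented outward (positive enclosed signed volume) when the
    mesh is closed.
    """

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    name: str = ""
    watertight: bool = field(default=False)
    boundary_edge_count: int = field(default=0)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) == 0 or len(self.vertices) == 0:
            raise EmptyInputError(f"mesh {self.name!r} has no geometry")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshParseError(
                f"mesh {self.name!r}: face index out of range "
                f"(max {self.faces.max()}, {len(self.vertices)} vertices)"
            )

    @classmethod
    def from_arrays(
        cls,
        vertices: np.ndarray,
        faces: np.ndarray,
        name: str = "",
        merge_tolerance: float = 1e-6,
    ) -> "TriMesh":
        """Build a mesh: merge duplicate vertices on a grid hash at
        ``merge_tolerance`` (mm), drop degenerate faces, orient faces
        outward for closed surfaces, and record watertightness."""
        vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
        faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        if len(vertices) == 0 or len(faces) == 0:
            raise EmptyInputError(f"mesh {name!r} has no geometry")

        keys = np.round(vertices / merge_tolerance).astype(np.int64)
        _, first, inverse = np.unique(
            keys, axis=0, return_index=True, return_inverse=True
        )
        merged = vertices[first]
        faces = inverse[faces]

        # drop faces with repeated vertices or (near-)zero area
        distinct = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        faces = faces[distinct]
        if len(faces) == 0:
            raise EmptyInputError(f"mesh {name!r}: all faces degenerate")
        tri = merged[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        faces = faces[areas > _DEGENERATE_AREA]
        if len(faces) == 0:
            raise EmptyInputError(f"mesh {name!r}: all faces degenerate")

        watertight, n_boundary = _edge_census(faces)
        mesh = cls.__new__(cls)
        mesh.vertices = merged
        mesh.faces = faces
        mesh.name = name
        mesh.watertight = watertight
        mesh.boundary_edge_count = n_boundary
        if watertight and _signed_volume_raw(mesh) < 0:
            mesh.faces = mesh.faces[:, ::-1].copy()
        return mesh

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]


def _edge_census(faces: np.ndarray) -> tuple[bool, int]:
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    watertight = bool(np.all(counts == 2))
    n_boundary = int(np.sum(counts == 1))
    return watertight, n_boundary


def load_stl(path, merge_tolerance: float = 1e-6, name: str | None = None) -> TriMesh:
    """Parse a binary or ASCII STL file into a :class:`TriMesh`.

    The dialect is auto-detected. Duplicate vertices are collapsed with a
    grid hash at ``merge_tolerance`` (default 1e-6 mm); watertightness is
    evaluated and recorded on the result.
    """
    path = str(path)
    try:
        raw = _trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:  # trimesh raises a mix of struct/value errors
        try:
            import os

            size = os.path.getsize(path)
        except OSError:
            size = -1
        raise MeshParseError(
            f"cannot parse STL {path!r} (file size {size} bytes): {exc}"
        ) from exc
    if isinstance(raw, _trimesh.Scene):
        # trimesh wraps unreadable/empty STL payloads in an empty scene
        geoms = list(raw.geometry.values())
        if not geoms:
            import os

            raise MeshParseError(
                f"cannot parse STL {path!r}: no triangles recovered from "
                f"{os.path.getsize(path)} bytes"
            )
        raw = _trimesh.util.concatenate(geoms)
    verts = np.asarray(raw.vertices, dtype=float)
    faces = np.asarray(raw.faces, dtype=np.int64)
    if len(verts) == 0 or len(faces) == 0:
        raise EmptyInputError(f"STL {path!r} contains no triangles")
    return TriMesh.from_arrays(
        verts, faces, name=name if name is not None else path,
        merge_tolerance=merge_tolerance,
    )


# ---------------------------------------------------------------------------
# volume and area


def _signed_volume_raw(mesh: TriMesh) -> float:
    tri = mesh.triangles
    return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)


def signed_volume(mesh: TriMesh) -> float:
    """Enclosed volume (mm^3) by summing signed tetrahedra face-origin.

    Exact for closed meshes and independent of the choice of origin.
    Non-watertight meshes get a warning and an approximate value.
    """
    if not mesh.watertight:
        warnings.warn(
            f"mesh {mesh.name!r} is not watertight "
            f"({mesh.boundary_edge_count} boundary edges); volume is approximate",
            stacklevel=2,
        )
    return abs(_signed_volume_raw(mesh))


def divergence_volume(mesh: TriMesh) -> float:
    """Volume via the divergence theorem (flux of the field (x, 0, 0)).

    Independent of the signed-tetrahedron route; used as a cross-check
    diagnostic on closed meshes.
    """
    tri = mesh.triangles
    n_area = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    cx = tri[:, :, 0].mean(axis=1)
    return abs(float(np.sum(n_area[:, 0] * cx)))


def surface_area(mesh: TriMesh) -> float:
    """Total surface area (mm^2): sum of per-triangle areas."""
    tri = mesh.triangles
    return float(
        0.5
        * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        ).sum()
    )


# ---------------------------------------------------------------------------
# principal frames


@dataclass
class PrincipalFrame:
    """Orthonormal frame ordered by descending variance.

    ``extents`` are projection spans (max minus min vertex coordinate along
    each axis), not eigenvalue square roots; ``eigenvalues`` carry the raw
    variances for diagnostics.
    """

    centroid: np.ndarray  # (3,)
    axes: np.ndarray  # (3, 3), rows are unit axes
    extents: np.ndarray  # (3,), L1 >= L2 >= L3, mm
    eigenvalues: np.ndarray  # (3,), descending

    def __post_init__(self) -> None:
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("principal axes are not orthonormal")
        if np.any(self.extents < 0) or np.any(np.diff(self.extents) > 1e-12):
            raise DegenerateGeometryError("extents must be sorted descending")


def _frame_from_axes(points: np.ndarray, axes: np.ndarray, eigvals: np.ndarray,
                     centroid: np.ndarray) -> PrincipalFrame:
    # deterministic sign: largest-magnitude component of each axis positive
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    # near-equal eigenvalues: order tied axes lexicographically
    order = sorted(
        range(3),
        key=lambda i: (-round(eigvals[i] / max(eigvals.max(), 1e-300), 9),
                       tuple(-axes[i])),
    )
    axes = axes[order]
    eigvals = eigvals[order]
    proj = (points - centroid) @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    # re-sort by extent in case of variance ties
    e_order = np.argsort(-extents, kind="stable")
    return PrincipalFrame(
        centroid=centroid,
        axes=axes[e_order],
        extents=extents[e_order],
        eigenvalues=eigvals[e_order],
    )


def principal_frame(mesh: TriMesh) -> PrincipalFrame:
    """PCA of the vertex coordinates.

    Eigen-decomposition of the vertex covariance gives the axes; the
    extents L1 >= L2 >= L3 are the spans of the vertex cloud projected on
    each axis. Requires a full-rank (non-coplanar) point cloud.
    """
    pts = mesh.vertices
    if len(pts) < 4:
        raise DegenerateGeometryError(
            f"need >= 4 vertices for a 3D frame, got {len(pts)}"
        )
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    rank = int(np.sum(eigvals > max(eigvals.max(), 0) * 1e-10))
    if rank < 3:
        raise DegenerateGeometryError(
            f"vertex cloud is rank {rank}; a full 3D frame needs rank 3"
        )
    axes = eigvecs.T[::-1].copy()  # descending variance
    return _frame_from_axes(pts, axes, eigvals[::-1].copy(), centroid)


def inertia_frame(mesh: TriMesh) -> PrincipalFrame:
    """Principal frame of the uniform-density solid (second-moment integral).

    Integrates x x^T over the enclosed volume by signed tetrahedra; its
    eigenvectors are the inertia-tensor principal axes. Extents are
    projection spans of the vertices along those axes, so they are directly
    comparable with :func:`principal_frame` extents.
    """
    tri = mesh.triangles
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    det = np.einsum("ij,ij->i", a, np.cross(b, c))
    vol = det.sum() / 6.0
    if abs(vol) < 1e-12:
        raise DegenerateGeometryError("enclosed volume is zero; no inertia frame")
    # tetra (0, a, b, c): centroid (a+b+c)/4, signed volume det/6
    centroid = (det[:, None] * (a + b + c) / 4.0).sum(axis=0) / det.sum()
    a = a - centroid
    b = b - centroid
    c = c - centroid
    det = np.einsum("ij,ij->i", a, np.cross(b, c))
    s = a + b + c
    cov = (
        det[:, None, None]
        * (
            np.einsum("ij,ik->ijk", s, s)
            + np.einsum("ij,ik->ijk", a, a)
            + np.einsum("ij,ik->ijk", b, b)
            + np.einsum("ij,ik->ijk", c, c)
        )
    ).sum(axis=0) / 120.0
    cov = cov / abs(vol)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axes = eigvecs.T[::-1].copy()
    return _frame_from_axes(mesh.vertices, axes, eigvals[::-1].copy(), centroid)


# ---------------------------------------------------------------------------
# dimensionless descriptors


def sphericity(volume_mm3: float, area_mm2: float) -> float:
    """psi = (36 pi V^2)^(1/3) / A; equals 1 for a perfect sphere."""
    if area_mm2 <= 0 or volume_mm3 <= 0:
        raise UndefinedDescriptorError(
            f"sphericity needs V > 0 and A > 0 (got V={volume_mm3}, A={area_mm2})"
        )
    return float((36.0 * np.pi * volume_mm3**2) ** (1.0 / 3.0) / area_mm2)


def dimensionless_shape(
    frame: PrincipalFrame, volume_mm3: float, area_mm2: float
) -> tuple[float, float, float]:
    """Elongation e = 1 - (L3/L1)^2, flatness f = 1 - (L2/L1)^2, and
    sphericity psi = (36 pi V^2)^(1/3) / A.

    Both e and f are 0 at the spherical limit and grow toward 1 as the
    minor / intermediate spans shrink relative to the major axis. Note the
    flatness here deliberately uses the intermediate span L2 against L1;
    see :func:`shape_diagnostics` for the conventional L3/L2 variant.
    """
    L1, L2, L3 = frame.extents
    if L1 <= 0:
        raise UndefinedDescriptorError("zero major extent; shape undefined")
    e = 1.0 - (L3 / L1) ** 2
    f = 1.0 - (L2 / L1) ** 2
    return float(e), float(f), sphericity(volume_mm3, area_mm2)


def shape_diagnostics(frame: PrincipalFrame) -> dict[str, float]:
    """Alternative anisotropy descriptors for diagnostic output.

    ``elongation_sqrt`` / ``flatness_sqrt`` are square-root variants
    (1 - ratio^2 replaced by sqrt of that), ``flatness_l3_l2`` is the
    conventional 1 - (L3/L2)^2, and the eigenvalue-based axis lengths are
    reported as 2*sqrt(variance) per axis.
    """
    L1, L2, L3 = frame.extents
    out = {
        "elongation_sqrt": float(np.sqrt(max(1.0 - (L3 / L1) ** 2, 0.0))),
        "flatness_sqrt": float(np.sqrt(max(1.0 - (L2 / L1) ** 2, 0.0))),
        "flatness_l3_l2": float(1.0 - (L3 / L2) ** 2) if L2 > 0 else float("nan"),
    }
    sd = 2.0 * np.sqrt(np.maximum(frame.eigenvalues, 0.0))
    out.update({f"eigen_axis_length_{i + 1}": float(v) for i, v in enumerate(sd)})
    return out


def convexity_ratio(mesh: TriMesh) -> float:
    """Object volume over convex-hull volume, in (0, 1] for closed meshes."""
    try:
        hull = ConvexHull(mesh.vertices)
    except QhullError as exc:
        raise DegenerateGeometryError(f"convex hull failed: {exc}") from exc
    v = signed_volume(mesh)
    if hull.volume <= 0:
        raise DegenerateGeometryError("convex hull has zero volume")
    return float(v / hull.volume)


# ---------------------------------------------------------------------------
# dihedral census


def dihedral_sharpness(
    mesh: TriMesh, sharp_threshold_deg: float = 90.0
) -> tuple[int, float]:
    """Count sharp edges and return the minimum interior dihedral angle.

    For every edge shared by exactly two faces the interior dihedral angle
    (measured inside the solid, outward normals assumed) is computed; edges
    with angle strictly below ``sharp_threshold_deg`` are sharp. Convex
    edges are < 180 deg, concave edges > 180 deg. Boundary edges are
    skipped with a warning.
    """
    faces = mesh.faces
    tri = mesh.triangles
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(norms > 0, norms, 1.0)
    centroids = tri.mean(axis=1)

    edge_map: dict[tuple[int, int], list[int]] = {}
    for fi in range(len(faces)):
        f = faces[fi]
        for k in range(3):
            e = (int(f[k]), int(f[(k + 1) % 3]))
            e = (min(e), max(e))
            edge_map.setdefault(e, []).append(fi)

    skipped = 0
    angles = []
    for (_, _), fs in edge_map.items():
        if len(fs) != 2:
            skipped += 1
            continue
        f1, f2 = fs
        n1, n2 = normals[f1], normals[f2]
        cosang = float(np.clip(np.dot(n1, n2), -1.0, 1.0))
        theta = np.degrees(np.arccos(cosang))
        # concave if the neighbour's centroid lies on the outer side of f1
        d = centroids[f2] - centroids[f1]
        concave = float(np.dot(n1, d)) > 1e-12 * max(np.linalg.norm(d), 1.0)
        interior = 180.0 + theta if concave else 180.0 - theta
        angles.append(interior)
    if skipped:
        warnings.warn(
            f"mesh {mesh.name!r}: {skipped} boundary/non-manifold edges skipped "
            "in dihedral census",
            stacklevel=2,
        )
    if not angles:
        return 0, float("nan")
    angles_arr = np.asarray(angles)
    # 1e-6 deg guard keeps exactly-at-threshold dihedrals (e.g. 90 deg box
    # edges after a rigid motion) from flipping on floating-point noise
    count = int(np.sum(angles_arr < sharp_threshold_deg - 1e-6))
    return count, float(angles_arr.min())


# ---------------------------------------------------------------------------
# aggregate descriptor record


@dataclass
class Shape3DDescriptors:
    """Full 3D descriptor block for one object (stored at full precision)."""

    volume_mm3: float
    surface_area_mm2: float
    surface_to_volume_per_mm: float
    extents_mm: tuple[float, float, float]  # L1 >= L2 >= L3, PCA spans
    aabb_extents_mm: tuple[float, float, float]  # input-frame box, descending
    elongation: float
    flatness: float
    sphericity: float
    convexity_ratio: float
    sharp_edge_count: int
    min_dihedral_deg: float
    mass_g: float | None = None
    watertight: bool = True
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "volume_mm3": self.volume_mm3,
            "surface_area_mm2": self.surface_area_mm2,
            "surface_to_volume_per_mm": self.surface_to_volume_per_mm,
            "l1_mm": self.extents_mm[0],
            "l2_mm": self.extents_mm[1],
            "l3_mm": self.extents_mm[2],
            "aabb_extent_1_mm": self.aabb_extents_mm[0],
            "aabb_extent_2_mm": self.aabb_extents_mm[1],
            "aabb_extent_3_mm": self.aabb_extents_mm[2],
            "elongation": self.elongation,
            "flatness": self.flatness,
            "sphericity": self.sphericity,
            "convexity_ratio": self.convexity_ratio,
            "sharp_edge_count": self.sharp_edge_count,
            "min_dihedral_deg": self.min_dihedral_deg,
            "mass_g": self.mass_g,
            "watertight": self.watertight,
        }
        d.update({f"diag_{k}": v for k, v in self.diagnostics.items()})
        return d

    def rounded(self, ndigits: int = 2) -> dict:
        """Report-style rounding (2 dp); storage stays full precision."""
        out = {}
        for k, v in self.to_dict().items():
            out[k] = round(v, ndigits) if isinstance(v, float) else v
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def describe_3d(
    mesh: TriMesh,
    mass_g: float | None = None,
    sharp_threshold_deg: float = 90.0,
) -> Shape3DDescriptors:
    """Compute the full 3D descriptor block for a mesh.

    Aggregates volume, area, A/V, PCA extents, axis-aligned bounding-box
    extents (input frame, sorted descending), elongation / flatness /
    sphericity, convexity ratio and the dihedral sharpness census.
    """
    with warnings.catch_warnings():
        if not mesh.watertight:
            warnings.simplefilter("ignore")
        V = signed_volume(mesh)
        A = surface_area(mesh)
        frame = principal_frame(mesh)
        e, f, psi = dimensionless_shape(frame, V, A)
        conv = convexity_ratio(mesh)
        count, min_dih = dihedral_sharpness(mesh, sharp_threshold_deg)
    if V <= 0:
        raise UndefinedDescriptorError("zero enclosed volume; A/V undefined")
    aabb = np.sort(mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0))[::-1]
    return Shape3DDescriptors(
        volume_mm3=V,
        surface_area_mm2=A,
        surface_to_volume_per_mm=A / V,
        extents_mm=tuple(float(x) for x in frame.extents),
        aabb_extents_mm=tuple(float(x) for x in aabb),
        elongation=e,
        flatness=f,
        sphericity=psi,
        convexity_ratio=conv,
        sharp_edge_count=count,
        min_dihedral_deg=min_dih,
        mass_g=mass_g,
        watertight=mesh.watertight,
        diagnostics=shape_diagnostics(frame),
    )
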