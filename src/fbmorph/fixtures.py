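"""Synthetic fixtures with analytic ground truth.

Generates watertight meshes (spheres, boxes, capsules, notched boxes,
spiked stars) and rendered calibrated photographs (dark shape + yellow
ruler band) whose descriptor values are known in closed form, so the
morphometry pipeline is testable end to end without any external data.
Every fixture is a pure function of (kind, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh
from scipy.spatial.transform import Rotation

from .errors import LayoutError
from .mesh import TriMesh

__all__ = ["GroundTruthRecord", "make_mesh", "render_photo", "MESH_KINDS", "PHOTO_SHAPES"]

MESH_KINDS = ("icosphere", "ellipsoid", "box", "capsule", "notched_box", "spiked_star")
PHOTO_SHAPES = ("disk", "square", "stadium", "polygon")

# measured discretization deficits of inscribed icospheres, with headroom
_ICO_VOL_TOL = {0: 0.45, 1: 0.12, 2: 0.035, 3: 0.011, 4: 0.0035, 5: 0.0015}
_ICO_AREA_TOL = {0: 0.30, 1: 0.08, 2: 0.022, 3: 0.006, 4: 0.002, 5: 0.0008}
_THOMSEN_BOUND = 0.0107  # relative bound of the p=1.6075 ellipsoid area formula


@dataclass
class GroundTruthRecord:
    """Analytic descriptor values for one fixture, with per-field tolerances.

    ``generator_params`` echoes every parameter (including the seed) needed
    to regenerate the fixture bit-exactly.
    """

    fixture_id: str
    analytic: dict = field(default_factory=dict)
    tolerance: dict = field(default_factory=dict)
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.analytic) - set(self.tolerance)
        if missing:
            raise ValueError(f"analytic fields without tolerance: {sorted(missing)}")


# ---------------------------------------------------------------------------
# polygon utilities (caps for extruded prisms)


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _ear_clip(pts: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple CCW polygon by ear clipping."""
    n = len(pts)
    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []

    def cross(o, a, b):
        return (pts[a, 0] - pts[o, 0]) * (pts[b, 1] - pts[o, 1]) - (
            pts[a, 1] - pts[o, 1]
        ) * (pts[b, 0] - pts[o, 0])

    def inside(p, a, b, c):
        d1 = cross(a, b, p)
        d2 = cross(b, c, p)
        d3 = cross(c, a, p)
        return d1 >= -1e-12 and d2 >= -1e-12 and d3 >= -1e-12

    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        guard += 1
        m = len(idx)
        clipped = False
        for k in range(m):
            a, b, c = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            if cross(a, b, c) <= 1e-12:
                continue  # reflex or collinear
            if any(
                inside(p, a, b, c) for p in idx if p not in (a, b, c)
            ):
                continue
            tris.append((a, b, c))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            raise ValueError("ear clipping failed; polygon may be non-simple")
    tris.append((idx[0], idx[1], idx[2]))
    return tris


def _extrude(pts2d: np.ndarray, height: float) -> tuple[np.ndarray, np.ndarray]:
    """Watertight triangulated prism from a simple CCW polygon, z in [0, h]."""
    pts2d = np.asarray(pts2d, dtype=float)
    if _polygon_area(pts2d) < 0:
        pts2d = pts2d[::-1]
    n = len(pts2d)
    bottom = np.column_stack([pts2d, np.zeros(n)])
    top = np.column_stack([pts2d, np.full(n, height)])
    verts = np.vstack([bottom, top])
    faces: list[tuple[int, int, int]] = []
    cap = _ear_clip(pts2d)
    for a, b, c in cap:
        faces.append((a, c, b))  # bottom, outward -z
        faces.append((n + a, n + b, n + c))  # top, outward +z
    for i in range(n):
        j = (i + 1) % n
        faces.append((i, j, n + j))
        faces.append((i, n + j, n + i))
    return verts, np.asarray(faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# mesh fixtures


def _apply_rigid(verts: np.ndarray, seed: int, rotate: bool) -> np.ndarray:
    if not rotate:
        return verts
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    return verts @ R.T + t


def make_mesh(kind: str, params: dict | None = None, seed: int = 0):
    """Generate a watertight fixture mesh and its ground-truth record.

    Supported kinds and their parameters (all lengths mm):

    - ``icosphere``: radius (5), subdivisions (3)
    - ``ellipsoid``: radii (4, 3, 2), subdivisions (3); area via the
      Thomsen p=1.6075 approximation (documented <= 1.07% bound)
    - ``box``: extents (8.24, 5.72, 4.51) — the case-object scale exemplar
    - ``capsule``: radius (2), length (5) cylindrical section, segments (64)
    - ``notched_box``: extents + notch_width_frac / notch_depth_frac of a
      rectangular channel cut into the top face; convexity known exactly
    - ``spiked_star``: star prism (n_points, outer/inner radius, height);
      the point ridges carry a closed-form sharp dihedral angle

    ``rotate=True`` in params applies a seeded random rigid motion (all
    ground-truth fields are rigid-motion invariant).
    """
    params = dict(params or {})
    rotate = bool(params.pop("rotate", False))
    if kind not in MESH_KINDS:
        raise ValueError(f"unknown mesh kind {kind!r}; choose from {MESH_KINDS}")
    builder = {
        "icosphere": _make_icosphere,
        "ellipsoid": _make_ellipsoid,
        "box": _make_box,
        "capsule": _make_capsule,
        "notched_box": _make_notched_box,
        "spiked_star": _make_spiked_star,
    }[kind]
    verts, faces, analytic, tol, echo = builder(**params)
    verts = _apply_rigid(verts, seed, rotate)
    echo.update({"kind": kind, "seed": seed, "rotate": rotate})
    fixture_id = f"{kind}-" + "-".join(
        f"{k}={v}" for k, v in sorted(echo.items()) if k != "kind"
    )
    mesh = TriMesh.from_arrays(verts, faces, name=fixture_id)
    record = GroundTruthRecord(
        fixture_id=fixture_id, analytic=analytic, tolerance=tol,
        generator_params=echo,
    )
    return mesh, record


def _make_icosphere(radius: float = 5.0, subdivisions: int = 3):
    if radius <= 0 or subdivisions < 0:
        raise ValueError("icosphere needs radius > 0 and subdivisions >= 0")
    m = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    analytic = {
        "volume_mm3": 4.0 / 3.0 * np.pi * radius**3,
        "surface_area_mm2": 4.0 * np.pi * radius**2,
        "extents_mm": (2 * radius, 2 * radius, 2 * radius),
        "sphericity": 1.0,
        "convexity_ratio": 1.0,
        "surface_to_volume_per_mm": 3.0 / radius,
        "sharp_edge_count": 0,
    }
    s = min(subdivisions, 5)
    tol = {
        "volume_mm3": _ICO_VOL_TOL[s],
        "surface_area_mm2": _ICO_AREA_TOL[s],
        "extents_mm": 0.01,
        "sphericity": 0.01,
        "convexity_ratio": 1e-6,
        "surface_to_volume_per_mm": _ICO_VOL_TOL[s] + _ICO_AREA_TOL[s],
        "sharp_edge_count": 0,
    }
    echo = {"radius": radius, "subdivisions": subdivisions}
    return m.vertices, m.faces, analytic, tol, echo


def _make_ellipsoid(radii=(4.0, 3.0, 2.0), subdivisions: int = 3):
    a, b, c = (float(r) for r in radii)
    if min(a, b, c) <= 0:
        raise ValueError("ellipsoid radii must be positive")
    m = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = m.vertices * np.array([a, b, c])
    p = 1.6075  # Thomsen approximation exponent
    area = 4.0 * np.pi * (
        ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    ) ** (1.0 / p)
    s = min(subdivisions, 5)
    # anisotropic scaling worsens the chordal deficit by roughly max/min axis
    aniso = max(a, b, c) / min(a, b, c)
    analytic = {
        "volume_mm3": 4.0 / 3.0 * np.pi * a * b * c,
        "surface_area_mm2": area,
        "extents_mm": tuple(sorted((2 * a, 2 * b, 2 * c), reverse=True)),
        "convexity_ratio": 1.0,
    }
    tol = {
        "volume_mm3": _ICO_VOL_TOL[s] * aniso,
        "surface_area_mm2": _ICO_AREA_TOL[s] * aniso + _THOMSEN_BOUND,
        "extents_mm": 0.02,
        "convexity_ratio": 1e-6,
    }
    echo = {"radii": (a, b, c), "subdivisions": subdivisions}
    return verts, m.faces, analytic, tol, echo


def _make_box(extents=(8.24, 5.72, 4.51)):
    a, b, c = (float(x) for x in extents)
    if min(a, b, c) <= 0:
        raise ValueError("box extents must be positive")
    m = _trimesh.creation.box(extents=(a, b, c))
    srt = tuple(sorted((a, b, c), reverse=True))
    analytic = {
        "volume_mm3": a * b * c,
        "surface_area_mm2": 2.0 * (a * b + b * c + a * c),
        "extents_mm": srt,
        "convexity_ratio": 1.0,
        "sharp_edge_count": 0,  # cube dihedrals are exactly 90 deg, not < 90
        "min_dihedral_deg": 90.0,
        "elongation": 1.0 - (srt[2] / srt[0]) ** 2,
        "flatness": 1.0 - (srt[1] / srt[0]) ** 2,
    }
    tol = {
        "volume_mm3": 1e-9, "surface_area_mm2": 1e-9, "extents_mm": 1e-9,
        "convexity_ratio": 1e-6, "sharp_edge_count": 0,
        "min_dihedral_deg": 1e-6, "elongation": 1e-9, "flatness": 1e-9,
    }
    return m.vertices, m.faces, analytic, tol, {"extents": (a, b, c)}


def _make_capsule(radius: float = 2.0, length: float = 5.0, segments: int = 64):
    if radius <= 0 or length <= 0 or segments < 8:
        raise ValueError("capsule needs radius > 0, length > 0, segments >= 8")
    m = _trimesh.creation.capsule(
        radius=radius, height=length, count=(segments, segments)
    )
    disc = 25.0 / segments**2  # chordal deficit ~ (pi/n)^2 with headroom
    analytic = {
        "volume_mm3": np.pi * radius**2 * length + 4.0 / 3.0 * np.pi * radius**3,
        "surface_area_mm2": 2.0 * np.pi * radius * length + 4.0 * np.pi * radius**2,
        "extents_mm": (length + 2 * radius, 2 * radius, 2 * radius),
        "convexity_ratio": 1.0,
        "sharp_edge_count": 0,
    }
    tol = {
        "volume_mm3": disc, "surface_area_mm2": disc, "extents_mm": disc,
        "convexity_ratio": 1e-6, "sharp_edge_count": 0,
    }
    echo = {"radius": radius, "length": length, "segments": segments}
    return m.vertices, m.faces, analytic, tol, echo


def _make_notched_box(
    extents=(10.0, 8.0, 6.0),
    notch_width_frac: float = 0.4,
    notch_depth_frac: float = 0.8,
):
    """Box with a rectangular channel cut through the full depth of the top
    face; the convex hull is the full box, so convexity is exact."""
    a, b, c = (float(x) for x in extents)  # width (x), depth (y), height (z)
    w, d = float(notch_width_frac), float(notch_depth_frac)
    if not (0 < w < 1 and 0 < d < 1):
        raise ValueError("notch fractions must be in (0, 1)")
    nw, nd = w * a, d * c
    x0, x1 = (a - nw) / 2.0, (a + nw) / 2.0
    cross = np.array(
        [
            (0.0, 0.0), (a, 0.0), (a, c), (x1, c), (x1, c - nd),
            (x0, c - nd), (x0, c), (0.0, c),
        ]
    )
    verts, faces = _extrude(cross, b)
    # extrusion is along z; swap so the channel depth runs along z again
    verts = verts[:, [0, 2, 1]]
    faces = faces[:, ::-1]
    v_box = a * b * c
    v = v_box - nw * nd * b
    area = (
        2.0 * (a * c - nw * nd)  # front/back caps
        + 2.0 * b * c + a * b  # outer sides + bottom
        + (a - nw) * b  # top shoulders
        + 2.0 * nd * b + nw * b  # channel walls + channel floor
    )
    analytic = {
        "volume_mm3": v,
        "surface_area_mm2": area,
        "convexity_ratio": v / v_box,
    }
    tol = {"volume_mm3": 1e-9, "surface_area_mm2": 1e-9, "convexity_ratio": 1e-9}
    echo = {
        "extents": (a, b, c), "notch_width_frac": w, "notch_depth_frac": d,
    }
    return verts, faces, analytic, tol, echo


def _make_spiked_star(
    n_points: int = 5,
    outer_radius: float = 6.0,
    inner_radius: float = 2.0,
    height: float = 3.0,
):
    """Star-polygon prism: the ridge of each star point is a sharp edge whose
    dihedral angle equals the planar apex angle of the point."""
    if n_points < 3 or inner_radius <= 0 or outer_radius <= inner_radius:
        raise ValueError("star needs n >= 3 and 0 < inner < outer radius")
    n = int(n_points)
    ang = np.pi / n
    pts = []
    for k in range(2 * n):
        r = outer_radius if k % 2 == 0 else inner_radius
        t = k * ang
        pts.append((r * np.cos(t), r * np.sin(t)))
    pts = np.asarray(pts)
    verts, faces = _extrude(pts, height)
    # planar apex angle at an outer vertex (closed form from the geometry)
    o = np.array([outer_radius, 0.0])
    p1 = inner_radius * np.array([np.cos(ang), np.sin(ang)])
    p2 = inner_radius * np.array([np.cos(ang), -np.sin(ang)])
    u, v = p1 - o, p2 - o
    apex = np.degrees(
        np.arccos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    )
    area2d = abs(_polygon_area(pts))
    perim = float(np.sum(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)))
    analytic = {
        "volume_mm3": area2d * height,
        "surface_area_mm2": 2.0 * area2d + perim * height,
        "min_dihedral_deg": float(apex),
        "sharp_edge_count": n if apex < 90.0 else 0,
    }
    tol = {
        "volume_mm3": 1e-9, "surface_area_mm2": 1e-9,
        "min_dihedral_deg": 1e-6, "sharp_edge_count": 0,
    }
    echo = {
        "n_points": n, "outer_radius": outer_radius,
        "inner_radius": inner_radius, "height": height,
    }
    return verts, faces, analytic, tol, echo


# ---------------------------------------------------------------------------
# rendered photographs


def render_photo(
    shape: str,
    params: dict | None = None,
    mm_per_px: float = 0.05,
    ruler: dict | None = None,
    noise_seed: int | None = None,
    canvas_px: tuple[int, int] = (480, 640),
    noise_fraction: float = 0.0,
):
    """Render a calibrated synthetic photograph: dark shape on a bright
    background with a yellow ruler band (dark ticks) along the bottom edge.

    ``ruler`` takes ``tick_spacing_mm`` (default 1.0) and ``tick_px``
    (default ``tick_spacing_mm / mm_per_px``). Supersampled coverage gives
    anti-aliased edges. Returns an (H, W, 3) uint8 image and the
    ground-truth record with the analytic 2D descriptor set.

    Shapes (all dimensions mm): ``disk`` (radius), ``square`` (side,
    angle_deg), ``stadium`` (length of the straight section, cap_radius,
    angle_deg), ``polygon`` (vertices, closed, CCW).
    """
    params = dict(params or {})
    ruler = dict(ruler or {})
    if shape not in PHOTO_SHAPES:
        raise ValueError(f"unknown shape {shape!r}; choose from {PHOTO_SHAPES}")
    h, w = canvas_px
    tick_spacing_mm = float(ruler.get("tick_spacing_mm", 1.0))
    tick_px = float(ruler.get("tick_px", tick_spacing_mm / mm_per_px))
    band_h = int(ruler.get("band_height_px", 50))

    # off-grid subpixel offset avoids degenerate edge/pixel-center alignment
    cx_mm = (w / 2.0 + 0.37) * mm_per_px
    cy_mm = ((h - band_h) / 2.0 + 0.23) * mm_per_px

    inside, analytic, tol, extent_mm = _shape_sdf(shape, params, cx_mm, cy_mm)
    if extent_mm / mm_per_px > min(w, h - band_h) - 40:
        raise LayoutError(
            f"shape extent {extent_mm:.1f} mm does not fit the canvas with margin"
        )

    ss = 4  # supersampling factor
    yy, xx = np.mgrid[0 : (h - band_h) * ss, 0 : w * ss]
    # pixel centers at integer coordinates, origin top-left
    xmm = (xx + 0.5) / ss * mm_per_px - 0.5 * mm_per_px
    ymm = (yy + 0.5) / ss * mm_per_px - 0.5 * mm_per_px
    cov = inside(xmm, ymm).astype(float)
    cov = cov.reshape(h - band_h, ss, w, ss).mean(axis=(1, 3))

    img = np.empty((h, w, 3), dtype=np.uint8)
    bg, fg = 235.0, 25.0
    body = bg + (fg - bg) * cov
    img[: h - band_h] = np.repeat(body[:, :, None], 3, axis=2).astype(np.uint8)

    # yellow ruler band with dark ticks
    band = np.zeros((band_h, w, 3), dtype=float)
    band[:, :] = (225, 195, 40)
    dark = np.array([35.0, 30.0, 25.0])
    x = tick_px / 2.0
    while x < w - 1:
        # anti-aliased 2 px tick centred at fractional column x
        for c in range(max(int(np.floor(x - 2)), 0), min(int(np.ceil(x + 2)) + 1, w)):
            covw = max(0.0, min(c + 0.5, x + 1.0) - max(c - 0.5, x - 1.0))
            if covw > 0:
                band[8:-8, c] = (1 - covw) * band[8:-8, c] + covw * dark
        x += tick_px
    img[h - band_h :] = band.astype(np.uint8)

    if noise_seed is not None and noise_fraction > 0:
        rng = np.random.default_rng(noise_seed)
        n_noise = int(noise_fraction * (h - band_h) * w)
        ys = rng.integers(0, h - band_h, n_noise)
        xs = rng.integers(0, w, n_noise)
        vals = rng.choice([20, 240], size=n_noise)
        img[ys, xs] = vals[:, None]

    analytic["mm_per_px"] = mm_per_px
    tol["mm_per_px"] = 0.01
    echo = {
        "shape": shape, "params": params, "mm_per_px": mm_per_px,
        "tick_spacing_mm": tick_spacing_mm, "tick_px": tick_px,
        "band_height_px": band_h, "canvas_px": list(canvas_px),
        "noise_seed": noise_seed, "noise_fraction": noise_fraction,
    }
    record = GroundTruthRecord(
        fixture_id=f"photo-{shape}", analytic=analytic, tolerance=tol,
        generator_params=echo,
    )
    return img, record


def _shape_sdf(shape: str, params: dict, cx: float, cy: float):
    """Return (inside(x, y), analytic descriptors, tolerances, max extent)."""
    if shape == "disk":
        r = float(params.get("radius", 5.0))
        if r <= 0:
            raise ValueError("disk radius must be positive")

        def inside(x, y):
            return (x - cx) ** 2 + (y - cy) ** 2 <= r**2

        analytic = {
            "area_mm2": np.pi * r**2, "perimeter_mm": 2 * np.pi * r,
            "feret_max_mm": 2 * r, "feret_min_mm": 2 * r,
            "aspect_ratio": 1.0, "circularity": 1.0, "solidity": 1.0,
            "min_curvature_radius_mm": r,
        }
        tol = {
            "area_mm2": 0.02, "perimeter_mm": 0.02, "feret_max_mm": 0.02,
            "feret_min_mm": 0.02, "aspect_ratio": 0.02, "circularity": 0.015,
            "solidity": 0.01, "min_curvature_radius_mm": 0.05,
        }
        return inside, analytic, tol, 2 * r

    if shape == "square":
        s = float(params.get("side", 5.0))
        ang = np.radians(float(params.get("angle_deg", 0.0)))
        if s <= 0:
            raise ValueError("square side must be positive")
        ca, sa = np.cos(ang), np.sin(ang)

        def inside(x, y):
            u = (x - cx) * ca + (y - cy) * sa
            v = -(x - cx) * sa + (y - cy) * ca
            return (np.abs(u) <= s / 2) & (np.abs(v) <= s / 2)

        analytic = {
            "area_mm2": s**2, "perimeter_mm": 4 * s,
            "feret_max_mm": s * np.sqrt(2), "feret_min_mm": s,
            "aspect_ratio": 1 / np.sqrt(2), "circularity": np.pi / 4,
            "solidity": 1.0,
        }
        tol = {
            "area_mm2": 0.02, "perimeter_mm": 0.02, "feret_max_mm": 0.02,
            "feret_min_mm": 0.02, "aspect_ratio": 0.02, "circularity": 0.02,
            "solidity": 0.01,
        }
        return inside, analytic, tol, s * np.sqrt(2)

    if shape == "stadium":
        L = float(params.get("length", 6.0))  # straight section
        r = float(params.get("cap_radius", 1.0))
        ang = np.radians(float(params.get("angle_deg", 0.0)))
        if L <= 0 or r <= 0:
            raise ValueError("stadium needs length > 0 and cap_radius > 0")
        ca, sa = np.cos(ang), np.sin(ang)

        def inside(x, y):
            u = (x - cx) * ca + (y - cy) * sa
            v = -(x - cx) * sa + (y - cy) * ca
            du = np.maximum(np.abs(u) - L / 2, 0.0)
            return du**2 + v**2 <= r**2

        analytic = {
            "area_mm2": 2 * r * L + np.pi * r**2,
            "perimeter_mm": 2 * L + 2 * np.pi * r,
            "feret_max_mm": L + 2 * r, "feret_min_mm": 2 * r,
            "aspect_ratio": 2 * r / (L + 2 * r), "solidity": 1.0,
            "min_curvature_radius_mm": r,
        }
        tol = {
            "area_mm2": 0.02, "perimeter_mm": 0.02, "feret_max_mm": 0.02,
            "feret_min_mm": 0.03, "aspect_ratio": 0.03, "solidity": 0.01,
            "min_curvature_radius_mm": 0.08,
        }
        return inside, analytic, tol, L + 2 * r

    # polygon
    import shapely

    pts = np.asarray(params["vertices"], dtype=float)
    if len(pts) < 3:
        raise ValueError("polygon needs >= 3 vertices")
    centroid_shift = pts.mean(axis=0)
    pts = pts - centroid_shift + np.array([cx, cy])
    poly = shapely.Polygon(pts)
    if not poly.is_valid:
        raise ValueError("polygon is not simple")

    def inside(x, y):
        return shapely.contains_xy(poly, x.ravel(), y.ravel()).reshape(x.shape)

    hull = poly.convex_hull
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    dmax = float(np.sqrt(d2.max()))
    analytic = {
        "area_mm2": poly.area, "perimeter_mm": poly.length,
        "feret_max_mm": dmax, "solidity": poly.area / hull.area,
    }
    # acute polygon corners are truncated by segmentation smoothing, so
    # area/perimeter recovery is looser than for smooth or right-angled shapes
    tol = {
        "area_mm2": 0.035, "perimeter_mm": 0.035, "feret_max_mm": 0.04,
        "solidity": 0.02,
    }
    span = pts.max(axis=0) - pts.min(axis=0)
    return inside, analytic, tol, float(np.hypot(*span))
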