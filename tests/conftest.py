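import numpy as np
import pytest

from fbmorph import airway, image, mesh
from fbmorph.fixtures import make_mesh, render_photo

# Published descriptor values of the worked clinical case (a small metallic
# fragment retrieved from a child's laryngo-tracheal tract), used to drive
# the rule engine without the original mesh/photograph.
CASE_3D = dict(
    volume_mm3=73.3,
    surface_area_mm2=106.3,
    extents_mm=(8.24, 5.72, 4.51),
    aabb_extents_mm=(8.50, 6.82, 4.60),  # width 6.82 = second AABB span
    convexity_ratio=0.68,
    sharp_edge_count=4,
    min_dihedral_deg=13.7,
    mass_g=0.5,
)
CASE_2D = dict(
    area_mm2=3.49,
    perimeter_mm=7.23,
    feret_max_mm=2.58,
    feret_min_mm=1.60,
    solidity=0.99,
    min_curvature_radius_mm=0.074,
)


@pytest.fixture(scope="session")
def case_d3() -> mesh.Shape3DDescriptors:
    c = CASE_3D
    L1, L2, L3 = c["extents_mm"]
    return mesh.Shape3DDescriptors(
        volume_mm3=c["volume_mm3"],
        surface_area_mm2=c["surface_area_mm2"],
        surface_to_volume_per_mm=c["surface_area_mm2"] / c["volume_mm3"],
        extents_mm=c["extents_mm"],
        aabb_extents_mm=c["aabb_extents_mm"],
        elongation=1 - (L3 / L1) ** 2,
        flatness=1 - (L2 / L1) ** 2,
        sphericity=mesh.sphericity(c["volume_mm3"], c["surface_area_mm2"]),
        convexity_ratio=c["convexity_ratio"],
        sharp_edge_count=c["sharp_edge_count"],
        min_dihedral_deg=c["min_dihedral_deg"],
        mass_g=c["mass_g"],
    )


@pytest.fixture(scope="session")
def case_d2() -> image.Shape2DDescriptors:
    c = CASE_2D
    return image.Shape2DDescriptors(
        area_mm2=c["area_mm2"],
        perimeter_mm=c["perimeter_mm"],
        feret_max_mm=c["feret_max_mm"],
        feret_min_mm=c["feret_min_mm"],
        aspect_ratio=c["feret_min_mm"] / c["feret_max_mm"],
        circularity=4 * np.pi * c["area_mm2"] / c["perimeter_mm"] ** 2,
        solidity=c["solidity"],
        min_curvature_radius_mm=c["min_curvature_radius_mm"],
    )


@pytest.fixture(scope="session")
def ref_2y_male() -> airway.AirwayReferenceSet:
    return airway.builtin_reference(2, "male")


# watertight mesh fixture suite shared across volume/frame/property tests
MESH_SUITE = [
    ("icosphere", {"radius": 5.0, "subdivisions": 3}),
    ("icosphere", {"radius": 2.0, "subdivisions": 2}),
    ("ellipsoid", {"radii": (4.0, 3.0, 2.0), "subdivisions": 3}),
    ("ellipsoid", {"radii": (6.0, 2.5, 1.5), "subdivisions": 3, "rotate": True}),
    ("box", {"extents": (8.24, 5.72, 4.51)}),
    ("box", {"extents": (10.0, 4.0, 2.0), "rotate": True}),
    ("capsule", {"radius": 2.0, "length": 5.0}),
    ("capsule", {"radius": 1.0, "length": 8.0, "rotate": True}),
    ("notched_box", {}),
    ("notched_box", {"extents": (12.0, 5.0, 4.0), "notch_width_frac": 0.5,
                     "notch_depth_frac": 0.5, "rotate": True}),
    ("spiked_star", {}),
    ("spiked_star", {"n_points": 7, "outer_radius": 5.0, "inner_radius": 2.5,
                     "height": 2.0, "rotate": True}),
]


@pytest.fixture(scope="session")
def mesh_suite():
    return [make_mesh(kind, params, seed=7 + i)
            for i, (kind, params) in enumerate(MESH_SUITE)]


@pytest.fixture(scope="session")
def disk_photo():
    return render_photo("disk", {"radius": 5.0}, mm_per_px=0.05)


@pytest.fixture(scope="session")
def square_photo():
    return render_photo("square", {"side": 5.0}, mm_per_px=0.05)


@pytest.fixture(scope="session")
def stadium_photo():
    return render_photo(
        "stadium", {"length": 6.0, "cap_radius": 1.0, "angle_deg": 20.0},
        mm_per_px=0.05,
    )
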