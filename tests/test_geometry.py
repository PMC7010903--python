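"""Cell geometry construction, sampling uniformity, layouts, and the well."""
import numpy as np
import pytest
from scipy.stats import chisquare

from celldose.geometry import (
    CYTOPLASM,
    GOLGI,
    MEMBRANE,
    NUCLEUS,
    GeometryError,
    MeshCell,
    SphereCell,
    TruncatedConeCell,
    build_well,
    cluster_layout,
    layout_monolayer,
    load_mesh_cell,
    make_sphere_cell,
    make_truncated_cone_cell,
    min_surface_distance,
    _unit_sphere_surface,
)
from celldose.synthetic import generate_mesh_cell


class TestSphereCell:
    def test_closed_form_volumes(self):
        cell = make_sphere_cell(9.0, 6.0)
        assert cell.cell_volume == pytest.approx(3053.6, rel=1e-3)
        assert cell.nucleus_volume == pytest.approx(904.8, rel=1e-3)

    def test_concentric_by_default(self):
        cell = make_sphere_cell(9.0, 6.0)
        np.testing.assert_array_equal(cell.nucleus_center, cell.center)

    def test_equal_radii_rejected(self):
        with pytest.raises(GeometryError):
            make_sphere_cell(9.0, 9.0)

    def test_protruding_nucleus_rejected(self):
        with pytest.raises(GeometryError, match="protrudes"):
            make_sphere_cell(9.0, 6.0, (0.0, 0.0, 4.0))


class TestTruncatedConeCell:
    def test_frustum_volume_closed_form(self):
        cell = make_truncated_cone_cell(
            12.0, 6.0, 10.0, nucleus_semi_axes=(6.0, 6.0, 3.0), golgi_tube_radius=0.8
        )
        # pi * h * (Rb^2 + Rb*Rt + Rt^2) / 3
        assert cell.cell_volume == pytest.approx(np.pi * 10 * 252 / 3, rel=1e-12)

    def test_family_spans_observed_volumes(self):
        """Self-similar scaling covers the observed cell and nucleus ranges."""
        lo = TruncatedConeCell.scaled_to_volume(1900.0)
        hi = TruncatedConeCell.scaled_to_volume(5500.0)
        assert lo.cell_volume == pytest.approx(1900.0)
        assert hi.cell_volume == pytest.approx(5500.0)
        assert lo.nucleus_volume <= 570.0 * 1.005
        assert hi.nucleus_volume >= 1652.0 / 1.005
        for cell in (lo, hi):
            cell.validate()

    def test_golgi_minimum_distance_honoured(self, reference_cell, rng):
        nuc = reference_cell.nucleus_center + _unit_sphere_surface(
            rng, 4000
        ) * reference_cell.nucleus_semi_axes
        d = min_surface_distance(reference_cell._golgi_surface(rng, 2000), nuc)
        assert d >= reference_cell.golgi_min_distance - 0.1

    def test_invalid_frustum_rejected(self):
        with pytest.raises(GeometryError):
            make_truncated_cone_cell(6.0, 12.0, 10.0)

    def test_nucleus_too_large_rejected(self):
        with pytest.raises(GeometryError, match="N"):
            make_truncated_cone_cell(8.0, 4.0, 6.0, nucleus_semi_axes=(7.9, 7.9, 2.9))

    def test_compartment_volume_additivity(self, reference_cell):
        c = reference_cell
        total = (
            c.compartment_volume(CYTOPLASM)
            + c.compartment_volume(NUCLEUS)
            + c.compartment_volume(GOLGI)
        )
        assert total == pytest.approx(c.cell_volume, rel=1e-12)


@pytest.mark.parametrize("compartment", [CYTOPLASM, NUCLEUS, GOLGI])
def test_sampled_points_satisfy_containment(reference_cell, rng, compartment):
    pts = reference_cell.sample_point(compartment, rng, 20_000)
    assert reference_cell.contains(compartment, pts).all()


def test_membrane_points_lie_on_surface(reference_cell, rng):
    pts = reference_cell.sample_point(MEMBRANE, rng, 5000)
    z, r = pts[:, 2], np.hypot(pts[:, 0], pts[:, 1])
    on_base = np.abs(z) < 1e-6
    on_top = np.abs(z - reference_cell.height) < 1e-6
    on_side = np.abs(r - np.asarray(reference_cell._radius_at(z))) < 1e-6
    assert np.all(on_base | on_top | on_side)


def test_octant_uniformity_in_spherical_nucleus(rng):
    cell = make_sphere_cell(9.0, 6.0)
    pts = cell.sample_point(NUCLEUS, rng, 40_000) - cell.nucleus_center
    octant = (pts[:, 0] > 0) * 4 + (pts[:, 1] > 0) * 2 + (pts[:, 2] > 0)
    counts = np.bincount(octant, minlength=8)
    assert chisquare(counts).pvalue > 0.01


@pytest.mark.parametrize(
    "make",
    [
        lambda: make_sphere_cell(9.0, 6.0),
        TruncatedConeCell.reference,
    ],
    ids=["sphere", "cone"],
)
def test_hit_or_miss_volume_matches_closed_form(make, rng):
    """MC hit-or-miss volume vs analytic, within 3 sigma (binomial)."""
    cell = make()
    lo = np.array([-16.0, -16.0, 0.0])
    hi = np.array([16.0, 16.0, 20.0])
    n = 200_000
    pts = lo + rng.random((n, 3)) * (hi - lo)
    vbox = np.prod(hi - lo)
    for comp in (CYTOPLASM, NUCLEUS):
        p = cell.contains(comp, pts).mean()
        mc = p * vbox
        sigma = vbox * np.sqrt(p * (1 - p) / n)
        assert abs(mc - cell.compartment_volume(comp)) < 3.5 * sigma


class TestLayouts:
    def test_touching_lattice_first_ring(self, reference_cell):
        lay = layout_monolayer(reference_cell, gap=0.0, cutoff_um=280.0)
        d = np.hypot(lay.positions[:, 0], lay.positions[:, 1])
        assert d.min() == pytest.approx(reference_cell.footprint_diameter)
        assert (d < lay.pitch * 1.01).sum() == 6

    def test_gap_scales_pitch(self, reference_cell):
        lay = layout_monolayer(reference_cell, gap=5.0)
        d = np.hypot(lay.positions[:, 0], lay.positions[:, 1])
        assert d.min() == pytest.approx(6 * reference_cell.footprint_diameter)

    def test_neighbor_count_matches_brute_force(self, reference_cell):
        lay = layout_monolayer(reference_cell, gap=0.0, cutoff_um=280.0)
        pitch = reference_cell.footprint_diameter
        count = 0
        for i in range(-30, 31):
            for j in range(-30, 31):
                if i == 0 and j == 0:
                    continue
                x = pitch * (i + 0.5 * j)
                y = pitch * np.sqrt(3) / 2 * j
                if np.hypot(x, y) <= 280.0:
                    count += 1
        assert lay.n_neighbors == count

    def test_layout_symmetric_under_negation(self, reference_cell):
        """Neighbour enumeration is symmetric: A sees B iff B sees A."""
        lay = layout_monolayer(reference_cell, gap=0.0, cutoff_um=150.0)
        pos = {tuple(np.round(p, 6)) for p in lay.positions}
        assert {tuple(np.round(-p, 6)) for p in lay.positions} == pos

    def test_cluster_sizes(self, reference_cell):
        assert cluster_layout(reference_cell, 1).n_neighbors == 0
        assert cluster_layout(reference_cell, 7).n_neighbors == 6

    def test_negative_gap_rejected(self, reference_cell):
        with pytest.raises(GeometryError):
            layout_monolayer(reference_cell, gap=-1.0)


class TestWell:
    def test_default_twelve_well_height(self):
        well = build_well(1.0)
        assert well.height_mm == pytest.approx(2.607, abs=0.01)

    def test_height_linear_in_volume(self):
        assert build_well(2.0).height_mm == pytest.approx(2 * build_well(1.0).height_mm)

    def test_volume_roundtrip(self):
        well = build_well(1.5, 11.05)
        vol = np.pi * well.radius_mm**2 * well.height_mm / 1e3
        assert vol == pytest.approx(well.volume_ml, rel=1e-3)


class TestMeshCell:
    def test_unit_cube_volume(self):
        import trimesh

        box = trimesh.creation.box((1.0, 1.0, 1.0))
        assert box.volume == pytest.approx(1.0)

    def test_synthetic_cell_volume_within_one_percent(self):
        meshes = generate_mesh_cell((3546.0, 1061.0, 70.0), seed=5)
        assert meshes["cytoplasm"].volume == pytest.approx(3546.0, rel=0.01)
        assert meshes["nucleus"].volume == pytest.approx(1061.0, rel=0.01)
        assert meshes["golgi"].volume == pytest.approx(70.0, rel=0.01)
        cell = MeshCell(meshes["cytoplasm"], meshes["nucleus"], meshes["golgi"])
        cell.validate()

    def test_mesh_with_hole_rejected(self):
        import trimesh

        meshes = generate_mesh_cell((3546.0, 1061.0, None), seed=5)
        cyto = meshes["cytoplasm"]
        holed = trimesh.Trimesh(cyto.vertices, cyto.faces[:-1], process=False)
        with pytest.raises(GeometryError, match="watertight"):
            MeshCell(holed, meshes["nucleus"])

    def test_nucleus_outside_rejected(self):
        meshes = generate_mesh_cell((3546.0, 1061.0, None), seed=5)
        meshes["nucleus"].apply_translation([30.0, 0.0, 0.0])
        with pytest.raises(GeometryError, match="nucleus"):
            MeshCell(meshes["cytoplasm"], meshes["nucleus"])

    def test_obj_roundtrip(self, tmp_path):
        generate_mesh_cell((3000.0, 900.0, 60.0), seed=2, out_dir=tmp_path)
        cell = load_mesh_cell(
            tmp_path / "synthetic_cytoplasm.obj",
            tmp_path / "synthetic_nucleus.obj",
            tmp_path / "synthetic_golgi.obj",
        )
        assert cell.cell_volume == pytest.approx(3000.0, rel=0.01)
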