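"""3D plant and scene construction."""

import numpy as np
import pytest

from canopyflux.architecture import PlantArchitecture, age_scale
from canopyflux.geometry import LayoutConfig, build_leaf, build_plant, build_scene
from canopyflux.synthetic import gen_architectures, gen_leaf_optics


def _arch(**kw):
    base = dict(
        n_leaves=21,
        internode_length=0.1286,
        leaf_length=0.36,
        leaf_width=0.38,
        lia_deg=75.0,
        ra_deg=9.0,
        tla_deg=-30.0,
        base_angle_deg=12.0,
        middle_angle_deg=3.0,
        outside_angle_deg=-43.0,
    )
    base.update(kw)
    return PlantArchitecture(**base)


def _projected_area(tris):
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    return 0.5 * np.abs(np.cross(e1, e2)[:, 2]).sum()


class TestArchitecture:
    def test_validation(self):
        with pytest.raises(ValueError):
            _arch(n_leaves=0)
        with pytest.raises(ValueError):
            _arch(leaf_length=-1.0)
        with pytest.raises(ValueError):
            _arch(lia_deg=180.0)
        with pytest.raises(ValueError):
            _arch(ra_deg=95.0)

    def test_age_scale_monotone_saturating(self):
        scales = [age_scale(r) for r in range(1, 10)]
        assert all(b >= a for a, b in zip(scales, scales[1:]))
        assert scales[5] == 1.0 and all(s == 1.0 for s in scales[5:])
        assert 0 < scales[0] < 1


class TestBuildLeaf:
    def test_upright_blue_vs_flat_green_centroids(self):
        # steeper insertion and positive rachis angle lift the leaflets
        archs = gen_architectures()
        blue = build_leaf(archs["blue"].with_leaves(21), 10, (0, 0, 1.0))
        green = build_leaf(archs["green"].with_leaves(21), 10, (0, 0, 1.0))
        assert blue.leaflet_centroid[:, 2].mean() > green.leaflet_centroid[:, 2].mean()

    def test_flat_leaf_normals_vertical_and_projection(self):
        flat = _arch(lia_deg=90.0, ra_deg=0.0, tla_deg=0.0, base_angle_deg=0.0,
                     middle_angle_deg=0.0, outside_angle_deg=0.0)
        leaf = build_leaf(flat, 10)
        e1 = leaf.triangles[:, 1] - leaf.triangles[:, 0]
        e2 = leaf.triangles[:, 2] - leaf.triangles[:, 0]
        n = np.cross(e1, e2)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        assert np.allclose(np.abs(n[:, 2]), 1.0, atol=1e-9)
        assert _projected_area(leaf.triangles) == pytest.approx(leaf.area, rel=1e-9)

    def test_fifteen_leaflets(self):
        leaf = build_leaf(_arch(), 10)
        assert leaf.n_leaflets == 15
        assert set(np.unique(leaf.leaflet_local)) == set(range(15))

    def test_invalid_rank(self):
        with pytest.raises(ValueError):
            build_leaf(_arch(n_leaves=5), 6)

    def test_area_invariant_under_rotations(self):
        a1 = build_leaf(_arch(), 10).area
        a2 = build_leaf(_arch(lia_deg=50.0, ra_deg=30.0, tla_deg=45.0,
                              base_angle_deg=-60.0, middle_angle_deg=20.0,
                              outside_angle_deg=80.0), 10).area
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_flatter_insertion_increases_projected_area(self):
        # increasing LIA toward 90° with other angles 0 flattens the leaf
        prev = -1.0
        for lia in (30.0, 50.0, 70.0, 90.0):
            arch = _arch(lia_deg=lia, ra_deg=0.0, tla_deg=0.0, base_angle_deg=0.0,
                         middle_angle_deg=0.0, outside_angle_deg=0.0)
            proj = _projected_area(build_leaf(arch, 10).triangles)
            assert proj > prev
            prev = proj


class TestBuildPlant:
    def test_leaflet_count_product(self):
        plant = build_plant(_arch())
        assert len(plant.leaflet_area) == 21 * 15

    def test_single_leaf_plant(self):
        plant = build_plant(_arch(n_leaves=1))
        assert len(plant.leaflet_area) == 15
        assert plant.leaflet_rank[0] == 1

    def test_crop_top_height(self):
        plant = build_plant(_arch(), base_position=(0, 0, 0.8))
        assert plant.top_height == pytest.approx(3.5, abs=0.01)


@pytest.fixture(scope="module")
def crop_scene():
    archs = gen_architectures()
    return build_scene(archs["white"], gen_leaf_optics("white"), LayoutConfig(), "crop")


class TestBuildScene:
    def test_lai_target(self, crop_scene):
        assert crop_scene.lai == pytest.approx(3.0, abs=0.1)

    def test_leaflet_id_count(self, crop_scene):
        assert crop_scene.n_leaflets == 32 * 21 * 15 == 10080
        # every leaflet id maps to exactly one (plant, rank)
        assert len(crop_scene.leaflet_plant) == 10080
        assert crop_scene.leaflet_rank.min() == 1 and crop_scene.leaflet_rank.max() == 21

    def test_validates(self, crop_scene):
        crop_scene.validate(box_tolerance=0.2)

    def test_deterministic(self):
        archs = gen_architectures()
        s1 = build_scene(archs["white"], gen_leaf_optics("white"), LayoutConfig(), "plant")
        s2 = build_scene(archs["white"], gen_leaf_optics("white"), LayoutConfig(), "plant")
        assert np.array_equal(s1.triangles, s2.triangles)

    def test_single_leaf_preset(self):
        archs = gen_architectures()
        scene = build_scene(archs["white"], gen_leaf_optics("white"), LayoutConfig(), "leaf")
        assert scene.n_leaflets == 15
        assert len(scene.lamp_segments) == 1

    def test_plants_above_lamp_raises(self):
        archs = gen_architectures()
        layout = LayoutConfig(lamp_height=2.0)
        with pytest.raises(ValueError, match="above the light"):
            build_scene(archs["white"], gen_leaf_optics("white"), layout, "crop")

    def test_obj_export(self, tmp_path):
        archs = gen_architectures()
        scene = build_scene(archs["white"], gen_leaf_optics("white"), LayoutConfig(), "leaf")
        path = tmp_path / "scene.obj"
        scene.export_obj(path)
        text = path.read_text()
        assert "leaflet_0" in text and "leaflet_14" in text
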