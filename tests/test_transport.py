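"""Monte Carlo light transport: sampling, conservation, analytic oracles."""

import numpy as np
import pytest

from canopyflux import LightSource, absorbance_summary, sample_rays, trace
from canopyflux.spectra import N_BANDS
from canopyflux.synthetic import gen_architectures, gen_leaf_optics
from canopyflux.geometry import LayoutConfig, build_scene

from conftest import (
    batched_absorbance,
    collimated_source,
    flat_spectrum,
    make_layer_scene,
    two_stream_layers,
)


class TestSampleRays:
    def test_delta_pattern_straight_down(self):
        src = collimated_source()
        _, dirs = sample_rays(src, 500, seed=1)
        assert np.allclose(dirs, [0.0, 0.0, -1.0])

    def test_isotropic_mean_downward_cosine(self):
        # analytic mean of cos over the lower hemisphere is 1/2
        seg = np.array([[[0.0, 0.0, 2.0], [1.0, 0.0, 2.0]]])
        src = LightSource(seg, flat_spectrum(), 100.0, "isotropic")
        _, dirs = sample_rays(src, 40_000, seed=2)
        assert -dirs[:, 2].mean() == pytest.approx(0.5, abs=0.01)

    def test_same_seed_identical_stream(self):
        src = collimated_source()
        o1, d1 = sample_rays(src, 1000, seed=42)
        o2, d2 = sample_rays(src, 1000, seed=42)
        assert np.array_equal(o1, o2) and np.array_equal(d1, d2)

    def test_origins_on_segment(self):
        seg = np.array([[[0.2, 0.3, 2.0], [0.2, 0.7, 2.0]]])
        src = LightSource(seg, flat_spectrum(), 100.0, "cosine")
        origins, _ = sample_rays(src, 200, seed=3)
        assert np.allclose(origins[:, 0], 0.2)
        assert origins[:, 1].min() >= 0.3 and origins[:, 1].max() <= 0.7


class TestTraceOracles:
    def test_opaque_cover_absorbs_everything(self):
        scene = make_layer_scene([(1.0, 0.0, 0.0)])  # black leaf covering the floor
        tally = trace(scene, collimated_source(), 5_000, seed=5)
        assert absorbance_summary(tally, "leaves") == pytest.approx(100.0, abs=1e-9)

    def test_single_transmitting_layer_split(self):
        # a = 0.8, T = 0.2, R = 0: deterministic weight split, one interaction
        scene = make_layer_scene([(1.0, 0.0, 0.2)])
        tally = trace(scene, collimated_source(), 5_000, seed=6)
        assert tally.leaflet_band.sum() == pytest.approx(80.0, abs=1e-9)
        assert tally.floor.sum() == pytest.approx(20.0, abs=1e-9)

    def test_empty_scene_all_to_floor(self):
        scene = make_layer_scene([])
        tally = trace(scene, collimated_source(), 2_000, seed=7)
        assert tally.floor.sum() == pytest.approx(100.0, abs=1e-9)
        assert tally.leaflet_band.sum() == 0.0

    def test_two_layers_match_two_stream_solution(self):
        r, t = 0.1, 0.2
        absorbed, floor, escaped = two_stream_layers(r, t, 2)
        scene = make_layer_scene([(1.5, r, t), (1.0, r, t)])
        src = collimated_source()
        mean, se, vals = batched_absorbance(scene, src, 10_000, 8, seed0=50)
        expected = 100.0 * absorbed.sum()
        assert abs(mean - expected) < max(3.0 * se, 0.05)
        # per-layer and floor split on one long run
        tally = trace(scene, src, 60_000, seed=60)
        per_layer = tally.leaflet_band.sum(axis=1) / tally.input_flux
        assert per_layer[0] == pytest.approx(absorbed[0], abs=0.01)
        assert per_layer[1] == pytest.approx(absorbed[1], abs=0.01)
        assert tally.floor.sum() / tally.input_flux == pytest.approx(floor, abs=0.01)
        assert tally.escaped.sum() / tally.input_flux == pytest.approx(escaped, abs=0.01)


class TestConservation:
    def test_exact_photon_balance_layers(self):
        scene = make_layer_scene([(1.5, 0.3, 0.3), (1.0, 0.2, 0.4)])
        tally = trace(scene, collimated_source(), 20_000, seed=8)
        c = tally.conservation()
        assert abs(c["residual"]) < 1e-9 * c["emitted"]
        assert c["max_band_residual"] < 1e-12 * c["emitted"]

    def test_exact_photon_balance_plant_scene(self, cfg):
        scene = cfg.scene_for("white", "plant")
        src = LightSource(scene.lamp_segments, flat_spectrum(), 100.0, "cosine")
        tally = trace(scene, src, 20_000, seed=9)
        c = tally.conservation()
        assert abs(c["residual"]) < 1e-9 * c["emitted"]
        assert c["truncated"] < 0.01 * c["emitted"]
        assert c["escaped"] < 0.2 * c["emitted"]


class TestProperties:
    def test_variance_shrinks_as_inverse_sqrt_rays(self):
        # SE of absorbance ~ n^(-1/2): log-log slope -0.5 ± 0.1
        scene = make_layer_scene([(1.5, 0.1, 0.2), (1.0, 0.1, 0.2)])
        src = collimated_source()
        sizes = [1_000, 10_000, 100_000]
        sds = []
        for i, n in enumerate(sizes):
            reps = 16 if n < 100_000 else 8
            _, _, vals = batched_absorbance(scene, src, n, reps, seed0=200 + 50 * i)
            sds.append(vals.std(ddof=1))
        slope = np.polyfit(np.log10(sizes), np.log10(sds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_mirror_unfolding_equivalence(self, cfg):
        # a 3x3 mirrored tiling of the box is physically identical to the
        # mirrored single box; central-plant absorbance must agree within MC error
        from canopyflux.geometry import Scene

        arch = gen_architectures()["white"].with_leaves(7, 0.1286)
        layout = LayoutConfig(floor_x=0.8, floor_y=0.8, row_x=(0.4,), plants_per_row=1,
                              lamp_x=(0.4,), lamp_length=0.6, lamp_height=2.5)
        base = build_scene(arch, gen_leaf_optics("white"), layout, "plant", size_scale=1.0)

        # build the 3x3 unfolded copy: reflectively tile triangles and lamps
        tris, lids, plants = [], [], []
        W = H = 0.8
        for ix in range(3):
            for iy in range(3):
                t = base.triangles.copy()
                x = t[..., 0]
                y = t[..., 1]
                if ix % 2 == 1:
                    x = W - x
                if iy % 2 == 1:
                    y = H - y
                t[..., 0] = x + ix * W
                t[..., 1] = y + iy * H
                tris.append(t)
                lids.append(np.where(base.leaflet_id >= 0,
                                     base.leaflet_id + (ix * 3 + iy) * base.n_leaflets,
                                     -1))
                plants.append(np.full(base.n_leaflets, ix * 3 + iy, dtype=np.int32))
        segs = []
        for ix in range(3):
            for iy in range(3):
                s = base.lamp_segments.copy()
                x = s[..., 0]
                y = s[..., 1]
                if ix % 2 == 1:
                    x = W - x
                if iy % 2 == 1:
                    y = H - y
                s[..., 0] = x + ix * W
                s[..., 1] = y + iy * H
                segs.append(s)
        tiled = Scene(
            triangles=np.concatenate(tris),
            surface_class=np.tile(base.surface_class, 9),
            leaflet_id=np.concatenate(lids),
            optics_index=np.tile(base.optics_index, 9),
            optics_R=base.optics_R,
            optics_T=base.optics_T,
            box=(0.0, 3 * W, 0.0, 3 * H),
            z_ceiling=base.z_ceiling,
            ground_area=9 * base.ground_area,
            n_leaflets=9 * base.n_leaflets,
            leaflet_plant=np.concatenate(plants),
            leaflet_rank=np.tile(base.leaflet_rank, 9),
            leaflet_area=np.tile(base.leaflet_area, 9),
            lamp_segments=np.concatenate(segs),
        )

        src_base = LightSource(base.lamp_segments, flat_spectrum(), 100.0, "cosine")
        src_tiled = LightSource(tiled.lamp_segments, flat_spectrum(), 100.0, "cosine")
        m1, se1, _ = batched_absorbance(base, src_base, 20_000, 6, seed0=300)
        # central copy is plant index 4 (ix = iy = 1)
        vals = []
        for k in range(6):
            tally = trace(tiled, src_tiled, 9 * 20_000, seed=400 + k)
            vals.append(9 * absorbance_summary(tally, "plant:4"))
        vals = np.array(vals)
        m2, se2 = vals.mean(), vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(m1 - m2) < 3.0 * np.hypot(se1, se2) + 0.05

    def test_absorbance_monotone_in_lai(self):
        # more full-cover layers absorb more, other things equal
        src = collimated_source()
        prev = 0.0
        for n_layers in (1, 2, 4):
            zs = np.linspace(1.0, 2.0, n_layers)
            scene = make_layer_scene([(z, 0.1, 0.4) for z in zs])
            tally = trace(scene, src, 20_000, seed=11)
            ab = absorbance_summary(tally, "leaves")
            assert ab > prev
            prev = ab


class TestSummary:
    def test_scope_partition(self, cfg):
        scene = cfg.scene_for("white", "plant")
        src = LightSource(scene.lamp_segments, flat_spectrum(), 100.0, "cosine")
        tally = trace(scene, src, 10_000, seed=12)
        total = absorbance_summary(tally, "leaves")
        per_plant = sum(absorbance_summary(tally, f"plant:{p}") for p in range(32))
        assert per_plant == pytest.approx(total, rel=1e-9)
        assert absorbance_summary(tally, "canopy") >= total

    def test_tally_dataframe_units(self):
        scene = make_layer_scene([(1.0, 0.0, 0.2)])
        tally = trace(scene, collimated_source(), 2_000, seed=13)
        df = tally.to_dataframe()
        assert df["absorbed_flux"].sum() == pytest.approx(80.0, abs=1e-9)
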