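import numpy as np
import pytest

from canopylight.brdf import dhr, diffuse_equivalent
from canopylight.spectra import band_aggregate, default_bands
from canopylight.synthetic import (SynthParams, assemble_canopy,
                                   export_canopy_mesh, fixture_optics,
                                   generate_plant, lai, synth_gonio_fixture)

BAND_BINS = np.array([6, 10, 10, 4])


def test_plant_structure_and_height():
    params = SynthParams()
    heights = []
    for seed in range(10):
        plant = generate_plant(params, np.random.default_rng(seed))
        orders = sorted(l.order for l in plant.leaves)
        assert orders == [1, 2, 3, 4, 5]
        z = [l.attachment[2]
             for l in sorted(plant.leaves, key=lambda l: l.order)]
        assert np.all(np.diff(z) > 0)
        heights.append(plant.height)
    assert np.all(np.abs(np.array(heights) - 0.212) < 3 * 0.03 + 1e-9)


def test_leaf_area_matches_independent_cross_product():
    plant = generate_plant(SynthParams(), np.random.default_rng(1))
    for leaf in plant.leaves:
        v, f = leaf.vertices, leaf.faces
        area = 0.0
        for tri in f:           # independent scalar loop
            a, b, c = v[tri[0]], v[tri[1]], v[tri[2]]
            area += 0.5 * np.linalg.norm(np.cross(b - a, c - a))
        assert leaf.area == pytest.approx(area, rel=1e-12)
        assert np.isfinite(v).all()


def test_flat_leaf_normals_point_up():
    params = SynthParams(inclination_by_order_deg=(0.0,) * 5,
                         inclination_jitter_deg=0.0, droop_deg=0.0, cup=0.0)
    plant = generate_plant(params, np.random.default_rng(2))
    for leaf in plant.leaves:
        v, f = leaf.vertices, leaf.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        assert np.allclose(n[:, 2], 1.0, atol=1e-9)


def test_canopy_layouts():
    params = SynthParams()
    s3 = assemble_canopy("grid3x3", 0.2, params, np.random.default_rng(0))
    assert s3.n_plants == 9 and s3.central_indices == (4,)
    s4 = assemble_canopy("grid4x3", 0.2, params, np.random.default_rng(0))
    assert s4.n_plants == 12 and len(s4.central_indices) == 2
    s1 = assemble_canopy("single", 0.2, params, np.random.default_rng(0))
    assert s1.n_plants == 1
    with pytest.raises(ValueError):
        assemble_canopy("grid3x3", -0.1, params, np.random.default_rng(0))
    with pytest.raises(ValueError):
        assemble_canopy("hexagon", 0.2, params, np.random.default_rng(0))


def test_canopy_determinism():
    params = SynthParams()
    a = assemble_canopy("grid3x3", 0.2, params, np.random.default_rng(5))
    b = assemble_canopy("grid3x3", 0.2, params, np.random.default_rng(5))
    for pa, pb in zip(a.plants, b.plants):
        for la, lb in zip(pa.leaves, pb.leaves):
            assert np.array_equal(la.vertices, lb.vertices)


def test_lai_value_and_range():
    params = SynthParams()
    vals = []
    for seed in range(20):
        scene = assemble_canopy("grid3x3", 0.2, params,
                                np.random.default_rng(seed))
        v = lai(scene)
        # definition check against an independent computation
        assert v == pytest.approx(
            sum(p.leaf_area for p in scene.plants) / (9 * 0.2 ** 2), rel=1e-12)
        vals.append(v)
    assert 3.625 <= np.mean(vals) <= 5.625
    assert all(3.625 <= v <= 5.625 for v in vals)
    single = assemble_canopy("single", 0.2, params, np.random.default_rng(0))
    with pytest.raises(ValueError):
        lai(single)


def test_mesh_export_roundtrip(tmp_path):
    import trimesh
    scene = assemble_canopy("single", 0.2, SynthParams(),
                            np.random.default_rng(0))
    path = tmp_path / "canopy.obj"
    export_canopy_mesh(scene, path)
    loaded = trimesh.load(path)
    if isinstance(loaded, trimesh.Scene):
        n_tris = sum(len(g.faces) for g in loaded.geometry.values())
    else:
        n_tris = len(loaded.faces)
    expected = sum(len(l.faces) for l in scene.plants[0].leaves) \
        + len(scene.plants[0].stem_faces)
    assert n_tris == expected


def test_fixture_optics_spectral_orderings():
    phong, diffuse, stem_refl = fixture_optics()
    assert 0.0 < stem_refl < 1.0
    names = default_bands().names
    for side in range(2):
        closure = np.array([dhr(phong, b, side, 40.0)
                            for b in range(30)]) + phong.tau[side]
        assert np.all(closure <= 1.0 + 1e-9)
        by_band = dict(zip(names, band_aggregate(closure) / BAND_BINS))
        # weakly absorbed far-red and green vs. pigment-absorbed red/blue
        assert by_band["far_red"] > by_band["green"] > by_band["red"] \
            >= by_band["blue"]
        spec_frac = phong.ks[side] / (phong.ks[side] + phong.kd[side])
        sf = dict(zip(names, band_aggregate(spec_frac) / BAND_BINS))
        assert sf["blue"] > sf["green"] and sf["red"] > sf["far_red"]
    # the diffuse twin reproduces DHR(40) per bin
    for b in (0, 10, 25):
        assert diffuse.rho[0, b] == pytest.approx(dhr(phong, b, 0, 40.0),
                                                  abs=1e-9)


def test_gonio_fixture_reference_albedos():
    phong, _, _ = fixture_optics()
    samples = synth_gonio_fixture(phong, theta_r=(0, 40, 80),
                                  phi_r=(0.0, 90.0))
    # green bins reflect more than blue bins (pigment absorption)
    green = samples.rho_ref[0, 7:16].mean()
    blue = samples.rho_ref[0, 0:6].mean()
    assert green > blue
    assert np.all(samples.samples["f"] >= 0)
    with pytest.raises(ValueError):
        synth_gonio_fixture(phong, noise_sd=-0.1)
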