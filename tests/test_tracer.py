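import numpy as np
import pytest

from canopylight.brdf import DiffuseLeafOptics, PhongLeafOptics
from canopylight.lighting import LightScenario
from canopylight.spectra import d65_photon_weights
from canopylight.tracer import (KernelOptics, build_index,
                                index_from_triangles, run_replicates, trace)
from canopylight.tracer.scene import SensorSet
from canopylight.tracer.kernel import _intersect_tri  # noqa: F401 (compile)


def _unit_leaf_index(z=0.5, ground_radius=5.0):
    """One horizontal unit-area square leaf (two triangles) at height z."""
    v = np.array([[0, 0, z], [1, 0, z], [1, 1, z], [0, 1, z]], dtype=float)
    return index_from_triangles(np.array([v[0], v[0]]),
                                np.array([v[1], v[2]]),
                                np.array([v[2], v[3]]),
                                [0, 0], [0, 0], n_groups=1, n_plants=1,
                                ground_radius=ground_radius)


def _gray_optics(kd=0.1, ks=0.0, n=1.0, tau=0.1):
    nb = 30
    opt = PhongLeafOptics(np.full(nb, kd), np.full(nb, ks), np.full(nb, n),
                          np.full(nb, tau))
    return KernelOptics.from_optics(opt, 0.15)


def _sensor(center, normal, radius=0.1):
    return SensorSet(np.atleast_2d(center).astype(float),
                     np.atleast_2d(normal).astype(float), radius,
                     np.array([0]), np.array([1]), np.array([0]),
                     np.array([0]))


# ---------------------------------------------------------------------------
# BVH


def _brute_force_hits(index, origins, dirs):
    """Vectorized Moller-Trumbore over all triangles (oracle)."""
    e1 = index.v1 - index.v0
    e2 = index.v2 - index.v0
    best_t = np.full(len(origins), np.inf)
    best_i = np.full(len(origins), -1)
    for i in range(index.n_triangles):
        p = np.cross(dirs, e2[i])
        det = p @ e1[i]
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = origins - index.v0[i]
        u = np.einsum("ij,ij->i", tvec, p) * inv
        q = np.cross(tvec, np.broadcast_to(e1[i], origins.shape))
        v = np.einsum("ij,ij->i", dirs, q) * inv
        t = (q @ e2[i]) * inv
        hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) \
            & (t > 1e-9)
        upd = hit & (t < best_t)
        best_t[upd] = t[upd]
        best_i[upd] = i
    return best_t, best_i


def test_bvh_matches_brute_force_on_random_rays(grid3x3_rig):
    from canopylight.tracer.kernel import _nearest_hit
    _, index, _ = grid3x3_rig
    rng = np.random.default_rng(17)
    n = 10_000
    origins = rng.uniform([-0.5, -0.5, 0.0], [0.5, 0.5, 0.4], size=(n, 3))
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bt, bi = _brute_force_hits(index, origins, dirs)
    stack = np.empty(256, dtype=np.int32)
    for k in range(n):
        t, tri = _nearest_hit(origins[k, 0], origins[k, 1], origins[k, 2],
                              dirs[k, 0], dirs[k, 1], dirs[k, 2],
                              index.v0, index.v1, index.v2,
                              index.node_min, index.node_max,
                              index.node_left, index.node_right,
                              index.node_start, index.node_count,
                              index.tri_order, stack)
        if bi[k] < 0:
            assert tri == -1
        else:
            assert tri == bi[k] or abs(t - bt[k]) < 1e-9


def test_empty_scene_rejected():
    from canopylight.synthetic import CanopyScene
    empty = CanopyScene([], np.zeros((0, 2)), "single", 0.2, ())
    with pytest.raises(ValueError):
        build_index(empty)


def test_triangle_count_matches_scene(grid3x3_rig):
    scene, index, _ = grid3x3_rig
    expected = sum(sum(len(l.faces) for l in p.leaves) + len(p.stem_faces)
                   for p in scene.plants)
    assert index.n_triangles == expected


# ---------------------------------------------------------------------------
# transport physics


def test_unit_leaf_interception_closed_form():
    """Horizontal unit leaf under a zenith sun absorbs E * w_b * a_b."""
    idx = _unit_leaf_index()
    ko = _gray_optics(kd=0.1, ks=0.05, n=8.0, tau=0.1)
    res = trace(idx, LightScenario(1.0, 0.0, 90.0), ko, 400_000, seed=1)
    w = d65_photon_weights()
    a = 1.0 - (0.1 + 0.05 + 0.1)    # full lobe at normal incidence
    assert res.absorbed.sum() == pytest.approx(1000.0 * a, rel=0.01)
    assert np.allclose(res.absorbed[0] / res.absorbed.sum(), w, atol=5e-3)


def test_fully_shaded_leaf_gets_nothing_without_reflections():
    v = np.array([[0, 0, 0.5], [1, 0, 0.5], [1, 1, 0.5], [0, 1, 0.5],
                  [0, 0, 0.2], [1, 0, 0.2], [1, 1, 0.2], [0, 1, 0.2]])
    idx = index_from_triangles(
        np.array([v[0], v[0], v[4], v[4]]),
        np.array([v[1], v[2], v[5], v[6]]),
        np.array([v[2], v[3], v[6], v[7]]),
        [0, 0, 1, 1], [0, 0, 0, 0], n_groups=2, n_plants=1, ground_radius=5.0)
    ko = _gray_optics()
    res = trace(idx, LightScenario(1.0, 0.0, 90.0), ko, 100_000, seed=2,
                reflections_enabled=False)
    assert res.absorbed[0].sum() > 0
    assert res.absorbed[1].sum() == 0.0
    res_on = trace(idx, LightScenario(1.0, 0.0, 90.0), ko, 100_000, seed=2)
    assert res_on.absorbed[1].sum() > 0      # scattered light reaches it


def test_empty_scene_sensor_reads_configured_irradiance():
    """A horizontal up-facing sensor under the discretized diffuse sky
    reads E_diffuse; a down-facing sensor under a zenith sun reads 0."""
    far = index_from_triangles([[0.6, 0.6, 0.0]], [[0.65, 0.6, 0]],
                               [[0.6, 0.65, 0]],
                               [0], [0], 1, 1, ground_radius=0.0,
                               extra_points=np.array(
                                   [[0, 0, 0.45], [0.45, 0, 0.0],
                                    [-0.45, 0, 0.0], [0, 0.45, 0],
                                    [0, -0.45, 0]]))
    up = _sensor([0, 0, 0.3], [0, 0, 1.0])
    res = trace(far, LightScenario(0.0, 0.0, 90.0), _gray_optics(),
                2_000_000, sensors=up, seed=3)
    assert res.sensor_ppfd.sum() == pytest.approx(1000.0, rel=0.05)
    down = _sensor([0, 0, 0.3], [0, 0, -1.0])
    res = trace(far, LightScenario(1.0, 0.0, 90.0), _gray_optics(),
                100_000, sensors=down, seed=4)
    assert res.sensor.sum() == 0.0


def test_energy_ledger_exact(grid3x3_rig, kernel_optics):
    _, index, sensors = grid3x3_rig
    ko_phong, ko_diff = kernel_optics
    for ko in (ko_phong, ko_diff):
        for refl in (True, False):
            res = trace(index, LightScenario(0.6, 0.0, 30.0), ko, 100_000,
                        sensors=sensors, seed=5, reflections_enabled=refl)
            assert res.ledger_residual() < 1e-9


def test_energy_ledger_exact_perbin_mode(grid3x3_rig, kernel_optics):
    _, index, _ = grid3x3_rig
    res = trace(index, LightScenario(0.6, 0.0, 30.0), kernel_optics[0],
                100_000, seed=6, spectral_mode="perbin")
    assert res.ledger_residual() < 1e-9


def test_spectral_modes_agree(single_plant_rig, kernel_optics):
    """Pilot-bin splitting and one-bin-per-ray tracing estimate the same
    per-leaf fluxes (checked at 3 sigma via replicate spread)."""
    _, index, _ = single_plant_rig
    sc = LightScenario(0.8, 0.0, 50.0)
    ko = kernel_optics[0]
    split = run_replicates(index, sc, ko, 200_000, seeds=[1, 2, 3])
    perbin = run_replicates(index, sc, ko, 200_000, seeds=[4, 5, 6],
                            spectral_mode="perbin")
    a, b = split.absorbed.sum(axis=1), perbin.absorbed.sum(axis=1)
    se = np.sqrt(split.absorbed_se.sum(axis=1) ** 2
                 + perbin.absorbed_se.sum(axis=1) ** 2)
    assert np.all(np.abs(a - b) <= 4 * se + 1e-4 * a.max())


def test_null_phong_equals_diffuse_bitwise(single_plant_rig):
    """With ks = 0 the Phong tracer and the diffuse tracer follow identical
    paths under a shared seed, so the comparison's MAPE collapses to 0."""
    _, index, _ = single_plant_rig
    kd = np.full(30, 0.12)
    tau = np.full(30, 0.08)
    phong = KernelOptics.from_optics(
        PhongLeafOptics(kd, np.zeros(30), np.ones(30), tau), 0.15)
    diff = KernelOptics.from_optics(DiffuseLeafOptics(kd, tau), 0.15)
    sc = LightScenario(0.5, 0.0, 50.0)
    ra = trace(index, sc, phong, 200_000, seed=11)
    rb = trace(index, sc, diff, 200_000, seed=11)
    assert np.array_equal(ra.absorbed, rb.absorbed)


def test_reflections_only_add_light(grid3x3_rig, kernel_optics):
    _, index, _ = grid3x3_rig
    sc = LightScenario(0.7, 0.0, 50.0)
    on = run_replicates(index, sc, kernel_optics[0], 200_000, seeds=[1, 2, 3])
    off = run_replicates(index, sc, kernel_optics[0], 200_000, seeds=[1, 2, 3],
                         reflections_enabled=False)
    tot_on = on.absorbed.sum(axis=1)
    tot_off = off.absorbed.sum(axis=1)
    se = np.sqrt(on.absorbed_se.sum(axis=1) ** 2
                 + off.absorbed_se.sum(axis=1) ** 2)
    assert np.all(tot_off <= tot_on + 3 * se + 1e-9)


def test_replicate_averaging():
    idx = _unit_leaf_index()
    ko = _gray_optics()
    sc = LightScenario(1.0, 0.0, 90.0)
    single = run_replicates(idx, sc, ko, 50_000, seeds=[7])
    alone = trace(idx, sc, ko, 50_000, seed=7)
    assert np.array_equal(single.absorbed, alone.absorbed)
    reps = [trace(idx, sc, ko, 50_000, seed=s) for s in (1, 2, 3)]
    mean = run_replicates(idx, sc, ko, 50_000, seeds=[1, 2, 3])
    assert np.allclose(mean.absorbed,
                       np.mean([r.absorbed for r in reps], axis=0))


def test_monte_carlo_error_scaling(grid3x3_rig, kernel_optics):
    """Replicate SE shrinks roughly as 1/sqrt(n_rays)."""
    _, index, _ = grid3x3_rig
    sc = LightScenario(1.0, 0.0, 50.0)
    ko = kernel_optics[0]
    small = run_replicates(index, sc, ko, 100_000, seeds=[1, 2, 3, 4, 5, 6])
    big = run_replicates(index, sc, ko, 400_000, seeds=[11, 12, 13, 14, 15, 16])
    ratio = (small.absorbed_se.sum() / big.absorbed_se.sum())
    assert 1.3 < ratio < 3.1          # 2 +- tolerance at 6 replicates


def test_trace_input_validation(single_plant_rig, kernel_optics):
    _, index, _ = single_plant_rig
    sc = LightScenario(0.5, 0.0, 50.0)
    with pytest.raises(ValueError):
        trace(index, sc, kernel_optics[0], 100, seed=1)
    with pytest.raises(ValueError):
        trace(index, sc, kernel_optics[0], 100_000, seed=None)
    with pytest.raises(ValueError):
        trace(index, sc, kernel_optics[0], 100_000, seed=1, max_depth=0)
    with pytest.raises(ValueError):
        trace(index, sc, kernel_optics[0], 100_000, seed=1,
              spectral_mode="wavelet")
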