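import numpy as np
import pytest

from canopylight.brdf import (BrdfSampleSet, DiffuseLeafOptics,
                              PhongLeafOptics, angles_to_directions,
                              diffuse_equivalent, dhr, fit_phong,
                              interaction_probabilities, phong_eval,
                              radiant_intensity_profile, sample_interaction,
                              specular_albedo_factor)
from canopylight.spectra import SpectralGrid
from canopylight.synthetic import synth_gonio_fixture

# coarse 3-band grid keeps the fitting tests fast
GRID3 = SpectralGrid(np.array([440.0, 540.0, 640.0, 740.0]))


def _optics(kd, ks, n, tau=0.0, grid=None):
    grid = grid or SpectralGrid()
    nb = grid.n_bins
    return PhongLeafOptics(np.full(nb, kd), np.full(nb, ks), np.full(nb, n),
                           np.full(nb, tau), grid)


# ---------------------------------------------------------------------------
# evaluation


def test_phong_eval_lambertian_limit():
    opt = _optics(0.3, 0.0, 1.0)
    wi, wo = angles_to_directions(35.0, 50.0, 120.0)
    assert phong_eval(opt, 0, 0, wi, wo) == pytest.approx(0.3 / np.pi)


def test_phong_eval_mirror_peak():
    opt = _optics(0.0, 0.2, 10.0)
    wi, wo = angles_to_directions(30.0, 30.0, 0.0)
    assert phong_eval(opt, 0, 0, wi, wo) == pytest.approx(0.2 * 12 / (2 * np.pi))


def test_phong_eval_matches_scalar_formula():
    """Independent scalar re-implementation at theta_i=40, theta_r=20."""
    kd, ks, n = 0.1, 0.1, 4.0
    opt = _optics(kd, ks, n)
    wi, wo = angles_to_directions(40.0, 20.0, 0.0)
    # in-plane: angle between mirror direction (at 40 on the specular side)
    # and wo (at 20) is 20 degrees
    cos_a = np.cos(np.deg2rad(40.0 - 20.0))
    expected = kd / np.pi + ks * (n + 2) / (2 * np.pi) * cos_a ** n
    assert phong_eval(opt, 0, 0, wi, wo) == pytest.approx(expected, rel=1e-12)


def test_phong_eval_rejects_below_horizon():
    opt = _optics(0.3, 0.0, 1.0)
    with pytest.raises(ValueError):
        phong_eval(opt, 0, 0, [0, 0, 1.0], [0, 0, -1.0])


def test_reciprocity_random_pairs():
    rng = np.random.default_rng(3)
    opt = _optics(0.08, 0.07, 17.0)
    v = rng.normal(size=(1000, 2, 3))
    v[..., 2] = np.abs(v[..., 2])
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    f_ab = phong_eval(opt, 0, 0, v[:, 0], v[:, 1])
    f_ba = phong_eval(opt, 0, 0, v[:, 1], v[:, 0])
    assert np.allclose(f_ab, f_ba, rtol=1e-12, atol=1e-15)


def test_radiant_intensity_profiles():
    # pure Lambertian: cosine profile peaks at the normal
    theta, prof = radiant_intensity_profile(_optics(0.3, 0.0, 1.0), 0, 0, 40.0)
    assert theta[np.argmax(prof)] == pytest.approx(0.0, abs=1.0)
    # strong narrow lobe: peak approaches the mirror angle
    theta, prof = radiant_intensity_profile(_optics(0.001, 0.5, 5000.0),
                                            0, 0, 40.0)
    assert abs(theta[np.argmax(prof)] - 40.0) < 2.0
    # mixed: cosine weighting pulls the peak strictly inside (0, 40)
    theta, prof = radiant_intensity_profile(_optics(0.1, 0.1, 10.0), 0, 0, 40.0)
    peak = theta[np.argmax(prof)]
    assert 0.0 < peak < 40.0


# ---------------------------------------------------------------------------
# hemispherical integrals


def test_dhr_lambertian_closure():
    opt = _optics(0.3, 0.0, 1.0)
    for theta in (0.0, 25.0, 60.0, 85.0):
        assert dhr(opt, 0, 0, theta) == pytest.approx(0.3, abs=1e-9)


def test_dhr_normal_incidence_full_lobe():
    opt = _optics(0.2, 0.1, 50.0)
    assert dhr(opt, 0, 0, 0.0) == pytest.approx(0.3, abs=1e-3)


def test_dhr_grazing_matches_monte_carlo():
    """Clipped-lobe quadrature vs. a 1e6-sample MC integration oracle."""
    n, theta = 5.0, 70.0
    opt = _optics(0.0, 0.3, n)
    rng = np.random.default_rng(11)
    N = 1_000_000
    u = rng.random(N) ** (1.0 / (n + 1.0))
    phi = 2 * np.pi * rng.random(N)
    sin_a = np.sqrt(1 - u ** 2)
    th = np.deg2rad(theta)
    cos_o = u * np.cos(th) + sin_a * np.sin(th) * np.cos(phi)
    vals = (n + 2.0) / (n + 1.0) * np.maximum(0.0, cos_o)
    mc = 0.3 * vals.mean()
    sigma = 0.3 * vals.std() / np.sqrt(N)
    val = dhr(opt, 0, 0, theta)
    assert val < 0.3
    assert abs(val - mc) < 3 * sigma + 1e-6


def test_energy_validation_rejects_hot_optics():
    opt = _optics(0.7, 0.0, 1.0, tau=0.4)
    with pytest.raises(ValueError):
        opt.validate_energy()


# ---------------------------------------------------------------------------
# diffuse equivalence


def test_diffuse_equivalent_identity_for_lambertian():
    opt = _optics(0.21, 0.0, 1.0, tau=0.1)
    diff = diffuse_equivalent(opt)
    assert np.allclose(diff.rho, 0.21, atol=1e-9)
    assert np.allclose(diff.tau, 0.1)
    # round trip through the Phong promotion
    again = diffuse_equivalent(diff.to_phong())
    assert np.allclose(again.rho, diff.rho, atol=1e-9)


def test_diffuse_equivalent_matches_dhr40():
    opt = _optics(0.05, 0.04, 8.0, tau=0.02)
    diff = diffuse_equivalent(opt)
    assert diff.rho[0, 0] == pytest.approx(dhr(opt, 0, 0, 40.0), rel=1e-9)


# ---------------------------------------------------------------------------
# fitting


def test_fit_recovers_noise_free_truth():
    truth = _optics(0.05, 0.04, 8.0, tau=0.02, grid=GRID3)
    samples = synth_gonio_fixture(truth, sides=("adaxial",))
    res = fit_phong(samples)
    assert np.allclose(res.optics.kd, truth.kd, rtol=0.01)
    assert np.allclose(res.optics.ks, truth.ks, rtol=0.01)
    assert np.allclose(res.optics.n_exp, truth.n_exp, rtol=0.01)
    assert np.all(res.converged)


def test_fit_lambertian_surface_yields_no_lobe():
    truth = _optics(0.2, 0.0, 1.0, grid=GRID3)
    samples = synth_gonio_fixture(truth, sides=("adaxial",))
    res = fit_phong(samples)
    assert np.all(res.optics.ks <= 1e-3)
    assert np.allclose(res.nrmse_phong, res.nrmse_diffuse, atol=1e-6)


def test_fit_identifiability_under_noise():
    """Parameter recovery within 5 percent under 2 percent noise."""
    truth = _optics(0.08, 0.05, 12.0, grid=GRID3)
    samples = synth_gonio_fixture(truth, noise_sd=0.02,
                                  rng=np.random.default_rng(5),
                                  sides=("adaxial",))
    res = fit_phong(samples)
    assert np.allclose(res.optics.kd, truth.kd, rtol=0.05)
    assert np.allclose(res.optics.ks, truth.ks, rtol=0.05)
    assert np.allclose(res.optics.n_exp, truth.n_exp, rtol=0.05)


def test_fit_dominance_over_diffuse_model():
    """Phong NRMSE never exceeds the equivalent-diffuse NRMSE per bin."""
    truth = PhongLeafOptics(np.array([0.05, 0.2, 0.4]),
                            np.array([0.06, 0.04, 0.03]),
                            np.array([14.0, 6.0, 2.0]),
                            np.zeros(3), GRID3)
    samples = synth_gonio_fixture(truth, noise_sd=0.1,
                                  rng=np.random.default_rng(9))
    res = fit_phong(samples)
    assert np.all(res.nrmse_phong <= res.nrmse_diffuse + 1e-9)


def test_fit_rejects_sparse_sample_sets():
    truth = _optics(0.1, 0.05, 8.0, grid=GRID3)
    samples = synth_gonio_fixture(truth, theta_i=(40.0,), theta_r=(0, 30, 60),
                                  phi_r=(0.0,), sides=("adaxial",))
    with pytest.raises(ValueError):
        fit_phong(samples)


def test_fit_rejects_infeasible_energy():
    truth = _optics(0.1, 0.05, 8.0, grid=GRID3)
    samples = synth_gonio_fixture(truth, sides=("adaxial",))
    samples.tau_ref = np.full((2, 3), 0.95)
    with pytest.raises(ValueError):
        fit_phong(samples)


# ---------------------------------------------------------------------------
# sampling


def test_black_surface_always_absorbs():
    opt = _optics(0.0, 0.0, 1.0)
    rng = np.random.default_rng(0)
    wi = np.array([0.3, 0.0, np.sqrt(1 - 0.09)])
    for _ in range(50):
        event, wo = sample_interaction(opt, 0, 0, wi, rng)
        assert event == "absorbed" and wo is None


def test_cosine_reflection_mean_cosine():
    """White diffuse surface: cosine-weighted wo has mean z of 2/3."""
    opt = DiffuseLeafOptics(np.ones(30), np.zeros(30))
    rng = np.random.default_rng(1)
    wi = np.array([0.0, 0.0, 1.0])
    zs = []
    for _ in range(100_000):
        event, wo = sample_interaction(opt, 0, 0, wi, rng)
        assert event == "reflected"
        zs.append(wo[2])
    # var of cos under cosine sampling is 1/18
    se = np.sqrt(1.0 / 18.0 / len(zs))
    assert abs(np.mean(zs) - 2.0 / 3.0) < 4 * se


def test_event_frequencies_match_probabilities():
    opt = _optics(0.05, 0.04, 8.0, tau=0.02)
    rng = np.random.default_rng(2)
    theta = 40.0
    wi = np.array([np.sin(np.deg2rad(theta)), 0.0, np.cos(np.deg2rad(theta))])
    p_d, p_s, p_t = interaction_probabilities(opt, 0, 0, theta)
    counts = {"reflected": 0, "transmitted": 0, "absorbed": 0}
    n = 200_000
    for _ in range(n):
        event, _ = sample_interaction(opt, 0, 0, wi, rng)
        counts[event] += 1
    for label, p in (("transmitted", p_t), ("absorbed", 1 - p_d - p_s - p_t),
                     ("reflected", p_d + p_s)):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(counts[label] / n - p) < 3.5 * se + 1e-9


def test_sampled_reflectance_matches_dhr():
    """MC event frequencies reproduce the analytic DHR within 3 sigma."""
    opt = _optics(0.1, 0.2, 6.0)
    rng = np.random.default_rng(4)
    theta = 55.0
    wi = np.array([np.sin(np.deg2rad(theta)), 0.0, np.cos(np.deg2rad(theta))])
    n = 100_000
    refl = sum(sample_interaction(opt, 0, 0, wi, rng)[0] == "reflected"
               for _ in range(n))
    p = dhr(opt, 0, 0, theta)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(refl / n - p) < 3 * se


def test_specular_factor_bounds():
    thetas = np.arange(0.0, 86.0, 5.0)
    for n in (0.5, 3.0, 20.0, 200.0):
        S = specular_albedo_factor(np.full_like(thetas, n), thetas)
        assert np.all(S <= 1.0 + 1e-12) and np.all(S > 0.0)
        assert S[0] == pytest.approx(1.0, abs=1e-6)
        # grazing incidence loses lobe mass below the horizon
        assert S[-1] < S[0]
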