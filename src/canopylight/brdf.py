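"""Modified-Phong leaf BRDF: evaluation, hemispherical integrals, sampling,
per-wavelength fitting, and the spectrally equivalent diffuse model.

Model
-----
The leaf surface reflectance is an energy-normalized modified Phong BRDF,

    f(wi, wo) = kd/pi + ks * (n+2)/(2*pi) * max(0, cos(alpha))**n      [1/sr]

where ``alpha`` is the angle between ``wo`` and the mirror direction of
``wi`` about the surface normal, ``kd`` is the hemispherical albedo of the
Lambertian term, ``ks`` the weight of the specular lobe and ``n`` its
shininess.  The lobe normalization makes the directional-hemispherical
reflectance (DHR) at normal incidence equal ``kd + ks``; at oblique
incidence part of the lobe dips below the horizon and the DHR is

    DHR(theta_i) = kd + ks * S(theta_i, n)

with ``S`` the cosine-weighted above-horizon lobe fraction (``S <= 1``,
``S(0, n) = 1``).  Transmission is Lambertian on the exit side with
per-bin transmittance ``tau``.

Conventions: directions are unit vectors in the local frame of the struck
side with the outward normal along +z; ``wi`` and ``wo`` both point away
from the surface.  In gonioreflectometer coordinates the incident beam
arrives from azimuth 180 deg, so the specular (forward-scattering) half
plane is at relative azimuth ``phi_r = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.optimize import least_squares

from .spectra import SpectralGrid, default_grid

__all__ = [
    "PhongLeafOptics",
    "DiffuseLeafOptics",
    "BrdfSampleSet",
    "PhongFitResult",
    "phong_eval",
    "specular_albedo_factor",
    "dhr",
    "radiant_intensity_profile",
    "fit_phong",
    "diffuse_equivalent",
    "sample_interaction",
    "angles_to_directions",
]

SIDES = ("adaxial", "abaxial")


# ---------------------------------------------------------------------------
# containers


def _as_side_bins(x, n_bins: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = np.stack([arr, arr])
    if arr.shape != (2, n_bins):
        raise ValueError(f"expected shape (2, {n_bins}), got {arr.shape}")
    return arr


@dataclass
class PhongLeafOptics:
    """Per-bin, per-side Phong parameters (side axis: adaxial, abaxial)."""

    kd: np.ndarray
    ks: np.ndarray
    n_exp: np.ndarray
    tau: np.ndarray
    grid: SpectralGrid = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        nb = self.grid.n_bins
        self.kd = _as_side_bins(self.kd, nb)
        self.ks = _as_side_bins(self.ks, nb)
        self.n_exp = _as_side_bins(self.n_exp, nb)
        self.tau = _as_side_bins(self.tau, nb)
        for name in ("kd", "ks", "tau"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be >= 0")
        if np.any(self.n_exp < 0):
            raise ValueError("n_exp must be >= 0")

    def validate_energy(self, eps_tol: float = 0.06, eps_near: float = 0.01,
                        theta_near: float = 40.0) -> None:
        """Energy closure DHR(theta_i) + tau <= 1 (+ tolerance).

        The grazing-angle tolerance ``eps_tol`` mirrors the few-percent
        closure error a fitted empirical shader is allowed at steep
        incidence; near-normal incidence (<= ``theta_near``) the budget is
        ``eps_near``.
        """
        thetas = np.arange(0.0, 86.0, 5.0)
        for side in range(2):
            for b in range(self.grid.n_bins):
                vals = dhr(self, b, side, thetas) + self.tau[side, b]
                if np.any(vals[thetas <= theta_near] > 1 + eps_near):
                    raise ValueError(
                        f"energy closure violated near normal incidence "
                        f"(side {SIDES[side]}, bin {b})"
                    )
                if np.any(vals > 1 + eps_tol):
                    raise ValueError(
                        f"energy closure violated (side {SIDES[side]}, bin {b})"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, side in enumerate(SIDES):
            for b, wl in enumerate(self.grid.bin_centers):
                rows.append(dict(bin_center_nm=wl, side=side,
                                 kd=self.kd[s, b], ks=self.ks[s, b],
                                 n_exp=self.n_exp[s, b], tau=self.tau[s, b]))
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   grid: SpectralGrid | None = None) -> "PhongLeafOptics":
        grid = grid or default_grid()
        nb = grid.n_bins
        kd, ks, n_exp, tau = (np.zeros((2, nb)) for _ in range(4))
        for s, side in enumerate(SIDES):
            sub = df[df["side"] == side].sort_values("bin_center_nm")
            if len(sub) != nb:
                raise ValueError(f"need {nb} rows for side {side}")
            kd[s] = sub["kd"].to_numpy()
            ks[s] = sub["ks"].to_numpy()
            n_exp[s] = sub["n_exp"].to_numpy()
            tau[s] = sub["tau"].to_numpy()
        return cls(kd, ks, n_exp, tau, grid)


@dataclass
class DiffuseLeafOptics:
    """Per-bin, per-side Lambertian reflectance and transmittance."""

    rho: np.ndarray
    tau: np.ndarray
    grid: SpectralGrid = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        nb = self.grid.n_bins
        self.rho = _as_side_bins(self.rho, nb)
        self.tau = _as_side_bins(self.tau, nb)
        if np.any(self.rho < 0) or np.any(self.tau < 0):
            raise ValueError("rho and tau must be >= 0")
        if np.any(self.rho + self.tau > 1 + 1e-9):
            raise ValueError("rho + tau must be <= 1 per bin")

    def to_phong(self) -> PhongLeafOptics:
        """Promote to a Phong model with no specular lobe (ks = 0)."""
        z = np.zeros_like(self.rho)
        return PhongLeafOptics(self.rho.copy(), z, z + 1.0, self.tau.copy(),
                               self.grid)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, side in enumerate(SIDES):
            for b, wl in enumerate(self.grid.bin_centers):
                rows.append(dict(bin_center_nm=wl, side=side,
                                 rho=self.rho[s, b], tau=self.tau[s, b]))
        return pd.DataFrame(rows)


@dataclass
class BrdfSampleSet:
    """Gonioreflectometer-style BRDF samples plus per-bin reference albedo.

    ``samples`` columns: bin (int), theta_i_deg, theta_r_deg, phi_r_deg,
    f (1/sr) and optionally side.  ``rho_ref`` (and optional ``tau_ref``)
    have shape (n_bins,) or (2, n_bins).
    """

    samples: pd.DataFrame
    rho_ref: np.ndarray
    tau_ref: np.ndarray | None = None
    grid: SpectralGrid = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        need = {"bin", "theta_i_deg", "theta_r_deg", "phi_r_deg", "f"}
        if not need.issubset(self.samples.columns):
            raise ValueError(f"sample table needs columns {sorted(need)}")
        if "side" not in self.samples.columns:
            self.samples = self.samples.assign(side="adaxial")
        if np.any(self.samples["f"] < 0):
            raise ValueError("BRDF values must be >= 0")
        th = self.samples[["theta_i_deg", "theta_r_deg"]].to_numpy()
        if np.any(th < 0) or np.any(th > 90):
            raise ValueError("zenith angles must lie in [0, 90] deg")
        self.rho_ref = _as_side_bins(self.rho_ref, self.grid.n_bins)
        if np.any(self.rho_ref < 0) or np.any(self.rho_ref > 1):
            raise ValueError("rho_ref must lie in [0, 1]")
        if self.tau_ref is not None:
            self.tau_ref = _as_side_bins(self.tau_ref, self.grid.n_bins)


# ---------------------------------------------------------------------------
# evaluation


def mirror(wi: np.ndarray) -> np.ndarray:
    """Mirror direction of ``wi`` about the +z normal."""
    out = np.asarray(wi, dtype=float).copy()
    out[..., 0] *= -1.0
    out[..., 1] *= -1.0
    return out


def angles_to_directions(theta_i_deg, theta_r_deg, phi_r_deg):
    """Goniometer angles -> (wi, wo) unit vectors in the local frame.

    The incident beam arrives from azimuth 180 deg so that the specular
    direction has relative azimuth ``phi_r = 0``.
    """
    ti = np.deg2rad(np.asarray(theta_i_deg, dtype=float))
    tr = np.deg2rad(np.asarray(theta_r_deg, dtype=float))
    pr = np.deg2rad(np.asarray(phi_r_deg, dtype=float))
    wi = np.stack([-np.sin(ti), np.zeros_like(ti), np.cos(ti)], axis=-1)
    wo = np.stack([np.sin(tr) * np.cos(pr), np.sin(tr) * np.sin(pr),
                   np.cos(tr)], axis=-1)
    return wi, wo


def _phong_f(kd, ks, n_exp, wi, wo):
    cos_a = np.clip(np.sum(mirror(wi) * np.asarray(wo), axis=-1), 0.0, 1.0)
    return kd / np.pi + ks * (n_exp + 2.0) / (2.0 * np.pi) * cos_a ** n_exp


def phong_eval(optics: PhongLeafOptics, bin: int, side: int,
               wi: np.ndarray, wo: np.ndarray) -> np.ndarray | float:
    """Evaluate the BRDF (1/sr) for directions in the struck side's frame."""
    wi = np.asarray(wi, dtype=float)
    wo = np.asarray(wo, dtype=float)
    if np.any(wi[..., 2] < 0) or np.any(wo[..., 2] < 0):
        raise ValueError("wi and wo must lie in the upper hemisphere")
    out = _phong_f(optics.kd[side, bin], optics.ks[side, bin],
                   optics.n_exp[side, bin], wi, wo)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# hemispherical integrals

_N_S, _N_PHI = 64, 128
_GL_X, _GL_W = leggauss(_N_S)
_S_NODES = 0.5 * (_GL_X + 1.0)          # s in (0, 1)
_S_WEIGHTS = 0.5 * _GL_W
_PHI = (np.arange(_N_PHI) + 0.5) * (2.0 * np.pi / _N_PHI)


def specular_albedo_factor(n_exp, theta_i_deg):
    """Cosine-weighted above-horizon fraction S(theta_i, n) of the lobe.

    S = (n+2)/(2 pi) * Int cos^n(alpha) * max(0, cos(theta_o)) d_omega over
    the alpha < 90 deg lobe around the mirror direction.  Computed with a
    Gauss-Legendre rule in s = cos(alpha)^(n+1) (which spreads nodes evenly
    over the lobe's energy for any shininess) times a uniform azimuth rule.
    Satisfies S(0, n) = 1 and S <= 1.
    """
    n_exp = np.asarray(n_exp, dtype=float)
    theta = np.deg2rad(np.asarray(theta_i_deg, dtype=float))
    scalar = n_exp.ndim == 0 and theta.ndim == 0
    n_exp, theta = np.atleast_1d(n_exp), np.atleast_1d(theta)
    n_exp, theta = np.broadcast_arrays(n_exp, theta)
    out = np.empty(n_exp.shape)
    for i in np.ndindex(n_exp.shape):
        n, th = n_exp[i], theta[i]
        u = _S_NODES ** (1.0 / (n + 1.0))          # cos(alpha)
        sin_a = np.sqrt(np.maximum(0.0, 1.0 - u * u))
        # cos(theta_o) for lobe axis at zenith angle th
        cos_to = (u[:, None] * np.cos(th)
                  + sin_a[:, None] * np.sin(th) * np.cos(_PHI)[None, :])
        integ = np.maximum(0.0, cos_to).mean(axis=1)  # azimuth average
        out[i] = ((n + 2.0) / (n + 1.0)) * np.sum(_S_WEIGHTS * integ)
    out = np.minimum(out, 1.0)
    return float(out.reshape(())) if scalar else out


def dhr(optics: PhongLeafOptics, bin: int, side: int, theta_i_deg):
    """Directional-hemispherical reflectance at incidence theta_i (deg)."""
    theta = np.asarray(theta_i_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta >= 90):
        raise ValueError("theta_i must lie in [0, 90) deg")
    S = specular_albedo_factor(optics.n_exp[side, bin], theta)
    return optics.kd[side, bin] + optics.ks[side, bin] * S


def radiant_intensity_profile(optics: PhongLeafOptics, bin: int, side: int,
                              theta_i_deg: float, n_points: int = 361):
    """In-plane radiant intensity I(theta_r) = cos(theta_r) * f.

    ``theta_r`` runs over [-90, 90] deg in the incidence plane; positive
    angles are on the specular (forward-scattering) side.  The cosine
    projection shifts the specular peak from the mirror angle towards the
    surface normal for any finite shininess.
    """
    if not 0.0 <= theta_i_deg < 90.0:
        raise ValueError("theta_i must lie in [0, 90) deg")
    theta_r = np.linspace(-90.0, 90.0, n_points)
    phi_r = np.where(theta_r >= 0, 0.0, 180.0)
    wi, wo = angles_to_directions(theta_i_deg, np.abs(theta_r), phi_r)
    f = _phong_f(optics.kd[side, bin], optics.ks[side, bin],
                 optics.n_exp[side, bin], wi, wo)
    return theta_r, np.cos(np.deg2rad(theta_r)) * f


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PhongFitResult:
    optics: PhongLeafOptics
    nrmse_phong: np.ndarray      # (2, n_bins)
    nrmse_diffuse: np.ndarray    # (2, n_bins)
    converged: np.ndarray        # (2, n_bins) bool

    def nrmse_frame(self) -> pd.DataFrame:
        rows = []
        for s, side in enumerate(SIDES):
            for b, wl in enumerate(self.optics.grid.bin_centers):
                rows.append(dict(bin_center_nm=wl, side=side,
                                 nrmse_phong=self.nrmse_phong[s, b],
                                 nrmse_diffuse=self.nrmse_diffuse[s, b],
                                 converged=bool(self.converged[s, b])))
        return pd.DataFrame(rows)


_FIT_N_STARTS = np.geomspace(0.5, 500.0, 6)


def fit_phong(samples: BrdfSampleSet, seed: int = 0,
              anchor_theta: float = 40.0) -> PhongFitResult:
    """Fit (kd, ks, n) per bin and side by constrained least squares.

    The fit minimizes the sum of squared BRDF residuals subject to the
    hemispherical-albedo anchor DHR(anchor_theta) = rho_ref, imposed by
    eliminating kd = rho_ref - ks * S(anchor_theta, n).  The search runs
    bounded multi-start least squares over (ks, log n) with shininess
    starts log-spaced in [0.5, 500].

    NRMSE (RMSE / mean measured BRDF) is reported both for the fitted Phong
    model and for the spectrally equivalent diffuse model f = rho_ref / pi
    (the ks = 0 member of the constrained family), so the Phong NRMSE can
    never exceed the diffuse NRMSE.
    """
    grid = samples.grid
    nb = grid.n_bins
    kd = np.zeros((2, nb))
    ks = np.zeros((2, nb))
    n_exp = np.ones((2, nb))
    tau = (samples.tau_ref.copy() if samples.tau_ref is not None
           else np.zeros((2, nb)))
    if np.any(samples.rho_ref + tau > 1 + 1e-9):
        raise ValueError("infeasible constraint: rho_ref + tau > 1")
    nrmse_p = np.full((2, nb), np.nan)
    nrmse_d = np.full((2, nb), np.nan)
    converged = np.zeros((2, nb), dtype=bool)

    sides_present = set(samples.samples["side"].unique())
    for s, side in enumerate(SIDES):
        src = side if side in sides_present else next(iter(sides_present))
        sub_all = samples.samples[samples.samples["side"] == src]
        for b in range(nb):
            sub = sub_all[sub_all["bin"] == b]
            if len(sub) < 8 or sub["theta_i_deg"].nunique() < 2:
                raise ValueError(
                    f"bin {b}: need >= 8 samples spanning >= 2 incidence angles"
                )
            wi, wo = angles_to_directions(sub["theta_i_deg"].to_numpy(),
                                          sub["theta_r_deg"].to_numpy(),
                                          sub["phi_r_deg"].to_numpy())
            f_meas = sub["f"].to_numpy()
            rho = samples.rho_ref[s, b]
            f_mean = f_meas.mean()
            scale = f_mean if f_mean > 0 else 1.0

            def resid(x):
                ks_, n_ = x[0], np.exp(x[1])
                kd_ = rho - ks_ * specular_albedo_factor(n_, anchor_theta)
                pen = min(0.0, kd_) * 1e3          # soft kd >= 0 barrier
                return np.append(
                    _phong_f(max(kd_, 0.0), ks_, n_, wi, wo) - f_meas, pen)

            best = None
            for n0 in _FIT_N_STARTS:
                res = least_squares(
                    resid, x0=[min(0.05, rho), np.log(n0)],
                    bounds=([0.0, np.log(0.5)], [1.0, np.log(500.0)]),
                    xtol=1e-12, ftol=1e-12)
                if best is None or res.cost < best.cost:
                    best = res
            sse_d = np.sum((rho / np.pi - f_meas) ** 2)
            sse_p = np.sum(resid(best.x)[:-1] ** 2)
            if sse_p <= sse_d:
                ks_, n_ = best.x[0], np.exp(best.x[1])
                kd_ = max(0.0, rho - ks_ * specular_albedo_factor(n_, anchor_theta))
                converged[s, b] = best.status > 0
            else:  # fall back to the nested diffuse member
                ks_, n_, kd_, sse_p = 0.0, 1.0, rho, sse_d
                converged[s, b] = True
            kd[s, b], ks[s, b], n_exp[s, b] = kd_, ks_, n_
            nrmse_p[s, b] = np.sqrt(sse_p / len(f_meas)) / scale
            nrmse_d[s, b] = np.sqrt(sse_d / len(f_meas)) / scale

    optics = PhongLeafOptics(kd, ks, n_exp, tau, grid)
    return PhongFitResult(optics, nrmse_p, nrmse_d, converged)


def diffuse_equivalent(optics: PhongLeafOptics,
                       anchor_theta: float = 40.0) -> DiffuseLeafOptics:
    """Diffuse model with the same DHR at the anchor incidence angle.

    rho(bin) = DHR(optics, bin, anchor_theta); tau is copied unchanged.
    """
    nb = optics.grid.n_bins
    rho = np.empty((2, nb))
    for s in range(2):
        for b in range(nb):
            rho[s, b] = dhr(optics, b, s, anchor_theta)
    return DiffuseLeafOptics(rho, optics.tau.copy(), optics.grid)


# ---------------------------------------------------------------------------
# sampling (reference implementation; the tracer kernel mirrors this logic)


def _cosine_sample(rng: np.random.Generator) -> np.ndarray:
    u1, u2 = rng.random(), rng.random()
    r = np.sqrt(u1)
    phi = 2.0 * np.pi * u2
    return np.array([r * np.cos(phi), r * np.sin(phi),
                     np.sqrt(max(0.0, 1.0 - u1))])


def _sample_phong_lobe(axis: np.ndarray, n: float,
                       rng: np.random.Generator,
                       max_tries: int = 256) -> np.ndarray | None:
    """Draw wo ~ cos^n(alpha) * cos(theta_o)+ around ``axis`` by rejection."""
    # orthonormal frame around the lobe axis
    a = np.array([1.0, 0.0, 0.0]) if abs(axis[2]) > 0.9 else np.array([0.0, 0.0, 1.0])
    t = np.cross(a, axis)
    t /= np.linalg.norm(t)
    bvec = np.cross(axis, t)
    for _ in range(max_tries):
        u1, u2 = rng.random(), rng.random()
        cos_a = u1 ** (1.0 / (n + 1.0))
        sin_a = np.sqrt(max(0.0, 1.0 - cos_a * cos_a))
        phi = 2.0 * np.pi * u2
        wo = (cos_a * axis + sin_a * (np.cos(phi) * t + np.sin(phi) * bvec))
        if wo[2] <= 0.0:       # below the horizon: clipped lobe
            continue
        if rng.random() < wo[2]:   # cos(theta_o) thinning
            return wo
    return None


def interaction_probabilities(optics, bin: int, side: int, theta_i_deg: float):
    """(p_diffuse_reflect, p_specular_reflect, p_transmit) for one incidence."""
    if isinstance(optics, DiffuseLeafOptics):
        return optics.rho[side, bin], 0.0, optics.tau[side, bin]
    p_spec = optics.ks[side, bin] * specular_albedo_factor(
        optics.n_exp[side, bin], theta_i_deg)
    return optics.kd[side, bin], p_spec, optics.tau[side, bin]


def sample_interaction(optics, bin: int, side: int, wi: np.ndarray,
                       rng: np.random.Generator):
    """Sample one surface event: ('absorbed'|'reflected'|'transmitted', wo).

    Event probabilities are (kd, ks*S(theta_i), tau, remainder); specular
    draws below the horizon are folded into the clipped lobe weight S, so
    event frequencies reproduce the analytic DHR.  ``wo`` is in the frame
    of the struck side (+z outward); a transmitted direction has wo_z < 0.
    """
    wi = np.asarray(wi, dtype=float)
    if wi[2] < 0:
        raise ValueError("wi must be in the upper hemisphere of the struck side")
    theta_i = np.rad2deg(np.arccos(np.clip(wi[2], -1.0, 1.0)))
    p_d, p_s, p_t = interaction_probabilities(optics, bin, side, theta_i)
    if p_d + p_s + p_t > 1.0 + 1e-9:
        raise ValueError("event probabilities sum to more than 1")
    u = rng.random()
    if u < p_d:
        return "reflected", _cosine_sample(rng)
    if u < p_d + p_s:
        wo = _sample_phong_lobe(mirror(wi), float(
            optics.n_exp[side, bin]), rng)
        if wo is None:      # vanishing acceptance: treat as absorbed
            return "absorbed", None
        return "reflected", wo
    if u < p_d + p_s + p_t:
        wo = _cosine_sample(rng)
        wo[2] = -wo[2]
        return "transmitted", wo
    return "absorbed", None
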