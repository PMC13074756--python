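"""Parametric cucumber-like plants, canopy layouts and BRDF fixtures.

The geometry generator emulates a young greenhouse cucumber at the
five-leaf stage: a short cylindrical stem carrying five laminae of
increasing order (1 = lowermost fully expanded, 5 = youngest), each built
as a cordate outline swept over a curved midrib and triangulated.  Default
parameters target a mean plant height of 0.212 m (sd 0.03 m) and a
per-plant one-sided leaf area of 0.185 m2, which puts a 3x3 grid at 0.2 m
spacing at a leaf area index of 4.625.

The optical fixture emulates measured leaf spectra: blue and red strongly
absorbed by pigments (low diffuse reflectance and transmittance, hence a
high *specular fraction*), green intermediate, far-red weakly absorbed
(near-diffuse, high reflectance and transmittance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import PchipInterpolator

from .brdf import BrdfSampleSet, DiffuseLeafOptics, PhongLeafOptics, SIDES, \
    angles_to_directions, _phong_f, dhr, diffuse_equivalent
from .spectra import SpectralGrid, default_grid

__all__ = [
    "SynthParams",
    "Leaf",
    "PlantArchitecture",
    "CanopyScene",
    "generate_plant",
    "assemble_canopy",
    "lai",
    "fixture_optics",
    "synth_gonio_fixture",
    "export_canopy_mesh",
]

LAYOUTS = ("single", "grid3x3", "grid4x3")


@dataclass
class SynthParams:
    """Tunables of the plant generator (lengths in metres, angles in deg)."""

    mean_height: float = 0.212
    height_sd: float = 0.03
    leaf_area_target: float = 0.185      # per-plant one-sided area, m2
    leaf_area_sd_rel: float = 0.08       # lognormal relative sd per plant
    # one-sided area fractions by leaf order 1..5 (rising to order 4,
    # youngest smallest)
    area_fractions: tuple = (0.15, 0.19, 0.24, 0.27, 0.15)
    phyllotaxis_step_deg: float = 144.0
    phyllotaxis_jitter_deg: float = 10.0
    # midrib take-off above horizontal, by order: lower leaves splay out
    # almost horizontally on long petioles, young leaves stand erect, so
    # each lamina keeps its own view of the sky (young plants are open)
    inclination_by_order_deg: tuple = (12.0, 22.0, 38.0, 55.0, 68.0)
    inclination_jitter_deg: float = 6.0
    # radial petiole offset of the lamina base from the stem, by order (m)
    petiole_radial_m: tuple = (0.085, 0.070, 0.052, 0.034, 0.018)
    droop_deg: float = 45.0              # midrib bend from base to tip
    aspect: float = 0.85                 # lamina half-width / midrib length
    cup: float = 0.12                    # transverse dishing of the lamina
    stem_radius: float = 0.004
    n_s: int = 7                         # midrib subdivisions
    n_t: int = 6                         # transverse subdivisions

    def __post_init__(self) -> None:
        if len(self.area_fractions) != 5:
            raise ValueError("need 5 area fractions (orders 1..5)")
        if min(self.mean_height, self.height_sd, self.leaf_area_target,
               self.stem_radius) <= 0:
            raise ValueError("size parameters must be positive")


@dataclass
class Leaf:
    order: int
    vertices: np.ndarray        # (nv, 3)
    faces: np.ndarray           # (nf, 3), wound so normals are adaxial
    area: float                 # one-sided, m2
    attachment: np.ndarray      # petiole attachment point on the stem
    ref_points: np.ndarray      # (3, 3) lamina reference points
    ref_normals: np.ndarray     # (3, 3) outward adaxial normals there


@dataclass
class PlantArchitecture:
    leaves: list                # 5 Leaf objects, orders 1..5
    stem_vertices: np.ndarray
    stem_faces: np.ndarray
    height: float

    def __post_init__(self) -> None:
        orders = sorted(l.order for l in self.leaves)
        if orders != [1, 2, 3, 4, 5]:
            raise ValueError("a plant must carry exactly leaves of orders 1..5")
        z = [l.attachment[2] for l in sorted(self.leaves, key=lambda l: l.order)]
        if np.any(np.diff(z) <= 0):
            raise ValueError("leaf order must increase with attachment height")

    @property
    def leaf_area(self) -> float:
        return float(sum(l.area for l in self.leaves))


@dataclass
class CanopyScene:
    plants: list                # list of PlantArchitecture
    positions: np.ndarray       # (n_plants, 2) planar positions
    layout: str
    spacing: float
    central_indices: tuple
    ground_radius: float = 0.0  # zero-reflectance ground disk at z=0

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def total_leaf_area(self) -> float:
        return float(sum(p.leaf_area for p in self.plants))


# ---------------------------------------------------------------------------
# geometry


def _width_profile(s: np.ndarray) -> np.ndarray:
    """Cordate half-width profile along the midrib (broadest near the base)."""
    return np.maximum(np.sin(np.pi * s ** 0.75) ** 0.9, 0.02)


def _build_lamina(length: float, azimuth: float, inclination: float,
                  droop: float, aspect: float, cup: float,
                  n_s: int, n_t: int, attachment: np.ndarray):
    """Sweep the cordate outline over a circular-arc midrib.

    The midrib leaves the stem at ``inclination`` above the horizontal and
    bends downward by ``droop`` from base to tip (angles in radians).
    Returns vertices, faces, midrib points and midrib normals.
    """
    s = np.linspace(0.0, 1.0, n_s)
    # midrib as polyline: tangent angle falls linearly with arc length
    ang = inclination - droop * s
    seg = length / (n_s - 1)
    dx = np.cos(ang) * seg
    dz = np.sin(ang) * seg
    rib = np.zeros((n_s, 3))
    rib[1:, 0] = np.cumsum(dx[:-1])
    rib[1:, 2] = np.cumsum(dz[:-1])
    tangents = np.stack([np.cos(ang), np.zeros(n_s), np.sin(ang)], axis=1)
    side = np.array([0.0, 1.0, 0.0])
    # tangent x side points up for a flat rib (the adaxial direction)
    normals = np.cross(tangents, side)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    half_w = aspect * length * _width_profile(s)
    t = np.linspace(-1.0, 1.0, n_t)
    verts = (rib[:, None, :]
             + t[None, :, None] * half_w[:, None, None] * side[None, None, :]
             - cup * (t ** 2)[None, :, None] * half_w[:, None, None]
             * normals[:, None, :])
    verts = verts.reshape(-1, 3)

    faces = []
    for i in range(n_s - 1):
        for j in range(n_t - 1):
            a = i * n_t + j
            b = a + 1
            c = a + n_t
            d = c + 1
            faces.append([a, c, b])
            faces.append([b, c, d])
    faces = np.asarray(faces, dtype=np.int64)

    # orient windings so face normals agree with the adaxial (upper) side
    v = verts
    fn = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    mean_rib_normal = normals.mean(axis=0)
    if np.dot(fn.sum(axis=0), mean_rib_normal) < 0:
        faces = faces[:, [0, 2, 1]]

    # rotate into the leaf azimuth and translate onto the stem
    ca, sa = np.cos(azimuth), np.sin(azimuth)
    rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    verts = verts @ rot.T + attachment
    rib_pts = rib @ rot.T + attachment
    rib_ns = normals @ rot.T

    # lamina reference points: centroid (s=1/2) and 1/3, 2/3 along the midrib
    ref_s = [0.5, 1.0 / 3.0, 2.0 / 3.0]
    idx = [int(round(x * (n_s - 1))) for x in ref_s]
    return verts, faces, rib_pts[idx], rib_ns[idx]


def _mesh_area(vertices: np.ndarray, faces: np.ndarray) -> float:
    v = vertices
    cross = np.cross(v[faces[:, 1]] - v[faces[:, 0]],
                     v[faces[:, 2]] - v[faces[:, 0]])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def _cylinder(p0: np.ndarray, p1: np.ndarray, radius: float,
              n_facets: int = 8):
    axis = p1 - p0
    h = np.linalg.norm(axis)
    mesh = trimesh.creation.cylinder(radius=radius, height=h,
                                     sections=n_facets)
    # trimesh builds the cylinder along +z centered at the origin
    mesh.apply_translation([0.0, 0.0, h / 2.0])
    z = np.array([0.0, 0.0, 1.0])
    d = axis / h
    if not np.allclose(d, z):
        rot = trimesh.geometry.align_vectors(z, d)
        mesh.apply_transform(rot)
    mesh.apply_translation(p0)
    return np.asarray(mesh.vertices), np.asarray(mesh.faces, dtype=np.int64)


def generate_plant(params: SynthParams, rng: np.random.Generator,
                   max_retries: int = 5) -> PlantArchitecture:
    """Generate one five-leaf plant; deterministic given (params, rng state)."""
    for _ in range(max_retries):
        height = float(rng.normal(params.mean_height, params.height_sd))
        height = max(height, 0.25 * params.mean_height)
        area_total = params.leaf_area_target * float(
            rng.lognormal(0.0, params.leaf_area_sd_rel))
        azim = float(rng.uniform(0.0, 360.0))
        attach_fracs = np.linspace(0.28, 0.92, 5)
        leaves = []
        ok = True
        for order in range(1, 6):
            frac = params.area_fractions[order - 1]
            target = area_total * frac
            azim += params.phyllotaxis_step_deg + float(
                rng.normal(0.0, params.phyllotaxis_jitter_deg))
            incl = np.deg2rad(
                params.inclination_by_order_deg[order - 1]
                + float(rng.normal(0.0, params.inclination_jitter_deg)))
            droop = np.deg2rad(params.droop_deg * float(rng.uniform(0.85, 1.15)))
            attach = np.array([0.0, 0.0, attach_fracs[order - 1] * height])
            # build at unit length, then rescale about the attachment point:
            # uniform scaling multiplies the one-sided area by k^2 exactly
            verts, faces, refs, refn = _build_lamina(
                1.0, np.deg2rad(azim), incl, droop, params.aspect,
                params.cup, params.n_s, params.n_t, np.zeros(3))
            a_unit = _mesh_area(verts, faces)
            if not np.isfinite(a_unit) or a_unit <= 0:
                ok = False
                break
            k = np.sqrt(target / a_unit)
            # petiole offset pushes the lamina base radially outward
            r0 = (params.petiole_radial_m[order - 1]
                  * height / params.mean_height)
            az = np.deg2rad(azim)
            radial = np.array([np.cos(az), np.sin(az), 0.0])
            verts = verts * k + attach + r0 * radial
            refs = refs * k + attach + r0 * radial
            area = _mesh_area(verts, faces)
            fn = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                          verts[faces[:, 2]] - verts[faces[:, 0]])
            if np.any(np.linalg.norm(fn, axis=1) < 1e-12):
                ok = False
                break
            leaves.append(Leaf(order, verts, faces, area, attach, refs, refn))
        if not ok:
            continue
        sv, sf = _cylinder(np.zeros(3), np.array([0.0, 0.0, height]),
                           params.stem_radius)
        return PlantArchitecture(leaves, sv, sf, height)
    raise RuntimeError("plant generation kept producing degenerate laminae")


def _grid_positions(layout: str, spacing: float):
    if layout == "single":
        return np.zeros((1, 2)), (0,)
    if layout == "grid3x3":
        xs, ys = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
        pos = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
        pos -= pos.mean(axis=0)
        central = (4,)                  # the interior plant of the 3x3 grid
        return pos * spacing, central
    if layout == "grid4x3":
        xs, ys = np.meshgrid(np.arange(4), np.arange(3), indexing="ij")
        pos = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
        pos -= pos.mean(axis=0)
        # the two interior plants: grid nodes (1,1) and (2,1)
        central = (1 * 3 + 1, 2 * 3 + 1)
        return pos * spacing, central
    raise ValueError(f"unknown layout {layout!r}; choose from {LAYOUTS}")


def assemble_canopy(layout: str, spacing: float, params: SynthParams,
                    rng: np.random.Generator) -> CanopyScene:
    """Independent plants on a regular lattice above a black ground disk."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    positions, central = _grid_positions(layout, spacing)
    plants = [generate_plant(params, rng) for _ in range(len(positions))]
    footprint = np.max(np.linalg.norm(positions, axis=1)) + 0.35
    return CanopyScene(plants, positions, layout, spacing, central,
                       ground_radius=3.0 * footprint)


def lai(scene: CanopyScene) -> float:
    """Leaf area index: one-sided leaf area per unit ground area."""
    if scene.layout == "single":
        raise ValueError("LAI is undefined for the single-plant layout")
    return scene.total_leaf_area / (scene.n_plants * scene.spacing ** 2)


def export_canopy_mesh(scene: CanopyScene, path, file_type: str | None = None):
    """Write the canopy as a multi-object OBJ/PLY triangle mesh."""
    scene_tm = trimesh.Scene()
    for i, (plant, pos) in enumerate(zip(scene.plants, scene.positions)):
        off = np.array([pos[0], pos[1], 0.0])
        for leaf in plant.leaves:
            scene_tm.add_geometry(
                trimesh.Trimesh(leaf.vertices + off, leaf.faces, process=False),
                node_name=f"plant{i}_leaf{leaf.order}_adaxial")
        scene_tm.add_geometry(
            trimesh.Trimesh(plant.stem_vertices + off, plant.stem_faces,
                            process=False),
            node_name=f"plant{i}_stem0")
    scene_tm.export(path, file_type=file_type)


# ---------------------------------------------------------------------------
# optical fixtures


def _smooth_curve(grid: SpectralGrid, wl_pts, values) -> np.ndarray:
    return PchipInterpolator(wl_pts, values)(grid.bin_centers)


def fixture_optics(grid: SpectralGrid | None = None):
    """Packaged cucumber-like leaf optics and stem reflectance.

    Spectral shape: chlorophyll absorbs strongly in blue and red (small
    diffuse reflectance/transmittance there, so the wax-layer specular lobe
    dominates), less in green, hardly at all in far-red where diffuse
    subsurface scattering dominates.  Returns (phong, diffuse-equivalent,
    stem_reflectance).
    """
    grid = grid or default_grid()
    wl = [440, 470, 500, 550, 600, 660, 700, 740]
    kd_ad = _smooth_curve(grid, wl, [0.020, 0.022, 0.045, 0.130, 0.085,
                                     0.038, 0.140, 0.430])
    tau_ad = _smooth_curve(grid, wl, [0.018, 0.020, 0.055, 0.190, 0.125,
                                      0.040, 0.180, 0.430])
    ks_ad = _smooth_curve(grid, wl, [0.060, 0.058, 0.050, 0.042, 0.046,
                                     0.056, 0.048, 0.042])
    n_ad = _smooth_curve(grid, wl, [14.0, 13.0, 9.0, 6.0, 7.0, 12.0,
                                    7.0, 5.0])
    # abaxial: matte and slightly brighter (dense trichomes), same tau
    kd_ab = np.minimum(kd_ad * 1.18 + 0.01, 0.52)
    ks_ab = ks_ad * 0.75
    n_ab = np.maximum(n_ad * 0.5, 1.5)
    tau_ab = tau_ad.copy()
    phong = PhongLeafOptics(np.stack([kd_ad, kd_ab]),
                            np.stack([ks_ad, ks_ab]),
                            np.stack([n_ad, n_ab]),
                            np.stack([tau_ad, tau_ab]), grid)
    phong.validate_energy()
    diffuse = diffuse_equivalent(phong)
    stem_reflectance = 0.15
    return phong, diffuse, stem_reflectance


def synth_gonio_fixture(optics_truth: PhongLeafOptics,
                        theta_i=(20.0, 40.0, 60.0),
                        theta_r=tuple(range(0, 81, 10)),
                        phi_r=(0.0, 45.0, 90.0, 135.0, 180.0),
                        noise_sd: float = 0.0,
                        rng: np.random.Generator | None = None,
                        sides=SIDES) -> BrdfSampleSet:
    """Gonioreflectometer-style sample set drawn from a known Phong truth.

    Samples are the exact model values times multiplicative Gaussian noise
    (1 + eps), clipped at zero; the per-bin reference albedo is the truth's
    DHR at 40 deg incidence.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    if noise_sd > 0 and rng is None:
        raise ValueError("need an rng when noise_sd > 0")
    grid = optics_truth.grid
    ti, tr, pr = [np.asarray(x, dtype=float) for x in (theta_i, theta_r, phi_r)]
    TI, TR, PR = np.meshgrid(ti, tr, pr, indexing="ij")
    TI, TR, PR = TI.ravel(), TR.ravel(), PR.ravel()
    wi, wo = angles_to_directions(TI, TR, PR)
    rows = []
    for side in sides:
        s = SIDES.index(side)
        for b in range(grid.n_bins):
            f = _phong_f(optics_truth.kd[s, b], optics_truth.ks[s, b],
                         optics_truth.n_exp[s, b], wi, wo)
            if noise_sd > 0:
                f = np.maximum(0.0, f * (1.0 + rng.normal(0.0, noise_sd,
                                                          size=f.shape)))
            rows.append(np.column_stack([
                np.full_like(f, b), TI, TR, PR, f,
                np.full_like(f, s)]))
    import pandas as pd
    table = pd.DataFrame(np.concatenate(rows),
                         columns=["bin", "theta_i_deg", "theta_r_deg",
                                  "phi_r_deg", "f", "side_idx"])
    table["bin"] = table["bin"].astype(int)
    table["side"] = table.pop("side_idx").astype(int).map(dict(enumerate(SIDES)))
    rho_ref = np.empty((2, grid.n_bins))
    for s in range(2):
        for b in range(grid.n_bins):
            rho_ref[s, b] = dhr(optics_truth, b, s, 40.0)
    return BrdfSampleSet(table, rho_ref, optics_truth.tau.copy(), grid)
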