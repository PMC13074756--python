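"""Forward Monte-Carlo tracing of a canopy under a light scenario."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..brdf import DiffuseLeafOptics, PhongLeafOptics, specular_albedo_factor
from ..lighting import LightScenario, scenario_sources
from .kernel import trace_kernel
from .scene import SceneIndex, SensorSet

__all__ = ["KernelOptics", "TallyResult", "trace", "run_replicates"]

_S_THETA_GRID = np.arange(0.0, 91.0)


@dataclass
class KernelOptics:
    """Leaf optics flattened into the kernel's lookup tables.

    ``s_table[side, bin, theta]`` holds the cosine-weighted above-horizon
    lobe fraction S(theta, n) on a 1-degree incidence grid, so the kernel
    can form the per-bin specular event probability ks * S by linear
    interpolation.
    """

    kd: np.ndarray
    ks: np.ndarray
    n_exp: np.ndarray
    tau: np.ndarray
    s_table: np.ndarray
    stem_reflectance: float
    mode: str                    # 'phong' or 'diffuse'

    @classmethod
    def from_optics(cls, optics, stem_reflectance: float = 0.15):
        if isinstance(optics, DiffuseLeafOptics):
            nb = optics.grid.n_bins
            return cls(optics.rho.copy(), np.zeros((2, nb)),
                       np.ones((2, nb)), optics.tau.copy(),
                       np.ones((2, nb, len(_S_THETA_GRID))),
                       stem_reflectance, "diffuse")
        if not isinstance(optics, PhongLeafOptics):
            raise TypeError("optics must be PhongLeafOptics or DiffuseLeafOptics")
        nb = optics.grid.n_bins
        s_table = np.empty((2, nb, len(_S_THETA_GRID)))
        for side in range(2):
            for b in range(nb):
                s_table[side, b] = specular_albedo_factor(
                    optics.n_exp[side, b], _S_THETA_GRID)
        return cls(optics.kd.copy(), optics.ks.copy(), optics.n_exp.copy(),
                   optics.tau.copy(), s_table, stem_reflectance, "phong")


@dataclass
class TallyResult:
    """Per-run tallies: fluxes in micromol s-1, PPFD in micromol m-2 s-1."""

    absorbed: np.ndarray         # (n_groups, nb) leaf absorbed photon flux
    stem_absorbed: np.ndarray    # (nb,)
    ground_absorbed: np.ndarray  # (nb,)
    escaped: np.ndarray          # (nb,)
    truncated: np.ndarray        # (nb,)
    emitted: np.ndarray          # (nb,)
    sensor: np.ndarray           # (ns, nb) accumulated crossing flux
    sensor_direct: np.ndarray    # (ns, nb) depth-0 portion of `sensor`
    sensor_area: float
    n_rays: int
    seed: int
    reflections_enabled: bool
    optics_mode: str
    scenario_id: str
    spectral_mode: str
    absorbed_se: np.ndarray | None = None
    sensor_se: np.ndarray | None = None
    n_replicates: int = 1

    @property
    def sensor_ppfd(self) -> np.ndarray:
        return self.sensor / self.sensor_area

    @property
    def sensor_ppfd_direct(self) -> np.ndarray:
        return self.sensor_direct / self.sensor_area

    def ledger_residual(self) -> float:
        """Relative imbalance of emitted vs. accounted weight (exact ~0)."""
        acct = (self.absorbed.sum() + self.stem_absorbed.sum()
                + self.ground_absorbed.sum() + self.escaped.sum()
                + self.truncated.sum())
        return float(abs(acct - self.emitted.sum()) / self.emitted.sum())

    def to_frame(self, index: SceneIndex,
                 sensors: SensorSet | None = None,
                 grid=None) -> pd.DataFrame:
        """Long-format tally table (absorbed flux and sensor PPFD)."""
        from ..spectra import default_grid
        grid = grid or default_grid()
        rows = []
        groups = index.group_frame()
        for _, gr in groups.iterrows():
            for b, wl in enumerate(grid.bin_centers):
                rows.append(dict(
                    scenario_id=self.scenario_id, optics_mode=self.optics_mode,
                    reflections=self.reflections_enabled,
                    plant=int(gr["plant"]), leaf_order=int(gr["leaf_order"]),
                    side="", sensor_id=-1, bin_center_nm=wl,
                    quantity="absorbed_flux",
                    value=self.absorbed[int(gr["group"]), b],
                    se=(self.absorbed_se[int(gr["group"]), b]
                        if self.absorbed_se is not None else np.nan)))
        if sensors is not None:
            sf = sensors.frame()
            ppfd = self.sensor_ppfd
            for _, sr in sf.iterrows():
                k = int(sr["sensor_id"])
                for b, wl in enumerate(grid.bin_centers):
                    rows.append(dict(
                        scenario_id=self.scenario_id,
                        optics_mode=self.optics_mode,
                        reflections=self.reflections_enabled,
                        plant=int(sr["plant"]),
                        leaf_order=int(sr["leaf_order"]), side=sr["side"],
                        sensor_id=k, bin_center_nm=wl, quantity="sensor_ppfd",
                        value=ppfd[k, b],
                        se=(self.sensor_se[k, b] / self.sensor_area
                            if self.sensor_se is not None else np.nan)))
        return pd.DataFrame(rows)


def _allocate_rays(power: np.ndarray, n_rays: int) -> np.ndarray:
    """Largest-remainder allocation proportional to source power."""
    p = power / power.sum()
    raw = p * n_rays
    alloc = np.floor(raw).astype(np.int64)
    short = n_rays - alloc.sum()
    if short > 0:
        order = np.argsort(-(raw - alloc))
        alloc[order[:short]] += 1
    alloc[(power > 0) & (alloc == 0)] = 1
    return alloc


def trace(index: SceneIndex, scenario: LightScenario,
          optics, n_rays: int, sensors: SensorSet | None = None,
          max_depth: int = 50, reflections_enabled: bool = True,
          spectral_mode: str = "split", seed: int | None = None,
          stem_reflectance: float = 0.15) -> TallyResult:
    """Trace one scenario and tally absorbed flux and sensor PPFD.

    ``spectral_mode='split'`` shoots rays carrying the whole 30-bin weight
    vector (pilot-bin splitting); ``'perbin'`` dedicates each ray to a
    single bin, the validation mode that mirrors a per-wavelength tracer.
    """
    if n_rays < 10_000:
        raise ValueError("n_rays must be >= 1e4")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible tracing")
    if spectral_mode not in ("split", "perbin"):
        raise ValueError("spectral_mode must be 'split' or 'perbin'")
    ko = (optics if isinstance(optics, KernelOptics)
          else KernelOptics.from_optics(optics, stem_reflectance))
    nb = ko.kd.shape[1]

    sources = scenario_sources(scenario)
    emit_area = np.pi * index.sphere_radius ** 2
    dirs = np.array([s.direction for s in sources])
    e_norm = np.array([s.irradiance_normal for s in sources])  # (S, nb)

    if spectral_mode == "split":
        power = e_norm.sum(axis=1)
        alloc = _allocate_rays(power, n_rays)
        src_w = e_norm * emit_area / alloc[:, None]
        ray_bin = np.full(len(sources), -1, dtype=np.int64)
        src_dir = dirs
    else:
        # expand every (source, bin) into its own single-bin beam
        power = e_norm.ravel()
        keep = power > 0
        alloc = np.zeros(keep.sum(), dtype=np.int64)
        alloc[:] = _allocate_rays(power[keep], n_rays)
        src_dir = np.repeat(dirs, nb, axis=0)[keep]
        bins = np.tile(np.arange(nb), len(sources))[keep]
        src_w = np.zeros((keep.sum(), nb))
        src_w[np.arange(keep.sum()), bins] = (power[keep] * emit_area / alloc)
        ray_bin = bins.astype(np.int64)

    if sensors is None:
        sen_c = np.zeros((0, 3))
        sen_n = np.zeros((0, 3))
        sen_r2 = 0.0
        sensor_area = np.nan
    else:
        sen_c = sensors.centers
        sen_n = sensors.normals
        sen_r2 = sensors.radius ** 2
        sensor_area = sensors.area

    absorbed = np.zeros((index.n_groups, nb))
    stem_abs = np.zeros(nb)
    ground_abs = np.zeros(nb)
    escaped = np.zeros(nb)
    truncated = np.zeros(nb)
    emitted = np.zeros(nb)
    sensor = np.zeros((len(sen_c), nb))
    sensor_direct = np.zeros((len(sen_c), nb))

    trace_kernel(index.v0, index.v1, index.v2, index.group,
                 index.node_min, index.node_max, index.node_left,
                 index.node_right, index.node_start, index.node_count,
                 index.tri_order, index.ground_radius,
                 ko.kd, ko.ks, ko.n_exp, ko.tau, ko.s_table,
                 ko.stem_reflectance,
                 sen_c, sen_n, sen_r2,
                 src_dir, alloc, src_w, ray_bin,
                 index.sphere_center, index.sphere_radius,
                 max_depth, reflections_enabled, int(seed) % (2 ** 31),
                 absorbed, stem_abs, ground_abs, escaped, truncated,
                 emitted, sensor, sensor_direct)

    return TallyResult(absorbed, stem_abs, ground_abs, escaped, truncated,
                       emitted, sensor, sensor_direct, sensor_area,
                       n_rays=int(alloc.sum()), seed=int(seed),
                       reflections_enabled=reflections_enabled,
                       optics_mode=ko.mode, scenario_id=scenario.scenario_id,
                       spectral_mode=spectral_mode)


def run_replicates(index: SceneIndex, scenario: LightScenario, optics,
                   n_rays: int, seeds, **kwargs) -> TallyResult:
    """Average independent replicate runs; spread kept as empirical SE."""
    seeds = list(seeds)
    if len(seeds) < 1:
        raise ValueError("need at least one replicate seed")
    results = [trace(index, scenario, optics, n_rays, seed=s, **kwargs)
               for s in seeds]
    ref = results[0]
    for r in results[1:]:
        if (r.reflections_enabled != ref.reflections_enabled
                or r.optics_mode != ref.optics_mode
                or r.scenario_id != ref.scenario_id
                or r.n_rays != ref.n_rays):
            raise ValueError("replicates must share their configuration")
    n = len(results)
    abs_stack = np.stack([r.absorbed for r in results])
    sen_stack = np.stack([r.sensor for r in results])
    mean = lambda key: np.mean([getattr(r, key) for r in results], axis=0)
    se = (abs_stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
          else np.zeros_like(ref.absorbed))
    sen_se = (sen_stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
              else np.zeros_like(ref.sensor))
    return TallyResult(abs_stack.mean(axis=0), mean("stem_absorbed"),
                       mean("ground_absorbed"), mean("escaped"),
                       mean("truncated"), mean("emitted"),
                       sen_stack.mean(axis=0), mean("sensor_direct"),
                       ref.sensor_area, ref.n_rays, seeds[0],
                       ref.reflections_enabled, ref.optics_mode,
                       ref.scenario_id, ref.spectral_mode,
                       absorbed_se=se, sensor_se=sen_se, n_replicates=n)
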