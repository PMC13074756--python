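"""Study orchestration: paired tracer runs, replicate averaging and the
summary tables of the Phong-vs-diffuse comparison.

A study runs, for every (arrangement, scenario), four tracer passes —
{phong, diffuse} x {reflections on, off} — with common random numbers
across passes of the same replicate, three replicates each.  From the
averaged tallies it derives:

* eta, the indirect-light proportion, from the with/without-reflection
  pair (phong optics);
* MAPE of spectrum-integrated absorbed photon flux per leaf between the
  Phong and equivalent-diffuse passes;
* MAPE of per-band sensor photon flux density;
* band shares of sensor PPFD;
* quantile and maximum-MAPE summary tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brdf import PhongLeafOptics, diffuse_equivalent
from .lighting import LightScenario, scenario_sweep
from .metrics import indirect_fraction, mape_frame, quantiles
from .spectra import band_aggregate, default_bands, default_grid
from .synthetic import SynthParams, assemble_canopy, fixture_optics, lai
from .tracer import KernelOptics, build_index, build_sensors, run_replicates

__all__ = ["RunConfig", "StudyBundle", "run_study", "report",
           "select_scenarios"]

_MODES = (("phong", True), ("phong", False),
          ("diffuse", True), ("diffuse", False))


@dataclass
class RunConfig:
    seed: int = 0
    n_rays: int = 2_000_000
    n_reps: int = 3
    max_depth: int = 50
    arrangements: tuple = ("single", "grid3x3", "grid4x3")
    # scenario subset: lists of accepted values, or None for 'all'
    subset_q_direct: tuple | None = (0.1, 0.2, 0.3, 0.4, 0.5,
                                     0.6, 0.7, 0.8, 0.9, 1.0)
    subset_azimuth: tuple | None = (0.0,)
    subset_altitude: tuple | None = (10.0, 50.0, 90.0)
    include_pure_diffuse: bool = True
    e_global: float = 1000.0
    optics_source: str = "fixture"       # 'fixture' or a phong-optics CSV
    spectral_mode: str = "split"
    sensor_offset: float = 0.005
    sensor_radius: float = 0.0025
    sensor_plants: str = "central"
    spacing: float = 0.2
    out_dir: str = "study_out"

    def __post_init__(self) -> None:
        if min(self.n_rays, self.n_reps, self.max_depth) <= 0:
            raise ValueError("numeric run parameters must be positive")
        unknown = set(self.arrangements) - {"single", "grid3x3", "grid4x3"}
        if unknown:
            raise ValueError(f"unknown arrangements {unknown}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for k in ("arrangements", "subset_q_direct", "subset_azimuth",
                  "subset_altitude"):
            if raw.get(k) is not None:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def select_scenarios(config: RunConfig):
    """Resolve the configured subset of the 360-scenario sweep."""
    out = []
    for s in scenario_sweep(config.e_global,
                            include_pure_diffuse=config.include_pure_diffuse):
        if s.q_direct == 0.0:
            out.append(s)
            continue
        if (config.subset_q_direct is not None
                and not np.any(np.isclose(s.q_direct, config.subset_q_direct))):
            continue
        if (config.subset_azimuth is not None
                and not np.any(np.isclose(s.sun_azimuth_deg,
                                          config.subset_azimuth))):
            continue
        if (config.subset_altitude is not None
                and not np.any(np.isclose(s.sun_altitude_deg,
                                          config.subset_altitude))):
            continue
        out.append(s)
    if not out:
        raise ValueError("scenario subset resolved to an empty set")
    return out


def _rep_seed(root: int, arr_i: int, scen_i: int, rep: int) -> int:
    """Counter-based replicate seed, shared across optics/reflection modes
    (common random numbers)."""
    ss = np.random.SeedSequence([root, arr_i, scen_i, rep])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class StudyBundle:
    """Everything run_study produces, in memory."""

    config: RunConfig
    leaf_records: pd.DataFrame     # per-leaf band/total absorbed flux
    sensor_records: pd.DataFrame   # per-sensor per-band PPFD
    tables: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir=None) -> Path:
        out = Path(out_dir or self.config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.leaf_records.to_csv(out / "leaf_records.csv", index=False)
        self.sensor_records.to_csv(out / "sensor_records.csv", index=False)
        for name, tab in self.tables.items():
            tab.to_csv(out / f"{name}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        self.config.to_yaml(out / "config.yaml")
        return out


def _band_rows(values_bins: np.ndarray):
    """Split a per-bin vector into total + four band values."""
    bands = band_aggregate(values_bins)
    names = ("total",) + tuple(default_bands().names)
    vals = np.concatenate([[values_bins.sum()], bands])
    return zip(names, vals)


def run_study(config: RunConfig,
              synth_params: SynthParams | None = None) -> StudyBundle:
    """Run the full paired-comparison study for the configured subset."""
    params = synth_params or SynthParams()
    scenarios = select_scenarios(config)
    if config.optics_source == "fixture":
        phong, diffuse, stem_refl = fixture_optics()
    else:
        phong = PhongLeafOptics.from_frame(pd.read_csv(config.optics_source))
        diffuse = diffuse_equivalent(phong)
        stem_refl = 0.15
    kernel_optics = {
        "phong": KernelOptics.from_optics(phong, stem_refl),
        "diffuse": KernelOptics.from_optics(diffuse, stem_refl),
    }

    leaf_rows, sensor_rows = [], []
    seeds_used = {}
    lai_by_arr = {}
    for arr_i, arrangement in enumerate(config.arrangements):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, arr_i]))
        scene = assemble_canopy(arrangement, config.spacing, params, rng)
        if arrangement != "single":
            lai_by_arr[arrangement] = lai(scene)
        sensors = build_sensors(scene, offset=config.sensor_offset,
                                radius=config.sensor_radius,
                                plants=config.sensor_plants)
        index = build_index(scene, extra_points=sensors.centers)
        sensor_meta = sensors.frame()
        group_meta = index.group_frame()
        central = set(scene.central_indices)
        for scen_i, scenario in enumerate(scenarios):
            rep_seeds = [_rep_seed(config.seed, arr_i, scen_i, r)
                         for r in range(config.n_reps)]
            seeds_used[f"{arrangement}/{scenario.scenario_id}"] = rep_seeds
            for mode, refl in _MODES:
                res = run_replicates(
                    index, scenario, kernel_optics[mode], config.n_rays,
                    rep_seeds, sensors=sensors, max_depth=config.max_depth,
                    reflections_enabled=refl,
                    spectral_mode=config.spectral_mode)
                base = dict(arrangement=arrangement,
                            scenario_id=scenario.scenario_id,
                            q_direct=scenario.q_direct,
                            altitude=scenario.sun_altitude_deg,
                            azimuth=scenario.sun_azimuth_deg,
                            optics_mode=mode, reflections=refl)
                for _, g in group_meta.iterrows():
                    gid = int(g["group"])
                    for band, val in _band_rows(res.absorbed[gid]):
                        leaf_rows.append(dict(
                            base, plant=int(g["plant"]),
                            central=int(g["plant"]) in central,
                            leaf_order=int(g["leaf_order"]), band=band,
                            value=val,
                            se=(res.absorbed_se[gid].sum()
                                if band == "total" else np.nan)))
                ppfd = res.sensor_ppfd
                for _, srow in sensor_meta.iterrows():
                    k = int(srow["sensor_id"])
                    for band, val in _band_rows(ppfd[k]):
                        sensor_rows.append(dict(
                            base, plant=int(srow["plant"]), central=True,
                            leaf_order=int(srow["leaf_order"]),
                            side=srow["side"], sensor_id=k, band=band,
                            value=val, se=np.nan))

    leaf_records = pd.DataFrame(leaf_rows)
    sensor_records = pd.DataFrame(sensor_rows)
    bundle = StudyBundle(config, leaf_records, sensor_records)
    bundle.tables = derive_tables(bundle)
    bundle.manifest = dict(
        version=__version__, python=platform.python_version(),
        config_hash=config.config_hash(), seeds=seeds_used,
        n_scenarios=len(scenarios), lai=lai_by_arr,
        table_families=sorted(bundle.tables.keys()))
    return bundle


# ---------------------------------------------------------------------------
# derived tables


def _paired(records: pd.DataFrame, keys, a_sel: dict, b_sel: dict,
            names=("phong", "diffuse")) -> pd.DataFrame:
    def pick(sel):
        m = np.ones(len(records), dtype=bool)
        for k, v in sel.items():
            m &= records[k] == v
        return records[m]
    a = pick(a_sel).set_index(keys)["value"]
    b = pick(b_sel).set_index(keys)["value"]
    df = pd.concat([a.rename(names[0]), b.rename(names[1])], axis=1)
    if df.isna().any().any():
        raise ValueError("comparison pairs are incomplete")
    return df.reset_index()


_LEAF_KEYS = ["arrangement", "scenario_id", "q_direct", "altitude",
              "plant", "central", "leaf_order"]
_SENSOR_KEYS = _LEAF_KEYS + ["side", "sensor_id", "band"]


def derive_tables(bundle: StudyBundle) -> dict:
    leaf = bundle.leaf_records
    sens = bundle.sensor_records
    tables = {}

    # eta per leaf from phong runs with/without reflections (total flux)
    tot = leaf[leaf["band"] == "total"]
    eta = _paired(tot, _LEAF_KEYS,
                  dict(optics_mode="phong", reflections=False),
                  dict(optics_mode="phong", reflections=True),
                  names=("without", "with"))
    eta = eta[eta["with"] > 0].copy()
    eta["eta_pct"] = 100.0 * indirect_fraction(eta["without"], eta["with"])
    tables["eta_leaf"] = eta
    central_eta = eta[eta["central"]]
    tables["eta_by_leaf_order"] = (
        central_eta.groupby(["arrangement", "leaf_order"])["eta_pct"]
        .agg(["mean", "sem", "count"]).reset_index()
        .rename(columns={"mean": "eta_pct", "sem": "se", "count": "n"}))
    tables["eta_by_q_direct"] = (
        central_eta.groupby(["arrangement", "q_direct"])["eta_pct"]
        .agg(["mean", "sem", "count"]).reset_index()
        .rename(columns={"mean": "eta_pct", "sem": "se", "count": "n"}))

    # absorbed-flux MAPE per leaf: phong vs diffuse, reflections on
    pairs = _paired(tot, _LEAF_KEYS,
                    dict(optics_mode="phong", reflections=True),
                    dict(optics_mode="diffuse", reflections=True))
    tables["absorbed_pairs"] = pairs
    for dim in ("leaf_order", "q_direct", "altitude"):
        tables[f"absorbed_mape_by_{dim}"] = mape_frame(
            pairs, ["arrangement", dim])

    # sensor-band MAPE: phong vs diffuse, reflections on
    spairs = _paired(sens, _SENSOR_KEYS,
                     dict(optics_mode="phong", reflections=True),
                     dict(optics_mode="diffuse", reflections=True))
    tables["sensor_pairs"] = spairs
    for dim in ("q_direct", "leaf_order"):
        tables[f"sensor_mape_by_{dim}"] = mape_frame(
            spairs, ["band", "side", dim])

    # band fractions of sensor PPFD (phong runs, reflections on)
    ph = sens[(sens["optics_mode"] == "phong") & sens["reflections"]
              & (sens["band"] != "total")]
    tot_ph = (ph.groupby(_SENSOR_KEYS[:-1])["value"].transform("sum"))
    frac = ph.assign(fraction=ph["value"] / tot_ph)
    tables["band_fractions"] = (
        frac.groupby(["band", "side", "leaf_order", "q_direct"])["fraction"]
        .agg(["mean", "sem", "count"]).reset_index()
        .rename(columns={"mean": "fraction", "sem": "se", "count": "n"}))

    # quantile table of per-record sensor MAPE by band and side
    spairs = spairs[spairs["diffuse"] > 0]
    rel = spairs.assign(
        ape_pct=100.0 * np.abs(spairs["phong"] - spairs["diffuse"])
        / spairs["diffuse"])
    qrows = []
    for (band, side), sub in rel.groupby(["band", "side"]):
        q = quantiles(sub["ape_pct"])
        qrows.append(dict(band=band, side=side, mean=sub["ape_pct"].mean(),
                          q25=q[0], q50=q[1], q90=q[2], n=len(sub)))
    tables["sensor_mape_quantiles"] = pd.DataFrame(qrows)

    # maximum MAPE summary
    mrows = []
    for dim in ("leaf_order", "q_direct", "altitude"):
        t = tables[f"absorbed_mape_by_{dim}"]
        i = t["mape_pct"].idxmax()
        mrows.append(dict(quantity="absorbed_flux", band="total",
                          side="", dimension=dim,
                          max_mape_pct=t.loc[i, "mape_pct"],
                          se_pct=t.loc[i, "se_pct"]))
    for dim in ("q_direct", "leaf_order"):
        t = tables[f"sensor_mape_by_{dim}"]
        for (band, side), sub in t.groupby(["band", "side"]):
            i = sub["mape_pct"].idxmax()
            mrows.append(dict(quantity="sensor_ppfd", band=band, side=side,
                              dimension=dim,
                              max_mape_pct=sub.loc[i, "mape_pct"],
                              se_pct=sub.loc[i, "se_pct"]))
    tables["max_mape"] = pd.DataFrame(mrows)
    return tables


def report(bundle: StudyBundle) -> str:
    """Human-readable study summary (pure function of the bundle)."""
    if not bundle.tables:
        raise ValueError("bundle is incomplete: tables missing")
    lines = ["canopylight study report",
             "========================",
             f"config hash: {bundle.config.config_hash()}",
             f"scenarios:   {bundle.manifest.get('n_scenarios', '?')}"]
    for arr, v in bundle.manifest.get("lai", {}).items():
        lines.append(f"LAI {arr}: {v:.3f}")
    eta = bundle.tables["eta_by_leaf_order"]
    i = eta["eta_pct"].idxmax()
    lines.append(
        f"peak indirect-light proportion (central plants): "
        f"{eta.loc[i, 'eta_pct']:.2f}% +- {eta.loc[i, 'se']:.2f}% "
        f"(arrangement {eta.loc[i, 'arrangement']}, "
        f"leaf order {eta.loc[i, 'leaf_order']})")
    ab = bundle.tables["max_mape"]
    ab_tot = ab[ab["quantity"] == "absorbed_flux"]
    j = ab_tot["max_mape_pct"].idxmax()
    lines.append(
        f"max absorbed-flux MAPE: {ab_tot.loc[j, 'max_mape_pct']:.2f}% "
        f"+- {ab_tot.loc[j, 'se_pct']:.2f}% (by {ab_tot.loc[j, 'dimension']})")
    sp = ab[(ab["quantity"] == "sensor_ppfd")]
    k = sp["max_mape_pct"].idxmax()
    lines.append(
        f"max sensor-PPFD MAPE: {sp.loc[k, 'max_mape_pct']:.2f}% "
        f"({sp.loc[k, 'band']}, {sp.loc[k, 'side']})")
    bf = bundle.tables["band_fractions"]
    hi = bf[bf["q_direct"] > 0.5]
    if len(hi):
        green = hi[hi["band"] == "green"]["fraction"].mean()
        lines.append(f"green-band share of sensor PPFD (>50% direct): "
                     f"{100 * green:.1f}%")
    return "\n".join(lines)
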