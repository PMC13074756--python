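"""Sky and sun models: hemispherical source discretization and scenarios.

The diffuse sky is an isotropic-radiance hemisphere discretized into 108
directed sources (9 altitude rings x 12 azimuth sectors), each placed at
its segment center and weighted by the cosine-projected solid angle of its
segment, so a horizontal surface in an empty scene receives exactly the
configured diffuse irradiance.  Direct sunlight is a single directed
source specified by azimuth and altitude whose *horizontal-plane*
irradiance is q_direct * E_global, keeping E_diffuse + E_direct = E_global
exact at every altitude.  All sources share the D65 photon spectrum.

Angle conventions: altitude is measured up from the horizon, azimuth
clockwise from north (+y), lengths in metres, irradiance in
micromol m-2 s-1 (photon flux density).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectralGrid, d65_photon_weights, default_grid

__all__ = [
    "DirectionalSource",
    "HemisphereModel",
    "LightScenario",
    "build_hemisphere",
    "scenario_sweep",
    "direct_horizontal_irradiance",
    "sun_direction",
    "scenario_sources",
]

N_ALTITUDE_RINGS = 9
N_AZIMUTH_SECTORS = 12


def sun_direction(azimuth_deg: float, altitude_deg: float) -> np.ndarray:
    """Downwelling unit propagation vector for a sky position."""
    az = np.deg2rad(azimuth_deg)
    alt = np.deg2rad(altitude_deg)
    # position on the sky dome ...
    toward = np.array([np.sin(az) * np.cos(alt),
                       np.cos(az) * np.cos(alt),
                       np.sin(alt)])
    # ... propagation is from the dome toward the scene
    return -toward


@dataclass
class DirectionalSource:
    direction: np.ndarray          # unit, downwelling (z < 0)
    irradiance_normal: np.ndarray  # per-bin, on a plane normal to direction
    altitude_deg: float
    azimuth_deg: float

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction[2] >= 0:
            raise ValueError("sources must be downwelling (direction z < 0)")
        if np.any(np.asarray(self.irradiance_normal) < 0):
            raise ValueError("irradiance must be >= 0")


@dataclass
class HemisphereModel:
    sources: list                  # 108 DirectionalSource
    e_diffuse: float               # total horizontal irradiance

    def __post_init__(self) -> None:
        if len(self.sources) != N_ALTITUDE_RINGS * N_AZIMUTH_SECTORS:
            raise ValueError("hemisphere must hold exactly 108 sources")

    def horizontal_irradiance(self) -> float:
        return float(sum(
            np.sum(s.irradiance_normal) * np.sin(np.deg2rad(s.altitude_deg))
            for s in self.sources))


def _ring_weights() -> np.ndarray:
    """Cosine-projected weight of each altitude ring, summing to 1.

    For an isotropic sky the horizontal irradiance from an altitude band
    [a0, a1] is proportional to the closed form
    Int cos(zenith) dOmega = pi * (sin^2 a1 - sin^2 a0); each of the 12
    sector sources in a ring carries 1/12 of its ring weight.
    """
    edges = np.deg2rad(np.arange(0.0, 91.0, 10.0))
    w = np.sin(edges[1:]) ** 2 - np.sin(edges[:-1]) ** 2
    return w / w.sum()


def build_hemisphere(e_diffuse: float,
                     grid: SpectralGrid | None = None) -> HemisphereModel:
    """Isotropic sky discretized as 9 x 12 directed sources."""
    if e_diffuse < 0:
        raise ValueError("E_diffuse must be >= 0")
    grid = grid or default_grid()
    spectrum = d65_photon_weights(grid)
    ring_w = _ring_weights()
    sources = []
    for i, alt in enumerate(np.arange(5.0, 90.0, 10.0)):
        e_horiz = e_diffuse * ring_w[i] / N_AZIMUTH_SECTORS
        e_normal = e_horiz / np.sin(np.deg2rad(alt))
        for az in np.arange(15.0, 360.0, 30.0):
            sources.append(DirectionalSource(
                sun_direction(az, alt), e_normal * spectrum, alt, az))
    return HemisphereModel(sources, e_diffuse)


@dataclass
class LightScenario:
    q_direct: float                # direct fraction of E_global
    sun_azimuth_deg: float
    sun_altitude_deg: float
    e_global: float = 1000.0       # horizontal PPFD, micromol m-2 s-1
    grid: SpectralGrid = field(default_factory=default_grid)
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_direct <= 1.0:
            raise ValueError("q_direct must lie in [0, 1]")
        if self.e_global <= 0:
            raise ValueError("E_global must be positive")
        if not self.scenario_id:
            self.scenario_id = (f"q{self.q_direct:.1f}"
                                f"_az{self.sun_azimuth_deg:.0f}"
                                f"_alt{self.sun_altitude_deg:.0f}")

    @property
    def e_direct(self) -> float:
        return self.q_direct * self.e_global

    @property
    def e_diffuse(self) -> float:
        return self.e_global - self.e_direct


def scenario_sweep(e_global: float = 1000.0,
                   grid: SpectralGrid | None = None,
                   include_pure_diffuse: bool = False):
    """The full factorial sweep: 10 direct fractions x 4 azimuths x 9
    altitudes = 360 scenarios.

    The directionless pure-diffuse case (q_direct = 0) is not part of the
    360; pass ``include_pure_diffuse=True`` to prepend it as a baseline.
    """
    if e_global <= 0:
        raise ValueError("E_global must be positive")
    grid = grid or default_grid()
    out = []
    if include_pure_diffuse:
        out.append(LightScenario(0.0, 0.0, 90.0, e_global, grid,
                                 scenario_id="q0.0_diffuse"))
    for q in np.arange(1, 11) / 10.0:
        for az in (0.0, 90.0, 180.0, 270.0):
            for alt in np.arange(10.0, 91.0, 10.0):
                out.append(LightScenario(float(q), az, alt, e_global, grid))
    return out


def direct_horizontal_irradiance(source: DirectionalSource) -> float:
    """Horizontal-plane irradiance of one directed source (sums over bins)."""
    return float(np.sum(source.irradiance_normal)
                 * np.sin(np.deg2rad(source.altitude_deg)))


def scenario_sources(scenario: LightScenario):
    """All active sources of a scenario (diffuse hemisphere + sun)."""
    sources = []
    if scenario.e_diffuse > 0:
        sources.extend(build_hemisphere(scenario.e_diffuse,
                                        scenario.grid).sources)
    if scenario.e_direct > 0:
        spectrum = d65_photon_weights(scenario.grid)
        alt = scenario.sun_altitude_deg
        e_normal = scenario.e_direct / np.sin(np.deg2rad(alt))
        sources.append(DirectionalSource(
            sun_direction(scenario.sun_azimuth_deg, alt),
            e_normal * spectrum, alt, scenario.sun_azimuth_deg))
    return sources


def scenario_table(scenarios) -> pd.DataFrame:
    return pd.DataFrame([
        dict(scenario_id=s.scenario_id, q_direct=s.q_direct,
             sun_azimuth_deg=s.sun_azimuth_deg,
             sun_altitude_deg=s.sun_altitude_deg, E_global=s.e_global)
        for s in scenarios])
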