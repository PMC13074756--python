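"""Spectral discretization, D65 photon weighting and band aggregation.

The simulation works on a fixed visible/far-red window, 440-740 nm, split
into 30 contiguous 10 nm bins.  For analysis the bins are aggregated into
four horticultural bands (blue, green, red, far-red).  All sources share the
relative spectrum of the CIE D65 standard illuminant, expressed as *photon*
flux (quanta) rather than energy, since photosynthetically relevant
quantities are photon counts: photon flux per wavelength is proportional to
S(lambda) * lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralGrid",
    "BandScheme",
    "default_grid",
    "default_bands",
    "d65_photon_weights",
    "photon_weights",
    "band_aggregate",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "d65_interpolator",
]

# CIE D65 relative spectral power distribution, 440-740 nm at 5 nm steps,
# normalized to 100 at 560 nm (CIE 15 tabulation).
_D65_WL = np.arange(440.0, 741.0, 5.0)
_D65_SPD = np.array([
    104.865, 110.936, 117.008, 117.410, 117.812, 116.336, 114.861, 115.392,
    115.923, 112.367, 108.811, 109.082, 109.354, 108.578, 107.802, 106.296,
    104.790, 106.239, 107.689, 106.047, 104.405, 104.225, 104.046, 102.023,
    100.000, 98.167, 96.334, 96.061, 95.788, 92.237, 88.686, 89.346,
    90.006, 89.803, 89.599, 88.649, 87.699, 85.494, 83.289, 83.494,
    83.699, 81.863, 80.027, 80.121, 80.215, 81.246, 82.278, 80.281,
    78.284, 74.003, 69.721, 70.665, 71.609, 72.979, 74.349, 67.977,
    61.604, 65.745, 69.886, 72.486, 75.087,
])


@dataclass(frozen=True)
class SpectralGrid:
    """Contiguous wavelength bins. Default: 30 x 10 nm over 440-740 nm."""

    bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(440.0, 741.0, 10.0)
    )

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be a 1-D array of >= 2 edges")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin_edges must be strictly ascending")
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must have uniform width")

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class BandScheme:
    """Named half-open wavelength intervals; the last band is closed above.

    Default is the horticultural scheme blue [440,500), green [500,600),
    red [600,700), far-red [700,740].
    """

    names: tuple = ("blue", "green", "red", "far_red")
    edges: tuple = (440.0, 500.0, 600.0, 700.0, 740.0)

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.names) + 1:
            raise ValueError("need len(names)+1 edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("band edges must ascend")

    def bin_to_band(self, grid: SpectralGrid) -> np.ndarray:
        """Map every grid bin to a band index; reject straddling bins."""
        lo = grid.bin_edges[:-1]
        hi = grid.bin_edges[1:]
        idx = np.searchsorted(np.asarray(self.edges), lo, side="right") - 1
        idx = np.clip(idx, 0, len(self.names) - 1)
        band_lo = np.asarray(self.edges)[idx]
        band_hi = np.asarray(self.edges)[idx + 1]
        if np.any(lo < band_lo - 1e-9) or np.any(hi > band_hi + 1e-9):
            raise ValueError("a grid bin straddles a band boundary")
        return idx


def default_grid() -> SpectralGrid:
    return SpectralGrid()


def default_bands() -> BandScheme:
    return BandScheme()


def d65_interpolator() -> tuple[np.ndarray, np.ndarray]:
    """The embedded D65 table, linearly interpolated to a 1 nm grid."""
    wl = np.arange(_D65_WL[0], _D65_WL[-1] + 0.5, 1.0)
    spd = np.interp(wl, _D65_WL, _D65_SPD)
    return wl, spd


def photon_weights(wavelength_nm: np.ndarray, spd: np.ndarray,
                   grid: SpectralGrid) -> np.ndarray:
    """Per-bin relative photon flux of an arbitrary SPD, summing to 1.

    Photon flux density per wavelength is S(lambda)*lambda/(h*c); the
    constant cancels in the normalization, so each bin weight is the
    integral of S*lambda over the bin (trapezoids on the given grid).
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    spd = np.asarray(spd, dtype=float)
    if grid.bin_edges[0] < wl[0] - 1e-9 or grid.bin_edges[-1] > wl[-1] + 1e-9:
        raise ValueError(
            f"grid [{grid.bin_edges[0]}, {grid.bin_edges[-1]}] nm outside "
            f"the SPD table [{wl[0]}, {wl[-1]}] nm"
        )
    photon = spd * wl
    weights = np.empty(grid.n_bins)
    for b in range(grid.n_bins):
        lo, hi = grid.bin_edges[b], grid.bin_edges[b + 1]
        mask = (wl >= lo - 1e-9) & (wl <= hi + 1e-9)
        weights[b] = np.trapezoid(photon[mask], wl[mask])
    return weights / weights.sum()


def d65_photon_weights(grid: SpectralGrid | None = None) -> np.ndarray:
    """Per-bin relative photon flux of the D65 illuminant, summing to 1."""
    grid = grid or default_grid()
    wl, spd = d65_interpolator()
    return photon_weights(wl, spd, grid)


def band_aggregate(values: np.ndarray, scheme: BandScheme | None = None,
                   grid: SpectralGrid | None = None) -> np.ndarray:
    """Sum per-bin values into per-band values (conserves the total exactly).

    ``values`` may have the bin axis last; aggregation applies along it.
    """
    grid = grid or default_grid()
    scheme = scheme or default_bands()
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != grid.n_bins:
        raise ValueError("last axis must match the number of grid bins")
    idx = scheme.bin_to_band(grid)
    out = np.zeros(values.shape[:-1] + (len(scheme.names),))
    for band in range(len(scheme.names)):
        out[..., band] = values[..., idx == band].sum(axis=-1)
    return out


def read_spectrum_csv(path) -> pd.DataFrame:
    """Read a two-column `wavelength_nm,value` spectrum (ascending nm)."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"spectrum CSV needs columns {sorted(required)}")
    if np.any(np.diff(df["wavelength_nm"].to_numpy()) <= 0):
        raise ValueError("wavelengths must be strictly ascending")
    return df


def write_spectrum_csv(path, wavelength_nm, value) -> None:
    pd.DataFrame({"wavelength_nm": wavelength_nm, "value": value}).to_csv(
        path, index=False
    )
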