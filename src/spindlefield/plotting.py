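"""Quick-look plots: vibration spectra and equatorial field maps."""

from __future__ import annotations

import numpy as np

from .analysis import SpectrumCurve
from .field import FieldFrame


def plot_spectrum(spectrum: SpectrumCurve, ax=None, **kwargs):
    """Line plot of a vibration spectrum (frequency in GHz)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(spectrum.frequency / 1e9, spectrum.amplitude, **kwargs)
    ax.set_xlabel("frequency [GHz]")
    ax.set_ylabel("spectral amplitude [a.u.]")
    ax.set_title(f"vibration spectrum, Q = {spectrum.Q:g}")
    return ax


def plot_plane_magnitude(frame: FieldFrame, ax=None, log: bool = True,
                         **kwargs):
    """Heat map of |E| on a plane grid (log10 colour scale by default)."""
    import matplotlib.pyplot as plt

    grid = frame.grid
    if grid.kind != "plane":
        raise ValueError("plane-grid frame required")
    if ax is None:
        _, ax = plt.subplots()
    mag = frame.magnitude.reshape(grid.shape)
    data = np.log10(np.maximum(mag, 1e-30)) if log else mag
    free = [i for i in range(3) if i != grid.plane_axis]
    extent = [grid.points[:, free[0]].min(), grid.points[:, free[0]].max(),
              grid.points[:, free[1]].min(), grid.points[:, free[1]].max()]
    im = ax.imshow(data.T, origin="lower", extent=extent, aspect="equal",
                   **kwargs)
    ax.set_xlabel(f"axis {free[0]} [nm]")
    ax.set_ylabel(f"axis {free[1]} [nm]")
    label = "log10 |E| [V/m]" if log else "|E| [V/m]"
    ax.figure.colorbar(im, ax=ax, label=label)
    return ax
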