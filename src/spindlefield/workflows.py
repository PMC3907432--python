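"""End-to-end study workflows.

These functions reproduce the headline numbers of the model from scratch:
the half-maximum band of the smallest-cell vibration spectrum, the peak
response frequency of the largest cell, and the spatial dynamic range of the
pulsed free-end field in the equatorial plane.

The spectra are evaluated in the free-end scenario (astral MTs fixed at both
ends, kinetochore/polar MTs free in the equatorial plane): with the
boundary-condition factors 2 (fixed-fixed) and 1 (fixed-free) of the
length-frequency law, that scenario is the one whose spectrum spans the
~8-18 GHz small-cell band and puts the largest-cell response near 1 GHz;
the all-fixed spectrum sits a factor ~2 higher.  See docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from . import constants
from .analysis import band_edges, model_spectrum, peak_frequency, \
    spatial_dynamic_range
from .dynamics import ExcitationSpec, assign_phases
from .field import plane_grid, superpose
from .geometry import SpindleModel, SpindleParams, build_spindle

LARGE_CELL_SCALE = 65.0 / 3.3  #: R_equiv 3.3 um -> 65 um


def small_cell_model(seed: int = 0, scenario: str = "free") -> SpindleModel:
    """Default smallest-cell spindle (R_equiv = 3.3 um, 300 MTs)."""
    return build_spindle(SpindleParams(scenario=scenario), seed=seed)


def small_cell_band(seed: int = 0, Q: float = constants.Q_DEFAULT,
                    model: SpindleModel | None = None,
                    f_max: float = 25e9, n_freq: int = 4000
                    ) -> tuple[float, float]:
    """Half-maximum band edges (Hz) of the smallest-cell spectrum at Q."""
    model = model or small_cell_model(seed)
    axis = np.linspace(1e6, f_max, n_freq)
    return band_edges(model_spectrum(model, Q, axis), threshold=0.5)


def large_cell_peak(seed: int = 0, Q: float = constants.Q_DEFAULT,
                    scale: float = LARGE_CELL_SCALE) -> float:
    """Frequency of maximal spectral response (Hz) of the scaled-up cell."""
    model = build_spindle(SpindleParams(scenario="free").scaled(scale),
                          seed=seed)
    return peak_frequency(model_spectrum(model, Q))


def equatorial_dynamic_range(seed: int = 0,
                             model: SpindleModel | None = None,
                             half_span: float = 496.0,
                             pitch: float = constants.VOXEL_EDGE_NM,
                             max_separation: float = 500.0) -> float:
    """Spatial dynamic range of the pulsed free-end field near a free MT end.

    Protocol: default smallest-cell spindle with free equatorial ends,
    pulsed undamped excitation at 1 nm antinode amplitude; |E| on an 8 nm
    pitch patch (~1 um^2) of the equatorial plane centred on the free end of
    the first kinetochore MT, at the first sample of the default time series
    after the excitation instant; the result is the maximum log10 intensity
    ratio over point pairs separated by at most ``max_separation`` nm,
    clamped points excluded.
    """
    model = model or small_cell_model(seed, scenario="free")
    excitation = ExcitationSpec()  # pulsed, undamped, 1 nm
    assign_phases(model, excitation)
    kp = next(mt for mt in model.microtubules if mt.mt_class == "kinetochore")
    end = kp.trajectory.point(kp.length)[0]
    grid = plane_grid(axis=0, offset=0.0, center=(end[1], end[2]),
                      half_span=half_span, pitch=pitch)
    t_sample = (constants.N_PERIODS_DEFAULT / model.frequencies().min()
                / constants.N_SAMPLES_DEFAULT)
    frame = superpose(model, excitation, t_sample, grid, aggregate="auto")
    return spatial_dynamic_range(frame, max_separation=max_separation)
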