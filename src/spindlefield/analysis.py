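"""Spectra and field statistics.

The vibration spectrum of the spindle is the superposition of one Lorentzian
line per MT, centred at its principal frequency with full width at half
maximum f_n / Q (the Q = f0 / delta-f convention).  Lines are unit-peak by
default, so superposed intensities reflect the number of MTs per length bin
and the spectrum resembles a histogram of MT lengths.

Field statistics: Monte-Carlo pooling of |E| over random-phase realizations
(per-point max / mean / min), and the spatial dynamic range — the largest
log10 intensity ratio between evaluation points closer than a given
separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import constants
from .dynamics import ExcitationSpec, FeedingMode, assign_phases
from .field import EvaluationGrid, FieldFrame, time_series
from .medium import MediumModel


# ---------------------------------------------------------------------------
# vibration spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumCurve:
    """Sampled vibration spectrum S(f)."""

    frequency: np.ndarray   # Hz, strictly increasing
    amplitude: np.ndarray   # dimensionless, >= 0
    Q: float

    def __post_init__(self):
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        if np.any(self.amplitude < 0):
            raise ValueError("spectrum amplitude must be non-negative")


def vibration_spectrum(frequencies: np.ndarray, Q: float,
                       axis: np.ndarray | None = None,
                       normalization: str = "peak") -> SpectrumCurve:
    """Sum of Lorentzians at the given resonance frequencies.

    Each line has FWHM ``f_n / Q``; ``normalization`` is ``"peak"`` (unit
    peak, default) or ``"area"`` (unit integral).
    """
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if len(frequencies) == 0:
        raise ValueError("need at least one resonance frequency")
    if np.any(frequencies <= 0) or Q <= 0:
        raise ValueError("frequencies and Q must be positive")
    if axis is None:
        axis = np.linspace(0.7 * frequencies.min(), 1.3 * frequencies.max(), 4001)
    axis = np.asarray(axis, dtype=float)
    half_width = frequencies / (2.0 * Q)              # (m,)
    lor = 1.0 / (1.0 + ((axis[:, None] - frequencies[None, :])
                        / half_width[None, :]) ** 2)  # (n, m) unit peak
    if normalization == "area":
        lor = lor / (np.pi * half_width[None, :])
    elif normalization != "peak":
        raise ValueError(f"unknown normalization {normalization!r}")
    return SpectrumCurve(axis, lor.sum(axis=1), Q)


def model_spectrum(model, Q: float = constants.Q_DEFAULT,
                   axis: np.ndarray | None = None,
                   normalization: str = "peak") -> SpectrumCurve:
    """Vibration spectrum of a spindle model from its principal frequencies."""
    return vibration_spectrum(model.frequencies(), Q, axis, normalization)


def band_edges(spectrum: SpectrumCurve,
               threshold: float = 0.5) -> tuple[float, float]:
    """Lowest and highest frequencies where S crosses ``threshold * max(S)``.

    Crossings are located by linear interpolation between axis samples.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    s = spectrum.amplitude
    f = spectrum.frequency
    s_max = s.max()
    if s_max <= 0:
        raise ValueError("flat zero spectrum has no band edges")
    level = threshold * s_max
    above = s >= level
    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]

    def interp(i_lo, i_hi):
        if s[i_hi] == s[i_lo]:
            return f[i_hi]
        w = (level - s[i_lo]) / (s[i_hi] - s[i_lo])
        return f[i_lo] + w * (f[i_hi] - f[i_lo])

    f_low = f[i0] if i0 == 0 else interp(i0 - 1, i0)
    f_high = f[i1] if i1 == len(f) - 1 else interp(i1 + 1, i1)
    return float(f_low), float(f_high)


def peak_frequency(spectrum: SpectrumCurve) -> float:
    """Frequency of maximal spectral response [Hz]."""
    return float(spectrum.frequency[int(np.argmax(spectrum.amplitude))])


# ---------------------------------------------------------------------------
# Monte-Carlo field statistics
# ---------------------------------------------------------------------------

@dataclass
class MCStats:
    """Per-point max / mean / min of |E| over time samples and realizations."""

    max: np.ndarray    # (n,) V/m
    mean: np.ndarray
    min: np.ndarray
    n_realizations: int
    n_samples: int
    seed: int
    grid: EvaluationGrid
    clamp_counts: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.min > self.mean + 1e-12) or np.any(self.mean > self.max + 1e-12):
            raise ValueError("MC statistics must satisfy min <= mean <= max")


def pool_stats(frames: list[FieldFrame], seed: int = 0,
               n_realizations: int = 1) -> MCStats:
    """Pool per-point |E| statistics over a list of frames."""
    mags = np.stack([fr.magnitude for fr in frames])
    clamps = (frames[0].clamp_counts if frames[0].clamp_counts is not None
              else None)
    return MCStats(max=mags.max(0), mean=mags.mean(0), min=mags.min(0),
                   n_realizations=n_realizations, n_samples=len(frames),
                   seed=seed, grid=frames[0].grid, clamp_counts=clamps)


def monte_carlo_stats(model, grid: EvaluationGrid, excitation: ExcitationSpec,
                      n_realizations: int = constants.N_REALIZATIONS_DEFAULT,
                      n_samples: int = constants.N_SAMPLES_DEFAULT,
                      n_periods: int = constants.N_PERIODS_DEFAULT,
                      seed: int = 0, medium: MediumModel | None = None,
                      aggregate: str = "auto") -> MCStats:
    """Pooled |E| statistics over random-phase realizations.

    Each realization redraws all MT phases from a child of ``seed``, runs a
    time series of ``n_samples`` frames over ``n_periods`` of the longest
    MT, and the per-point max / mean / min of |E| are pooled over samples
    and realizations.  Reproducible for a fixed seed.
    """
    if excitation.mode is not FeedingMode.RANDOM:
        raise ValueError("Monte-Carlo statistics require random feeding")
    children = np.random.SeedSequence(seed).spawn(n_realizations)
    running_max = np.full(len(grid), -np.inf)
    running_min = np.full(len(grid), np.inf)
    running_sum = np.zeros(len(grid))
    clamps = None
    for child in children:
        exc = ExcitationSpec(mode=FeedingMode.RANDOM,
                             antinode_amplitude=excitation.antinode_amplitude,
                             Q=excitation.Q, damped=excitation.damped,
                             seed=int(child.generate_state(1)[0] % (2 ** 31)))
        assign_phases(model, exc)
        frames = time_series(model, exc, grid, n_periods=n_periods,
                             n_samples=n_samples, medium=medium,
                             aggregate=aggregate)
        mags = np.stack([fr.magnitude for fr in frames])
        running_max = np.maximum(running_max, mags.max(0))
        running_min = np.minimum(running_min, mags.min(0))
        running_sum += mags.mean(0)
        clamps = frames[0].clamp_counts
    return MCStats(max=running_max, mean=running_sum / n_realizations,
                   min=running_min, n_realizations=n_realizations,
                   n_samples=n_samples, seed=seed, grid=grid,
                   clamp_counts=clamps)


# ---------------------------------------------------------------------------
# spatial dynamic range
# ---------------------------------------------------------------------------

def spatial_dynamic_range(source: FieldFrame | MCStats,
                          max_separation: float = 500.0,
                          which: str = "magnitude") -> float:
    """Largest log10 |E| ratio between points within ``max_separation`` nm.

    Clamped points and exact zeros are excluded.  For plane grids the pair
    search runs as a sliding circular minimum filter; scattered point sets
    are compared pairwise.  ``which`` selects the field of an
    :class:`MCStats` source (``"max"``, ``"mean"`` or ``"min"``).
    """
    if isinstance(source, MCStats):
        values = getattr(source, which)
        grid = source.grid
        clamp_counts = source.clamp_counts
    else:
        values = source.magnitude
        grid = source.grid
        clamp_counts = source.clamp_counts
    valid = values > 0
    if clamp_counts is not None:
        valid &= clamp_counts == 0
    if valid.sum() < 2:
        raise ValueError("need at least two valid evaluation points")
    logv = np.where(valid, np.log10(np.where(valid, values, 1.0)), np.nan)

    if grid.kind == "plane" and grid.voxel_edge:
        pitch = grid.voxel_edge
        radius = int(np.floor(max_separation / pitch))
        if radius < 1:
            raise ValueError("max_separation below the grid pitch")
        ii, jj = np.mgrid[-radius:radius + 1, -radius:radius + 1]
        footprint = (ii ** 2 + jj ** 2) * pitch ** 2 <= max_separation ** 2
        img = logv.reshape(grid.shape)
        img_min = np.where(np.isnan(img), np.inf, img)
        local_min = ndimage.minimum_filter(img_min, footprint=footprint,
                                           mode="constant", cval=np.inf)
        diff = img - local_min
        diff = diff[np.isfinite(diff)]
        if diff.size == 0:
            raise ValueError("no qualifying point pair")
        return float(diff.max())

    pts = grid.points[valid]
    lv = logv[valid]
    best = 0.0
    found = False
    for i in range(len(pts)):
        d = np.linalg.norm(pts - pts[i], axis=1)
        near = (d <= max_separation) & (d > 0)
        if near.any():
            found = True
            best = max(best, float((lv[i] - lv[near]).max()))
    if not found:
        raise ValueError("no qualifying point pair")
    return best
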