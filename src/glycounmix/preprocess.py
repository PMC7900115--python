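"""Binning and normalization conventions that make spectra NMF-ready.

The analysis operates on a fixed wavenumber grid: the glycan fingerprint
window from 1000 to 1150 cm^-1 in 2 cm^-1 steps gives 76 bins; the extended
window from 952 to 1150 cm^-1 gives 100 bins. Raw scans are binned onto the
grid (mean intensity per half-open bin window) and area-normalized so that
the trapezoidal integral over the analysis window equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum

__all__ = [
    "WavenumberGrid",
    "FINGERPRINT_WINDOW",
    "EXTENDED_WINDOW",
    "n_bins",
    "bin_spectrum",
    "normalize_area",
]

#: Diagnostic C-O/C-C stretching window for glycan identity, cm^-1.
FINGERPRINT_WINDOW: tuple[float, float] = (1000.0, 1150.0)
#: Extended window used for the glucosyl/galactosyl-ceramide standards, cm^-1.
EXTENDED_WINDOW: tuple[float, float] = (952.0, 1150.0)

_ALIGN_TOL = 1e-9


def n_bins(start: float, stop: float, step: float) -> int:
    """Number of bin centers of a start/stop/step grid, endpoints included.

    The closed form is (stop - start)/step + 1; the range must be an integer
    multiple of the step (within 1e-9 relative to the step).

    >>> n_bins(1000, 1150, 2)
    76
    >>> n_bins(952, 1150, 2)
    100
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if stop <= start:
        raise ValueError("stop must exceed start")
    ratio = (stop - start) / step
    if abs(ratio - round(ratio)) > _ALIGN_TOL * max(1.0, abs(ratio)):
        raise ValueError("grid misalignment: (stop - start) not divisible by step")
    return int(round(ratio)) + 1


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber grid defined by start/stop/step (cm^-1).

    `centers` is the strictly increasing vector of bin centers, including
    both endpoints.
    """

    start: float
    stop: float
    step: float
    centers: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", float(self.start))
        object.__setattr__(self, "stop", float(self.stop))
        object.__setattr__(self, "step", float(self.step))
        n = n_bins(self.start, self.stop, self.step)  # validates invariants
        centers = self.start + self.step * np.arange(n)
        object.__setattr__(self, "centers", centers)

    @property
    def n_points(self) -> int:
        return int(self.centers.size)

    @property
    def window(self) -> tuple[float, float]:
        return (float(self.start), float(self.stop))

    def edges(self) -> np.ndarray:
        """Bin edges; bin b spans [centers[b] - step/2, centers[b] + step/2)."""
        return np.concatenate(
            [self.centers - self.step / 2.0, [self.centers[-1] + self.step / 2.0]]
        )


#: Default grids matching the two analysis windows.
def fingerprint_grid(step: float = 2.0) -> WavenumberGrid:
    return WavenumberGrid(*FINGERPRINT_WINDOW, step)


def extended_grid(step: float = 2.0) -> WavenumberGrid:
    return WavenumberGrid(*EXTENDED_WINDOW, step)


def bin_spectrum(spectrum: Spectrum, grid: WavenumberGrid) -> Spectrum:
    """Bin a raw spectrum onto a uniform grid.

    Bin b centered at c_b collects raw points with wavenumber in the
    half-open window [c_b - step/2, c_b + step/2); every raw point lands in
    at most one bin. The bin value is the arithmetic mean of the collected
    intensities, so values stay on the intensity scale regardless of raw
    sampling density. Interior bins that collect no points are filled by
    linear interpolation between neighboring non-empty bins; empty bins at
    the edges take the nearest non-empty value.

    Raises
    ------
    ValueError
        If no raw point falls into any bin ("no overlap with grid").
    """
    edges = grid.edges()
    w, y = spectrum.wavenumbers, spectrum.intensities
    inside = (w >= edges[0]) & (w < edges[-1])
    if not np.any(inside):
        raise ValueError("no overlap with grid")
    idx = np.digitize(w[inside], edges) - 1
    n = grid.n_points
    sums = np.bincount(idx, weights=y[inside], minlength=n)
    counts = np.bincount(idx, minlength=n)
    empty = counts == 0
    values = np.divide(sums, np.where(empty, 1, counts))
    if np.any(empty):
        values[empty] = np.interp(
            grid.centers[empty], grid.centers[~empty], values[~empty]
        )
    meta = dict(spectrum.meta)
    meta["binned"] = f"{grid.start}:{grid.stop}:{grid.step}"
    return Spectrum(grid.centers.copy(), values, meta)


def normalize_area(
    spectrum: Spectrum, window: tuple[float, float] = FINGERPRINT_WINDOW
) -> Spectrum:
    """Scale a spectrum so its trapezoidal area over `window` equals 1.

    Idempotent and invariant to positive rescaling of the input. Raises
    ValueError for a non-positive window area ("degenerate spectrum").
    """
    mask = spectrum.window_mask(window)
    if mask.sum() < 2:
        raise ValueError("degenerate spectrum: fewer than 2 points in window")
    area = float(
        np.trapezoid(spectrum.intensities[mask], spectrum.wavenumbers[mask])
    )
    if area <= 0:
        raise ValueError("degenerate spectrum: non-positive area in window")
    return spectrum.with_intensities(spectrum.intensities / area)
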