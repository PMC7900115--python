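"""Core spectrum container used throughout the package.

An IR spectrum is a pair of same-length vectors: wavenumbers in cm^-1
(strictly increasing) and intensities in linear absorbance / ion-yield
units, plus free-form provenance metadata (species, adduct, m/z, source).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["Spectrum"]


@dataclass
class Spectrum:
    """Paired wavenumber/intensity vectors with provenance metadata.

    Parameters
    ----------
    wavenumbers : array-like of float
        Strictly increasing wavenumbers, cm^-1.
    intensities : array-like of float
        Intensities, arbitrary linear units. Same length as `wavenumbers`.
        Negative values are allowed (e.g. noise below baseline); they are
        only clipped where non-negativity is required (NMF input).
    meta : dict, optional
        Free-form key/value provenance (species, adduct, mz, source, ...).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size == 0:
            raise ValueError("empty spectrum")
        if np.any(~np.isfinite(self.wavenumbers)):
            raise ValueError("non-finite wavenumber")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        self.meta = dict(self.meta)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.wavenumbers.copy(), self.intensities.copy(), dict(self.meta)
        )

    def with_intensities(
        self, intensities: np.ndarray, extra_meta: Mapping | None = None
    ) -> "Spectrum":
        """New spectrum on the same grid with replaced intensities."""
        meta = dict(self.meta)
        if extra_meta:
            meta.update(extra_meta)
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float), meta)

    def same_grid(self, other: "Spectrum", tol: float = 1e-9) -> bool:
        """Whether two spectra share an identical wavenumber grid."""
        return len(self) == len(other) and bool(
            np.allclose(self.wavenumbers, other.wavenumbers, rtol=0, atol=tol)
        )

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of points inside the closed interval `window`."""
        lo, hi = float(window[0]), float(window[1])
        if hi <= lo:
            raise ValueError("window must satisfy hi > lo")
        return (self.wavenumbers >= lo) & (self.wavenumbers <= hi)


def require_common_grid(*spectra: Spectrum) -> None:
    """Raise ValueError unless all spectra share one wavenumber grid."""
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise ValueError("spectra are not on a common wavenumber grid")
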