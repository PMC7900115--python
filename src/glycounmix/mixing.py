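"""Ratio-weighted averaging of pure spectra and agreement scoring.

Under the linear-response assumption, a mixture spectrum is the molar
fraction weighted average of the area-normalized pure spectra. This module
implements that forward model (used to sanity-check measured or simulated
mixtures) and simple agreement metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import FINGERPRINT_WINDOW, normalize_area
from .spectra import Spectrum, require_common_grid

__all__ = ["MixingRatio", "weighted_average_spectra", "compare_spectra"]


@dataclass(frozen=True)
class MixingRatio:
    """Named non-negative weights summing to 1 (molar fractions)."""

    labels: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(self.labels) != len(self.weights):
            raise ValueError("labels and weights must have equal length")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @classmethod
    def from_parts(cls, labels: Sequence[str], parts: Sequence[float]) -> "MixingRatio":
        """Build from unnormalized parts, e.g. (95, 5) -> (0.95, 0.05)."""
        parts = [float(p) for p in parts]
        total = sum(parts)
        if total <= 0:
            raise ValueError("parts must have positive sum")
        return cls(tuple(labels), tuple(p / total for p in parts))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.weights))


def weighted_average_spectra(
    spectra: Sequence[Spectrum],
    ratio: MixingRatio,
    window: tuple[float, float] = FINGERPRINT_WINDOW,
) -> Spectrum:
    """Weight, sum, and area-normalize pure spectra on a common grid.

    Pure spectra are first area-normalized over `window` (weights therefore
    represent fractional spectral contribution, equal to molar fraction
    under the equal-response assumption), combined elementwise as
    sum_i w_i * I_i, and the result is normalized to unit window area.
    """
    if len(spectra) != len(ratio.labels):
        raise ValueError("one spectrum per ratio label required")
    require_common_grid(*spectra)
    normed = [normalize_area(s, window) for s in spectra]
    combined = np.zeros_like(normed[0].intensities)
    for w, s in zip(ratio.weights, normed):
        combined += w * s.intensities
    out = Spectrum(
        normed[0].wavenumbers.copy(),
        combined,
        {"species": "+".join(f"{l}:{w:g}" for l, w in ratio.as_dict().items())},
    )
    return normalize_area(out, window)


def compare_spectra(
    a: Spectrum, b: Spectrum, window: tuple[float, float] = FINGERPRINT_WINDOW
) -> dict[str, float]:
    """RMS difference, cosine similarity and max |diff| over a window."""
    require_common_grid(a, b)
    mask = a.window_mask(window)
    x = a.intensities[mask]
    y = b.intensities[mask]
    diff = x - y
    rms = float(np.sqrt(np.mean(diff**2)))
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    cosine = float(x @ y / (nx * ny)) if nx > 0 and ny > 0 else float("nan")
    return {"rms": rms, "cosine": cosine, "max_abs": float(np.max(np.abs(diff)))}
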