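"""Synthetic glycolipid fingerprint spectra and mixtures.

No machine-readable experimental spectra are publicly deposited for this
class of cryogenic gas-phase IR measurements, so the package ships a
generator that emulates their statistical structure: per-isomer band
patterns in the 1000-1150 cm^-1 glycan fingerprint window (with at least
one diagnostic band unique to each isomer, e.g. 1065 cm^-1 for the
alpha-galactosyl species), linear scaling of band intensities with molar
fraction, and additive white Gaussian noise whose level sets the
signal-to-noise contrast between the "synthetic standard" and
"biological extract" regimes.

Bands are rendered as unit-height Gaussians; computed stick spectra
(harmonic or anharmonic line lists) can be frequency-scaled, shifted and
broadened onto the same grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import FINGERPRINT_WINDOW, WavenumberGrid
from .spectra import Spectrum

__all__ = [
    "PeakBand",
    "IsomerModel",
    "IsomerLibrary",
    "StickSpectrum",
    "NoiseModel",
    "render_fingerprint",
    "broaden_sticks",
    "simulate_mixture_spectrum",
    "default_library",
]

#: Default Gaussian full width at half maximum for fixture bands, cm^-1.
#: Cryogenic bands are narrow and well resolved; 8 cm^-1 keeps the fixture
#: isomers distinguishable on a 2 cm^-1 grid.
DEFAULT_FWHM = 8.0

_FOUR_LN2 = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class PeakBand:
    """A single absorption band: center (cm^-1), relative intensity, FWHM."""

    center: float
    intensity: float
    fwhm: float = DEFAULT_FWHM

    def __post_init__(self) -> None:
        if self.center <= 0:
            raise ValueError("band center must be positive")
        if self.intensity < 0:
            raise ValueError("band intensity must be non-negative")
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be positive")


@dataclass(frozen=True)
class IsomerModel:
    """Named per-isomer fingerprint model: an ordered list of bands."""

    name: str
    bands: tuple[PeakBand, ...]
    adduct: str = "[M+H]+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if not self.name:
            raise ValueError("isomer model needs a name")


@dataclass(frozen=True)
class IsomerLibrary:
    """A set of isomer fingerprint models sharing one analysis window."""

    models: tuple[IsomerModel, ...]
    window: tuple[float, float] = FINGERPRINT_WINDOW

    def __post_init__(self) -> None:
        object.__setattr__(self, "models", tuple(self.models))
        names = [m.name for m in self.models]
        if len(set(names)) != len(names):
            raise ValueError("isomer names must be pairwise distinct")
        lo, hi = self.window
        for m in self.models:
            if not any(lo <= b.center <= hi and b.intensity > 0 for b in m.bands):
                raise ValueError(
                    f"model {m.name!r} has no positive band inside the window"
                )

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.models]

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, name: str) -> IsomerModel:
        for m in self.models:
            if m.name == name:
                return m
        raise KeyError(f"unknown isomer {name!r}")

    def subset(self, names: Sequence[str]) -> "IsomerLibrary":
        return IsomerLibrary(tuple(self[n] for n in names), self.window)


@dataclass(frozen=True)
class StickSpectrum:
    """A computed line list with a frequency scale factor and shift.

    Each stick at frequency f is placed at ``scale_factor * f + shift``
    before broadening; the shift is signed (cm^-1).
    """

    frequencies: np.ndarray
    intensities: np.ndarray
    scale_factor: float = 1.0
    shift: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        a = np.asarray(self.intensities, dtype=float)
        if f.ndim != 1 or a.ndim != 1 or f.size != a.size:
            raise ValueError("frequencies and intensities must be same-length 1-D")
        if np.any(a < 0):
            raise ValueError("stick intensities must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "intensities", a)


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian noise, parameterized by signal-to-noise.

    ``snr`` is defined as (max clean intensity on the grid) / (noise
    standard deviation). ``snr=None`` (or infinity) means noiseless.
    """

    snr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr is not None and not (self.snr > 0):
            raise ValueError("snr must be positive (or None for noiseless)")

    @property
    def noiseless(self) -> bool:
        return self.snr is None or math.isinf(self.snr)


def _gaussian_profile(
    grid: np.ndarray, center: float, intensity: float, fwhm: float
) -> np.ndarray:
    # unit-height Gaussian: value `intensity` at the band center
    return intensity * np.exp(-_FOUR_LN2 * ((grid - center) / fwhm) ** 2)


def render_fingerprint(model: IsomerModel, grid: WavenumberGrid) -> Spectrum:
    """Render an isomer model as a sum of unit-height Gaussian bands.

    Deterministic and non-negative everywhere; band intensities superpose
    linearly. Raises ValueError for a model without bands.
    """
    if not model.bands:
        raise ValueError("empty model")
    centers = grid.centers
    y = np.zeros_like(centers)
    for band in model.bands:
        y += _gaussian_profile(centers, band.center, band.intensity, band.fwhm)
    return Spectrum(centers.copy(), y, {"species": model.name, "adduct": model.adduct})


def broaden_sticks(
    sticks: StickSpectrum, grid: WavenumberGrid, fwhm: float = DEFAULT_FWHM
) -> Spectrum:
    """Scale, shift and Gaussian-broaden a stick spectrum onto a grid.

    Each stick at frequency f with intensity a contributes a unit-height
    Gaussian of height a centered at ``scale_factor*f + shift``. Sticks
    outside the grid contribute their in-window tails only. The integrated
    area is proportional to the total stick intensity (common fwhm).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    centers = grid.centers
    y = np.zeros_like(centers)
    positions = sticks.scale_factor * sticks.frequencies + sticks.shift
    for pos, a in zip(positions, sticks.intensities):
        y += _gaussian_profile(centers, pos, a, fwhm)
    meta = {"source": "sticks", "scale_factor": sticks.scale_factor,
            "shift": sticks.shift}
    return Spectrum(centers.copy(), y, meta)


def simulate_mixture_spectrum(
    library: IsomerLibrary,
    fractions: Mapping[str, float],
    grid: WavenumberGrid,
    noise: NoiseModel = NoiseModel(),
) -> Spectrum:
    """Simulate a mixture spectrum by linear molar mixing plus noise.

    The clean spectrum is the fraction-weighted sum of the pure renders
    (band intensities scale linearly with molar fraction). Zero-mean
    Gaussian noise with sd = max(clean)/snr is added, drawn from
    ``numpy.random.default_rng(noise.seed)``; the output is bit-reproducible
    for a fixed seed. Negative intensities produced by the noise are kept.

    Raises
    ------
    ValueError
        If fractions are negative, do not sum to 1 (within 1e-9), or name
        an isomer absent from the library.
    """
    fracs = dict(fractions)
    for name in fracs:
        try:
            library[name]
        except KeyError as exc:
            raise ValueError(str(exc)) from exc
    if any(f < 0 for f in fracs.values()):
        raise ValueError("fractions must be non-negative")
    total = sum(fracs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {total}")

    clean = np.zeros_like(grid.centers)
    for name, f in fracs.items():
        if f == 0:
            continue
        clean = clean + f * render_fingerprint(library[name], grid).intensities

    meta = {
        "species": "+".join(f"{n}:{fracs[n]:g}" for n in sorted(fracs)),
        "fractions": dict(fracs),
        "snr": noise.snr,
        "seed": noise.seed,
    }
    if noise.noiseless:
        return Spectrum(grid.centers.copy(), clean, meta)
    sd = float(np.max(clean)) / float(noise.snr)
    rng = np.random.default_rng(noise.seed)
    noisy = clean + rng.normal(0.0, sd, size=clean.shape)
    return Spectrum(grid.centers.copy(), noisy, meta)


def _equalize_response(
    models: Sequence[IsomerModel],
    window: tuple[float, float],
    target_area: float = 100.0,
) -> tuple[IsomerModel, ...]:
    """Rescale band intensities so every model renders the same window area.

    This encodes the equal-response assumption of linear spectral mixing
    (equal integrated absorbance per mole for all isomers), under which
    molar fractions and spectral-area fractions coincide. Unequal response
    factors can be reintroduced deliberately to study quantification bias.
    """
    fine = WavenumberGrid(window[0], window[1], 0.1)
    out = []
    for m in models:
        rendered = render_fingerprint(m, fine)
        area = float(np.trapezoid(rendered.intensities, rendered.wavenumbers))
        scale = target_area / area
        bands = tuple(
            PeakBand(b.center, b.intensity * scale, b.fwhm) for b in m.bands
        )
        out.append(IsomerModel(m.name, bands, m.adduct))
    return tuple(out)


def default_library() -> IsomerLibrary:
    """Four-isomer fixture emulating alpha/beta-Gal/Glc phytosphingosines.

    Band patterns partially overlap (shared backbone vibrations would do the
    same) but every model keeps at least one band whose center is >= 6 cm^-1
    away from every band of every other model, so the isomers remain
    identifiable on a 2 cm^-1 grid. The 1065 cm^-1 band diagnostic for the
    alpha-galactosyl species appears in exactly one model. Band intensities
    are rescaled so all four isomers share the same integrated response
    over the fingerprint window (see `_equalize_response`).
    """
    # All four isomers share two backbone C-O/C-C stretching bands (1040,
    # 1110 cm^-1), the way a common sugar-lipid scaffold would; each adds
    # smaller diagnostic bands whose positions are >= 6 cm^-1 from every
    # band of every other isomer. The shared bands produce the realistic
    # spectral congestion that makes 4-component unmixing harder than the
    # binary case.
    # Every band center stays >= 26 cm^-1 (> 3 fwhm) inside the window so
    # edge truncation is negligible, and every model carries the same
    # intensity multiset, making the integrated responses analytically
    # equal before the numerical equalization.
    backbone = (PeakBand(1040.0, 1.0), PeakBand(1110.0, 0.9))
    models = (
        IsomerModel(
            "alpha-Gal-phytosphingosine",
            backbone + (PeakBand(1030.0, 0.3), PeakBand(1065.0, 0.7)),
        ),
        IsomerModel(
            "beta-Gal-phytosphingosine",
            backbone + (PeakBand(1124.0, 0.3), PeakBand(1080.0, 0.7)),
        ),
        IsomerModel(
            "alpha-Glc-phytosphingosine",
            backbone + (PeakBand(1026.0, 0.3), PeakBand(1095.0, 0.7)),
        ),
        IsomerModel(
            "beta-Glc-phytosphingosine",
            backbone + (PeakBand(1048.0, 0.3), PeakBand(1104.0, 0.7)),
        ),
    )
    return IsomerLibrary(
        _equalize_response(models, FINGERPRINT_WINDOW), FINGERPRINT_WINDOW
    )
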