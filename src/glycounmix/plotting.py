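"""Minimal figure helpers for the study pipelines (matplotlib, Agg-safe)."""

from __future__ import annotations

from typing import Sequence

from .deconvolution import AbundanceTable
from .spectra import Spectrum


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_spectra(
    spectra: Sequence[Spectrum], labels: Sequence[str], path, title: str = ""
) -> None:
    """Overlay spectra with vertical offsets, save to `path`."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4))
    offset = 0.0
    for spectrum, label in zip(spectra, labels):
        span = float(spectrum.intensities.max() - spectrum.intensities.min())
        ax.plot(spectrum.wavenumbers, spectrum.intensities + offset, label=label)
        offset += 1.1 * (span if span > 0 else 1.0)
    ax.set_xlabel("wavenumber / cm$^{-1}$")
    ax.set_ylabel("intensity (offset)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_abundances(table: AbundanceTable, path, title: str = "") -> None:
    """Stacked-bar isomer percentages per spectrum, save to `path`."""
    plt = _pyplot()
    pivot = table.pivot()
    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = None
    for isomer in pivot.columns:
        ax.bar(pivot.index, pivot[isomer], bottom=bottom, label=isomer)
        bottom = pivot[isomer] if bottom is None else bottom + pivot[isomer]
    ax.set_ylabel("recovered percentage")
    ax.tick_params(axis="x", rotation=75, labelsize=6)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
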