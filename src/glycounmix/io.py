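"""Readers and writers for spectra, peak lists, result tables, manifests.

On-disk conventions
-------------------
* Spectrum files: two-column delimited text (comma, tab or whitespace),
  wavenumber in cm^-1 then intensity in linear units; '#'-prefixed lines
  are comments, and ``# key: value`` comments round-trip as metadata.
* Peak-list files: three columns (center_cm-1, intensity, fwhm_cm-1) with
  one header line.
* Library files: YAML mapping isomer name -> peak-list path.
* Result tables: tab-delimited text with a header row.
* Run manifests: JSON snapshot of config, seeds, file checksums, timestamps.

No unit conversion happens on I/O; cm^-1 and linear absorbance are
canonical.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .spectra import Spectrum
from .synthetic import IsomerLibrary, IsomerModel, PeakBand

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_peak_list",
    "write_peak_list",
    "load_library",
    "RunManifest",
]

_META_RE = re.compile(r"^#\s*([^:]+?)\s*:\s*(.*)$")


def _split_row(line: str) -> list[str]:
    if "," in line:
        return [c.strip() for c in line.split(",")]
    if "\t" in line:
        return [c.strip() for c in line.split("\t")]
    return line.split()


def _parse_columns(path, n_cols: int, skip_header: bool = False):
    """Parse a delimited text file into float columns plus '#' metadata."""
    meta: dict[str, str] = {}
    rows: list[tuple[float, ...]] = []
    text = Path(path).read_text()
    header_skipped = not skip_header
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _META_RE.match(line)
            if m:
                meta[m.group(1)] = m.group(2)
            continue
        if not header_skipped:
            header_skipped = True
            continue
        cells = _split_row(line)
        if len(cells) < n_cols:
            raise ValueError(f"{path}: line {lineno}: expected {n_cols} columns")
        try:
            rows.append(tuple(float(c) for c in cells[:n_cols]))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
    return rows, meta


def read_spectrum(path) -> Spectrum:
    """Read a two-column spectrum file; rows are sorted by wavenumber.

    Raises ValueError with the offending line number for non-numeric cells,
    and for duplicate wavenumbers.
    """
    rows, meta = _parse_columns(path, 2)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        raise ValueError(f"{path}: duplicate wavenumber")
    return Spectrum(arr[:, 0], arr[:, 1], meta)


def write_spectrum(spectrum: Spectrum, path, delimiter: str = ",") -> None:
    """Write a spectrum as delimited text; metadata as '# key: value' lines.

    Values are formatted with 17 significant digits so read/write
    round-trips are exact. Refuses to write an empty spectrum.
    """
    if len(spectrum) == 0:  # unreachable via Spectrum, guards raw callers
        raise ValueError("refusing to write empty spectrum")
    lines = []
    for key, value in spectrum.meta.items():
        if isinstance(value, (dict, list, tuple)):
            value = json.dumps(value)
        lines.append(f"# {key}: {value}")
    for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
        lines.append(f"{w:.17g}{delimiter}{y:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_peak_list(path) -> tuple[PeakBand, ...]:
    """Read a three-column (center, intensity, fwhm) peak list, one header line."""
    rows, _ = _parse_columns(path, 3, skip_header=True)
    if not rows:
        raise ValueError(f"{path}: no peaks")
    return tuple(PeakBand(c, i, f) for c, i, f in rows)


def write_peak_list(bands: Iterable[PeakBand], path) -> None:
    lines = ["center_cm-1\tintensity\tfwhm_cm-1"]
    for b in bands:
        lines.append(f"{b.center:.17g}\t{b.intensity:.17g}\t{b.fwhm:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_library(path) -> IsomerLibrary:
    """Load an isomer library from a YAML config mapping name -> peak list.

    Optional top-level key ``window: [lo, hi]``; peak-list paths are
    resolved relative to the config file.
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, Mapping) or not cfg:
        raise ValueError(f"{path}: expected a mapping of isomer -> peak list")
    window = tuple(cfg.get("window", (1000.0, 1150.0)))
    models = []
    for name, entry in cfg.items():
        if name == "window":
            continue
        bands = read_peak_list(path.parent / entry)
        models.append(IsomerModel(str(name), bands))
    return IsomerLibrary(tuple(models), (float(window[0]), float(window[1])))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, checksums, timestamps."""

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def record_seed(self, stage: str, seed: int) -> None:
        self.seeds[stage] = int(seed)

    def record_file(self, path) -> None:
        self.checksums[str(path)] = _sha256(path)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)
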