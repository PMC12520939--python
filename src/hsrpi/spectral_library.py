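"""Spectral axis and the four-component C–H reference library.

Hyperspectral stimulated-Raman stacks over the C–H stretch window
(2800–3050 cm⁻¹) are unmixed against four reference standards: a protein
standard (BSA, CH₃ stretch near 2930 cm⁻¹), a nucleic-acid standard
(purified DNA, band near 2955 cm⁻¹), an unsaturated-lipid standard
(triolein, CH₂ near 2850 plus the olefinic =C–H near 3010 cm⁻¹) and a
saturated-lipid standard (palmitic acid, CH₂ 2850 with a 2880 shoulder).
This module defines the spectral axis, reference spectra and the assembled
library (the unmixing design matrix), plus synthesis of idealized
Gaussian-band standards so the whole pipeline is testable without
instrument data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPONENTS",
    "DEFAULT_PEAK_TABLES",
    "SpectralAxis",
    "ReferenceSpectrum",
    "SpectralLibrary",
    "DegenerateLibraryError",
    "build_spectral_axis",
    "default_axis",
    "synthesize_reference_spectrum",
    "assemble_library",
    "default_library",
    "load_reference_csv",
    "save_reference_csv",
    "load_library_manifest",
]

#: Fixed component order used everywhere downstream (chemical-map pages,
#: truth CSV columns, abundance vectors).
COMPONENTS = ("protein", "nucleic_acid", "unsaturated_lipid", "saturated_lipid")

#: Idealized Gaussian band tables (center cm⁻¹, FWHM-ish width cm⁻¹, height a.u.)
#: for synthetic standards.  Band positions follow standard C–H assignments;
#: widths and heights are free parameters of the simulator, not measured values.
DEFAULT_PEAK_TABLES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "protein": ((2930.0, 18.0, 1.0), (2875.0, 22.0, 0.35)),
    "nucleic_acid": ((2955.0, 16.0, 1.0), (2890.0, 24.0, 0.35)),
    "unsaturated_lipid": ((2850.0, 15.0, 0.75), (3010.0, 12.0, 0.55), (2895.0, 20.0, 0.25)),
    "saturated_lipid": ((2850.0, 12.0, 1.0), (2880.0, 15.0, 0.45)),
}

_MIN_SINGULAR_VALUE = 1e-6


class DegenerateLibraryError(ValueError):
    """Raised when the four reference spectra are not linearly independent."""


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered Raman-shift axis (cm⁻¹) of a hyperspectral stack."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise ValueError("spectral axis needs at least 2 channels")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)

    @property
    def n_channels(self) -> int:
        return int(self.wavenumbers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        # tolerance accommodates axes round-tripped through text formats
        return self.wavenumbers.shape == other.wavenumbers.shape and np.allclose(
            self.wavenumbers, other.wavenumbers, rtol=0, atol=1e-6
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.wavenumbers.size, float(self.wavenumbers[0]), float(self.wavenumbers[-1])))


@dataclass
class ReferenceSpectrum:
    """One standard's spectrum on a given axis.

    ``normalization`` is ``"raw"`` for as-synthesized/as-loaded intensities
    and ``"l2"`` after unit-Euclidean-norm scaling inside a library.
    """

    component_name: str
    axis: SpectralAxis
    intensities: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.component_name not in COMPONENTS:
            raise ValueError(f"unknown component {self.component_name!r}; expected one of {COMPONENTS}")
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (self.axis.n_channels,):
            raise ValueError("intensity vector length must match the axis channel count")
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite and nonnegative")
        if self.normalization not in ("raw", "l2"):
            raise ValueError("normalization must be 'raw' or 'l2'")
        self.intensities = y


@dataclass
class SpectralLibrary:
    """The unmixing design: four l2-normalized references on one axis."""

    axis: SpectralAxis
    references: tuple[ReferenceSpectrum, ...]
    matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if tuple(r.component_name for r in self.references) != COMPONENTS:
            raise ValueError(f"references must be exactly {COMPONENTS} in order")
        for r in self.references:
            if r.axis != self.axis:
                raise ValueError("all references must share the library axis")
        X = np.column_stack([r.intensities for r in self.references])
        smin = np.linalg.svd(X, compute_uv=False)[-1]
        if smin <= _MIN_SINGULAR_VALUE:
            raise DegenerateLibraryError(
                f"reference spectra are (near-)linearly dependent: smallest singular value {smin:.3g}"
            )
        self.matrix = X  # C x 4

    @property
    def components(self) -> tuple[str, ...]:
        return COMPONENTS


def build_spectral_axis(start_cm1: float, end_cm1: float, n_channels: int) -> SpectralAxis:
    """Evenly spaced axis from ``start_cm1`` to ``end_cm1`` inclusive."""
    if not start_cm1 < end_cm1:
        raise ValueError(f"start ({start_cm1}) must be below end ({end_cm1})")
    if n_channels < 2:
        raise ValueError("n_channels must be at least 2")
    return SpectralAxis(np.linspace(start_cm1, end_cm1, int(n_channels)))


def default_axis(n_channels: int = 64) -> SpectralAxis:
    """Default C–H window axis, 2800–3050 cm⁻¹ inclusive."""
    return build_spectral_axis(2800.0, 3050.0, n_channels)


def synthesize_reference_spectrum(
    component_name: str,
    axis: SpectralAxis,
    peaks: Sequence[tuple[float, float, float]],
) -> ReferenceSpectrum:
    """Sum-of-Gaussians idealized standard spectrum.

    ``peaks`` is a list of (center cm⁻¹, width cm⁻¹, height a.u.) triples;
    each contributes ``height * exp(-(ν - center)² / (2 width²))``.
    """
    if len(peaks) == 0:
        raise ValueError("peak list must be non-empty")
    wn = axis.wavenumbers
    y = np.zeros_like(wn)
    for center, width, height in peaks:
        if width <= 0 or height <= 0:
            raise ValueError("peak widths and heights must be positive")
        y += height * np.exp(-0.5 * ((wn - center) / width) ** 2)
    return ReferenceSpectrum(component_name, axis, y, normalization="raw")


def assemble_library(
    specs: Sequence[ReferenceSpectrum],
    target_axis: SpectralAxis,
) -> SpectralLibrary:
    """Resample four references onto ``target_axis``, l2-normalize, validate.

    Linear interpolation; zero outside each source spectrum's span.  Raises
    :class:`DegenerateLibraryError` if the resulting columns are not
    linearly independent (e.g. duplicated standards or out-of-band peaks).
    """
    names = [s.component_name for s in specs]
    if sorted(names) != sorted(COMPONENTS):
        raise ValueError(f"need exactly one spectrum per component {COMPONENTS}, got {names}")
    by_name = {s.component_name: s for s in specs}
    resampled = []
    for name in COMPONENTS:
        src = by_name[name]
        y = np.interp(target_axis.wavenumbers, src.axis.wavenumbers, src.intensities, left=0.0, right=0.0)
        norm = float(np.linalg.norm(y))
        if norm == 0.0:
            raise DegenerateLibraryError(f"component {name!r} resamples to an all-zero spectrum")
        resampled.append(ReferenceSpectrum(name, target_axis, y / norm, normalization="l2"))
    return SpectralLibrary(target_axis, tuple(resampled))


def default_library(axis: SpectralAxis | None = None) -> SpectralLibrary:
    """Library of the four synthetic standards on ``axis`` (default 64-channel)."""
    axis = axis or default_axis()
    specs = [synthesize_reference_spectrum(name, axis, DEFAULT_PEAK_TABLES[name]) for name in COMPONENTS]
    return assemble_library(specs, axis)


# ---------------------------------------------------------------------------
# CSV / manifest I/O

def save_reference_csv(spectrum: ReferenceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": spectrum.axis.wavenumbers, "intensity": spectrum.intensities}
    ).to_csv(path, index=False, float_format="%.12g")


def load_reference_csv(path: str | Path, component_name: str) -> ReferenceSpectrum:
    """Read a two-column ``wavenumber_cm1,intensity`` standard spectrum."""
    df = pd.read_csv(path)
    missing = {"wavenumber_cm1", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    order = np.argsort(df["wavenumber_cm1"].to_numpy())
    axis = SpectralAxis(df["wavenumber_cm1"].to_numpy(float)[order])
    return ReferenceSpectrum(component_name, axis, df["intensity"].to_numpy(float)[order])


def load_library_manifest(path: str | Path) -> SpectralLibrary:
    """Build a library from a JSON manifest.

    Schema::

        {"axis": {"start_cm1": 2800, "end_cm1": 3050, "n_channels": 64},
         "components": {"protein": "bsa.csv", ...}}

    Component CSV paths are resolved relative to the manifest file.
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    ax = spec["axis"]
    axis = build_spectral_axis(ax["start_cm1"], ax["end_cm1"], ax["n_channels"])
    specs = [
        load_reference_csv(path.parent / spec["components"][name], name) for name in COMPONENTS
    ]
    return assemble_library(specs, axis)


def _as_assembled(library: SpectralLibrary) -> SpectralLibrary:
    """Re-assembling an assembled library is a no-op (idempotence helper)."""
    return assemble_library([replace(r) for r in library.references], library.axis)
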