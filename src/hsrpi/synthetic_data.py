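"""Seeded synthetic hyperspectral cohorts with ground truth.

No raw images from the study are deposited, so every downstream stage is
exercised on simulated data: dissociated cells rendered as non-overlapping
disks on a dark background, each pixel's spectrum a nonnegative mixture of
the four reference standards plus additive Gaussian channel noise.  Eleven
cell classes (six acute-leukemia subtypes and five normal hematopoietic
populations) carry class-specific mean abundance profiles encoding the
study's qualitative contrasts; see ``data/class_profiles.yaml``.

Cell-to-cell biological variation is log-normal (per-component CV), with an
optional per-cell multiplicative "sample effect" factor mimicking
inter-patient intensity variation.  The recorded ground-truth abundance of
each cell is the *rendered* abundance, i.e. includes that factor, so the
truth tables are exactly what a perfect unmixing would recover.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .spectral_library import COMPONENTS, SpectralLibrary, default_library

__all__ = [
    "CLASS_LABELS",
    "ClassProfile",
    "CellGroundTruth",
    "CohortConfig",
    "PlacementError",
    "load_default_profiles",
    "sample_cells",
    "render_field",
    "generate_cohort",
]

CLASS_LABELS = (
    "AML-M2", "AML-M3", "AML-M4", "AML-M5",
    "ALL-Ph-", "ALL-Ph+",
    "HSPC", "granulocyte", "monocyte", "B_cell", "T_cell",
)

#: Subset used by the default end-to-end leukemia-subtype benchmark.
LEUKEMIA_CLASSES = CLASS_LABELS[:6]

TRUTH_CSV_COLUMNS = ["cell_id", "class"] + list(COMPONENTS) + ["area_px"]


class PlacementError(RuntimeError):
    """Cells could not be placed without overlap within the attempt budget."""


@dataclass
class ClassProfile:
    """Population-level parameters for one cell class."""

    class_label: str
    mean_abundance: np.ndarray  # 4-vector, component order = COMPONENTS
    cv_abundance: float = 0.12
    mean_radius_px: float = 8.0
    cv_radius: float = 0.06

    def __post_init__(self) -> None:
        mu = np.asarray(self.mean_abundance, dtype=float)
        if mu.shape != (4,) or np.any(mu < 0):
            raise ValueError("mean_abundance must be a nonnegative 4-vector")
        if not (0 < self.cv_abundance <= 1) or not (0 < self.cv_radius <= 1):
            raise ValueError("CV values must lie in (0, 1]")
        if self.mean_radius_px < 2:
            raise ValueError("mean_radius_px must be >= 2")
        self.mean_abundance = mu


@dataclass
class CellGroundTruth:
    cell_id: int
    class_label: str
    center: tuple[int, int] | None = None  # (row, col); set at render time
    radius_px: float = 0.0
    true_abundance: np.ndarray = field(default_factory=lambda: np.zeros(4))
    true_area_px: int = 0


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort.

    ``patient_cv`` is the CV of the per-cell multiplicative intensity
    factor (0 disables it).  Cells are distributed over as many fields of
    ``image_size`` as needed so that no field holds more than
    ``cells_per_field`` cells.
    """

    classes: Sequence[ClassProfile]
    cells_per_class: int = 30
    image_size: tuple[int, int] = (192, 192)
    cells_per_field: int = 10
    noise_sigma: float = 0.02
    background_level: float = 0.0
    patient_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_class < 1:
            raise ValueError("cells_per_class must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.cells_per_field < 1:
            raise ValueError("cells_per_field must be >= 1")


def load_default_profiles(
    labels: Iterable[str] | None = None,
    path: str | Path | None = None,
) -> list[ClassProfile]:
    """Load class profiles from YAML (the packaged defaults if no path)."""
    if path is None:
        text = (importlib.resources.files("hsrpi") / "data" / "class_profiles.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)["classes"]
    labels = list(labels) if labels is not None else list(raw)
    profiles = []
    for label in labels:
        entry = raw[label]
        profiles.append(
            ClassProfile(
                class_label=label,
                mean_abundance=np.array([entry["mean_abundance"][c] for c in COMPONENTS]),
                cv_abundance=float(entry["cv_abundance"]),
                mean_radius_px=float(entry["mean_radius_px"]),
                cv_radius=float(entry["cv_radius"]),
            )
        )
    return profiles


def _lognormal(rng: np.random.Generator, mean: np.ndarray | float, cv: float, size=None) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and CV.

    A zero mean yields exactly zero (a component a class simply lacks).
    """
    mean = np.asarray(mean, dtype=float)
    sigma2 = np.log1p(cv**2)
    mu = np.log(np.where(mean > 0, mean, 1.0)) - sigma2 / 2.0
    draws = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)
    return np.where(np.broadcast_to(mean, np.shape(draws)) > 0, draws, 0.0)


def sample_cells(profile: ClassProfile, n: int, rng: np.random.Generator) -> list[CellGroundTruth]:
    """Draw ``n`` cells' abundances and radii for one class.

    Abundances and radii are log-normal around the profile means with the
    profile CVs.  Positions and areas are assigned later by
    :func:`render_field`; cell ids start at 1 and are local to this call.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    abundances = np.column_stack(
        [_lognormal(rng, profile.mean_abundance[j], profile.cv_abundance, size=n) for j in range(4)]
    )
    radii = _lognormal(rng, profile.mean_radius_px, profile.cv_radius, size=n)
    return [
        CellGroundTruth(
            cell_id=i + 1,
            class_label=profile.class_label,
            radius_px=float(radii[i]),
            true_abundance=abundances[i],
        )
        for i in range(n)
    ]


def _disk_footprint(center: tuple[int, int], radius: float, shape: tuple[int, int]):
    r0, c0 = center
    rad = int(np.ceil(radius))
    rows = np.arange(max(0, r0 - rad), min(shape[0], r0 + rad + 1))
    cols = np.arange(max(0, c0 - rad), min(shape[1], c0 + rad + 1))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return rr[inside], cc[inside]


def render_field(
    cells: Sequence[CellGroundTruth],
    library: SpectralLibrary,
    config: CohortConfig,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one field; returns ``(cube H×W×C, truth label mask H×W)``.

    Cell centers are rejection-sampled until disks are disjoint and fully
    inside the frame (``max_attempts`` per cell, else
    :class:`PlacementError`).  Each in-cell pixel's spectrum is
    ``X @ (factor * true_abundance)`` plus background and i.i.d. Gaussian
    channel noise; the sample-effect ``factor`` is folded into the cell's
    recorded ``true_abundance`` and the rendered pixel count into
    ``true_area_px``.  Mask pixels carry the cell's ``cell_id``.
    """
    H, W = config.image_size
    X = library.matrix  # C x 4
    C = X.shape[0]
    mask = np.zeros((H, W), dtype=np.uint16)
    cube = np.full((H, W, C), float(config.background_level), dtype=np.float64)

    placed: list[tuple[int, int, float]] = []
    for cell in cells:
        rad = cell.radius_px
        if 2 * rad + 2 >= min(H, W):
            raise PlacementError(f"cell radius {rad:.1f} px does not fit a {H}x{W} field")
        lo_r, hi_r = int(np.ceil(rad)) + 1, H - int(np.ceil(rad)) - 2
        lo_c, hi_c = int(np.ceil(rad)) + 1, W - int(np.ceil(rad)) - 2
        for _ in range(max_attempts):
            r0 = int(rng.integers(lo_r, hi_r + 1))
            c0 = int(rng.integers(lo_c, hi_c + 1))
            if all((r0 - r) ** 2 + (c0 - c) ** 2 > (rad + prad + 1) ** 2 for r, c, prad in placed):
                break
        else:
            raise PlacementError(
                f"could not place cell {cell.cell_id} after {max_attempts} attempts; "
                f"reduce cells_per_field or enlarge image_size"
            )
        placed.append((r0, c0, rad))
        if config.patient_cv > 0:
            factor = float(_lognormal(rng, 1.0, config.patient_cv))
        else:
            factor = 1.0
        cell.true_abundance = cell.true_abundance * factor
        cell.center = (r0, c0)
        rr, cc = _disk_footprint((r0, c0), rad, (H, W))
        cell.true_area_px = int(rr.size)
        cube[rr, cc, :] += X @ cell.true_abundance
        mask[rr, cc] = cell.cell_id

    if config.noise_sigma > 0:
        cube += rng.normal(0.0, config.noise_sigma, size=cube.shape)
    return cube, mask


def generate_cohort(config: CohortConfig, out_dir: str | Path, library: SpectralLibrary | None = None) -> dict:
    """Write a full cohort to ``out_dir`` and return its manifest.

    Outputs per field: ``field_###.tif`` (multi-page float32, one page per
    channel, ascending wavenumber) and ``field_###_mask.tif`` (uint16 truth
    labels).  Plus ``axis.json`` (wavenumber sidecar), ``truth.csv`` and
    ``manifest.json``.  Cell ids are global and appear verbatim in masks.
    Deterministic for a fixed ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library = library or default_library()
    rng = np.random.default_rng(config.seed)

    # sample all cells, then deal them into fields round-robin by class block
    all_cells: list[CellGroundTruth] = []
    for profile in config.classes:
        cells = sample_cells(profile, config.cells_per_class, rng)
        all_cells.extend(cells)
    for gid, cell in enumerate(all_cells, start=1):
        cell.cell_id = gid
    if len(all_cells) > 65535:
        raise ValueError("cohort exceeds uint16 mask capacity")

    fields = [
        all_cells[i : i + config.cells_per_field]
        for i in range(0, len(all_cells), config.cells_per_field)
    ]
    manifest: dict = {
        "seed": config.seed,
        "image_size": list(config.image_size),
        "noise_sigma": config.noise_sigma,
        "background_level": config.background_level,
        "patient_cv": config.patient_cv,
        "classes": [p.class_label for p in config.classes],
        "cells_per_class": config.cells_per_class,
        "fields": [],
    }
    axis_path = out / "axis.json"
    axis_path.write_text(json.dumps({"wavenumbers": library.axis.wavenumbers.tolist()}))

    for i, cells in enumerate(fields):
        cube, mask = render_field(cells, library, config, rng)
        img_path = out / f"field_{i:03d}.tif"
        mask_path = out / f"field_{i:03d}_mask.tif"
        tifffile.imwrite(img_path, np.moveaxis(cube, 2, 0).astype(np.float32), photometric="minisblack")
        tifffile.imwrite(mask_path, mask)
        manifest["fields"].append(
            {
                "image": img_path.name,
                "mask": mask_path.name,
                "cell_ids": [c.cell_id for c in cells],
            }
        )

    truth = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in all_cells],
            "class": [c.class_label for c in all_cells],
            **{
                comp: [c.true_abundance[j] for c in all_cells]
                for j, comp in enumerate(COMPONENTS)
            },
            "area_px": [c.true_area_px for c in all_cells],
        }
    )[TRUTH_CSV_COLUMNS]
    truth.to_csv(out / "truth.csv", index=False, float_format="%.8g")
    manifest["truth_csv"] = "truth.csv"
    manifest["axis_json"] = axis_path.name
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_field(dataset_dir: str | Path, field_entry: Mapping) -> tuple[np.ndarray, np.ndarray]:
    """Read one field's (cube H×W×C, mask) back from a cohort directory."""
    d = Path(dataset_dir)
    cube = np.moveaxis(tifffile.imread(d / field_entry["image"]).astype(np.float64), 0, 2)
    mask = tifffile.imread(d / field_entry["mask"])
    return cube, mask
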