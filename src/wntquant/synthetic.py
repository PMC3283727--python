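"""Synthetic ground-truth generators for every downstream stage.

Three generators, each emulating one measured data type:

- cell-population tables: a two-population (non-dividing/dividing) mixture of
  per-cell marker volumes with a linear Calcein-Hoechst relation, dividing
  cells scaled jointly by a known factor (~2, the DNA/volume doubling through
  S/M phase);
- phantom image stacks: ellipsoidal cells with a nested nucleus, a
  whole-cell (Calcein) body and a finite-thickness membrane (DiI) shell,
  rendered on a calibrated voxel grid with analytic ground-truth volumes;
- immunoblot datasets: standard lanes on an exact intensity-mass line plus
  sample lanes, with additive Gaussian densitometry noise.

All randomness flows through explicit integer seeds; identical parameters
and seed reproduce outputs bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import gaussian

from .volumes import CHANNEL_ROLES, ImageStack, VoxelCalibration

__all__ = [
    "PopulationParams",
    "CellPhantom",
    "PhantomSpec",
    "BlotSimParams",
    "BlotDataset",
    "generate_cell_population",
    "render_image_stack",
    "generate_blot_dataset",
    "write_image_stack",
]

#: pooled non-dividing marker means (pL) used as generator defaults
DEFAULT_ND_MEANS = (1.51, 0.53, 1.89)  # calcein, hoechst, dii


@dataclass(frozen=True)
class PopulationParams:
    """Two-population (non-dividing / dividing) volume-mixture parameters.

    ``cv`` is the coefficient of variation of the lognormal cell-size factor
    applied along the Hoechst (DNA) axis; the Calcein and DiI volumes are
    derived from the Hoechst volume through per-cell marker ratios perturbed
    by ``ratio_noise_sd`` (relative SD), which reproduces the larger marginal
    scatter of the cytoplasmic markers.  Volumes are lognormal, keeping them
    positive and right-skewed.
    """

    n_cells: int = 469
    dividing_fraction: float = 0.085
    mean_volumes_nd: tuple[float, float, float] = DEFAULT_ND_MEANS
    d_over_nd_ratio: float = 2.0
    cv: float = 0.25
    ratio_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.dividing_fraction <= 1.0:
            raise ValueError("dividing_fraction must lie in [0, 1]")
        if min(self.mean_volumes_nd) <= 0:
            raise ValueError("all mean volumes must be > 0")
        if self.d_over_nd_ratio <= 0:
            raise ValueError("d_over_nd_ratio must be > 0")
        if self.cv < 0 or self.ratio_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")


def _lognormal_factor(rng: np.random.Generator, rel_sd: float, n: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1."""
    if rel_sd == 0:
        return np.ones(n)
    sigma2 = math.log1p(rel_sd**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def generate_cell_population(params: PopulationParams) -> pd.DataFrame:
    """Per-cell marker volumes (pL) with hidden true ND/D labels.

    Dividing cells scale all three marker volumes jointly by
    ``d_over_nd_ratio``.  With ``cv=0`` and ``ratio_noise_sd=0`` every
    D-labelled cell's volumes are exactly ``d_over_nd_ratio`` times the
    non-dividing means.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    mean_c, mean_h, mean_d = params.mean_volumes_nd

    dividing = rng.random(n) < params.dividing_fraction
    scale = np.where(dividing, params.d_over_nd_ratio, 1.0)

    size = _lognormal_factor(rng, params.cv, n)
    hoechst = mean_h * scale * size
    calcein = hoechst * (mean_c / mean_h) * _lognormal_factor(
        rng, params.ratio_noise_sd, n
    )
    dii = calcein * (mean_d / mean_c) * _lognormal_factor(
        rng, params.ratio_noise_sd, n
    )

    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "v_calcein_pl": calcein,
            "v_hoechst_pl": hoechst,
            "v_dii_pl": dii,
            "true_label": np.where(dividing, "D", "ND"),
        }
    ).set_index("cell_id")


# ---------------------------------------------------------------------------
# phantom image stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellPhantom:
    """One ellipsoidal cell: nested nucleus, cell body, membrane shell.

    All lengths in micrometres.  The DiI shell extends outward from the cell
    surface by ``shell_thickness`` (the stain marks the membrane and the
    near-membrane cytoplasm, not the bilayer alone), so the filled DiI object
    is an ellipsoid with semi-axes ``cell_semiaxes + shell_thickness``.
    """

    center: tuple[float, float, float]            # z, y, x (um)
    cell_semiaxes: tuple[float, float, float]     # z, y, x (um)
    nucleus_semiaxes: tuple[float, float, float]  # z, y, x (um)
    shell_thickness: float = 1.0

    def __post_init__(self) -> None:
        if min(self.cell_semiaxes) <= 0 or min(self.nucleus_semiaxes) < 0:
            raise ValueError("semi-axes must be positive")
        if any(nu > ce for nu, ce in zip(self.nucleus_semiaxes, self.cell_semiaxes)):
            raise ValueError("nucleus semi-axes must not exceed cell semi-axes")
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be >= 0")

    @property
    def outer_semiaxes(self) -> tuple[float, float, float]:
        t = self.shell_thickness
        return tuple(a + t for a in self.cell_semiaxes)

    def true_volumes_pl(self) -> dict[str, float]:
        """Analytic marker volumes in pL (4/3 pi abc / 1000)."""
        def vol(axes: Sequence[float]) -> float:
            return 4.0 / 3.0 * math.pi * axes[0] * axes[1] * axes[2] / 1000.0

        return {
            "calcein": vol(self.cell_semiaxes),
            "hoechst": vol(self.nucleus_semiaxes),
            "dii": vol(self.outer_semiaxes),
        }


@dataclass(frozen=True)
class PhantomSpec:
    """A set of cell phantoms plus rendering (intensity/noise) settings."""

    cells: tuple[CellPhantom, ...] = ()
    intensities: dict | None = None     # role -> AU; default 1000 each
    background: float = 100.0           # AU
    noise_sd: float = 0.0               # AU, additive Gaussian
    blur_sigma: float = 0.0             # um, optional optical blur
    seed: int = 0

    def intensity(self, role: str) -> float:
        levels = self.intensities or {}
        value = float(levels.get(role, 1000.0))
        if value <= self.background:
            raise ValueError(f"{role} intensity must exceed the background level")
        return value


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    calibration: VoxelCalibration,
    center: Sequence[float],
    semiaxes: Sequence[float],
) -> np.ndarray:
    """Voxels whose *centers* lie inside the analytic ellipsoid."""
    if min(semiaxes) <= 0:
        return np.zeros(shape, dtype=bool)
    steps = (calibration.dz, calibration.dy, calibration.dx)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    acc = np.zeros(shape)
    for g, step, c, a in zip(grids, steps, center, semiaxes):
        acc = acc + (((g + 0.5) * step - c) / a) ** 2
    return acc <= 1.0


def render_image_stack(
    spec: PhantomSpec,
    calibration: VoxelCalibration,
    shape: tuple[int, int, int] | None = None,
    allow_truncation: bool = False,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a 3-channel phantom stack; returns (stack, ground-truth table).

    Nucleus voxels carry the Hoechst signal, the whole cell interior carries
    Calcein, and the shell between the cell surface and the outer surface
    carries DiI.  Ground-truth analytic volumes (pL) are returned per cell.
    Phantoms must fit inside the stack unless ``allow_truncation`` is set
    (used to exercise border-exclusion rules).
    """
    steps = np.array([calibration.dz, calibration.dy, calibration.dx])
    if shape is None:
        if spec.cells:
            margin = 2.0  # um
            hi = max(
                (c.center[i] + c.outer_semiaxes[i] + margin)
                for c in spec.cells
                for i in range(3)
            )
            extent = np.array([hi, hi, hi])
        else:
            extent = np.array([10.0, 10.0, 10.0])
        shape = tuple(int(np.ceil(e / s)) for e, s in zip(extent, steps))

    if not allow_truncation:
        for c in spec.cells:
            for i in range(3):
                lo = c.center[i] - c.outer_semiaxes[i]
                hi = c.center[i] + c.outer_semiaxes[i]
                if lo < 0 or hi > shape[i] * steps[i]:
                    raise ValueError(
                        "phantom extends beyond the stack bounds; enlarge the "
                        "stack or pass allow_truncation=True"
                    )

    channels = {
        role: np.full(shape, spec.background, dtype=float) for role in CHANNEL_ROLES
    }
    truth_rows = []
    for idx, cell in enumerate(spec.cells, start=1):
        cell_mask = _ellipsoid_mask(shape, calibration, cell.center, cell.cell_semiaxes)
        nuc_mask = _ellipsoid_mask(
            shape, calibration, cell.center, cell.nucleus_semiaxes
        )
        outer_mask = _ellipsoid_mask(
            shape, calibration, cell.center, cell.outer_semiaxes
        )
        channels["calcein"][cell_mask] = spec.intensity("calcein")
        channels["hoechst"][nuc_mask] = spec.intensity("hoechst")
        channels["dii"][outer_mask & ~cell_mask] = spec.intensity("dii")
        truth = cell.true_volumes_pl()
        truth_rows.append(
            {
                "cell_id": idx,
                "true_calcein_pl": truth["calcein"],
                "true_hoechst_pl": truth["hoechst"],
                "true_dii_pl": truth["dii"],
            }
        )

    rng = np.random.default_rng(spec.seed)
    for role, img in channels.items():
        if spec.blur_sigma > 0:
            sigma_vox = [spec.blur_sigma / s for s in steps]
            img = gaussian(img, sigma=sigma_vox, preserve_range=True)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels[role] = img

    truth_df = pd.DataFrame(
        truth_rows,
        columns=["cell_id", "true_calcein_pl", "true_hoechst_pl", "true_dii_pl"],
    ).set_index("cell_id")
    return ImageStack(channels, calibration), truth_df


def write_image_stack(
    stack: ImageStack,
    truth: pd.DataFrame,
    out_dir: str | Path,
    name: str = "phantom",
) -> dict[str, Path]:
    """Write a multi-channel TIFF, ground-truth CSV and voxel-size JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arr = np.stack([stack.channel(role) for role in CHANNEL_ROLES]).astype(np.float32)
    tiff_path = out / f"{name}.tif"
    tifffile.imwrite(tiff_path, arr, metadata={"axes": "CZYX"})
    csv_path = out / f"{name}_truth.csv"
    truth.to_csv(csv_path)
    cal = stack.calibration
    sidecar = {
        "voxel_um": {"dx": cal.dx, "dy": cal.dy, "dz": cal.dz},
        "channels": list(CHANNEL_ROLES),
        "axes": "CZYX",
    }
    json_path = out / f"{name}.json"
    json_path.write_text(json.dumps(sidecar, indent=2))
    return {"tiff": tiff_path, "truth": csv_path, "sidecar": json_path}


# ---------------------------------------------------------------------------
# immunoblot datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlotSimParams:
    """Linear intensity-mass blot simulator with additive noise."""

    standard_masses: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0)  # ng
    slope: float = 100.0          # AU per ng
    intercept: float = 0.0        # AU
    noise_sd: float = 0.0         # AU
    sample_true_masses: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.standard_masses) < 3:
            raise ValueError("at least 3 standard masses are required")
        if min(self.standard_masses) <= 0:
            raise ValueError("standard masses must be strictly positive")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class BlotDataset:
    """Simulated standard and sample lanes with hidden true masses."""

    standards: pd.DataFrame   # columns mass_ng, intensity_au
    samples: pd.DataFrame     # columns true_mass_ng, intensity_au

    def to_frame(self) -> pd.DataFrame:
        std = self.standards.assign(role="standard")
        smp = self.samples.assign(role="sample")
        return pd.concat([std, smp], ignore_index=True)


def generate_blot_dataset(params: BlotSimParams) -> BlotDataset:
    """Standard and sample lanes: intensity = slope * mass + intercept + noise."""
    rng = np.random.default_rng(params.seed)

    def lane_intensity(masses: np.ndarray) -> np.ndarray:
        clean = params.slope * masses + params.intercept
        if params.noise_sd > 0:
            clean = clean + rng.normal(0.0, params.noise_sd, size=masses.shape)
        return np.maximum(clean, 0.0)

    std_masses = np.asarray(params.standard_masses, dtype=float)
    standards = pd.DataFrame(
        {"mass_ng": std_masses, "intensity_au": lane_intensity(std_masses)}
    )
    smp_masses = np.asarray(params.sample_true_masses, dtype=float)
    samples = pd.DataFrame(
        {"true_mass_ng": smp_masses, "intensity_au": lane_intensity(smp_masses)}
    )
    return BlotDataset(standards=standards, samples=samples)
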