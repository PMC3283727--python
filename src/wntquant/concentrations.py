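"""Quantitative immunoblot densitometry to molecules per cell and nM.

The whole-cell-lysate chain: a standard curve fitted to lanes of known
recombinant-protein mass converts sample band intensity to mass of the
specific protein per lane; dividing by the total protein loaded and
multiplying by the total protein content of one cell gives mass per cell;
molecular weight and Avogadro's number convert to molecules per cell, and the
resting (non-dividing) whole-cell volume converts to molar concentration.

The sub-cellular-fraction chain works the same way per fraction (nuclear,
cytosol, membrane), scaling each loaded aliquot back to the full fraction
volume and dividing by the number of cells fractionated; summed compartment
concentrations are compared with the whole-cell-lysate value as a recovery
check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "AVOGADRO",
    "BlotLane",
    "StandardCurve",
    "CellLineContext",
    "ConcentrationRecord",
    "CompartmentConcentrations",
    "fit_standard_curve",
    "quantify_lane",
    "wcl_concentration",
    "molecules_to_nM",
    "nM_to_molecules",
    "compartment_concentration",
    "crosscal_active",
    "load_cell_lines",
]

AVOGADRO = 6.02214e23  # /mol


@dataclass(frozen=True)
class BlotLane:
    """One densitometry lane: either a standard (known mass) or a sample."""

    intensity: float                       # AU
    known_mass: float | None = None        # ng, standards only
    loaded_total_protein: float | None = None  # ng, samples only
    replicate_id: str | int | None = None
    fraction: str = "wcl"                  # wcl | nuclear | cytosol | membrane

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("lane intensity must be >= 0")
        if (self.known_mass is None) == (self.loaded_total_protein is None):
            raise ValueError(
                "exactly one of known_mass (standard) or loaded_total_protein "
                "(sample) must be set"
            )

    @property
    def is_standard(self) -> bool:
        return self.known_mass is not None


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of band intensity on loaded mass."""

    slope: float                 # AU per ng
    intercept: float             # AU
    r_squared: float
    mass_range: tuple[float, float]  # ng

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be > 0")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")

    def predict(self, mass_ng: float) -> float:
        return self.slope * mass_ng + self.intercept


@dataclass(frozen=True)
class CellLineContext:
    """Per-cell-line constants required by the conversion chains."""

    name: str
    total_protein_per_cell: float          # pg/cell (BCA + cell count)
    resting_volume: float                  # pL, non-dividing whole-cell (DiI)
    cell_count: float | None = None        # cells, fractionation experiments
    original_volume_scale: float = 1.0     # fraction of the lysate loaded

    def __post_init__(self) -> None:
        if self.total_protein_per_cell <= 0:
            raise ValueError("total_protein_per_cell must be > 0")
        if self.resting_volume <= 0:
            raise ValueError("resting_volume must be > 0")
        if self.cell_count is not None and self.cell_count <= 0:
            raise ValueError("cell_count must be > 0")
        if not 0 < self.original_volume_scale <= 1:
            raise ValueError("original_volume_scale must be in (0, 1]")


@dataclass(frozen=True)
class ConcentrationRecord:
    """Fully propagated whole-cell concentration of one protein."""

    protein: str
    mass_per_ng_tp: float        # ng specific protein per ng total protein
    mass_per_cell: float         # pg
    mol_weight: float            # Da
    molecules_per_cell: float
    conc: float                  # nM
    sem: float                   # nM
    n_replicates: int

    def __post_init__(self) -> None:
        # molecules and nM must be two views of the same quantity
        expected = (self.mass_per_cell * 1e-12 / self.mol_weight) * AVOGADRO
        if expected > 0 and abs(self.molecules_per_cell - expected) > 1e-6 * expected:
            raise ValueError("molecules_per_cell inconsistent with mass_per_cell")


@dataclass(frozen=True)
class CompartmentConcentrations:
    """Per-compartment concentrations and the fractionation recovery check."""

    protein: str
    nuclear: float | None        # nM
    cytosol: float | None        # nM
    membrane: float | None       # nM
    recovery_percent: float | None = None   # vs whole-cell lysate

    def total(self) -> float:
        return sum(v for v in (self.nuclear, self.cytosol, self.membrane)
                   if v is not None)


# ---------------------------------------------------------------------------
# standard curve and lane quantification
# ---------------------------------------------------------------------------

def fit_standard_curve(
    standards: Sequence[BlotLane], through_origin: bool = False
) -> StandardCurve:
    """Fit intensity = slope * mass + intercept to the standard lanes.

    Requires at least three standards with non-degenerate masses.  With
    ``through_origin=True`` the intercept is forced to zero.
    """
    lanes = [ln for ln in standards if ln.is_standard]
    if len(lanes) < 3:
        raise ValueError("at least 3 standard lanes are required to fit a curve")
    mass = np.array([ln.known_mass for ln in lanes], dtype=float)
    inten = np.array([ln.intensity for ln in lanes], dtype=float)
    if np.ptp(mass) == 0:
        raise ValueError("standard masses are all equal; curve unfittable")
    if through_origin:
        slope = float(np.dot(mass, inten) / np.dot(mass, mass))
        intercept = 0.0
        resid = inten - slope * mass
        ss_tot = float(np.sum((inten - inten.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    else:
        fit = stats.linregress(mass, inten)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return StandardCurve(
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        mass_range=(float(mass.min()), float(mass.max())),
    )


def quantify_lane(
    lane: BlotLane, curve: StandardCurve
) -> tuple[float, bool]:
    """Invert the standard curve: returns (mass_ng, extrapolated_flag).

    Intensities below the curve intercept imply negative mass and are clamped
    to zero with a warning (sub-background lane).
    """
    mass = (lane.intensity - curve.intercept) / curve.slope
    if mass < 0:
        warnings.warn(
            f"lane intensity {lane.intensity} below the standard-curve "
            "intercept; mass clamped to 0 ng"
        )
        return 0.0, True
    lo, hi = curve.mass_range
    return float(mass), bool(mass < lo or mass > hi)


# ---------------------------------------------------------------------------
# unit conversions (centralized to avoid unit drift)
# ---------------------------------------------------------------------------

def molecules_to_nM(molecules: float, volume_pl: float) -> float:
    """Convert a per-cell molecule count to nM within a given cell volume (pL)."""
    if volume_pl <= 0:
        raise ValueError("volume must be > 0 pL")
    # nM = molecules / (N_A * volume in L) * 1e9;  1 pL = 1e-12 L
    return molecules / (AVOGADRO * volume_pl * 1e-12) * 1e9


def nM_to_molecules(conc_nm: float, volume_pl: float) -> float:
    """Inverse of :func:`molecules_to_nM`."""
    if volume_pl <= 0:
        raise ValueError("volume must be > 0 pL")
    return conc_nm * 1e-9 * AVOGADRO * volume_pl * 1e-12


# ---------------------------------------------------------------------------
# whole-cell-lysate chain
# ---------------------------------------------------------------------------

def wcl_concentration(
    mass_per_lane: float | Sequence[float],
    loaded_tp: float | Sequence[float],
    context: CellLineContext,
    mol_weight: float,
    protein: str = "",
) -> ConcentrationRecord:
    """Whole-cell-lysate chain from per-lane protein mass to nM.

    Per replicate, the specific-protein mass per lane (ng) is divided by the
    total protein loaded in that lane (ng); the replicate mean, scaled by the
    total protein content of one cell (pg), gives mass per cell, which the
    molecular weight and the resting cell volume convert to molecules per
    cell and nM.  The SEM over replicates is propagated linearly through the
    (purely multiplicative) remainder of the chain.
    """
    masses = np.atleast_1d(np.asarray(mass_per_lane, dtype=float))
    loads = np.atleast_1d(np.asarray(loaded_tp, dtype=float))
    if loads.size == 1:
        loads = np.full_like(masses, loads[0])
    if masses.shape != loads.shape:
        raise ValueError("mass_per_lane and loaded_tp must have matching shapes")
    if np.any(loads <= 0):
        raise ValueError("loaded total protein must be > 0 ng")
    if mol_weight <= 0:
        raise ValueError("molecular weight must be > 0 Da")

    per_ng_tp = masses / loads                    # step C, per replicate
    mean_ratio = float(per_ng_tp.mean())          # step D
    n = per_ng_tp.size
    sem_ratio = float(per_ng_tp.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0

    mass_per_cell = mean_ratio * context.total_protein_per_cell      # pg (F)
    molecules = (mass_per_cell * 1e-12 / mol_weight) * AVOGADRO      # G
    conc = molecules_to_nM(molecules, context.resting_volume)        # I, J
    sem = conc * (sem_ratio / mean_ratio) if mean_ratio > 0 else 0.0

    return ConcentrationRecord(
        protein=protein,
        mass_per_ng_tp=mean_ratio,
        mass_per_cell=mass_per_cell,
        mol_weight=mol_weight,
        molecules_per_cell=molecules,
        conc=conc,
        sem=sem,
        n_replicates=int(n),
    )


# ---------------------------------------------------------------------------
# sub-cellular fraction chain
# ---------------------------------------------------------------------------

_FRACTIONS = ("nuclear", "cytosol", "membrane")


def compartment_concentration(
    fraction_lanes: Mapping[str, Sequence[BlotLane]],
    curve: StandardCurve,
    context: CellLineContext,
    mol_weight: float,
    wcl_record: ConcentrationRecord | None = None,
    protein: str = "",
    loss_warn_threshold: float = 90.0,
) -> CompartmentConcentrations:
    """Per-fraction concentrations and recovery against the whole-cell value.

    Each fraction's lane masses (from the standard curve) are scaled back to
    the full fraction volume, divided by the number of cells fractionated,
    and converted to nM with the resting cell volume.  Missing fractions are
    reported absent; recovery is then computed over the present ones with a
    warning.
    """
    if context.cell_count is None:
        raise ValueError("cell_count is required for fractionation experiments")
    if mol_weight <= 0:
        raise ValueError("molecular weight must be > 0 Da")

    conc: dict[str, float | None] = {}
    for frac in _FRACTIONS:
        lanes = fraction_lanes.get(frac)
        if not lanes:
            conc[frac] = None
            continue
        masses = np.array([quantify_lane(ln, curve)[0] for ln in lanes])
        mass_in_sample = masses.mean() / context.original_volume_scale   # ng (F)
        mass_per_cell = mass_in_sample / context.cell_count              # ng (H)
        molecules = (mass_per_cell * 1e-9 / mol_weight) * AVOGADRO       # I
        conc[frac] = molecules_to_nM(molecules, context.resting_volume)  # K, L

    missing = [f for f in _FRACTIONS if conc[f] is None]
    if missing:
        warnings.warn(
            f"fractions missing ({', '.join(missing)}); recovery computed over "
            "the present compartments only"
        )

    recovery = None
    if wcl_record is not None and wcl_record.conc > 0:
        total = sum(v for v in conc.values() if v is not None)
        recovery = 100.0 * total / wcl_record.conc
        if recovery < loss_warn_threshold:
            warnings.warn(
                f"fractionation recovery {recovery:.1f}% of the whole-cell "
                "lysate concentration: material loss during fractionation"
            )

    return CompartmentConcentrations(
        protein=protein,
        nuclear=conc["nuclear"],
        cytosol=conc["cytosol"],
        membrane=conc["membrane"],
        recovery_percent=recovery,
    )


# ---------------------------------------------------------------------------
# active-protein cross-calibration
# ---------------------------------------------------------------------------

def crosscal_active(
    total_curve: StandardCurve,
    active_curve: StandardCurve,
    range_rtol: float = 1e-6,
) -> float:
    """Calibration factor mapping active-epitope intensities to the total scale.

    Both curves must be fitted on the same standard masses (two identical
    standard sets probed with the two antibodies); the factor is the ratio of
    slopes, total/active.
    """
    lo_t, hi_t = total_curve.mass_range
    lo_a, hi_a = active_curve.mass_range
    if (abs(lo_t - lo_a) > range_rtol * max(lo_t, lo_a, 1e-12)
            or abs(hi_t - hi_a) > range_rtol * max(hi_t, hi_a, 1e-12)):
        raise ValueError(
            "standard-curve mass ranges differ; the two blots must share "
            "the same standard masses"
        )
    return total_curve.slope / active_curve.slope


# ---------------------------------------------------------------------------
# bundled cell-line dataset
# ---------------------------------------------------------------------------

def load_cell_lines(path: str | None = None) -> dict:
    """Load the bundled per-cell-line dataset (volumes, molecule counts)."""
    if path is None:
        ref = resources.files("wntquant").joinpath("data/cell_lines.yaml")
        with ref.open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return raw["cell_lines"]


def cell_line_wcl_concentrations(
    line: str, cell_lines: Mapping | None = None
) -> dict[str, float]:
    """Whole-cell concentrations (nM) from the bundled molecule counts.

    Converts each protein's molecules-per-cell entry with the line's
    non-dividing DiI (resting whole-cell) volume.
    """
    data = cell_lines if cell_lines is not None else load_cell_lines()
    rec = data[line]
    volume = float(rec["volumes_pl"]["dii"]["nd"][0])
    return {
        protein: molecules_to_nM(count_k * 1000.0, volume)
        for protein, count_k in rec["molecules_per_cell_k"].items()
    }
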