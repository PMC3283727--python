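"""3D confocal volumetry: segmentation, per-cell marker volumes, population split.

Live cells are stained with three markers — Calcein AM (cytoplasm of viable
cells, including the nuclear region), Hoechst 33342 (nuclei) and Vybrant DiI
(membrane and near-membrane cytoplasm, so the filled DiI object is the whole
cell) — and imaged as 3D confocal stacks.  Each channel is thresholded,
hole-filled and labelled; objects are matched across channels by nucleus
centroid containment; voxel counts times the voxel volume give per-cell
marker volumes in pL.

Because DNA content (and with it nuclear volume) roughly doubles through
S/M phase while cells maintain their nuclear-to-cell volume ratio, the
Hoechst axis separates dividing (D) from non-dividing (ND, resting) cells.
Compartment volumes follow by subtraction: nuclei = Hoechst, cytosol =
Calcein - Hoechst, membrane-outer cytoplasm = DiI - Calcein.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.segmentation import clear_border

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNEL_ROLES",
    "VoxelCalibration",
    "ImageStack",
    "SegmentationOptions",
    "CellVolumeRecord",
    "CompartmentVolumes",
    "PopulationSplit",
    "PopulationSummary",
    "segment_channel",
    "measure_cell_volumes",
    "split_populations",
    "compartment_volumes",
    "normalized_ratio_stats",
    "summarize_population",
    "aggregate_d_over_nd",
]

CHANNEL_ROLES = ("calcein", "hoechst", "dii")

UM3_PER_PL = 1000.0  # 1 pL = 1e-15 m^3 = 1000 um^3


@dataclass(frozen=True)
class VoxelCalibration:
    """Voxel edge lengths in micrometres."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel dimensions must be > 0 um")

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def voxel_volume_pl(self) -> float:
        return self.voxel_volume_um3 / UM3_PER_PL


class ImageStack:
    """Three-channel 3D intensity stack with voxel calibration.

    ``channels`` maps each marker role (calcein, hoechst, dii) to a
    ``(planes, rows, cols)`` array; all channels must share one shape.
    """

    def __init__(
        self,
        channels: Mapping[str, np.ndarray],
        calibration: VoxelCalibration,
    ) -> None:
        missing = [r for r in CHANNEL_ROLES if r not in channels]
        if missing:
            raise ValueError(f"channel roles missing: {missing}")
        arrays = {}
        shape = None
        for role in CHANNEL_ROLES:
            arr = np.asarray(channels[role])
            if arr.ndim != 3:
                raise ValueError(f"channel {role!r} must be a 3D array")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("all channels must share the same shape")
            arrays[role] = arr
        self.channels = arrays
        self.calibration = calibration
        self.shape = shape

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise KeyError(f"unknown channel role {role!r}")
        return self.channels[role]


@dataclass(frozen=True)
class SegmentationOptions:
    """Segmentation knobs for one channel.

    ``threshold`` is either ``"otsu"`` (global 3D Otsu) or an absolute
    intensity floor; ``threshold_floor`` optionally overrides an Otsu value
    that falls below it (guards against all-background images where Otsu
    splits noise).
    """

    threshold: float | str = "otsu"
    threshold_floor: float | None = None
    min_volume_pl: float = 0.05
    exclude_border: bool = True
    fill_holes: bool = True


@dataclass(frozen=True)
class CellVolumeRecord:
    """Per-cell fluorescence-marked volumes (pL)."""

    cell_id: int
    v_calcein: float
    v_hoechst: float
    v_dii: float

    def __post_init__(self) -> None:
        if min(self.v_calcein, self.v_hoechst, self.v_dii) < 0:
            raise ValueError("marker volumes must be >= 0")

    @property
    def ratio(self) -> float:
        """Normalised volume, Calcein/Hoechst (defined for v_hoechst > 0)."""
        if self.v_hoechst <= 0:
            raise ZeroDivisionError("ratio undefined for zero Hoechst volume")
        return self.v_calcein / self.v_hoechst


@dataclass(frozen=True)
class CompartmentVolumes:
    """Nuclei / cytosol / membrane-outer-cytoplasm decomposition (pL)."""

    nuclei: float
    cytosol: float
    membrane_outer: float

    @property
    def total(self) -> float:
        return self.nuclei + self.cytosol + self.membrane_outer

    def ncm_ratio(self) -> tuple[float, float, float]:
        """Volumes normalised to nuclei = 1."""
        if self.nuclei <= 0:
            raise ValueError("N:C:M ratio undefined for zero nuclear volume")
        return (1.0, self.cytosol / self.nuclei, self.membrane_outer / self.nuclei)


@dataclass
class PopulationSplit:
    """ND/D labels plus the calcein-vs-hoechst fit statistics behind them."""

    labels: pd.Series                # index = cell_id, values "ND"/"D"
    slope: float
    intercept: float
    r_squared: float                 # whole table
    r_squared_nd: float              # ND subset
    cutoff_hoechst_pl: float
    cutoff_factor: float

    @property
    def n_dividing(self) -> int:
        return int((self.labels == "D").sum())

    @property
    def n_nondividing(self) -> int:
        return int((self.labels == "ND").sum())


@dataclass
class PopulationSummary:
    """Per-marker Total/ND/D statistics and compartment ratios for one dataset."""

    marker_stats: pd.DataFrame       # index marker, columns mean/sd x total/nd/d
    d_over_nd: dict[str, float | None]
    ncm_ratio: tuple[float, float, float] | None
    n_total: int
    n_nd: int
    n_d: int


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_channel(
    stack: ImageStack, role: str, options: SegmentationOptions | None = None
) -> np.ndarray:
    """Threshold, fill and label one channel; returns a labelled 3D mask.

    Steps: global threshold (Otsu or absolute) -> slice-wise hole filling,
    then a 3D closing and 3D fill -> connected-component labelling ->
    removal of objects below the minimum volume or touching the stack border
    (if enabled).  An all-background channel yields zero objects, not an
    error.
    """
    opts = options or SegmentationOptions()
    img = np.asarray(stack.channel(role), dtype=float)

    if isinstance(opts.threshold, str):
        if opts.threshold != "otsu":
            raise ValueError(f"unknown threshold method {opts.threshold!r}")
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=np.int32)
        thr = float(threshold_otsu(img))
        if opts.threshold_floor is not None:
            thr = max(thr, opts.threshold_floor)
    else:
        thr = float(opts.threshold)
    binary = img > thr
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)

    if opts.fill_holes:
        for z in range(binary.shape[0]):
            binary[z] = ndi.binary_fill_holes(binary[z])
        # pad before closing: the erosion half of an unpadded closing shaves
        # voxels off objects touching the stack faces, which would defeat the
        # border-exclusion rule below
        padded = np.pad(binary, 1, mode="edge")
        padded = ndi.binary_closing(padded, structure=np.ones((3, 3, 3), bool))
        binary = padded[1:-1, 1:-1, 1:-1]
        binary = ndi.binary_fill_holes(binary)

    if opts.exclude_border:
        binary = clear_border(binary)

    labels, n = ndi.label(binary)
    if n == 0:
        return labels.astype(np.int32)

    min_voxels = opts.min_volume_pl * UM3_PER_PL / stack.calibration.voxel_volume_um3
    counts = np.bincount(labels.ravel())
    too_small = np.flatnonzero(counts < min_voxels)
    if too_small.size:
        labels[np.isin(labels, too_small[too_small > 0])] = 0
    # relabel compactly
    labels, _ = ndi.label(labels > 0)
    return labels.astype(np.int32)


def _centroids(labels: np.ndarray) -> dict[int, tuple[float, ...]]:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    cents = ndi.center_of_mass(np.ones_like(labels), labels, ids)
    return dict(zip(ids.tolist(), cents))


def measure_cell_volumes(
    masks: Mapping[str, np.ndarray],
    calibration: VoxelCalibration,
) -> tuple[list[CellVolumeRecord], list[dict]]:
    """Match objects across channels and return per-cell marker volumes (pL).

    A cell is a Calcein object containing exactly one Hoechst-object
    centroid; the DiI object is the one containing that Calcein object's
    centroid.  Nuclei outside any Calcein object are orphans (excluded,
    reported); Calcein objects holding two or more nuclei are flagged as
    dividing candidates and excluded.  Returns ``(records, issues)``.
    """
    for role in CHANNEL_ROLES:
        if role not in masks:
            raise ValueError(f"mask for channel {role!r} missing")
    cal_mask = masks["calcein"]
    hoe_mask = masks["hoechst"]
    dii_mask = masks["dii"]
    vox_pl = calibration.voxel_volume_pl

    counts = {role: np.bincount(masks[role].ravel()) for role in CHANNEL_ROLES}

    def _vol(role: str, label: int) -> float:
        return float(counts[role][label] * vox_pl)

    issues: list[dict] = []
    nuclei_by_cell: dict[int, list[int]] = {}
    for nuc_id, cent in _centroids(hoe_mask).items():
        idx = tuple(int(round(c)) for c in cent)
        cal_label = int(cal_mask[idx])
        if cal_label == 0:
            issues.append({"kind": "orphan_nucleus", "hoechst_label": int(nuc_id)})
            logger.warning("nucleus %d lies outside any calcein object", nuc_id)
            continue
        nuclei_by_cell.setdefault(cal_label, []).append(int(nuc_id))

    records: list[CellVolumeRecord] = []
    cell_id = 0
    for cal_label, nuc_ids in sorted(nuclei_by_cell.items()):
        if len(nuc_ids) > 1:
            issues.append({
                "kind": "multinucleate",
                "calcein_label": int(cal_label),
                "hoechst_labels": nuc_ids,
            })
            logger.warning(
                "calcein object %d holds %d nuclei; flagged as dividing "
                "candidate and excluded", cal_label, len(nuc_ids),
            )
            continue
        cal_cent = ndi.center_of_mass(cal_mask == cal_label)
        dii_label = int(dii_mask[tuple(int(round(c)) for c in cal_cent)])
        if dii_label == 0:
            issues.append({"kind": "no_dii_object", "calcein_label": int(cal_label)})
            logger.warning("calcein object %d has no enclosing DiI object", cal_label)
            continue
        cell_id += 1
        records.append(
            CellVolumeRecord(
                cell_id=cell_id,
                v_calcein=_vol("calcein", cal_label),
                v_hoechst=_vol("hoechst", nuc_ids[0]),
                v_dii=_vol("dii", dii_label),
            )
        )
    return records, issues


def records_to_frame(records: Sequence[CellVolumeRecord]) -> pd.DataFrame:
    """Tabulate records; the ratio column is NaN where Hoechst volume is 0."""
    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "v_calcein_pl": [r.v_calcein for r in records],
            "v_hoechst_pl": [r.v_hoechst for r in records],
            "v_dii_pl": [r.v_dii for r in records],
        }
    ).set_index("cell_id")
    df["ratio"] = np.where(
        df["v_hoechst_pl"] > 0, df["v_calcein_pl"] / df["v_hoechst_pl"], np.nan
    )
    return df


# ---------------------------------------------------------------------------
# population split and statistics
# ---------------------------------------------------------------------------

MIN_SPLIT_RECORDS = 10


def split_populations(
    records: Sequence[CellVolumeRecord] | pd.DataFrame,
    cutoff_factor: float = 1.5,
    nd_seed_quantile: float = 0.75,
) -> PopulationSplit:
    """Separate dividing (D) from non-dividing (ND) cells on the Hoechst axis.

    DNA replication gives dividing cells roughly twice the nuclear (Hoechst)
    volume, producing a separated upper mode.  Cells below the
    ``nd_seed_quantile`` Hoechst quantile seed the ND population; cells with
    Hoechst volume above ``cutoff_factor`` times the ND median are labelled
    D, and the median/labelling step is iterated once.  Linear-fit statistics
    of Calcein on Hoechst are reported for the whole table and the ND subset.

    Fewer than 10 records: everything is labelled ND with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to split")
    hoechst = df["v_hoechst_pl"].to_numpy(float)
    calcein = df["v_calcein_pl"].to_numpy(float)

    if len(df) < MIN_SPLIT_RECORDS:
        warnings.warn(
            f"only {len(df)} cells; too few to separate populations - "
            "labelling all non-dividing"
        )
        labels = pd.Series("ND", index=df.index, name="label")
        return PopulationSplit(
            labels=labels, slope=np.nan, intercept=np.nan, r_squared=np.nan,
            r_squared_nd=np.nan, cutoff_hoechst_pl=np.inf,
            cutoff_factor=cutoff_factor,
        )

    if np.ptp(hoechst) == 0 or np.ptp(calcein) == 0:
        raise ValueError("degenerate volumes (no variance); fit undefined")

    fit = stats.linregress(hoechst, calcein)

    nd_mask = hoechst <= np.quantile(hoechst, nd_seed_quantile)
    cutoff = cutoff_factor * float(np.median(hoechst[nd_mask]))
    nd_mask = hoechst <= cutoff                       # first labelling
    cutoff = cutoff_factor * float(np.median(hoechst[nd_mask]))  # iterate once
    nd_mask = hoechst <= cutoff

    labels = pd.Series(np.where(nd_mask, "ND", "D"), index=df.index, name="label")
    if nd_mask.sum() >= 3 and np.ptp(hoechst[nd_mask]) > 0:
        fit_nd = stats.linregress(hoechst[nd_mask], calcein[nd_mask])
        r2_nd = float(fit_nd.rvalue**2)
    else:
        r2_nd = np.nan
    return PopulationSplit(
        labels=labels,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        r_squared_nd=r2_nd,
        cutoff_hoechst_pl=cutoff,
        cutoff_factor=cutoff_factor,
    )


def compartment_volumes(record: CellVolumeRecord) -> CompartmentVolumes:
    """Decompose marker volumes into nuclei / cytosol / membrane-outer (pL).

    nuclei = Hoechst, cytosol = Calcein - Hoechst, membrane-outer cytoplasm =
    DiI - Calcein; the three parts sum to the DiI (whole-cell) volume exactly.
    Requires v_dii >= v_calcein >= v_hoechst — a violation indicates a
    segmentation failure and is an error, never clamped.
    """
    if record.v_calcein < record.v_hoechst:
        raise ValueError(
            f"cell {record.cell_id}: calcein volume {record.v_calcein} pL < "
            f"hoechst volume {record.v_hoechst} pL"
        )
    if record.v_dii < record.v_calcein:
        raise ValueError(
            f"cell {record.cell_id}: dii volume {record.v_dii} pL < "
            f"calcein volume {record.v_calcein} pL"
        )
    return CompartmentVolumes(
        nuclei=record.v_hoechst,
        cytosol=record.v_calcein - record.v_hoechst,
        membrane_outer=record.v_dii - record.v_calcein,
    )


def normalized_ratio_stats(
    records: Sequence[CellVolumeRecord] | pd.DataFrame,
    bins: int = 20,
) -> dict:
    """Per-cell Calcein/Hoechst ratios: mean, SD and histogram.

    Cells with zero Hoechst volume are excluded with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    n_zero = int((df["v_hoechst_pl"] <= 0).sum())
    if n_zero:
        warnings.warn(f"{n_zero} cells with zero Hoechst volume excluded from ratios")
    ok = df[df["v_hoechst_pl"] > 0]
    ratios = (ok["v_calcein_pl"] / ok["v_hoechst_pl"]).to_numpy(float)
    if ratios.size == 0:
        raise ValueError("no cells with positive Hoechst volume")
    counts, edges = np.histogram(ratios, bins=bins)
    return {
        "ratios": ratios,
        "mean": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0,
        "hist_counts": counts,
        "hist_edges": edges,
        "n": int(ratios.size),
        "n_excluded": n_zero,
    }


_MARKER_COLS = {
    "calcein": "v_calcein_pl",
    "hoechst": "v_hoechst_pl",
    "dii": "v_dii_pl",
}


def summarize_population(
    records: Sequence[CellVolumeRecord] | pd.DataFrame,
    split: PopulationSplit,
) -> PopulationSummary:
    """Total/ND/D mean +/- SD per marker, D/ND ratios, and the N:C:M ratio.

    The N:C:M (nuclei : cytosol : membrane-outer cytoplasm) ratio is computed
    from the non-dividing marker means, normalised to nuclei = 1.  An empty D
    subset leaves the D statistics and ratios absent.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if not df.index.equals(split.labels.index):
        raise ValueError("split labels do not cover the records")
    nd = df[split.labels == "ND"]
    dv = df[split.labels == "D"]

    rows = []
    d_over_nd: dict[str, float | None] = {}
    for marker, col in _MARKER_COLS.items():
        row = {
            "marker": marker,
            "mean_total": df[col].mean(),
            "sd_total": df[col].std(ddof=1) if len(df) > 1 else 0.0,
            "mean_nd": nd[col].mean() if len(nd) else np.nan,
            "sd_nd": nd[col].std(ddof=1) if len(nd) > 1 else 0.0,
            "mean_d": dv[col].mean() if len(dv) else np.nan,
            "sd_d": dv[col].std(ddof=1) if len(dv) > 1 else 0.0,
        }
        rows.append(row)
        if len(dv) and len(nd):
            d_over_nd[marker] = float(row["mean_d"] / row["mean_nd"])
        else:
            d_over_nd[marker] = None

    stats_df = pd.DataFrame(rows).set_index("marker")
    ncm = None
    if len(nd):
        mean_rec = CellVolumeRecord(
            cell_id=-1,
            v_calcein=float(nd["v_calcein_pl"].mean()),
            v_hoechst=float(nd["v_hoechst_pl"].mean()),
            v_dii=float(nd["v_dii_pl"].mean()),
        )
        ncm = compartment_volumes(mean_rec).ncm_ratio()
    return PopulationSummary(
        marker_stats=stats_df,
        d_over_nd=d_over_nd,
        ncm_ratio=ncm,
        n_total=len(df),
        n_nd=len(nd),
        n_d=len(dv),
    )


def aggregate_d_over_nd(
    summaries: Sequence[PopulationSummary] | Sequence[Mapping[str, float]],
) -> dict[str, float]:
    """Mean-of-cell-lines D/ND ratio per marker across several summaries."""
    acc: dict[str, list[float]] = {m: [] for m in _MARKER_COLS}
    for s in summaries:
        ratios = s.d_over_nd if isinstance(s, PopulationSummary) else s
        for marker, val in ratios.items():
            if val is not None and np.isfinite(val):
                acc[marker].append(float(val))
    return {m: float(np.mean(v)) for m, v in acc.items() if v}
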