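"""Configuration and orchestration: synthetic -> volumes -> concentrations -> model.

A single YAML config drives reproducible end-to-end runs; the stages share
the cell-line context so that volumes measured upstream feed the
concentration conversion and the concentrations feed the model calibration.
Every run writes a manifest (config hash, seed, package version) from which
any report value can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import concentrations as conc_mod
from . import model as model_mod
from . import synthetic as synth_mod
from . import volumes as vol_mod

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_report", "calibration_input_for_line"]

STAGES = ("synth", "volumes", "conc", "model")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list[str]
    out_dir: Path
    seed: int = 0
    voxel: tuple[float, float, float] = (0.2, 0.2, 0.5)  # dx, dy, dz um
    synth: dict = field(default_factory=dict)
    volumes: dict = field(default_factory=dict)
    conc: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw, base_dir=Path(path).parent)

    @classmethod
    def from_mapping(cls, raw: Mapping, base_dir: Path | None = None) -> "RunConfig":
        base = base_dir or Path.cwd()
        stages = raw.get("stages", list(STAGES))
        if isinstance(stages, str):
            stages = [stages]
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        if "out_dir" not in raw:
            raise ConfigError("out_dir missing from config")
        voxel = tuple(raw.get("voxel", (0.2, 0.2, 0.5)))
        if len(voxel) != 3 or min(voxel) <= 0:
            raise ConfigError("voxel must be three positive lengths (um)")
        cfg = cls(
            stages=list(stages),
            out_dir=(base / raw["out_dir"]).resolve(),
            seed=int(raw.get("seed", 0)),
            voxel=voxel,  # type: ignore[arg-type]
            synth=dict(raw.get("synth", {})),
            volumes=dict(raw.get("volumes", {})),
            conc=dict(raw.get("conc", {})),
            model=dict(raw.get("model", {})),
            raw=dict(raw),
        )
        # referenced input paths must exist up front
        for section, key in (("volumes", "stacks"), ("conc", "blots"),
                             ("conc", "context"), ("conc", "mw"),
                             ("model", "params"), ("model", "totals")):
            val = getattr(cfg, section).get(key)
            if val is not None and not Path(val).exists():
                raise ConfigError(f"{section}.{key} path does not exist: {val}")
        return cfg

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _calibration(cfg: RunConfig) -> vol_mod.VoxelCalibration:
    dx, dy, dz = cfg.voxel
    return vol_mod.VoxelCalibration(dx=dx, dy=dy, dz=dz)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_synth(cfg: RunConfig, out: Path) -> dict:
    """Generate population table, phantom stack and blot dataset with truth."""
    sdir = out / "synth"
    sdir.mkdir(parents=True, exist_ok=True)
    scfg = cfg.synth

    pop_params = synth_mod.PopulationParams(
        seed=cfg.seed, **scfg.get("population", {})
    )
    pop = synth_mod.generate_cell_population(pop_params)
    pop_path = sdir / "population.csv"
    pop.to_csv(pop_path)

    cal = _calibration(cfg)
    phantom_cfg = scfg.get("phantom", {})
    cells = []
    for c in phantom_cfg.get(
        "cells",
        [  # default: two well-separated ellipsoidal cells
            {"center": (12, 12, 12), "cell_semiaxes": (6, 7, 7.5),
             "nucleus_semiaxes": (4, 4.5, 5)},
            {"center": (12, 12, 34), "cell_semiaxes": (5, 6, 6.5),
             "nucleus_semiaxes": (3.5, 4, 4.5)},
        ],
    ):
        cells.append(synth_mod.CellPhantom(
            center=tuple(c["center"]),
            cell_semiaxes=tuple(c["cell_semiaxes"]),
            nucleus_semiaxes=tuple(c["nucleus_semiaxes"]),
            shell_thickness=float(c.get("shell_thickness", 1.0)),
        ))
    spec = synth_mod.PhantomSpec(
        cells=tuple(cells),
        noise_sd=float(phantom_cfg.get("noise_sd", 0.0)),
        blur_sigma=float(phantom_cfg.get("blur_sigma", 0.0)),
        seed=cfg.seed,
    )
    stack, truth = synth_mod.render_image_stack(spec, cal)
    paths = synth_mod.write_image_stack(stack, truth, sdir, name="phantom")

    blot_cfg = dict(scfg.get("blot", {}))
    blot_cfg.setdefault("sample_true_masses", (4.0, 8.0, 12.0))
    blot_params = synth_mod.BlotSimParams(seed=cfg.seed, **blot_cfg)
    blot = synth_mod.generate_blot_dataset(blot_params)

    context = {
        "name": "synthetic",
        "total_protein_per_cell_pg": 150.0,
        "resting_volume_pl": 1.5,
        "loaded_tp_ng": 20000.0,
        "mol_weight_da": 90000.0,
    }
    lanes = []
    for i, row in blot.standards.iterrows():
        lanes.append({"lane_id": f"std{i+1}", "protein": "synthetic",
                      "role": "standard", "mass_ng": row.mass_ng,
                      "intensity_au": row.intensity_au,
                      "loaded_tp_ng": "", "fraction": "wcl", "replicate": 1})
    for i, row in blot.samples.iterrows():
        lanes.append({"lane_id": f"smp{i+1}", "protein": "synthetic",
                      "role": "sample", "mass_ng": "",
                      "intensity_au": row.intensity_au,
                      "loaded_tp_ng": context["loaded_tp_ng"],
                      "fraction": "wcl", "replicate": i + 1})
    blots_path = sdir / "blots.csv"
    pd.DataFrame(lanes).to_csv(blots_path, index=False)

    context_path = sdir / "context.yaml"
    context_path.write_text(yaml.safe_dump({"synthetic": context}))
    mw_path = sdir / "mw.yaml"
    mw_path.write_text(yaml.safe_dump({"synthetic": context["mol_weight_da"]}))

    # ground truth the conc stage should recover
    true_ratio = float(np.mean(blot.samples.true_mass_ng)) / context["loaded_tp_ng"]
    true_mass_per_cell = true_ratio * context["total_protein_per_cell_pg"]
    true_molecules = true_mass_per_cell * 1e-12 / context["mol_weight_da"] * conc_mod.AVOGADRO
    truth_json = {
        "population": {"n_cells": pop_params.n_cells,
                       "dividing_fraction": pop_params.dividing_fraction,
                       "d_over_nd_ratio": pop_params.d_over_nd_ratio},
        "blot": {"true_sample_masses_ng": list(blot_params.sample_true_masses),
                 "true_conc_nM": conc_mod.molecules_to_nM(
                     true_molecules, context["resting_volume_pl"])},
    }
    truth_path = sdir / "truth.json"
    truth_path.write_text(json.dumps(truth_json, indent=2))

    return {
        "population_csv": str(pop_path),
        "phantom_tiff": str(paths["tiff"]),
        "phantom_truth_csv": str(paths["truth"]),
        "phantom_sidecar": str(paths["sidecar"]),
        "blots_csv": str(blots_path),
        "context_yaml": str(context_path),
        "mw_yaml": str(mw_path),
        "truth_json": str(truth_path),
    }


def _read_stack(path: Path, cal: vol_mod.VoxelCalibration) -> vol_mod.ImageStack:
    arr = tifffile.imread(path)
    if arr.ndim != 4 or arr.shape[0] != 3:
        raise ConfigError(
            f"stack {path} must be a 3-channel CZYX TIFF, got shape {arr.shape}"
        )
    channels = dict(zip(vol_mod.CHANNEL_ROLES, arr))
    return vol_mod.ImageStack(channels, cal)


def _stage_volumes(cfg: RunConfig, out: Path, upstream: dict) -> dict:
    vdir = out / "volumes"
    vdir.mkdir(parents=True, exist_ok=True)
    vcfg = cfg.volumes

    stack_path = vcfg.get("stacks")
    if stack_path is None:
        synth_out = upstream.get("synth")
        if not synth_out:
            raise ConfigError(
                "volumes stage needs volumes.stacks or an upstream synth stage"
            )
        stack_path = synth_out["phantom_tiff"]
    cal = _calibration(cfg)
    stack = _read_stack(Path(stack_path), cal)

    opts = vol_mod.SegmentationOptions(
        min_volume_pl=float(vcfg.get("min_volume_pl", 0.05)),
        exclude_border=bool(vcfg.get("border_exclude", True)),
    )
    masks = {role: vol_mod.segment_channel(stack, role, opts)
             for role in vol_mod.CHANNEL_ROLES}
    records, issues = vol_mod.measure_cell_volumes(masks, cal)
    df = vol_mod.records_to_frame(records)

    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # small phantom sets trip the small-n rule
        split = vol_mod.split_populations(records) if records else None
    if split is not None:
        df["label"] = split.labels
        summary = vol_mod.summarize_population(df.drop(columns="label"), split)
        ratio_stats = vol_mod.normalized_ratio_stats(df)
        summary_json = {
            "n_total": summary.n_total, "n_nd": summary.n_nd, "n_d": summary.n_d,
            "fit": {"slope": split.slope, "intercept": split.intercept,
                    "r_squared": split.r_squared,
                    "r_squared_nd": split.r_squared_nd},
            "marker_stats_pl": json.loads(summary.marker_stats.to_json(orient="index")),
            "d_over_nd": summary.d_over_nd,
            "ncm_ratio": summary.ncm_ratio,
            "ratio_mean": ratio_stats["mean"],
            "ratio_sd": ratio_stats["sd"],
            "issues": issues,
        }
    else:
        summary_json = {"n_total": 0, "issues": issues}

    cells_path = vdir / "cells.csv"
    df.to_csv(cells_path)
    summary_path = vdir / "summary.json"
    summary_path.write_text(json.dumps(summary_json, indent=2, default=float))
    return {"cells_csv": str(cells_path), "summary_json": str(summary_path)}


def _stage_conc(cfg: RunConfig, out: Path, upstream: dict) -> dict:
    cdir = out / "conc"
    cdir.mkdir(parents=True, exist_ok=True)
    ccfg = cfg.conc

    synth_out = upstream.get("synth", {})
    blots_path = ccfg.get("blots") or synth_out.get("blots_csv")
    context_path = ccfg.get("context") or synth_out.get("context_yaml")
    mw_path = ccfg.get("mw") or synth_out.get("mw_yaml")
    if blots_path is None:
        raise ConfigError("conc stage needs conc.blots or an upstream synth stage")
    if context_path is None or mw_path is None:
        raise ConfigError("conc stage needs conc.context and conc.mw")

    lanes = pd.read_csv(blots_path)
    contexts = yaml.safe_load(Path(context_path).read_text())
    mws = yaml.safe_load(Path(mw_path).read_text())

    results = []
    for protein, group in lanes.groupby("protein"):
        stds = [
            conc_mod.BlotLane(intensity=r.intensity_au, known_mass=r.mass_ng)
            for r in group[group.role == "standard"].itertuples()
        ]
        curve = conc_mod.fit_standard_curve(stds)
        samples = group[group.role == "sample"]
        masses, loads = [], []
        for r in samples.itertuples():
            lane = conc_mod.BlotLane(
                intensity=r.intensity_au,
                loaded_total_protein=float(r.loaded_tp_ng),
            )
            mass, _ = conc_mod.quantify_lane(lane, curve)
            masses.append(mass)
            loads.append(float(r.loaded_tp_ng))
        ctx_key = ccfg.get("cell_line") or next(iter(contexts))
        ctx_raw = contexts[ctx_key]
        context = conc_mod.CellLineContext(
            name=ctx_key,
            total_protein_per_cell=float(ctx_raw["total_protein_per_cell_pg"]),
            resting_volume=float(ctx_raw["resting_volume_pl"]),
        )
        rec = conc_mod.wcl_concentration(
            masses, loads, context, float(mws[protein]), protein=str(protein)
        )
        results.append({
            "protein": rec.protein, "cell_line": ctx_key,
            "curve_slope": curve.slope, "curve_r2": curve.r_squared,
            "mass_per_ng_tp": rec.mass_per_ng_tp,
            "mass_per_cell_pg": rec.mass_per_cell,
            "molecules_per_cell": rec.molecules_per_cell,
            "conc_nM": rec.conc, "sem_nM": rec.sem,
            "n_replicates": rec.n_replicates,
        })
    res_df = pd.DataFrame(results)
    csv_path = cdir / "concentrations.csv"
    res_df.to_csv(csv_path, index=False)
    json_path = cdir / "concentrations.json"
    json_path.write_text(res_df.to_json(orient="records", indent=2))
    return {"concentrations_csv": str(csv_path),
            "concentrations_json": str(json_path)}


def calibration_input_for_line(
    line: str,
    params: model_mod.ReactionParameters,
    cell_lines: Mapping | None = None,
) -> model_mod.CalibrationInput:
    """Build model initial totals for one cell line from the bundled dataset.

    Measured proteins (beta-catenin, axin, APC, GSK3beta) are converted from
    molecules per cell with the line's resting (non-dividing DiI) volume;
    the unmeasured Dsh and TCF totals default to the Xenopus reference values.
    """
    concs = conc_mod.cell_line_wcl_concentrations(line, cell_lines)
    return model_mod.CalibrationInput(
        beta_catenin=concs["beta_catenin"],
        axin=concs["axin"],
        apc=concs["apc"],
        gsk3=concs["gsk3"],
        dsh=params.totals["Dsh"],
        tcf=params.totals["TCF"],
        name=line,
        dsh_tcf_assumed=True,
    )


def _stage_model(cfg: RunConfig, out: Path, upstream: dict) -> dict:
    mdir = out / "model"
    mdir.mkdir(parents=True, exist_ok=True)
    mcfg = cfg.model

    params = model_mod.load_parameters(mcfg.get("params"))
    w = float(mcfg.get("wnt", 0.0))

    inputs: list[model_mod.CalibrationInput] = []
    if mcfg.get("totals"):
        totals = yaml.safe_load(Path(mcfg["totals"]).read_text())
        for name, t in totals.items():
            inputs.append(model_mod.CalibrationInput(
                beta_catenin=float(t["beta_catenin"]), axin=float(t["axin"]),
                apc=float(t["apc"]), gsk3=float(t["gsk3"]),
                dsh=float(t.get("dsh", params.totals["Dsh"])),
                tcf=float(t.get("tcf", params.totals["TCF"])),
                name=name,
                dsh_tcf_assumed=("dsh" not in t or "tcf" not in t),
            ))
    elif mcfg.get("cell_lines"):
        names = mcfg["cell_lines"]
        data = conc_mod.load_cell_lines()
        if names == "all":
            names = list(data)
        for name in names:
            if name == "Xenopus":
                inputs.append(model_mod.xenopus_input(params))
            else:
                inputs.append(calibration_input_for_line(name, params, data))
    else:
        raise ConfigError("totals missing: model stage needs model.totals or "
                          "model.cell_lines")

    rows = []
    for inp in inputs:
        rep = model_mod.run_calibration(inp, params, w=w)
        rows.append(rep.as_record())
    rep_df = pd.DataFrame(rows)
    csv_path = mdir / "retention.csv"
    rep_df.to_csv(csv_path, index=False)
    json_path = mdir / "retention.json"
    json_path.write_text(rep_df.to_json(orient="records", indent=2))
    return {"retention_csv": str(csv_path), "retention_json": str(json_path)}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

_STAGE_FUNCS = {
    "synth": lambda cfg, out, up: _stage_synth(cfg, out),
    "volumes": _stage_volumes,
    "conc": _stage_conc,
    "model": _stage_model,
}


def run_pipeline(config: RunConfig | str | Path | Mapping) -> dict:
    """Execute the requested stages in order and write a consolidated report.

    Returns the run report: a manifest (config hash, seed, version) plus the
    per-stage output paths and the consolidated tables of
    :func:`make_report`.
    """
    if isinstance(config, (str, Path)):
        cfg = RunConfig.from_file(config)
    elif isinstance(config, RunConfig):
        cfg = config
    else:
        cfg = RunConfig.from_mapping(config)

    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, dict] = {}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("running stage %s", stage)
        outputs[stage] = _STAGE_FUNCS[stage](cfg, out, outputs)

    from . import __version__

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": list(outputs),
    }
    report = {"manifest": manifest, "outputs": outputs,
              "tables": make_report(outputs)}
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      default=float))
    report["report_json"] = str(report_path)
    return report


def make_report(stage_outputs: Mapping[str, Mapping]) -> dict:
    """Consolidate stage outputs into table-shaped blocks.

    Blocks mirror the shapes of the headline result tables: population split
    statistics, per-marker volume statistics with compartment ratios,
    per-protein concentrations, and per-parameterization retention ratios.
    """
    if not stage_outputs:
        raise ValueError("no stage outputs to report")
    tables: dict[str, Any] = {}
    vol_out = stage_outputs.get("volumes")
    if vol_out:
        summary = json.loads(Path(vol_out["summary_json"]).read_text())
        tables["population_split"] = {
            k: summary.get(k) for k in ("n_total", "n_nd", "n_d", "fit")
        }
        tables["volume_stats"] = {
            k: summary.get(k)
            for k in ("marker_stats_pl", "d_over_nd", "ncm_ratio",
                      "ratio_mean", "ratio_sd")
        }
    conc_out = stage_outputs.get("conc")
    if conc_out:
        tables["concentrations"] = json.loads(
            Path(conc_out["concentrations_json"]).read_text()
        )
    model_out = stage_outputs.get("model")
    if model_out:
        tables["retention"] = json.loads(
            Path(model_out["retention_json"]).read_text()
        )
    return tables
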