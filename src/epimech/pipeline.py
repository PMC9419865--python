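"""End-to-end orchestration: simulate, analyse, compare, report.

``run_pipeline`` executes the selected stages in dependency order on
synthetic inputs (or files on disk), writes one CSV/JSON output per
stage, and assembles a consolidated report in which every number is
copied from a stage output — the report itself computes nothing.
Determinism: the whole run is a function of (config, seed); reports
carry a config hash instead of a timestamp so two identical runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cells as cells_mod
from . import fibers as fibers_mod
from . import synthetic, wound as wound_mod
from .contact import ContactFitConfig, ContactModel, aggregate_by_region
from .datatypes import ContactModelParams
from .exceptions import ConfigError, InputMissingError
from .stats import compare_groups

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("afm", "fibers", "cells", "wound", "stats")


@dataclass
class RunConfig:
    """Pipeline run configuration.

    ``stages`` selects what runs; per-stage parameter maps override the
    generator and analysis defaults.  Unknown keys anywhere are
    rejected, and a config round-trips through YAML unchanged.
    """

    stages: list = field(default_factory=lambda: list(_STAGES))
    seed: int = 0
    out_dir: str = "epimech_out"
    verbosity: str = "INFO"
    afm: dict = field(default_factory=dict)
    fibers: dict = field(default_factory=dict)
    cells: dict = field(default_factory=dict)
    wound: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputMissingError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage_afm(cfg: RunConfig, out: Path) -> dict:
    """Simulate a small per-region cohort on both substrates and fit each curve."""
    p = cfg.afm
    n_rep = int(p.get("n_replicates", 3))
    noise_abs = p.get("noise_sd_nN")          # absolute nN, overrides the relative default
    noise_frac = float(p.get("noise_frac", 0.02))  # fraction of each curve's peak force
    R = float(p.get("probe_radius_um", 2.6)) * 1e-6
    # per (substrate, region) true moduli, Pa; membrane terms on cells only
    cohort = p.get(
        "cohort",
        {
            "NCCI": {"junction": 30.73, "cytoplasm": 20.0, "nucleus": 12.0},
            "TCPS": {"junction": 12.0, "cytoplasm": 45.0, "nucleus": 30.0},
        },
    )
    beta_by_substrate = p.get("beta", {"NCCI": 1.37, "TCPS": 0.0314})
    results, truth_rows = [], []
    seed = cfg.seed
    fit_cfg = ContactFitConfig()
    for substrate, regions in cohort.items():
        for region, E_true in regions.items():
            K_m = float(beta_by_substrate.get(substrate, 0.0)) * E_true * R
            params = ContactModelParams(E=E_true, R=R, w=1e-5, K_m=K_m, z0=1.0)
            if noise_abs is not None:
                noise = float(noise_abs)
            else:
                clean, _ = synthetic.gen_force_curve(
                    params, z_range=1.4, n_points=400, seed=0
                )
                noise = noise_frac * float(clean.approach[1].max())
            for rep in range(n_rep):
                seed += 1
                curve, truth = synthetic.gen_force_curve(
                    params, z_range=1.4, n_points=400, noise_sd=noise, seed=seed,
                    region=region, substrate_label=substrate,
                    sample_id=f"{substrate}-{region}-{rep}",
                )
                results.append(ContactModel(curve, fit_cfg).fit())
                truth_rows.append({"sample_id": curve.sample_id, **truth.parameters})
    fits = pd.DataFrame([r.to_dict() for r in results])
    fits.to_csv(out / "afm_fits.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "afm_truth.csv", index=False)
    summary = aggregate_by_region(results)
    summary.to_csv(out / "afm_summary.csv", index=False)
    return {"fits": fits, "summary": summary}


def _stage_fibers(cfg: RunConfig, out: Path) -> dict:
    p = cfg.fibers
    img, truth = synthetic.gen_fiber_image(
        n_fibers=int(p.get("n_fibers", 60)),
        diameter_mean=float(p.get("diameter_mean_nm", 622.0)),
        diameter_sd=float(p.get("diameter_sd_nm", 31.0)),
        orientation_kappa=float(p.get("orientation_kappa", 0.0)),
        pixel_size=float(p.get("pixel_size_nm", 50.0)),
        image_size=int(p.get("image_size_px", 1024)),
        noise_sd=float(p.get("noise_sd", 0.02)),
        seed=cfg.seed,
    )
    mask = fibers_mod.segment_fibers(img)
    diam = fibers_mod.fiber_diameters(mask, truth.parameters["pixel_size_nm"])
    pores = fibers_mod.pore_sizes(mask, truth.parameters["pixel_size_nm"])
    orient = fibers_mod.orientation_anisotropy(img)
    hm_n, _ = synthetic.gen_height_map(
        "gaussian_field", amplitude=float(p.get("rq_nanofiber_um", 0.34)), seed=cfg.seed
    )
    hm_t, _ = synthetic.gen_height_map(
        "gaussian_field", amplitude=float(p.get("rq_tcps_um", 0.02)), seed=cfg.seed + 1
    )
    rq = {"NCCI": fibers_mod.rq_roughness(hm_n), "TCPS": fibers_mod.rq_roughness(hm_t)}
    pd.DataFrame({"diameter_nm": diam["diameters_nm"]}).to_csv(out / "diameters.csv", index=False)
    pd.DataFrame({"pore_diameter_um": pores["pore_diameters_um"]}).to_csv(out / "pores.csv", index=False)
    pd.DataFrame({"bin_start_rad": orient["bin_edges_rad"][:-1],
                  "power": orient["angular_power"]}).to_csv(out / "orientation.csv", index=False)
    roughness = {"rq_um": rq, "ratio": rq["NCCI"] / rq["TCPS"]}
    (out / "roughness.json").write_text(json.dumps(roughness, indent=2))
    return {
        "diameter_mean_nm": diam["mean_nm"],
        "diameter_sd_nm": diam["sd_nm"],
        "pore_mean_um": pores["mean_um"],
        "anisotropy_S": orient["anisotropy_S"],
        "roughness": roughness,
        "truth": truth.parameters,
    }


def _stage_cells(cfg: RunConfig, out: Path) -> dict:
    p = cfg.cells
    groups = p.get("intensity_mean_per_group", {"NCCI": 170.0, "TCPS": 25.0})
    n_cells = int(p.get("n_cells", 30))
    feats = {}
    for i, (group, mean_int) in enumerate(groups.items()):
        image, labels_true, truth = synthetic.gen_monolayer_image(
            n_cells=n_cells,
            mean_area=float(p.get("mean_area_um2", 400.0)),
            eccentricity_target=float(p.get("eccentricity", 0.6)),
            intensity_mean_per_group=mean_int,
            pixel_size=float(p.get("pixel_size_um", 0.5)),
            seed=cfg.seed + i,
        )
        nuclei = cells_mod.segment_nuclei(image[0], pixel_size=truth.parameters["pixel_size_um"])
        cells_lab = cells_mod.segment_cells(image[1], nuclei)
        df = cells_mod.shape_features(cells_lab, intensity_image=image[1], nuclei=nuclei)
        df["group"] = group
        feats[group] = df
        df.to_csv(out / f"cell_features_{group}.csv", index=False)
    names = list(groups)
    fc = cells_mod.fold_change(
        feats[names[0]]["mean_grey"], feats[names[1]]["mean_grey"], seed=cfg.seed
    )
    (out / "fold_change.json").write_text(json.dumps(fc, indent=2))
    return {"features": feats, "fold_change": fc,
            "area_means": {g: float(df["area_um2"].mean()) for g, df in feats.items()}}


def _stage_wound(cfg: RunConfig, out: Path) -> dict:
    p = cfg.wound
    series, truth = synthetic.gen_wound_series(
        initial_width=float(p.get("initial_width_um", 400.0)),
        front_velocity=float(p.get("front_velocity_um_per_h", 11.2)),
        timepoints=p.get("timepoints_h", [0, 6, 12, 18, 24]),
        seed=cfg.seed,
    )
    res = wound_mod.wound_kinetics(series)
    res.to_frame().to_csv(out / "wound_kinetics.csv", index=False)
    summary = {
        "closure_time_h": res.closure_time,
        "velocity_um_per_h": res.velocity,
        "velocity_total_um_per_h": res.velocity_total,
        "true_velocity_um_per_h": truth.parameters["front_velocity_um_per_h"],
    }
    (out / "wound_summary.json").write_text(json.dumps(summary, indent=2))
    return {"result": res, "summary": summary}


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """Run the selected stages; returns the consolidated report dict.

    Any stage failure halts the run with the stage name and cause;
    outputs of completed stages are preserved on disk.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    report = {"config_hash": config.digest(), "seed": config.seed,
              "stages": list(config.stages)}
    state = {}
    runners = {"afm": _stage_afm, "fibers": _stage_fibers,
               "cells": _stage_cells, "wound": _stage_wound}
    for stage in [s for s in config.stages if s != "stats"]:
        logger.info("running stage %s", stage)
        try:
            state[stage] = runners[stage](config, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if "afm" in state:
        s = state["afm"]["summary"]
        report["afm"] = s.to_dict(orient="records")
    if "fibers" in state:
        report["fibers"] = {k: v for k, v in state["fibers"].items() if k != "truth"}
    if "cells" in state:
        report["cells"] = {"fold_change": state["cells"]["fold_change"],
                           "area_means_um2": state["cells"]["area_means"]}
    if "wound" in state:
        report["wound"] = state["wound"]["summary"]

    if "stats" in config.stages:
        comparisons = {}
        if "afm" in state:
            fits = state["afm"]["fits"]
            for region in fits["region"].unique():
                sub = fits[fits["region"] == region]
                a = sub[sub["substrate"] == "NCCI"]["E_Pa"].to_numpy()
                b = sub[sub["substrate"] == "TCPS"]["E_Pa"].to_numpy()
                if a.size >= 2 and b.size >= 2:
                    paired = bool(config.stats.get("paired", True)) and a.size == b.size
                    gc = compare_groups(a, b, paired=paired)
                    comparisons[f"E_{region}_NCCI_vs_TCPS"] = {
                        "t": gc.statistic, "df": gc.df, "p": gc.p_value,
                        "n_a": gc.n_a, "n_b": gc.n_b, "paired": gc.paired,
                    }
        if "cells" in state:
            feats = state["cells"]["features"]
            names = list(feats)
            if len(names) == 2:
                a = feats[names[0]]["mean_grey"].to_numpy()
                b = feats[names[1]]["mean_grey"].to_numpy()
                paired = bool(config.stats.get("paired", True)) and a.size == b.size
                gc = compare_groups(a, b, paired=paired)
                comparisons[f"intensity_{names[0]}_vs_{names[1]}"] = {
                    "t": gc.statistic, "df": gc.df, "p": gc.p_value,
                    "n_a": gc.n_a, "n_b": gc.n_b, "paired": gc.paired,
                }
        report["comparisons"] = comparisons
        pd.DataFrame(comparisons).T.to_csv(out / "comparisons.csv")

    (out / "report.json").write_text(json.dumps(_to_jsonable(report), indent=2, sort_keys=True))
    (out / "report.md").write_text(_markdown_report(report))
    (out / "run_log.json").write_text(json.dumps(
        {"config": asdict(config), "config_hash": config.digest(), "seed": config.seed},
        indent=2, sort_keys=True))
    return report


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.DataFrame, pd.Series)):
        return json.loads(obj.to_json())
    if hasattr(obj, "to_frame"):
        return json.loads(obj.to_frame().to_json())
    if hasattr(obj, "__dataclass_fields__"):
        return _to_jsonable(asdict(obj))
    return obj


def _markdown_report(report: dict) -> str:
    lines = ["# epimech pipeline report", "",
             f"- config hash: `{report['config_hash']}`",
             f"- seed: {report['seed']}", ""]
    if "afm" in report:
        lines += ["## AFM nanomechanics (per substrate/region)", ""]
        for row in report["afm"]:
            lines.append(
                f"- {row['substrate']}/{row['region']}: "
                f"E = {row['E_Pa_mean']:.3g} Pa (n={row['n']})"
                f", beta = {row['beta_mean']:.3g}"
            )
        lines.append("")
    if "fibers" in report:
        f = report["fibers"]
        lines += ["## Fiber morphometry", "",
                  f"- diameter: {f['diameter_mean_nm']:.0f} +/- {f['diameter_sd_nm']:.0f} nm",
                  f"- mean pore: {f['pore_mean_um']:.2f} um",
                  f"- anisotropy S: {f['anisotropy_S']:.3f}",
                  f"- roughness ratio NCCI/TCPS: {f['roughness']['ratio']:.1f}", ""]
    if "cells" in report:
        fc = report["cells"]["fold_change"]
        lines += ["## Cell morphometrics", "",
                  f"- intensity fold change: {fc['fold_change']:.2f} "
                  f"[{fc['ci_low']:.2f}, {fc['ci_high']:.2f}]", ""]
    if "wound" in report:
        w = report["wound"]
        closure = w["closure_time_h"]
        lines += ["## Wound kinetics", "",
                  f"- closure: {closure if closure is not None else 'not reached'} h",
                  f"- per-front velocity: {w['velocity_um_per_h']:.2f} um/h", ""]
    if "comparisons" in report:
        lines += ["## Group comparisons", ""]
        for name, c in report["comparisons"].items():
            lines.append(f"- {name}: t = {c['t']:.3g}, df = {c['df']:.3g}, p = {c['p']:.3g}")
        lines.append("")
    return "\n".join(lines)
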