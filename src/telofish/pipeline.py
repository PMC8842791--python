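"""Pipeline orchestration: simulate -> quantify -> metrics -> stats -> report.

A run is driven by a nested configuration dictionary (YAML on disk) whose
defaults are all recorded in :data:`DEFAULT_CONFIG`; the effective merged
config is written next to the outputs, so a run is reproducible from its
output directory alone.  All warnings raised by any stage are captured into
``run.log`` alongside timestamped events.
"""

from __future__ import annotations

import copy
import datetime
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .metrics import summarize_specimens
from .quant import quantify_image
from .simulate import (AcquisitionSpec, SpecimenSpec, default_compartments,
                       simulate_cohort)
from .stats import TestResult, anova_oneway, t_unpaired, tukey_hsd

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "RunLog", "load_config", "run_pipeline",
           "make_report", "simulate_from_config", "quantify_cohort",
           "compare_groups"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "paths": {"input": None, "output": "telofish_out"},
    "simulate": None,  # optional: {"groups": [...], "acquisition": {...}}
    "background": {"method": "percentile", "value": 50.0},
    "sharpen": {"amount": 0.5},
    "rollingball": {"radius": 5.0},
    "segment": {"threshold": "noise", "threshold_value": None,
                "min_area": 2, "max_area": 1000, "connectivity": 8},
    "tfi": {"scale": 1.0},
    "metrics": {"tlv_value": "tfi", "compare_on": "mean_ratio",
                "with_ratios": True},
    "stats": {"variant": "student", "round_p": False},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge DEFAULT_CONFIG <- YAML file <- overrides (later wins)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


class RunLog:
    """Timestamped event/warning log written to ``run.log``.

    Every warning emitted by any pipeline stage is captured here; warnings
    are never silently dropped.
    """

    def __init__(self) -> None:
        self.events: list[str] = []
        self.warnings: list[str] = []

    def event(self, msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        line = f"{stamp}  {msg}"
        self.events.append(line)
        logger.info(msg)

    def warn(self, msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self.warnings.append(f"{stamp}  WARNING  {msg}")
        logger.warning(msg)

    def write(self, path: str | Path, config_hash: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"telofish {__version__}  config_hash={config_hash}\n")
            for line in self.events:
                fh.write(line + "\n")
            for line in self.warnings:
                fh.write(line + "\n")


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:12]


def simulate_from_config(cfg: dict, out_dir: str | Path, run_log: RunLog | None = None) -> dict:
    """Build a simulated cohort from the config's ``simulate`` section.

    Each group entry accepts: tissue_class, n_specimens, n_epithelial,
    n_stromal, epithelial_ratio, mucus_fraction, mucus_signal_boost,
    spot_sigma_log; ``acquisition`` overrides AcquisitionSpec fields.
    """
    sim = cfg.get("simulate")
    if not sim:
        raise ValueError("config has no 'simulate' section")
    acq = AcquisitionSpec(**(sim.get("acquisition") or {}))
    group_specs = []
    for grp in sim["groups"]:
        comps = default_compartments(
            n_epithelial=grp.get("n_epithelial", 64),
            n_stromal=grp.get("n_stromal", 36),
            epithelial_signal_ratio=grp.get("epithelial_ratio", 0.9),
            mucus_fraction=grp.get("mucus_fraction", 0.0),
            mucus_signal_boost=grp.get("mucus_signal_boost", 1.0),
            spot_sigma_log=grp.get("spot_sigma_log", 0.5),
            nucleus_radius=grp.get("nucleus_radius", 24.0),
            spots_per_cell=grp.get("spots_per_cell", 15.0))
        template = SpecimenSpec(specimen_id="sim", tissue_class=grp["tissue_class"],
                                acquisition=acq, compartments=comps)
        group_specs.append((grp["tissue_class"], template, int(grp["n_specimens"])))
    manifest = simulate_cohort(group_specs, int(cfg["seed"]), out_dir)
    if run_log:
        run_log.event(f"simulated {len(manifest['specimens'])} specimens "
                      f"into {out_dir}")
    return manifest


def quantify_cohort(input_dir: str | Path, cfg: dict,
                    run_log: RunLog | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every specimen listed in ``manifest.json`` in ``input_dir``.

    Cell annotations (compartment/subtype/tissue_class per label) are taken
    from ``annotations.csv`` if present, else from the simulator's
    ``truth.csv``.  Returns tidy (cells, spots) tables.
    """
    input_dir = Path(input_dir)
    man_path = input_dir / "manifest.json"
    if not man_path.exists():
        raise FileNotFoundError(f"no manifest.json in {input_dir}")
    manifest = json.loads(man_path.read_text())

    ann_path = input_dir / "annotations.csv"
    if not ann_path.exists():
        ann_path = input_dir / "truth.csv"
    if not ann_path.exists():
        raise FileNotFoundError(f"no annotations.csv or truth.csv in {input_dir}")
    ann = pd.read_csv(ann_path)

    seg = cfg["segment"]
    all_cells, all_spots = [], []
    for entry in manifest["specimens"]:
        sid = entry["specimen_id"]
        for key in ("cy3", "dapi", "labels"):
            if not (input_dir / entry[key]).exists():
                raise FileNotFoundError(
                    f"specimen {sid}: missing {key} file {entry[key]}")
        cy3 = tifffile.imread(input_dir / entry["cy3"]).astype(float)
        dapi = tifffile.imread(input_dir / entry["dapi"]).astype(float)
        rois = tifffile.imread(input_dir / entry["labels"]).astype(int)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            spots, cells = quantify_image(
                cy3, dapi, rois,
                background_method=cfg["background"]["method"],
                background_value=cfg["background"]["value"],
                sharpen_amount=cfg["sharpen"]["amount"],
                rollingball_radius=cfg["rollingball"]["radius"],
                threshold=seg["threshold"],
                threshold_value=seg["threshold_value"],
                min_area=seg["min_area"], max_area=seg["max_area"],
                connectivity=seg["connectivity"],
                tfi_scale=cfg["tfi"]["scale"])
        if run_log:
            for w in caught:
                run_log.warn(f"{sid}: {w.message}")
            run_log.event(f"quantified {sid}: {len(cells)} cells, {len(spots)} spots")
        sid_ann = ann[ann["specimen_id"] == sid]
        cells = cells.merge(
            sid_ann[["cell_label", "compartment", "subtype"]],
            on="cell_label", how="left")
        cells.insert(0, "specimen_id", sid)
        cells.insert(1, "tissue_class", entry.get("tissue_class",
                     sid_ann["tissue_class"].iloc[0] if len(sid_ann) else ""))
        cells.insert(2, "image_id", sid)
        spots.insert(0, "specimen_id", sid)
        all_cells.append(cells)
        all_spots.append(spots)
    cells = pd.concat(all_cells, ignore_index=True)
    spots = pd.concat(all_spots, ignore_index=True)
    return cells, spots


def compare_groups(specimens: pd.DataFrame, value: str = "mean_ratio",
                   variant: str = "student") -> pd.DataFrame:
    """Compare tissue classes on a per-specimen metric.

    Two classes: unpaired t-test of the chosen variant.  More: one-way ANOVA
    plus Tukey HSD pairwise rows.  Returns a tidy ``tests.csv`` table.
    """
    groups = [(tc, grp[value].dropna().to_numpy())
              for tc, grp in specimens.groupby("tissue_class", sort=False)]
    groups = [(tc, v) for tc, v in groups if len(v) > 0]
    rows: list[dict] = []

    def add(comparison: str, res: TestResult, ns: list[int]) -> None:
        df = res.df if not isinstance(res.df, tuple) else \
            f"{res.df[0]:g},{res.df[1]:g}"
        rows.append(dict(comparison=comparison, value=value, method=res.method,
                         statistic=res.statistic, df=df, p=res.p,
                         n=",".join(str(n) for n in ns)))

    if len(groups) < 2:
        return pd.DataFrame(rows, columns=["comparison", "value", "method",
                                           "statistic", "df", "p", "n"])
    if len(groups) == 2:
        (na, xa), (nb, xb) = groups
        add(f"{na} vs {nb}", t_unpaired(xa, xb, variant), [len(xa), len(xb)])
    else:
        vals = [v for _, v in groups]
        add(" vs ".join(tc for tc, _ in groups), anova_oneway(vals),
            [len(v) for v in vals])
        for res in tukey_hsd(vals):
            i, j = res.pair
            add(f"{groups[i][0]} vs {groups[j][0]}", res,
                [len(groups[i][1]), len(groups[j][1])])
    return pd.DataFrame(rows, columns=["comparison", "value", "method",
                                       "statistic", "df", "p", "n"])


def make_report(out_dir: str | Path, round_p: bool = False) -> str:
    """Render a plain-markdown run report from the output CSVs.

    Every number in the report is read back from a CSV cell, so regenerating
    the report never changes it unless the CSVs change.
    """
    out_dir = Path(out_dir)
    lines = ["# telofish run report", ""]
    spec_path = out_dir / "specimens.csv"
    if spec_path.exists():
        specimens = pd.read_csv(spec_path)
        lines.append("## Per-group metrics (mean ± SD (n))")
        lines.append("")
        for metric in ("mean_tfi", "mean_ratio", "tlv"):
            if metric not in specimens.columns:
                continue
            lines.append(f"### {metric}")
            for tc, grp in specimens.groupby("tissue_class", sort=False):
                vals = grp[metric].dropna()
                if len(vals) == 0:
                    continue
                sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
                lines.append(f"- {tc}: {vals.mean():.4g} ± {sd:.4g} SD "
                             f"(n = {len(vals)})")
            lines.append("")
    tests_path = out_dir / "tests.csv"
    if tests_path.exists():
        tests = pd.read_csv(tests_path)
        if len(tests):
            lines.append("## Statistical tests")
            lines.append("")
            for _, row in tests.iterrows():
                p = round(row["p"], 2) if round_p else row["p"]
                p_str = f"{p:.2f}" if round_p else f"{p:.4g}"
                lines.append(f"- {row['comparison']} ({row['value']}): "
                             f"{row['method']}, statistic = {row['statistic']:.3f}, "
                             f"df = {row['df']}, p = {p_str} (n = {row['n']})")
            lines.append("")
    return "\n".join(lines)


def run_pipeline(cfg: dict) -> Path:
    """Execute the configured pipeline end to end.

    Writes cells.csv, spots.csv, specimens.csv, ratios.csv, tests.csv,
    report.md, run.log and config_effective.yaml into the output directory.
    Identical config + seed reproduce identical CSVs.
    """
    cfg = _deep_merge(DEFAULT_CONFIG, cfg)
    out_dir = Path(cfg["paths"]["output"])
    out_dir.mkdir(parents=True, exist_ok=True)
    run_log = RunLog()
    chash = _config_hash(cfg)
    run_log.event(f"run started (seed={cfg['seed']}, config={chash})")

    if cfg.get("simulate"):
        input_dir = out_dir / "simulated"
        simulate_from_config(cfg, input_dir, run_log)
    else:
        if not cfg["paths"]["input"]:
            raise ValueError("config needs paths.input or a simulate section")
        input_dir = Path(cfg["paths"]["input"])

    cells, spots = quantify_cohort(input_dir, cfg, run_log)
    cells.to_csv(out_dir / "cells.csv", index=False)
    spots.to_csv(out_dir / "spots.csv", index=False)

    m = cfg["metrics"]
    try:
        specimens, ratios = summarize_specimens(
            cells, tlv_value=m["tlv_value"], with_ratios=m["with_ratios"])
    except ValueError as exc:
        raise ValueError(f"metrics failed: {exc}") from exc
    specimens.to_csv(out_dir / "specimens.csv", index=False)
    ratios.to_csv(out_dir / "ratios.csv", index=False)
    run_log.event(f"metrics: {len(specimens)} specimens, {len(ratios)} ratio cells")

    tests = compare_groups(specimens, value=m["compare_on"],
                           variant=cfg["stats"]["variant"])
    tests.to_csv(out_dir / "tests.csv", index=False)
    run_log.event(f"stats: {len(tests)} test row(s)")

    report = make_report(out_dir, round_p=cfg["stats"]["round_p"])
    (out_dir / "report.md").write_text(report)
    with open(out_dir / "config_effective.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    run_log.event("run finished")
    run_log.write(out_dir / "run.log", chash)
    return out_dir
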