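"""End-to-end orchestration: validated YAML configs driving the stages.

A run config declares a seed, an output directory and an ordered list of
stages.  Stages exchange results through a shared context; each writes any
tabular output as CSV stamped with a provenance header (config hash, seed,
package version).  A stage failure halts everything downstream.

Supported stages and their parameters:

``simulate_fate``    repeats, cells_per_repeat, probabilities
``cmh``              condition_a, condition_b, categories
``simulate_scene``   n_cells, positive_fraction, cluster_fraction, channels...
``quantify``         antigen channels to measure (defaults to all)
``classify``         channel -> cutoff value mapping, or negative-control key
``tension_curve``    r0, strains
``simulate_afm``     r0, p_prime, n_curves, noise_sd
``afm_fit``          r0
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import shape, synth, stats as fstats
from .errors import ConfigError, StageError
from .imaging import CutoffModel, quantify_scene

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("nichemech")

KNOWN_STAGES = (
    "simulate_fate", "cmh", "simulate_scene", "quantify", "classify",
    "tension_curve", "simulate_afm", "afm_fit",
)


@dataclass
class RunConfig:
    stages: list
    seed: int = 0
    output_dir: str | None = None
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(source) -> RunConfig:
    """Parse and validate a YAML config (path, file object or dict)."""
    if isinstance(source, dict):
        data = source
    elif hasattr(source, "read"):
        data = yaml.safe_load(source)
    else:
        data = yaml.safe_load(Path(source).read_text())
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    stages = data.get("stages")
    if not isinstance(stages, list) or not stages:
        raise ConfigError("config must declare a non-empty 'stages' list")
    norm = []
    for i, st in enumerate(stages):
        if isinstance(st, str):
            st = {"name": st}
        if not isinstance(st, dict) or "name" not in st:
            raise ConfigError(f"stage #{i} must be a name or a mapping with 'name'")
        if st["name"] not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage '{st['name']}'; known: {KNOWN_STAGES}")
        norm.append(dict(st))
    seed = data.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError("seed must be a non-negative integer")
    level = str(data.get("log_level", "INFO")).upper()
    if level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        raise ConfigError(f"invalid log_level '{level}'")
    return RunConfig(stages=norm, seed=seed, output_dir=data.get("output_dir"),
                     log_level=level, raw=data)


def _write_csv(df: pd.DataFrame, path: Path, provenance: str):
    with open(path, "w") as fh:
        fh.write(provenance + "\n")
        df.to_csv(fh, index=False)


def _stage_simulate_fate(params, ctx, rng):
    spec = synth.FateSimSpec(
        probabilities=params.get("probabilities", synth.DEFAULT_FATE_PROBS),
        repeats=params.get("repeats", 3),
        cells_per_repeat=params.get("cells_per_repeat", 200),
        seed=int(rng.integers(2 ** 31)),
    )
    ctx["fate_table"] = synth.gen_fate_counts(spec)
    return {"rows": len(ctx["fate_table"].counts)}


def _stage_cmh(params, ctx, rng):
    table = ctx.get("fate_table")
    if table is None:
        raise ValueError("no fate table in context (run simulate_fate or classify first)")
    cond_a = params["condition_a"]
    cond_b = params["condition_b"]
    cats = params.get("categories", list(fstats.CATEGORIES))
    results = {}
    for cat in cats:
        res = fstats.cmh_test_category(table, cond_a, cond_b, cat)
        results[cat] = {"statistic": res.statistic, "p_value": res.p_value,
                        "strata": res.strata_used}
    ctx["cmh_results"] = results
    return results


def _stage_simulate_scene(params, ctx, rng):
    channels = {}
    for name, cm in params.get("channels", {"antigen": {}}).items():
        channels[name] = synth.ChannelModel(**cm)
    spec = synth.SceneSpec(
        n_cells=params.get("n_cells", 6),
        positive_fraction=params.get("positive_fraction", 1.0),
        cluster_fraction=params.get("cluster_fraction", 0.0),
        channels=channels,
        seed=int(rng.integers(2 ** 31)),
    )
    ctx["scene"], ctx["scene_truth"] = synth.gen_cell_scene(spec)
    return {"n_cells": int(ctx["scene_truth"].labels.max())}


def _stage_quantify(params, ctx, rng):
    scene = ctx.get("scene")
    if scene is None:
        raise ValueError("no scene in context (run simulate_scene first)")
    records = quantify_scene(scene, antigen_channels=params.get("channels"))
    ctx["records"] = records
    rows = [{"cell_id": r.cell_id, "area_um2": r.area_um2, **{
        f"level_{k}": v for k, v in r.levels.items()}} for r in records]
    ctx["quantify_df"] = pd.DataFrame(rows)
    return {"n_records": len(records)}


def _stage_classify(params, ctx, rng):
    records = ctx.get("records")
    if records is None:
        raise ValueError("no quantified records in context")
    cutoffs = {k: CutoffModel(cutoff=float(v), n_controls=0, method="configured")
               for k, v in params.get("cutoffs", {}).items()}
    calls = [fstats.classify_fate(
        {"pax7": r.levels.get("pax7", 0.0), "myod": r.levels.get("myod", 0.0)},
        cutoffs, cell_id=r.cell_id) for r in records]
    table = fstats.FateTable.from_calls(
        calls, condition=params.get("condition", "scene"), repeat=params.get("repeat", 1))
    if "fate_table" in ctx:
        ctx["fate_table"] = fstats.FateTable(
            pd.concat([ctx["fate_table"].counts, table.counts], ignore_index=True))
    else:
        ctx["fate_table"] = table
    return {"n_calls": len(calls)}


def _stage_tension_curve(params, ctx, rng):
    r0 = params.get("r0", 8.7)
    strains = params.get("strains", [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.54])
    summaries = shape.tension_vs_strain(r0, strains)
    rows = []
    for eps, summ in zip(strains, summaries):
        if isinstance(summ, Exception):
            rows.append({"strain": eps, "error": str(summ)})
        else:
            rows.append({"strain": eps, "t_overall_rel": summ.t_overall_rel,
                         "t_axial_rel": summ.t_axial_rel,
                         "t_overall": summ.t_overall, "t_axial": summ.t_axial})
    ctx["tension_df"] = pd.DataFrame(rows)
    return {"n_points": len(rows)}


def _stage_simulate_afm(params, ctx, rng):
    spec = synth.AFMSimSpec(
        r0=params.get("r0", 8.0),
        p_prime=params.get("p_prime", 200.0),
        n_curves=params.get("n_curves", 5),
        noise_sd=params.get("noise_sd", 0.02),
        seed=int(rng.integers(2 ** 31)),
    )
    ctx["afm_curves"] = synth.gen_afm_curves(spec)
    ctx["afm_r0"] = spec.r0
    return {"n_curves": spec.n_curves}


def _stage_afm_fit(params, ctx, rng):
    from .afm import fit_pressure_scale
    curves = ctx.get("afm_curves")
    if curves is None:
        raise ValueError("no AFM curves in context")
    r0 = params.get("r0", ctx.get("afm_r0", 8.0))
    fits = [fit_pressure_scale(c, r0) for c in curves]
    ctx["afm_fits"] = pd.DataFrame(
        [{"cell_id": c.cell_id, "p_prime": f.p_prime,
          "t_overall_est": f.t_overall_est, "residual": f.residual}
         for c, f in zip(curves, fits)])
    return {"median_p_prime": float(np.median([f.p_prime for f in fits]))}


_HANDLERS = {
    "simulate_fate": _stage_simulate_fate,
    "cmh": _stage_cmh,
    "simulate_scene": _stage_simulate_scene,
    "quantify": _stage_quantify,
    "classify": _stage_classify,
    "tension_curve": _stage_tension_curve,
    "simulate_afm": _stage_simulate_afm,
    "afm_fit": _stage_afm_fit,
}

_OUTPUTS = {  # context key -> file name for stages that produce tables
    "quantify_df": "cells.csv",
    "tension_df": "tension_curve.csv",
    "afm_fits": "afm_fits.csv",
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run report.

    The report carries per-stage status and summaries plus provenance
    (config hash, seed, package version).  The first stage failure marks all
    later stages as skipped and re-raises as :class:`StageError`.
    """
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    rng = np.random.default_rng(config.seed)
    provenance = f"# nichemech config={config.config_hash} seed={config.seed} version={__version__}"
    report = {"config_hash": config.config_hash, "seed": config.seed,
              "version": __version__, "stages": []}
    ctx = {}
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    failure = None
    for st in config.stages:
        name = st["name"]
        params = {k: v for k, v in st.items() if k != "name"}
        entry = {"name": name, "status": "skipped"}
        if failure is None:
            try:
                log.info("running stage %s", name)
                entry["summary"] = _HANDLERS[name](params, ctx, rng)
                entry["status"] = "ok"
            except Exception as exc:  # halt downstream stages
                entry["status"] = "failed"
                entry["error"] = str(exc)
                failure = StageError(name, exc)
        report["stages"].append(entry)
    if outdir:
        manifests = []
        for key, fname in _OUTPUTS.items():
            if key in ctx:
                _write_csv(ctx[key], outdir / fname, provenance)
                manifests.append(fname)
        if "cmh_results" in ctx:
            (outdir / "cmh.json").write_text(
                provenance + "\n" + json.dumps(ctx["cmh_results"], indent=2))
            manifests.append("cmh.json")
        report["outputs"] = manifests
    report["context_keys"] = sorted(ctx)
    if failure is not None:
        report["failed_stage"] = failure.stage
        raise failure
    return report
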