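"""Configuration-driven pipeline: simulate -> fit -> project -> impact -> report.

Each stage reads its inputs from the output directory (or from the previous
stage in memory), writes its artifacts there, and records them in a run
manifest with content digests.  Scenario stacks are not persisted: they are
regenerated deterministically from the config seed, so every stage is
re-runnable from the persisted intermediates plus the config.  Identical
config and seeds give bitwise-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import build_spec, expand
from .impact import (decompose_impacts, regional_change, sensitivity_correlates,
                     type_response, weighted_location)
from .landscape import (CLIMATE_PREDICTORS, FIXED_PREDICTORS, LandscapeConfig,
                        PREDICTOR_NAMES, generate_environment, generate_scenarios,
                        generate_true_model, sample_vegetation)
from .model import (FitOptions, PVMModel, comparison_table, drop_one_importance,
                    evaluate, fit)
from .projection import assignment, frequency_vector, project, type_cooccurrence
from .raster_io import (read_stack, read_vegmap, write_field, write_stack,
                        write_vegmap)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config",
           "STAGES"]

STAGES = ("simulate", "fit", "project", "impact", "report")

_SCHEMA = {
    "landscape": {"grid_rows": int, "grid_cols": int, "n_types": int,
                  "autocorrelation_length": (int, float), "gradient_weight": (int, float),
                  "coefficient_scale": (int, float), "seed": int},
    "model": {"ridge": (int, float), "tolerance": (int, float),
              "max_iterations": int, "subsample": (int, type(None)),
              "importance": bool, "seed": int},
    "scenarios": {"n_scenarios": int, "dmat_range": list, "dppt_range": list,
                  "coupling": (int, float), "spatial_amplitude": (int, float),
                  "seed": int},
    "impact": {"drop_predictors": list, "alpha": (int, float)},
    "output": {"directory": str},
}

_DEFAULTS = {
    "landscape": {"grid_rows": 120, "grid_cols": 120, "n_types": 8,
                  "autocorrelation_length": 6.0, "gradient_weight": 0.2,
                  "coefficient_scale": 0.3, "seed": 0},
    "model": {"ridge": 1e-6, "tolerance": 1e-8, "max_iterations": 500,
              "subsample": None, "importance": True, "seed": 0},
    "scenarios": {"n_scenarios": 54, "dmat_range": [0.69, 5.67],
                  "dppt_range": [-23.0, 38.0], "coupling": 0.95,
                  "spatial_amplitude": 0.2, "seed": 0},
    "impact": {"drop_predictors": ["soil_depth", "cwd", "jja"], "alpha": 0.05},
    "output": {"directory": "vegmosaic_run"},
}


class ConfigError(ValueError):
    """Configuration failed validation; the message carries the field path."""


@dataclass
class PipelineConfig:
    landscape: dict
    model: dict
    scenarios: dict
    impact: dict
    output: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = raw or {}
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        sections = {}
        for section, fields in _SCHEMA.items():
            given = raw.get(section) or {}
            if not isinstance(given, dict):
                raise ConfigError(f"{section}: expected a mapping")
            bad = set(given) - set(fields)
            if bad:
                raise ConfigError(f"{section}.{sorted(bad)[0]}: unknown field")
            merged = {**_DEFAULTS[section], **given}
            for key, typ in fields.items():
                if not isinstance(merged[key], typ):
                    raise ConfigError(
                        f"{section}.{key}: expected {typ}, got {type(merged[key]).__name__}")
            sections[section] = merged
        return cls(**sections)

    def to_dict(self) -> dict:
        return {"landscape": self.landscape, "model": self.model,
                "scenarios": self.scenarios, "impact": self.impact,
                "output": self.output}

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.from_dict(raw)


@dataclass
class RunManifest:
    """Provenance record: config hash, seeds, versions, and artifact digests."""

    config_hash: str
    software_version: str
    seeds: dict
    stages: list = dfield(default_factory=list)
    files: dict = dfield(default_factory=dict)
    timestamps: dict = dfield(default_factory=dict)

    def record(self, stage: str, outdir: Path, names) -> None:
        self.stages.append(stage)
        self.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")
        for name in names:
            p = outdir / name
            self.files[name] = _sha256(p)

    def verify(self, outdir: Path) -> None:
        """Check every referenced artifact exists and matches its digest."""
        for name, digest in self.files.items():
            p = outdir / name
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing artifact {name}")
            if _sha256(p) != digest:
                raise ValueError(f"artifact {name} does not match its recorded digest")

    def write(self, outdir: Path) -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _landscape_config(cfg: PipelineConfig) -> LandscapeConfig:
    ls = cfg.landscape
    return LandscapeConfig(
        grid_rows=ls["grid_rows"], grid_cols=ls["grid_cols"], n_types=ls["n_types"],
        autocorrelation_length=float(ls["autocorrelation_length"]),
        gradient_weight=float(ls["gradient_weight"]), seed=ls["seed"],
    )


def _scenario_suite(cfg: PipelineConfig, baseline):
    sc = cfg.scenarios
    return generate_scenarios(
        baseline,
        n_scenarios=sc["n_scenarios"],
        dmat_range=tuple(sc["dmat_range"]),
        dppt_range=tuple(sc["dppt_range"]),
        coupling=float(sc["coupling"]),
        spatial_amplitude=float(sc["spatial_amplitude"]),
        seed=sc["seed"],
    )


def stage_simulate(cfg: PipelineConfig, outdir: Path, log=print) -> dict:
    lcfg = _landscape_config(cfg)
    log(f"[simulate] {lcfg.grid_rows}x{lcfg.grid_cols} grid, K={lcfg.n_types}, "
        f"seed={lcfg.seed}")
    env = generate_environment(lcfg)
    spec = build_spec(PREDICTOR_NAMES, env.samples())
    truth = generate_true_model(lcfg.n_types, spec,
                                coefficient_scale=float(cfg.landscape["coefficient_scale"]),
                                seed=lcfg.seed)
    vegmap = sample_vegetation(env, truth, seed=lcfg.seed)
    write_stack(env, outdir / "environment.tif")
    write_vegmap(vegmap, outdir / "vegetation.tif")
    truth.to_json(outdir / "truth_model.json")
    return {"env": env, "vegmap": vegmap, "truth": truth}


def stage_fit(cfg: PipelineConfig, outdir: Path, state=None, log=print) -> dict:
    state = state or {}
    env = state.get("env") or read_stack(outdir / "environment.tif")
    vegmap = state.get("vegmap") or read_vegmap(outdir / "vegetation.tif")
    samples = env.samples()
    labels = vegmap.labels.ravel()
    mcfg = cfg.model
    if mcfg["subsample"]:
        rng = np.random.default_rng(mcfg["seed"])
        idx = rng.choice(len(samples), size=min(mcfg["subsample"], len(samples)),
                         replace=False)
        samples_fit, labels_fit = samples.iloc[idx], labels[idx]
    else:
        samples_fit, labels_fit = samples, labels
    options = FitOptions(ridge=float(mcfg["ridge"]), tolerance=float(mcfg["tolerance"]),
                         max_iterations=mcfg["max_iterations"], seed=mcfg["seed"])
    log(f"[fit] n={len(samples_fit)}, ridge={options.ridge}")
    spec = build_spec(PREDICTOR_NAMES, samples_fit)
    design = expand(spec, samples_fit)
    model = fit(design, labels_fit, options, class_names=vegmap.class_names)
    metrics = evaluate(model, design, labels_fit)
    model.to_json(outdir / "model.json")
    with open(outdir / "fit_metrics.json", "w") as fh:
        json.dump({k: (v if not isinstance(v, float) else float(v))
                   for k, v in metrics.__dict__.items()}, fh, indent=2)
    log(f"[fit] proportion correct {metrics.proportion_correct:.3f}, "
        f"avg max probability {metrics.average_max_probability:.3f}")
    if mcfg["importance"]:
        log("[fit] drop-one predictor importance (refits one model per predictor)")
        rows = drop_one_importance(samples_fit, labels_fit, PREDICTOR_NAMES, options,
                                   climate_predictors=CLIMATE_PREDICTORS,
                                   fixed_predictors=FIXED_PREDICTORS,
                                   class_names=vegmap.class_names)
        comparison_table(rows).to_csv(outdir / "model_comparison.csv", index=False)
    return {**state, "env": env, "vegmap": vegmap, "model": model}


def stage_project(cfg: PipelineConfig, outdir: Path, state=None, log=print) -> dict:
    state = state or {}
    env = state.get("env") or read_stack(outdir / "environment.tif")
    model = state.get("model") or PVMModel.from_json(outdir / "model.json")
    suite = _scenario_suite(cfg, env)
    log(f"[project] baseline + {len(suite)} scenarios")
    baseline_field = project(model, env)
    write_field(baseline_field, outdir / "baseline_field.tif")
    future_fields = [project(model, s) for s in suite.scenarios]

    rows = []
    f0 = frequency_vector(baseline_field, provenance="modelled baseline")
    for name, val in zip(f0.class_names, f0.f):
        rows.append({"scenario": "baseline", "delta_mat": 0.0, "delta_ppt_percent": 0.0,
                     "class": name, "frequency": val})
    for scen, fld in zip(suite.scenarios, future_fields):
        fv = frequency_vector(fld, provenance=scen.label)
        for name, val in zip(fv.class_names, fv.f):
            rows.append({"scenario": scen.label, "delta_mat": scen.delta_mat,
                         "delta_ppt_percent": scen.delta_ppt_percent,
                         "class": name, "frequency": val})
    pd.DataFrame(rows).to_csv(outdir / "frequencies.csv", index=False)

    cooc = type_cooccurrence(baseline_field)
    pd.DataFrame(cooc, index=model.class_names,
                 columns=model.class_names).to_csv(outdir / "cooccurrence.csv")
    amap = assignment(baseline_field)
    counts, edges = amap.pmax_histogram
    with open(outdir / "pmax_histogram.json", "w") as fh:
        json.dump({"counts": counts.tolist(), "bin_edges": edges.tolist()}, fh)
    return {**state, "env": env, "model": model, "suite": suite,
            "baseline_field": baseline_field, "future_fields": future_fields}


def stage_impact(cfg: PipelineConfig, outdir: Path, state=None, log=print) -> dict:
    state = state or {}
    env = state.get("env") or read_stack(outdir / "environment.tif")
    model = state.get("model") or PVMModel.from_json(outdir / "model.json")
    suite = state.get("suite") or _scenario_suite(cfg, env)
    baseline_field = state.get("baseline_field") or project(model, env)
    future_fields = state.get("future_fields") or [project(model, s) for s in suite.scenarios]
    log(f"[impact] decomposing change across {len(suite)} scenarios")

    import tifffile

    summary = decompose_impacts(baseline_field, future_fields, suite)
    for name, arr in (("sensitivity", summary.sensitivity),
                      ("exposure", summary.exposure),
                      ("vulnerability", summary.vulnerability)):
        tifffile.imwrite(outdir / f"{name}.tif", arr.astype(np.float32),
                         photometric="minisblack")

    f0 = frequency_vector(baseline_field)
    reg_rows = []
    for scen, fld in zip(suite.scenarios, future_fields):
        reg_rows.append({
            "scenario": scen.label, "delta_mat": scen.delta_mat,
            "delta_ppt_percent": scen.delta_ppt_percent,
            "regional_bray_curtis": regional_change(f0, frequency_vector(fld)),
        })
    pd.DataFrame(reg_rows).to_csv(outdir / "regional_change.csv", index=False)

    freq_matrix = np.stack([fld.values.mean(axis=0) for fld in future_fields])
    dmat, dppt = suite.delta_mat, suite.delta_ppt_percent
    resp_rows = []
    if len(suite) >= 6:
        for j, name in enumerate(model.class_names):
            tr = type_response(freq_matrix[:, j], dmat, dppt, class_name=name,
                               alpha=float(cfg.impact["alpha"]))
            resp_rows.append({"class": name, "form": tr.chosen_form,
                              "direction": tr.direction,
                              **{f"coef_{k}": v for k, v in tr.coefficients.items()}})
        pd.DataFrame(resp_rows).to_csv(outdir / "type_responses.csv", index=False)

    loc_rows = []
    axes = {"elevation_m": env.elevation, "coast_distance_km": env.coast_distance}
    for name in model.class_names:
        row = {"class": name}
        for axis_name, axis in axes.items():
            for tag, fld in (("baseline", baseline_field), ("warmest", future_fields[-1])):
                try:
                    row[f"{tag}_{axis_name}"] = weighted_location(fld, axis, name)
                except ValueError:
                    # a type can lose all probability mass under extreme warming
                    row[f"{tag}_{axis_name}"] = float("nan")
        loc_rows.append(row)
    pd.DataFrame(loc_rows).to_csv(outdir / "weighted_locations.csv", index=False)

    correlates = sensitivity_correlates(
        summary.sensitivity, env.samples(),
        drop=cfg.impact["drop_predictors"])
    with open(outdir / "sensitivity_correlates.json", "w") as fh:
        json.dump(correlates, fh, indent=2)
    return {**state, "suite": suite, "impact_summary": summary}


def stage_report(cfg: PipelineConfig, outdir: Path, state=None, log=print) -> dict:
    state = state or {}
    report = {}
    for name in ("fit_metrics.json", "sensitivity_correlates.json"):
        p = outdir / name
        if p.exists():
            with open(p) as fh:
                report[name.removesuffix(".json")] = json.load(fh)
    reg = outdir / "regional_change.csv"
    if reg.exists():
        df = pd.read_csv(reg)
        report["regional_change"] = {
            "max_bray_curtis": float(df["regional_bray_curtis"].max()),
            "spearman_vs_delta_mat": float(
                df["regional_bray_curtis"].corr(df["delta_mat"], method="spearman")),
        }
    summary = state.get("impact_summary")
    if summary is not None:
        report["impact"] = {
            "sensitivity_range": [float(np.min(summary.sensitivity)),
                                  float(np.max(summary.sensitivity))],
            "exposure_range": [float(np.min(summary.exposure)),
                               float(np.max(summary.exposure))],
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log(f"[report] wrote {outdir / 'report.json'}")
    return state


_STAGE_FUNCS = {"simulate": stage_simulate, "fit": stage_fit,
                "project": stage_project, "impact": stage_impact,
                "report": stage_report}

_STAGE_ARTIFACTS = {
    "simulate": ["environment.tif", "vegetation.tif", "truth_model.json"],
    "fit": ["model.json", "fit_metrics.json", "model_comparison.csv"],
    "project": ["baseline_field.tif", "frequencies.csv", "cooccurrence.csv",
                "pmax_histogram.json"],
    "impact": ["sensitivity.tif", "exposure.tif", "vulnerability.tif",
               "regional_change.csv", "type_responses.csv",
               "weighted_locations.csv", "sensitivity_correlates.json"],
    "report": ["report.json"],
}


def run_pipeline(config, outdir=None, stages=STAGES, seed: int | None = None,
                 log=print) -> RunManifest:
    """Run the requested stages in order and return the run manifest.

    ``config`` is a path to a YAML file or a config mapping; ``seed``
    overrides every stage seed at once.  Stage failures raise with the
    stage name attached.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    elif isinstance(config, PipelineConfig):
        cfg = config
    else:
        cfg = PipelineConfig.from_dict(config)
    if seed is not None:
        cfg.landscape["seed"] = seed
        cfg.model["seed"] = seed
        cfg.scenarios["seed"] = seed
    outdir = Path(outdir or cfg.output["directory"])
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        config_hash=cfg.config_hash,
        software_version=__version__,
        seeds={"landscape": cfg.landscape["seed"], "model": cfg.model["seed"],
               "scenarios": cfg.scenarios["seed"]},
    )
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2)

    state: dict = {}
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
        try:
            state = _STAGE_FUNCS[stage](cfg, outdir, state, log=log) \
                if stage != "simulate" else stage_simulate(cfg, outdir, log=log)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        produced = [n for n in _STAGE_ARTIFACTS[stage] if (outdir / n).exists()]
        manifest.record(stage, outdir, produced)
    manifest.write(outdir)
    return manifest
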