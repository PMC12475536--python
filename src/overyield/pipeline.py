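"""End-to-end orchestration: data -> metrics -> partition -> models -> SEM.

A single declarative config drives the full analysis. Every subset rule is a
named, counted filter recorded in the run manifest: plots with abiotic
manipulations are excluded, richness is capped at six, and the SEM sees only
experiments whose height and diameter inventories are at most a year apart
and plots with defined structural diversity. Standardization is recomputed
on each analysis subset, never inherited.

All randomness flows from the single ``seed``; outputs are CSV tables with
provenance header comments plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import inventory as inv
from . import partition as pt
from .diversity import plot_metrics
from .errors import OveryieldError
from .mixedmodels import FitResult, coefficient_table, fit_h1, fit_h3, fit_h4
from .sem import SemSpec, fit_piecewise
from .standardize import DEFAULT_RULES, apply_scaling
from .synthetic import GeneratorConfig, generate, scenario

log = logging.getLogger("overyield")

MAX_RICHNESS = 6
MAX_HEIGHT_INTERVAL_YR = 1.0


class PipelineStageError(OveryieldError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 1
    source: str = "synthetic"               # 'synthetic' | 'files'
    scenario: str = "paper_like"
    generator: dict = field(default_factory=dict)   # GeneratorConfig overrides
    files: dict = field(default_factory=dict)       # trees/plots/traits paths
    analyses: tuple[str, ...] = ("partition", "h1", "h3", "h4", "sem")
    structural_metric: str = "gini"
    sem_interaction: str = "richness:structural"
    max_richness: int = MAX_RICHNESS
    outdir: str = "results/run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise OveryieldError(f"unknown config keys: {sorted(unknown)}")
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(**raw)


def _write_csv(df: pd.DataFrame, path: Path, seed: int, stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# overyield {__version__}\n# seed: {seed}\n# stage: {stage}\n")
        df.to_csv(fh, index=False)


def _comp_label(comp: dict) -> str:
    return "+".join(sorted(comp))


def load_inputs(config: PipelineConfig):
    """Obtain (trees, plots, traits) from the generator or from CSV files."""
    if config.source == "synthetic":
        gen_cfg = scenario(config.scenario, seed=config.seed, **config.generator)
        ds = generate(gen_cfg)
        return ds.trees, ds.plots, ds.traits, ds.truth
    if config.source == "files":
        trees = inv.read_trees(config.files["trees"], config.files.get("tree_columns"))
        plots = inv.read_plots(config.files["plots"], config.files.get("plot_columns"))
        traits = inv.read_traits(config.files["traits"], config.files.get("trait_columns"))
        return trees, plots, traits, None
    raise OveryieldError(f"unknown source {config.source!r}")


def run(config: PipelineConfig) -> dict:
    """Execute the configured analyses; returns the manifest dict.

    Partial outputs are kept on stage failure; the error is re-raised
    labelled with its stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": f"overyield {__version__}",
        "seed": config.seed,
        "config": {**dataclasses.asdict(config), "analyses": list(config.analyses)},
        "stages": [],
        "filters": [],
        "outputs": [],
    }

    def record_filter(name, before, after):
        manifest["filters"].append({"filter": name, "before": int(before), "after": int(after),
                                    "removed": int(before - after)})
        log.info("filter %s: %d -> %d plots", name, before, after)

    def finish_stage(name):
        manifest["stages"].append(name)

    stage = "load"
    try:
        trees, plots, traits, truth = load_inputs(config)
        inv.validate_traits(traits, plots)
        finish_stage(stage)

        stage = "filter"
        n0 = len(plots)
        plots = plots[~plots["abiotic_manipulation"].astype(bool)]
        record_filter("abiotic_manipulation", n0, len(plots))
        n0 = len(plots)
        plots = plots[plots["composition"].map(len) <= config.max_richness]
        record_filter(f"richness<={config.max_richness}", n0, len(plots))
        plots = plots.reset_index(drop=True)
        trees = trees[trees["plot_id"].isin(set(plots["plot_id"]))].reset_index(drop=True)
        finish_stage(stage)

        stage = "metrics"
        metrics = plot_metrics(trees, plots, traits, structural_metric=config.structural_metric)
        metrics["composition"] = plots.set_index("plot_id")["composition"].map(_comp_label).reindex(
            metrics["plot_id"]
        ).to_numpy()
        _write_csv(metrics, outdir / "metrics.csv", config.seed, "metrics")
        manifest["outputs"].append("metrics.csv")
        finish_stage(stage)

        stage = "partition"
        part = None
        if "partition" in config.analyses or "h3" in config.analyses:
            prod = inv.productivity_table(trees, plots).set_index("plot_id")["productivity"]
            spt = inv.species_productivity_table(trees, plots)
            part, details = pt.partition_table(plots, prod, spt, return_details=True)
            part["composition"] = part["plot_id"].map(
                plots.set_index("plot_id")["composition"].map(_comp_label)
            )
            _write_csv(part, outdir / "partition.csv", config.seed, "partition")
            _write_csv(
                pt.delta_ry_table(details), outdir / "partition_species.csv",
                config.seed, "partition",
            )
            manifest["outputs"] += ["partition.csv", "partition_species.csv"]
            ok = part[part["flag"] == "ok"]
            manifest["partition_summary"] = {
                "n_mixtures": int(len(part)),
                "n_partitioned": int(len(ok)),
                "mean_nbe": float(ok["nbe"].mean()),
                "mean_se": float(ok["se"].mean()),
                "mean_ce": float(ok["ce"].mean()),
                "se_share": float(ok["se"].mean() / ok["nbe"].mean())
                if len(ok) and abs(ok["nbe"].mean()) > 1e-12
                else float("nan"),
            }
            finish_stage(stage)

        if "h1" in config.analyses:
            stage = "h1"
            sub = apply_scaling(metrics, DEFAULT_RULES)
            fit = fit_h1(sub)
            _write_csv(coefficient_table(fit), outdir / "h1_coefficients.csv", config.seed, stage)
            manifest["outputs"].append("h1_coefficients.csv")
            manifest["h1"] = _fit_summary(fit)
            finish_stage(stage)

        if "h3" in config.analyses:
            stage = "h3"
            ok = part[part["flag"] == "ok"]
            merged = ok.merge(
                metrics[["plot_id", "cwm_wd", "cwm_lnc", "fdis_wd", "fdis_lnc"]], on="plot_id"
            )
            sub = apply_scaling(merged, DEFAULT_RULES)
            manifest["h3"] = {}
            for resp in ("se", "ce", "nbe"):
                fit = fit_h3(sub, resp)
                name = f"h3_{resp}_coefficients.csv"
                _write_csv(coefficient_table(fit), outdir / name, config.seed, stage)
                manifest["outputs"].append(name)
                manifest["h3"][resp] = _fit_summary(fit)
            finish_stage(stage)

        if "h4" in config.analyses:
            stage = "h4"
            spt = inv.species_productivity_table(trees, plots)
            sp_table = spt.merge(traits[["species", "wd", "lnc", "class"]], on="species")
            plot_info = plots.set_index("plot_id")
            sp_table["block"] = sp_table["plot_id"].map(plot_info["block"])
            sp_table["richness"] = sp_table["plot_id"].map(plot_info["composition"].map(len))
            sp_table["composition"] = sp_table["plot_id"].map(
                plot_info["composition"].map(_comp_label)
            )
            # traits z-scored across experiments; species productivity stays on
            # its raw nonnegative scale for the log-plus-constant transform
            h4_rules = [r for r in DEFAULT_RULES if r.variable in ("wd", "lnc")]
            sub = apply_scaling(sp_table, h4_rules)
            fit = fit_h4(sub)
            _write_csv(coefficient_table(fit), outdir / "h4_coefficients.csv", config.seed, stage)
            manifest["outputs"].append("h4_coefficients.csv")
            manifest["h4"] = _fit_summary(fit) | {"log_constant": fit.constant}
            finish_stage(stage)

        if "sem" in config.analyses:
            stage = "sem"
            plot_info = plots.set_index("plot_id")
            interval = plot_info["height_diam_interval_yr"].reindex(metrics["plot_id"]).to_numpy()
            n0 = len(metrics)
            sem_data = metrics[interval <= MAX_HEIGHT_INTERVAL_YR]
            record_filter("height_diam_interval<=1yr", n0, len(sem_data))
            n0 = len(sem_data)
            sem_data = sem_data.dropna(subset=["structural", "fdis_all", "productivity"])
            record_filter("structural_diversity_defined", n0, len(sem_data))
            sub = apply_scaling(sem_data, DEFAULT_RULES)
            res = fit_piecewise(
                SemSpec(interaction=config.sem_interaction,
                        structural_metric=config.structural_metric),
                sub,
            )
            _write_csv(res.paths, outdir / "sem_paths.csv", config.seed, stage)
            (outdir / "sem_report.txt").write_text(
                f"# overyield {__version__}\n# seed: {config.seed}\n" + res.report() + "\n"
            )
            manifest["outputs"] += ["sem_paths.csv", "sem_report.txt"]
            manifest["sem"] = {
                "c_stat": res.c_stat,
                "df": res.df,
                "pvalue": res.pvalue,
                "aic": res.aic,
                "n_experiments": int(sem_data["experiment"].nunique()),
                "indirect": res.indirect,
            }
            finish_stage(stage)
    except Exception as err:  # noqa: BLE001 — re-labelled with the failing stage
        manifest["error"] = {"stage": stage, "message": str(err)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_safe))
        raise PipelineStageError(stage, err) from err

    if truth is not None:
        manifest["truth"] = {
            "expected_mean_nbe": truth["expected_mean_nbe"],
            "expected_se_share": truth["expected_se_share"],
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_safe))
    return manifest


def _fit_summary(fit: FitResult) -> dict:
    return {
        "params": {k: float(v) for k, v in fit.params.items()},
        "pvalues": {k: float(v) for k, v in fit.pvalues.items()},
        "dispersion": {k: float(v) for k, v in fit.disp_params.items()},
        "vc": {k: float(v) for k, v in fit.vc.items()},
        "loglik": float(fit.loglik),
        "aic": float(fit.aic),
        "nobs": int(fit.nobs),
    }


def _json_safe(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    return str(obj)
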