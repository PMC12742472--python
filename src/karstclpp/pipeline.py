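"""End-to-end orchestration: simulate or read inputs, run the CLPP,
diversity, CFU, and environmental-statistics stages, and write TSV outputs
plus a JSON run manifest sufficient to reproduce every output."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .clpp import clpp_timecourse, substrate_profile, substrate_prevalence
from .cultivation import cfu_per_g_dm
from .diversity import alpha_diversity_report, rarefaction_curve
from .envstats import (
    DEFAULT_CLUSTER_PARAMETERS,
    cluster_samples,
    exceedance_report,
    spearman_screen,
)
from .io import (
    default_layout,
    read_dilution_counts,
    read_env_table,
    read_otu_table,
    read_plate_series,
    read_substrate_registry,
)
from .model import ValidationError, standard_conditions
from . import synthetic

log = logging.getLogger("karstclpp")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``).

    ``inputs`` maps stage inputs to file paths; ``simulate`` holds generator
    parameter blocks for stages that should run on synthetic data instead.
    CLI flags override config keys upstream of construction.
    """

    output_dir: Path
    seed: int = 0
    threshold: float = 0.400
    threshold_on: str = "response"
    censored_policy: str = "half_limit"
    alpha: float = 0.05
    rarefaction_depth: int | None = None
    cluster_parameters: tuple[str, ...] | None = DEFAULT_CLUSTER_PARAMETERS
    inputs: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)
    layout_path: Path | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "output_dir" not in raw:
            raise ValidationError("config must set output_dir")
        raw["output_dir"] = Path(raw["output_dir"])
        if raw.get("layout_path"):
            raw["layout_path"] = Path(raw["layout_path"])
        if "cluster_parameters" in raw and raw["cluster_parameters"] is not None:
            raw["cluster_parameters"] = tuple(raw["cluster_parameters"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _preflight(config: RunConfig) -> list[str]:
    """Check referenced paths before running any stage."""
    paths = []
    if config.layout_path:
        paths.append(config.layout_path)
    for key, val in config.inputs.items():
        if key == "plates":
            for spec in val:
                paths.append(spec["path"])
        else:
            paths.append(val)
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise PipelineError(f"pre-flight: missing input paths {missing}")
    return [str(p) for p in paths]


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order and return the run
    manifest (also written to ``<output_dir>/manifest.json``).

    Stage failures abort the run with the failing stage named. Outputs are
    deterministic given the config (all randomness flows from recorded
    seeds), so re-running from a manifest's config reproduces every output
    byte-identically.
    """
    logging.basicConfig(level=config.log_level)
    inputs_seen = _preflight(config)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    layout = (
        read_substrate_registry(config.layout_path)
        if config.layout_path else default_layout()
    )
    conditions = standard_conditions()
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "inputs": inputs_seen,
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        log.info("stage %s: %s", stage, info)

    # ---- CLPP ----
    try:
        series_list = []
        for spec in config.inputs.get("plates", []):
            cond = conditions[spec.get("condition", "20C_aerobic")]
            series_list.append(read_plate_series(
                spec["path"], layout, cond, sample_id=spec.get("sample_id"),
            ))
        for i, block in enumerate(config.simulate.get("plates", [])):
            block = dict(block)
            cond = conditions[block.pop("condition", "20C_aerobic")]
            sample_id = block.pop("sample_id", f"SIM{i + 1}")
            block.setdefault("seed", config.seed + i)
            params = synthetic.PlateSimParams(**block)
            series_list.append(synthetic.simulate_plate(
                params, cond, sample_id=sample_id, layout=layout,
            ))
        if series_list:
            profiles = []
            for series in series_list:
                metrics = clpp_timecourse(
                    series, config.threshold, config.threshold_on
                )
                name = f"clpp_{series.sample_id}_{series.condition.label()}.tsv"
                _write(metrics.table, out / name)
                manifest["outputs"].append(name)
                profiles.append(
                    substrate_profile(series, series.times_h[-1])
                )
            prevalence = substrate_prevalence(profiles, config.threshold)
            _write(prevalence.rename_axis("position"), out / "substrate_prevalence.tsv")
            manifest["outputs"].append("substrate_prevalence.tsv")
            record("clpp", n_plates=len(series_list))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage clpp failed: {exc}") from exc

    # ---- diversity ----
    try:
        otu = None
        if "otu" in config.inputs:
            otu = read_otu_table(config.inputs["otu"])
        elif "otu" in config.simulate:
            block = dict(config.simulate["otu"])
            block.setdefault("seed", config.seed)
            otu = synthetic.simulate_otu_table(
                synthetic.CommunitySimParams(**block)
            )
        if otu is not None:
            report = alpha_diversity_report(
                otu, depth=config.rarefaction_depth, seed=config.seed
            )
            _write(report, out / "alpha_diversity.tsv")
            curves = rarefaction_curve(otu, mode="analytic")
            _write(curves, out / "rarefaction_curves.tsv", index=False)
            manifest["outputs"] += ["alpha_diversity.tsv", "rarefaction_curves.tsv"]
            record("diversity", n_samples=len(otu.samples),
                   rarefied_depth=int(report["rarefied_depth"].iloc[0]))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage diversity failed: {exc}") from exc

    # ---- environmental statistics ----
    try:
        env = None
        if "env" in config.inputs:
            env = read_env_table(config.inputs["env"])
        elif "env" in config.simulate:
            block = dict(config.simulate["env"])
            block.setdefault("seed", config.seed)
            env = synthetic.simulate_env_table(**block)
        if env is not None:
            dendro = cluster_samples(
                env, config.censored_policy,
                parameters=config.cluster_parameters,
            )
            (out / "sample_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
            manifest["outputs"].append("sample_dendrogram.nwk")
            if env.regulatory_limit is not None and env.regulatory_limit.notna().any():
                exc_report = exceedance_report(env)
                rows = [
                    {"parameter": p, "samples_above_limit": ",".join(s)}
                    for p, s in exc_report.items()
                ]
                _write(pd.DataFrame(rows), out / "limit_exceedance.tsv", index=False)
                manifest["outputs"].append("limit_exceedance.tsv")
            shared = (
                set(otu.samples) & set(env.samples) if otu is not None else set()
            )
            if otu is not None and len(shared) >= 4:
                screen = spearman_screen(
                    otu.relative_abundance(), env.substituted(config.censored_policy),
                    alpha=config.alpha, seed=config.seed,
                )
                _write(screen.table, out / "spearman_screen.tsv", index=False)
                manifest["outputs"].append("spearman_screen.tsv")
            record("envstats", n_samples=len(env.samples))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage envstats failed: {exc}") from exc

    # ---- CFU ----
    try:
        recs = None
        if "dilution_counts" in config.inputs:
            recs = read_dilution_counts(config.inputs["dilution_counts"])
        if recs:
            rows = []
            for rec in recs:
                res = cfu_per_g_dm(rec)
                rows.append({
                    "sample_id": res.sample_id, "medium": res.medium,
                    "condition": res.condition,
                    "mean_x10e4_cfu_per_g_dm": res.mean_cfu_per_g_dm / 1e4,
                    "sd_x10e4_cfu_per_g_dm": (
                        res.sd_cfu_per_g_dm / 1e4
                        if res.sd_cfu_per_g_dm is not None else ""
                    ),
                    "n_replicates": res.n_replicates,
                })
            _write(pd.DataFrame(rows), out / "cfu.tsv", index=False)
            manifest["outputs"].append("cfu.tsv")
            record("cfu", n_records=len(recs))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage cfu failed: {exc}") from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
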