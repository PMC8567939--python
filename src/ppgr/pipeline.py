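"""End-to-end orchestration: simulate/load -> fit -> metrics -> compare.

A run is driven by a :class:`RunConfig` (round-trippable through YAML)
and produces, under its output directory: per-group-period posterior
summary CSVs, fitted-curve and population-curve CSVs, a glycemic summary
table, the comparison table, and a key=value manifest recording the seed,
every file written and the convergence status of every fit.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import AnalysisDataset, align_period, read_cgm_csv, read_food_diary
from .metrics import aggregate_histogram, summaries_frame, trace_summary
from .model import (
    PosteriorResult,
    PriorConfig,
    population_response_curve,
    summarize_posterior,
    variance_explained,
)
from .sampler import SamplerConfig, fit_model, posterior_fitted_curve, _curve_draws
from .stats import build_group_table
from .synthetic import GROUPS, SimulationConfig, SyntheticCohort, generate_cohort

log = logging.getLogger("ppgr")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, message: str, manifest: dict) -> None:
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.manifest = manifest


@dataclasses.dataclass
class RunConfig:
    """Pipeline settings.

    ``source`` is either the string ``"simulate"`` or a mapping with
    ``cgm`` and ``diary`` CSV paths plus an optional ``group_map``
    (patient_id -> group; defaults to the longest group label prefixing
    the patient id).
    """

    outdir: str = "ppgr_run"
    seed: int = 0
    source: str | Mapping[str, object] = "simulate"
    simulation: dict = dataclasses.field(default_factory=dict)
    prior: dict = dataclasses.field(default_factory=dict)
    sampler: dict = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def simulation_config(self) -> SimulationConfig:
        kw = dict(self.simulation)
        kw.setdefault("seed", self.seed)
        for key in ("group_beta_mean", "group_alpha_mean"):
            if key in kw:  # YAML maps use 'GROUP.period' string keys
                kw[key] = {
                    tuple(k.split(".")) if isinstance(k, str) else tuple(k): v
                    for k, v in kw[key].items()
                }
        if "carb_range" in kw:
            kw["carb_range"] = tuple(kw["carb_range"])
        return SimulationConfig(**kw)

    def prior_config(self) -> PriorConfig:
        return PriorConfig(**self.prior)

    def sampler_config(self) -> SamplerConfig:
        return SamplerConfig(**self.sampler)


def _load_datasets(
    config: RunConfig,
) -> tuple[dict[tuple[str, str], list[AnalysisDataset]], list, SyntheticCohort | None]:
    """Return datasets keyed by (group, period), all traces, and the cohort
    when the source is synthetic."""
    if config.source == "simulate":
        cohort = generate_cohort(config.simulation_config())
        grouped: dict[tuple[str, str], list[AnalysisDataset]] = {}
        traces = []
        for p in cohort.patients:
            grouped.setdefault((p.group, p.period), []).append(p.dataset())
            traces.append((p.group, p.trace))
        return grouped, traces, cohort

    src = dict(config.source)
    cgm_path, diary_path = src["cgm"], src["diary"]
    for path in (cgm_path, diary_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    group_map = src.get("group_map") or {}
    traces_list, report = read_cgm_csv(cgm_path)
    for line in report.lines():
        log.info(line)
    meals, mreport = read_food_diary(diary_path)
    for line in mreport.lines():
        log.info(line)

    def _group_of(pid: str) -> str:
        if pid in group_map:
            return group_map[pid]
        matches = [g for g in GROUPS if pid.startswith(g)]
        if not matches:
            raise ValueError(f"cannot infer group for patient {pid!r}")
        return max(matches, key=len)

    grouped = {}
    traces = []
    for tr in traces_list:
        g = _group_of(tr.patient_id)
        ds = align_period(tr, [m for m in meals if m.patient_id == tr.patient_id])
        grouped.setdefault((g, tr.period), []).append(ds)
        traces.append((g, tr))
    return grouped, traces, None


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run simulate/load -> fit -> metrics -> compare; return the manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "outputs": [],
    }

    def _write(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(str(path))
        return path

    # --- stage 1: data ---
    try:
        grouped, traces, cohort = _load_datasets(config)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("data", str(exc), manifest) from exc
    if cohort is not None:
        paths = cohort.write_fixtures(outdir / "data")
        manifest["outputs"] += [str(p) for p in paths.values()]

    # --- stage 2: fit ---
    results: dict[tuple[str, str], PosteriorResult] = {}
    prior = config.prior_config()
    sampler_cfg = config.sampler_config()
    r2: dict[tuple[str, str], float] = {}
    try:
        for (g, period), datasets in sorted(grouped.items()):
            log.info("fitting %s/%s (%d patients)", g, period, len(datasets))
            res = fit_model(datasets, prior, sampler_cfg, seed=config.seed)
            res.group = g
            results[(g, period)] = res
            _write(summarize_posterior(res), f"posterior_{g}_{period}.csv")
            _write(
                population_response_curve(res, 1.0, np.arange(-90.0, 91.0, 5.0)),
                f"population_curve_{g}_{period}.csv",
            )
            for ds in datasets:
                curve = posterior_fitted_curve(res, ds)
                mask = ds.observed_mask
                r2[(ds.patient_id, period)] = variance_explained(
                    ds.glucose[mask], curve["mean"].to_numpy()[mask]
                )
            curves = pd.concat(
                [
                    posterior_fitted_curve(res, ds).assign(patient_id=ds.patient_id)
                    for ds in datasets
                ]
            )
            _write(curves, f"fitted_curves_{g}_{period}.csv")
        manifest["converged"] = all(r.converged for r in results.values())
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit", str(exc), manifest) from exc

    # --- stage 3: glycemic metrics ---
    try:
        summaries = []
        for g, tr in traces:
            s = trace_summary(tr, r_squared=r2.get((tr.patient_id, tr.period)))
            summaries.append((g, s))
        frame = summaries_frame([s for _, s in summaries])
        frame.insert(1, "group", [g for g, _ in summaries])
        _write(frame, "glycemic_summaries.csv")
        for (g, period) in sorted({(g, s.period) for g, s in summaries}):
            hist = aggregate_histogram(
                [tr for gg, tr in traces if gg == g and tr.period == period]
            )
            _write(hist, f"histogram_{g}_{period}.csv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("metrics", str(exc), manifest) from exc

    # --- stage 4: comparison table ---
    try:
        tidy = _tidy_values(frame, results)
        table = build_group_table(tidy)
        _write(table, "comparison_table.csv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("compare", str(exc), manifest) from exc

    manifest_path = outdir / "manifest.txt"
    with open(manifest_path, "w") as fh:
        fh.write(f"version={manifest['version']}\n")
        fh.write(f"seed={manifest['seed']}\n")
        fh.write(f"converged={manifest.get('converged')}\n")
        for p in manifest["outputs"]:
            fh.write(f"output={p}\n")
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _tidy_values(frame: pd.DataFrame, results) -> pd.DataFrame:
    """Long-format metric values feeding the comparison table."""
    metric_cols = [
        c
        for c in frame.columns
        if c not in ("patient_id", "group", "period") and frame[c].notna().any()
    ]
    rows = []
    for _, r in frame.iterrows():
        for c in metric_cols:
            rows.append(
                {
                    "patient_id": r["patient_id"],
                    "group": r["group"],
                    "period": r["period"],
                    "metric": c,
                    "value": r[c],
                }
            )
    for (g, period), res in results.items():
        summ = summarize_posterior(res)
        for name in ("beta_p", "alpha_p"):
            sub = summ[summ["parameter"] == name]
            for _, r in sub.iterrows():
                rows.append(
                    {
                        "patient_id": r["patient"],
                        "group": g,
                        "period": period,
                        "metric": name,
                        "value": r["mean"],
                    }
                )
    return pd.DataFrame(rows)
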