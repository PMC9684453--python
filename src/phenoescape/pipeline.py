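"""End-to-end orchestration: records → window screen → per-group fits →
summaries and cross-continent comparisons → gridded projection → report.

A single global seed fans out deterministically to per-stage seeds
(NumPy ``SeedSequence`` children), so a rerun with the same config and
seed reproduces every artifact byte-for-byte.  Each stage persists its
outputs under the run directory; the projection stage reads cached fit
summaries from disk, so downstream stages can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import ClimateGrid, read_grid, write_grid
from .model import MCMCConfig, PriorSpec, fit_all_groups
from .projection import (
    WindowMap,
    continental_summary,
    delta_window,
    light_window,
    mask_forest,
    predict_surface,
    scenario_delta_summary,
)
from .records import RecordSet, read_records, write_records
from .results import ParameterSummary, compare_intervals
from .simulate import simulate_grids, simulate_monthly, simulate_study, SyntheticConfig
from .windows import screen_windows

log = logging.getLogger("phenoescape")

STAGES = ("simulate", "screen", "fit", "project", "report")


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    outdir: str = "phenoescape_run"
    seed: int = 0
    # either a records CSV or synthetic-study settings
    records_path: str | None = None
    synthetic: dict = field(default_factory=dict)  # kwargs to simulate_study
    # grids: either paths or synthetic fixture settings
    grid_paths: dict = field(default_factory=dict)  # keys: spring_temp_current, ...
    grid_extent: tuple = (-90.0, -70.0, 38.0, 52.0)
    grid_resolution: float = 1.0
    scenario_delta: float = 5.0
    # model settings
    priors: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    run_screen: bool = True
    mask_threshold: float = 0.01
    delta_future_minus_current: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = np.random.SeedSequence(
            [self.seed, STAGES.index(stage) + 1]
        ).generate_state(1, dtype=np.uint32)
        return int(h[0]) % (2**31)


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages; returns a dict of artifact paths.

    Any stage failure raises with a stage-labelled message.  Later stages
    read the persisted outputs of earlier ones, so a subset of stages can
    be rerun against cached artifacts.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    for stage in stages:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, out, artifacts)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage label
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.info("stage %-8s done in %.2f s", stage, time.perf_counter() - t0)
    _write_manifest(config, out, artifacts)
    return artifacts


# ---------------------------------------------------------------------- #
def _stage_simulate(config: PipelineConfig, out: Path, art: dict) -> None:
    if config.records_path:
        report = read_records(config.records_path)
        rs = report.recordset
        report.write_rejects(out / "rejects.csv")
        art["rejects"] = str(out / "rejects.csv")
    else:
        rs, manifest = simulate_study(
            seed=config.stage_seed("simulate"), **config.synthetic
        )
        with open(out / "true_parameters.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        art["true_parameters"] = str(out / "true_parameters.json")
    write_records(rs, out / "records.csv")
    art["records"] = str(out / "records.csv")

    if not config.grid_paths:
        grids = simulate_grids(
            extent=tuple(config.grid_extent),
            resolution=config.grid_resolution,
            scenario_delta=config.scenario_delta,
        )
        for name, g in grids.items():
            p = out / f"grid_{name}.nc"
            write_grid(g, p)
            art[f"grid_{name}"] = str(p)


def _stage_screen(config: PipelineConfig, out: Path, art: dict) -> None:
    if not config.run_screen:
        return
    report = read_records(out / "records.csv")
    rs = report.recordset
    monthly = simulate_monthly(
        SyntheticConfig(seed=config.stage_seed("screen")), rs
    )
    result = screen_windows(rs, monthly)
    result.write_csv(out / "window_screen.csv")
    art["window_screen"] = str(out / "window_screen.csv")


def _stage_fit(config: PipelineConfig, out: Path, art: dict) -> None:
    report = read_records(out / "records.csv")
    rs = report.recordset
    priors = PriorSpec(**config.priors)
    mcmc = MCMCConfig(seed=config.stage_seed("fit"), **config.mcmc)
    fits = fit_all_groups(rs, priors=priors, mcmc=mcmc)
    summaries = {}
    for (stratum, continent), res in fits.items():
        key = f"{stratum}_{continent}"
        res.save_draws_csv(out / f"draws_{key}.csv")
        art[f"draws_{key}"] = str(out / f"draws_{key}.csv")
        summaries[key] = res.to_summary_json()
        summaries[key]["predictive_r2"] = res.predictive_r2()
        summaries[key]["r2_sse"] = res.r2_sse()
    with open(out / "fit_summaries.json", "w") as fh:
        json.dump(summaries, fh, indent=1, sort_keys=True)
    art["fit_summaries"] = str(out / "fit_summaries.json")

    # cross-continent sensitivity comparisons per stratum
    rows = []
    for stratum in ("tree", "wildflower"):
        keys = [k for k in summaries if k.startswith(stratum + "_")]
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                a = _summary_from_json(summaries[ka], "beta1")
                b = _summary_from_json(summaries[kb], "beta1")
                cmp_ = compare_intervals(a, b)
                rows.append(
                    {"stratum": stratum, "a": ka, "b": kb,
                     "verdict": cmp_.verdict}
                )
    pd.DataFrame(rows, columns=["stratum", "a", "b", "verdict"]).to_csv(
        out / "comparisons.csv", index=False
    )
    art["comparisons"] = str(out / "comparisons.csv")


def _summary_from_json(summary_json: dict, name: str) -> ParameterSummary:
    p = summary_json["parameters"][name]
    return ParameterSummary(
        name=name, mean=p["mean"], median=p["median"], sd=p["sd"],
        lower=p["lower"], upper=p["upper"],
    )


def _load_group_summaries(out: Path) -> dict:
    with open(out / "fit_summaries.json") as fh:
        return json.load(fh)


def _stage_project(config: PipelineConfig, out: Path, art: dict) -> None:
    summaries = _load_group_summaries(out)

    def grid(name: str) -> ClimateGrid:
        if name in config.grid_paths:
            return read_grid(config.grid_paths[name])
        return read_grid(out / f"grid_{name}.nc")

    temp_c = grid("spring_temp_current")
    temp_f = grid("spring_temp_future")
    elev = grid("elevation")
    forest = grid("forest_fraction")

    continents = sorted(
        {k.split("_", 1)[1] for k in summaries if k.startswith("wildflower_")}
        & {k.split("_", 1)[1] for k in summaries if k.startswith("tree_")}
    )
    rows = []
    for cont in continents:
        wf = {n: _summary_from_json(summaries[f"wildflower_{cont}"], n)
              for n in ("community_intercept", "beta1", "beta2")}
        tr = {n: _summary_from_json(summaries[f"tree_{cont}"], n)
              for n in ("community_intercept", "beta1", "beta2")}
        maps = {}
        for scen, temp in (("current", temp_c), ("future", temp_f)):
            ffd = predict_surface(wf, temp, elev, "wildflower", cont)
            lod = predict_surface(tr, temp, elev, "tree", cont)
            wmap = mask_forest(
                light_window(ffd, lod), forest, config.mask_threshold
            )
            maps[scen] = wmap
            p = out / f"window_{cont}_{scen}.nc"
            write_grid(wmap.grid.with_values(
                wmap.grid.values.astype(np.float32)), p)
            art[f"window_{cont}_{scen}"] = str(p)
            mean, sd = continental_summary(wmap)
            rows.append({"continent": cont, "quantity": f"window_{scen}",
                         "mean": mean, "sd": sd})
        dmap = delta_window(
            maps["current"], maps["future"],
            future_minus_current=config.delta_future_minus_current,
        )
        p = out / f"window_{cont}_delta.nc"
        write_grid(dmap.grid.with_values(dmap.grid.values.astype(np.float32)), p)
        art[f"window_{cont}_delta"] = str(p)
        mean, sd = continental_summary(dmap)
        rows.append({"continent": cont, "quantity": "delta_window",
                     "mean": mean, "sd": sd})
        tmean, tsd = scenario_delta_summary(
            temp_c, temp_f, mask=forest, threshold=config.mask_threshold
        )
        rows.append({"continent": cont, "quantity": "delta_spring_temp",
                     "mean": tmean, "sd": tsd})
    pd.DataFrame(rows).to_csv(out / "continental_summaries.csv", index=False)
    art["continental_summaries"] = str(out / "continental_summaries.csv")


def _stage_report(config: PipelineConfig, out: Path, art: dict) -> None:
    lines = ["# phenoescape run report", ""]
    for name in sorted(art):
        lines.append(f"- {name}: {Path(art[name]).name}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
    art["report"] = str(out / "report.md")


def _write_manifest(config: PipelineConfig, out: Path, art: dict) -> None:
    manifest = {
        "phenoescape_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "config": asdict(config),
        "files": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in sorted(art.items())
            if Path(p).exists()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "fit": _stage_fit,
    "project": _stage_project,
    "report": _stage_report,
}
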