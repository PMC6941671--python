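"""End-to-end orchestration: DOE -> simulator -> surrogate -> evaluation.

Each experiment writes its datasets (CSV with a commented units line and a
JSON sidecar recording seeds, ranges and unit mappings), the fitted
surrogates, evaluation reports (per-group R^2/MAE with mean +/- SD),
feature-importance tables, and a run manifest with the config hash and
per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import doe as doe_mod
from . import reduced_lv as rl
from . import surrogate as sg
from .config import ACTIVE_UNIT_MAP, RunConfig, config_hash, config_to_dict

__all__ = ["RunManifest", "ExperimentResult", "run_pv_experiment", "run_stress_experiment"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunManifest:
    """Provenance record for one experiment run."""

    experiment: str
    config_hash: str
    seeds: Dict[str, int]
    row_counts: Dict[str, int]
    best_params: Dict[str, Dict[str, float]]
    reports: Dict[str, Dict[str, float]]
    warnings: List[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ExperimentResult:
    """In-memory handle on everything a run produced."""

    manifest: RunManifest
    train: pd.DataFrame
    test: pd.DataFrame
    models: Dict[str, sg.SurrogateModel]
    reports: Dict[str, sg.EvalReport]
    importance: Dict[str, Dict[str, float]]


def _write_csv(df: pd.DataFrame, path: Path, units_line: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# units: {units_line}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def run_pv_experiment(
    cfg: RunConfig, outdir: Optional[str] = None
) -> ExperimentResult:
    """DOE(80) -> 80 cycles -> 77/3 split -> grid search -> P & V surrogates.

    Returns the in-memory result; when ``outdir`` is given, also writes
    datasets, models, reports and the manifest there.
    """
    started = _now()
    pv = cfg.pv
    ranges = pv.feature_ranges()
    plan = doe_mod.latin_hypercube(pv.n_samples, ranges, cfg.seeds.doe)
    plan = doe_mod.maximin_optimize(plan, pv.maximin_iters, cfg.seeds.maximin)
    train, test = rl.generate_pv_dataset(
        plan, cfg.lv_spec(), cfg.rv_spec(), pv.circulation,
        n_train=pv.n_train, n_test=pv.n_test, seed=cfg.seeds.split, n_out=pv.n_out,
    )

    models, reports, importance, best_params = {}, {}, {}, {}
    for target in ("P_LV", "V_LV"):
        gs = sg.grid_search(
            train, target, cfg.grid, cfg.seeds.train,
            group_key="cycle_id", features=list(rl.PV_FEATURES),
        )
        best_params[target] = gs.best_params
        model = sg.fit(train, target, gs.best_params, cfg.seeds.train,
                       features=list(rl.PV_FEATURES))
        models[target] = model
        reports[target] = sg.evaluate(model, test, group_key="cycle_id")
        importance[target] = sg.feature_importance(model)

    manifest = RunManifest(
        experiment="pv",
        config_hash=config_hash(cfg),
        seeds=dataclasses.asdict(cfg.seeds),
        row_counts={"train": len(train), "test": len(test)},
        best_params=best_params,
        reports={t: r.summary() for t, r in reports.items()},
        started=started,
        finished=_now(),
    )
    result = ExperimentResult(manifest, train, test, models, reports, importance)
    if outdir is not None:
        _write_pv_artifacts(cfg, result, Path(outdir))
    return result


def _pv_summary_table(result: ExperimentResult) -> pd.DataFrame:
    """Truth-vs-predicted trace summaries averaged over the test cycles."""
    frames = []
    for cid, frame in result.test.groupby("cycle_id"):
        truth = rl.PVTrace(chamber="LV", t=frame["t"].to_numpy(),
                           P=frame["P_LV"].to_numpy(), V=frame["V_LV"].to_numpy())
        pred = rl.PVTrace(
            chamber="LV", t=frame["t"].to_numpy(),
            P=sg.predict(result.models["P_LV"], frame[list(rl.PV_FEATURES)]),
            V=np.maximum(sg.predict(result.models["V_LV"], frame[list(rl.PV_FEATURES)]), 1e-6),
        )
        tab = sg.summary_error_table(truth, pred)
        tab.insert(0, "cycle_id", cid)
        frames.append(tab)
    table = pd.concat(frames, ignore_index=True)
    agg = table.groupby(["quantity", "metric"], sort=False).agg(
        truth_mean=("truth", "mean"), truth_sd=("truth", lambda v: float(np.std(v))),
        predicted_mean=("predicted", "mean"),
        predicted_sd=("predicted", lambda v: float(np.std(v))),
        pct_error_mean=("pct_error", "mean"),
        pct_error_sd=("pct_error", lambda v: float(np.std(v))),
    ).reset_index()
    return agg


def _write_pv_artifacts(cfg: RunConfig, result: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    units = ("cycle_id:-, l0_LV:um, l0_RV:um, t0_LV:s, t0_RV:s, "
             "Tmax_LV:kPa, Tmax_RV:kPa, t:s, P_LV:mmHg, V_LV:ml")
    _write_csv(result.train, out / "pv_train.csv", units)
    _write_csv(result.test, out / "pv_test.csv", units)
    sidecar = {
        "seeds": result.manifest.seeds,
        "ranges": {n: [lo, hi] for n, lo, hi in
                   zip(cfg.pv.feature_ranges().names, cfg.pv.feature_ranges().lows,
                       cfg.pv.feature_ranges().highs)},
        "unit_mapping": {k: {"scale": s, "unit": u} for k, (s, u) in ACTIVE_UNIT_MAP.items()},
        "n_out": cfg.pv.n_out,
    }
    _write_json(sidecar, out / "pv_dataset.json")
    for target, model in result.models.items():
        model.save(str(out / f"model_{target}"))
    report_rows = [
        {"model": t, **r.summary()} for t, r in result.reports.items()
    ]
    pd.DataFrame(report_rows).to_csv(out / "pv_scores.csv", index=False,
                                     float_format=_FLOAT_FMT)
    imp = pd.DataFrame(result.importance).rename_axis("feature").reset_index()
    imp.to_csv(out / "pv_importance.csv", index=False, float_format=_FLOAT_FMT)
    _pv_summary_table(result).to_csv(out / "pv_trace_summaries.csv", index=False,
                                     float_format=_FLOAT_FMT)
    _write_json(result.manifest.to_dict(), out / "pv_manifest.json")
    _write_json(config_to_dict(cfg), out / "config.json")


def run_stress_experiment(
    cfg: RunConfig, outdir: Optional[str] = None,
    targets: Optional[List[str]] = None,
) -> ExperimentResult:
    """DOE(120) -> 120 ED stress fields -> 100/20 split -> per-target surrogates.

    Each stress component (S11, S22, S12 by default) gets its own grid
    search and fit, mirroring the separately tuned published models.
    """
    started = _now()
    st = cfg.stress
    ranges = st.feature_ranges()
    plan = doe_mod.latin_hypercube(st.n_samples, ranges, cfg.seeds.doe)
    plan = doe_mod.maximin_optimize(plan, st.maximin_iters, cfg.seeds.maximin)
    train, test = rl.generate_stress_dataset(
        plan, st.geometry, n_train=st.n_train, n_test=st.n_test,
        seed=cfg.seeds.split, PED=st.PED, base_passive=st.base_passive(),
    )

    models, reports, importance, best_params = {}, {}, {}, {}
    for target in (targets if targets is not None else st.targets):
        gs = sg.grid_search(
            train, target, cfg.grid, cfg.seeds.train,
            group_key="model_id", features=list(rl.STRESS_FEATURES),
        )
        best_params[target] = gs.best_params
        model = sg.fit(train, target, gs.best_params, cfg.seeds.train,
                       features=list(rl.STRESS_FEATURES))
        models[target] = model
        reports[target] = sg.evaluate(model, test, group_key="model_id")
        importance[target] = sg.feature_importance(model)

    manifest = RunManifest(
        experiment="stress",
        config_hash=config_hash(cfg),
        seeds=dataclasses.asdict(cfg.seeds),
        row_counts={"train": len(train), "test": len(test)},
        best_params=best_params,
        reports={t: r.summary() for t, r in reports.items()},
        started=started,
        finished=_now(),
    )
    result = ExperimentResult(manifest, train, test, models, reports, importance)
    if outdir is not None:
        _write_stress_artifacts(cfg, result, Path(outdir))
    return result


def _write_stress_artifacts(cfg: RunConfig, result: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    units = ("model_id:-, element_id:-, a:MPa, a_s:MPa, a_f:MPa, a_fs:MPa, "
             "r:mm, theta:rad, z:mm, S11:kPa, S22:kPa, S12:kPa")
    _write_csv(result.train, out / "stress_train.csv", units)
    _write_csv(result.test, out / "stress_test.csv", units)
    sidecar = {
        "seeds": result.manifest.seeds,
        "ranges_mpa": {k: list(v) for k, v in cfg.stress.ranges_mpa.items()},
        "PED_mmHg": cfg.stress.PED,
        "D_mpa_inv": cfg.stress.D_mpa_inv,
        "exponents": cfg.stress.exponents,
        "unit_note": "a-constants in MPa in the table, kPa internally (x1000)",
    }
    _write_json(sidecar, out / "stress_dataset.json")
    for target, model in result.models.items():
        model.save(str(out / f"model_{target}"))
    report_rows = [{"model": t, **r.summary()} for t, r in result.reports.items()]
    pd.DataFrame(report_rows).to_csv(out / "stress_scores.csv", index=False,
                                     float_format=_FLOAT_FMT)
    imp = pd.DataFrame(result.importance).rename_axis("feature").reset_index()
    imp.to_csv(out / "stress_importance.csv", index=False, float_format=_FLOAT_FMT)
    _write_json(result.manifest.to_dict(), out / "stress_manifest.json")
    _write_json(config_to_dict(cfg), out / "config.json")
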