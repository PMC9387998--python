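"""End-to-end orchestration: simulate -> preprocess -> fit -> features ->
stats -> classify/evaluate, with a manifest and per-stage seed fan-out.

A single master seed is expanded into per-stage seeds through
``numpy.random.SeedSequence([master, stage_index])`` so that stages can
be re-run in isolation and the whole run is reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .classify import CohortDataset, make_forest, make_logistic_pipeline
from .damping import fit_second_order
from .evaluate import five_by_two_f_test, tlpo_cv
from .features import build_feature_table
from .preprocess import INVALID, PS_ERROR, QCConfig, label_direction_error, qc_filter
from .stats import MixedModelSpec, fit_metric_model, mann_whitney_error_rate
from .synthetic import SimulationConfig, simulate_cohort

__all__ = [
    "PipelineConfig",
    "stage_seed",
    "preprocess_cohort",
    "fit_cohort",
    "run_pipeline",
]

STAGES = (
    "simulate",
    "validate",
    "preprocess",
    "fit_damping",
    "features",
    "stats",
    "evaluate",
)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    out_dir: str = "runs/latest"
    seed: int = 0
    simulation: SimulationConfig | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    with_forest: bool = True
    with_5x2: bool = False
    tlpo_with_selection: bool = False
    log_level: str = "INFO"


def preprocess_cohort(trajectories, qc: QCConfig | None = None):
    """QC-filter and response-type a cohort.

    Returns ``(table, rejected)``: a saccade-level DataFrame of analyzable
    responses (QC-kept, excluding prosaccade directional errors and
    undeterminable trials) and a DataFrame of exclusions with reasons.
    """
    cfg = qc or QCConfig()
    kept, rejected = qc_filter(trajectories, cfg)
    rows, excluded = [], [
        {"participant_id": s.participant_id, "task": s.task,
         "trial_index": s.trial_index, "reason": r}
        for s, r in rejected
    ]
    for s in kept:
        rtype = label_direction_error(s)
        if rtype in (PS_ERROR, INVALID):
            excluded.append(
                {"participant_id": s.participant_id, "task": s.task,
                 "trial_index": s.trial_index, "reason": rtype}
            )
            continue
        rows.append(
            dict(
                participant_id=s.participant_id,
                group=s.group,
                task=s.task,
                trial_index=s.trial_index,
                target_side=s.target_side,
                response_type=rtype,
                latency_ms=s.latency_ms,
                amplitude_deg=s.amplitude_deg,
                peak_velocity_deg_s=s.peak_velocity_deg_s,
            )
        )
    return pd.DataFrame(rows), pd.DataFrame(excluded)


def fit_cohort(trajectories, table: pd.DataFrame, qc: QCConfig | None = None):
    """Fit the second-order model to every saccade in ``table``.

    Adds ``sigma``, ``omega0``, ``fit_mse``, ``sigma_se`` and ``fit_kept``
    (converged and sigma_se within the precision threshold) columns.
    """
    cfg = qc or QCConfig()
    by_key = {
        (t.participant_id, t.task, t.trial_index): t for t in trajectories
    }
    cols = {c: [] for c in ("sigma", "omega0", "fit_mse", "sigma_se", "fit_kept")}
    for row in table.itertuples(index=False):
        tr = by_key[(row.participant_id, row.task, row.trial_index)]
        try:
            f = fit_second_order(tr, cfg.velocity_threshold_deg_s)
        except ValueError:
            from .damping import SecondOrderFit

            f = SecondOrderFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False)
        cols["sigma"].append(f.sigma)
        cols["omega0"].append(f.omega0)
        cols["fit_mse"].append(f.mse)
        cols["sigma_se"].append(f.sigma_se)
        cols["fit_kept"].append(bool(f.converged and f.sigma_se <= cfg.sigma_se_max))
    out = table.copy()
    for c, v in cols.items():
        out[c] = v
    return out


def _stats_report(table: pd.DataFrame):
    report = {}
    for metric, transform in (
        ("latency_ms", "identity"),
        ("sigma", "identity"),
        ("amplitude_deg", "sqrt"),
    ):
        if metric not in table.columns or table[metric].dropna().empty:
            continue
        res = fit_metric_model(table, MixedModelSpec(metric, transform=transform))
        report[metric] = res.to_dict()
    return report


def run_pipeline(config: PipelineConfig):
    """Run the full synthetic study; returns the manifest dict.

    Every stage persists its outputs under ``config.out_dir`` so it can be
    re-run in isolation; failures abort with the stage name after partial
    outputs are flushed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": []}
    t0 = time.time()

    def record(stage, **outputs):
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": stage_seed(config.seed, stage),
                "elapsed_s": round(time.time() - t0, 2),
                "outputs": {k: str(v) for k, v in outputs.items()},
            }
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "simulate"
    try:
        sim = config.simulation or SimulationConfig(
            n_pd=10, n_control=10, trials_per_task=20
        )
        sim = sim.with_(seed=stage_seed(config.seed, "simulate"))
        trajectories, truth = simulate_cohort(sim)
        sio.write_trajectories(
            trajectories, out / "trajectory_samples.csv", out / "trial_summaries.csv"
        )
        truth.to_csv(out / "truth.csv", index=False)
        record(stage, samples=out / "trajectory_samples.csv",
               summaries=out / "trial_summaries.csv", truth=out / "truth.csv")

        stage = "validate"
        trajectories = sio.read_trajectories(
            out / "trajectory_samples.csv", out / "trial_summaries.csv"
        )
        record(stage)

        stage = "preprocess"
        table, excluded = preprocess_cohort(trajectories, config.qc)
        table.to_csv(out / "saccade_table.csv", index=False)
        excluded.to_csv(out / "excluded.csv", index=False)
        record(stage, table=out / "saccade_table.csv", excluded=out / "excluded.csv")

        stage = "fit_damping"
        fitted = fit_cohort(trajectories, table, config.qc)
        fitted.to_csv(out / "saccade_fits.csv", index=False)
        record(stage, fits=out / "saccade_fits.csv")

        stage = "features"
        feats = build_feature_table(fitted)
        sio.write_feature_table(feats, out / "features.csv")
        record(stage, features=out / "features.csv")

        stage = "stats"
        report = _stats_report(fitted)
        err = feats.set_index("group")["as_error_rate"]
        pd_rates = feats.loc[feats["group"] == "PD", "as_error_rate"].dropna()
        hc_rates = feats.loc[feats["group"] == "control", "as_error_rate"].dropna()
        if len(pd_rates) and len(hc_rates):
            U, p = mann_whitney_error_rate(pd_rates, hc_rates)
            report["as_error_rate"] = {"mann_whitney_U": U, "pvalue": p}
        (out / "stats.json").write_text(json.dumps(report, indent=2, default=float))
        record(stage, stats=out / "stats.json")

        stage = "evaluate"
        ds = CohortDataset.from_feature_table(feats)
        eseed = stage_seed(config.seed, "evaluate")
        logistic = make_logistic_pipeline(with_selection=config.tlpo_with_selection)
        res_l = tlpo_cv(ds.X, ds.y, logistic, seed=eseed)
        evaluation = {
            "logistic": {"auc": res_l.auc, "n_fits": res_l.n_fits,
                         "train_size_per_fit": res_l.train_size_per_fit},
        }
        pd.DataFrame({"fpr": res_l.roc_fpr, "tpr": res_l.roc_tpr}).to_csv(
            out / "roc_logistic.csv", index=False
        )
        if config.with_forest:
            forest = make_forest(n_trees=400)
            res_f = tlpo_cv(ds.X, ds.y, forest, seed=eseed + 1)
            evaluation["forest"] = {"auc": res_f.auc, "n_fits": res_f.n_fits,
                                    "train_size_per_fit": res_f.train_size_per_fit}
            pd.DataFrame({"fpr": res_f.roc_fpr, "tpr": res_f.roc_tpr}).to_csv(
                out / "roc_forest.csv", index=False
            )
            if config.with_5x2:
                cmp = five_by_two_f_test(ds.X, ds.y, logistic, forest, seed=eseed + 2)
                evaluation["five_by_two"] = {
                    "F": cmp.F, "pvalue": cmp.pvalue, "degenerate": cmp.degenerate
                }
        (out / "evaluation.json").write_text(
            json.dumps(evaluation, indent=2, default=float)
        )
        record(stage, evaluation=out / "evaluation.json")
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return manifest
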