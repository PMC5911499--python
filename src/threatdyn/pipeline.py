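"""End-to-end orchestration: measures, fitting, and model comparison.

Thin drivers over the computational modules, shared by the CLI and the
test suite.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio, kinematics
from .bayes_glm import MODEL_SPECS, build_design_matrix, fit_model
from .config import PipelineConfig
from .entropy import EntropyConfig, multiscale_sample_entropy
from .errors import ConfigError
from .model_eval import compare_models, kfold_evaluate

logger = logging.getLogger(__name__)


def load_dataset(data_dir):
    data_dir = Path(data_dir)
    trajectories = dataio.read_trajectories(data_dir / "trajectories.csv")
    trials = dataio.read_trials(data_dir / "trials.csv")
    surveys = dataio.read_surveys(data_dir / "survey.csv")
    return trajectories, trials, surveys


def compute_measures(
    table: pd.DataFrame,
    trajectories: dict,
    entropy_config: EntropyConfig | None = None,
) -> pd.DataFrame:
    """Fill the auc/se_raw/se_log/rt_s columns from the raw trajectories."""
    entropy_config = entropy_config or EntropyConfig()
    table = table.copy()
    aucs, se_raws, se_logs, rts = [], [], [], []
    for rec in table.to_dict(orient="records"):
        traj = trajectories[(rec["participant_id"], rec["trial_id"])]
        norm = kinematics.normalize_trajectory(traj, response=rec["response"])
        aucs.append(kinematics.compute_auc(norm))
        rts.append(kinematics.compute_rt(traj))
        series = kinematics.distance_to_endpoint_series(norm)
        msse = multiscale_sample_entropy(series, entropy_config)
        se_raws.append(msse.se_raw)
        se_logs.append(msse.se_log)
    table["auc"] = aucs
    table["se_raw"] = se_raws
    table["se_log"] = se_logs
    table["rt_s"] = rts
    for col in ("auc", "se_raw", "rt_s"):
        vals = table[col].to_numpy()
        logger.info("%s: mean=%.4f sd=%.4f", col, vals.mean(), vals.std(ddof=1))
    return table


def build_table(config: PipelineConfig):
    trajectories, trials, surveys = load_dataset(config.data_dir)
    table = dataio.build_analysis_table(
        trajectories,
        trials,
        surveys,
        drop_unusable=config.drop_unusable,
        drop_single_response=config.drop_single_response,
    )
    return table, trajectories


def fit_models(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Fit every requested model spec on the full analysis table."""
    fits = {}
    for name in config.models:
        if name not in MODEL_SPECS:
            raise ConfigError(f"unknown model {name!r}")
        spec = MODEL_SPECS[name]
        design = build_design_matrix(table, spec)
        fits[name] = fit_model(
            design,
            table["accuracy"].to_numpy(dtype=float),
            table["participant_id"].to_numpy(),
            spec,
            config.sampler,
        )
        logger.info("fitted %s (%d columns)", name, design.X.shape[1])
    return fits


def run_comparison(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """10-fold evaluation of every requested model plus pairwise comparisons."""
    results = {}
    for name in config.models:
        if name not in MODEL_SPECS:
            raise ConfigError(f"unknown model {name!r}")
        results[name] = kfold_evaluate(
            MODEL_SPECS[name],
            table,
            k=config.kfold_k,
            seed=config.seed,
            sampler_config=config.sampler,
            accuracy_rule=config.accuracy_rule,
        )
    report = {"models": {}, "comparisons": {}}
    for name, res in results.items():
        report["models"][name] = {
            "elpd_in": res.elpd_in.summary(),
            "elpd_out": res.elpd_out.summary(),
            "accuracy_in": res.accuracy_in.summary(),
            "accuracy_out": res.accuracy_out.summary(),
        }
    for a, b in itertools.combinations(config.models, 2):
        elpd_cmp = compare_models(results[a].elpd_out, results[b].elpd_out)
        acc_cmp = compare_models(
            results[a].accuracy_out.overall, results[b].accuracy_out.overall
        )
        report["comparisons"][f"{a}_vs_{b}"] = {
            "elpd_out": elpd_cmp.summary(),
            "accuracy_out": acc_cmp.summary(),
        }
    return report


def format_comparison_report(report: dict) -> str:
    """Plain-text table of ELPD and accuracy summaries with 95% UIs."""
    lines = []
    lines.append(f"{'model':<14}{'ELPD out (95% UI)':<34}{'accuracy out (95% UI)':<30}")
    for name, entry in report["models"].items():
        e = entry["elpd_out"]
        a = entry["accuracy_out"]["overall"]
        lines.append(
            f"{name:<14}"
            f"{e['mean']:9.2f} ({e['q2.5']:9.2f}, {e['q97.5']:9.2f})    "
            f"{a['mean']:6.3f} ({a['q2.5']:6.3f}, {a['q97.5']:6.3f})"
        )
    lines.append("")
    lines.append(f"{'comparison':<30}{'ELPD diff (95% UI)':<34}{'acc diff (95% UI)'}")
    for pair, entry in report["comparisons"].items():
        e = entry["elpd_out"]
        a = entry["accuracy_out"]
        lines.append(
            f"{pair:<30}"
            f"{e['mean']:8.2f} ({e['q2.5']:8.2f}, {e['q97.5']:8.2f})    "
            f"{a['mean']:7.3f} ({a['q2.5']:7.3f}, {a['q97.5']:7.3f})"
        )
    return "\n".join(lines)


def save_fit(fit, out_prefix) -> None:
    """Draws table (CSV) plus a JSON metadata sidecar."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    C, D, p = fit.beta.shape
    chains = np.repeat(np.arange(C), D)
    draw_idx = np.tile(np.arange(D), C)
    df = pd.DataFrame(fit.beta_flat, columns=fit.labels)
    df.insert(0, "chain", chains)
    df.insert(1, "draw", draw_idx)
    df["sigma_u"] = fit.sigma_flat
    df.to_csv(f"{out_prefix}_draws.csv", index=False)
    meta = {
        "spec": fit.spec.to_dict(),
        "labels": fit.labels,
        "transform": fit.meta.to_dict(),
        "sampler": fit.sampler_config.to_dict(),
        "diagnostics": fit.diagnostics,
        "participants": list(fit.participant_index),
    }
    Path(f"{out_prefix}_meta.json").write_text(json.dumps(meta, indent=2))
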