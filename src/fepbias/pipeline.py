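"""End-to-end orchestration: simulate -> score -> clean -> laterality ->
correlations -> models -> Bayesian model averaging -> report.

Every stage persists its table as plain CSV (full float precision) and the
run writes a resolved-config snapshot plus a structured JSON log of counts,
so a seed and a config fully determine the bundle.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict

import pandas as pd

from . import bma as bma_mod
from . import regression as reg_mod
from .cleaning import clean_cohort, sex_analysis_filter
from .config import AQ_SUBSCALES, PipelineConfig
from .cohort import simulate_cohort
from .instruments import score_participants, subscale_alphas
from .laterality import score_laterality

__all__ = ["run_pipeline", "render_report", "write_tables", "read_participants", "read_trials"]

log = logging.getLogger("fepbias")

CONTINUOUS_DESCRIPTIVES = [
    "age",
    "ehi_score",
    "aq_total",
    *AQ_SUBSCALES,
    "lq1",
    "lq2",
]

REPORT_COLUMNS = [
    "term",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "p",
    "sr2",
    "prior_incl",
    "posterior_incl",
    "bf_inclusion",
    "evidence",
]


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_participants(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "age", "sex", "pilot_flag", "bot_response_valid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"participants file {path}: missing columns {sorted(missing)}")
    return df


def read_trials(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {
        "participant_id",
        "trial_index",
        "emotion",
        "left_vf_on_top",
        "is_attention_check",
        "check_passed",
        "chosen_side",
        "rt_ms",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trials file {path}: missing columns {sorted(missing)}")
    bad = ~df["chosen_side"].isin(["left_vf", "right_vf", "none"])
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(f"trials file {path}: row {row}, column chosen_side invalid")
    return df


def run_pipeline(
    config: PipelineConfig,
    out_dir: Path | str,
    participants: pd.DataFrame | None = None,
    trials: pd.DataFrame | None = None,
) -> Dict[str, object]:
    """Run every stage; returns the in-memory artifacts and writes the bundle.

    When ``participants``/``trials`` are omitted they are simulated from
    ``config.simulation`` (real data, if available, enters through the same
    two schemas).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: Dict[str, object] = {}

    if participants is None or trials is None:
        participants, trials = simulate_cohort(config.simulation)
        log.info("simulated %d participants", len(participants))
    _float_csv(participants, out / "participants.csv")
    _float_csv(trials, out / "trials.csv")
    counts["n_simulated"] = int(len(participants))

    scored = score_participants(participants)
    _float_csv(scored, out / "scored_participants.csv")

    clean_p, clean_t, report = clean_cohort(
        scored, trials, config.cleaning, n_task_trials=config.simulation.n_trials
    )
    (out / "cleaning_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    counts["n_retained"] = report.n_retained
    log.info("cleaning retained %d of %d", report.n_retained, report.n_input)

    lat = score_laterality(
        clean_t,
        denominator=config.lq1_denominator,
        n_nominal=config.simulation.n_trials,
    )
    _float_csv(lat, out / "laterality.csv")

    analysis = clean_p.merge(lat, on="participant_id", how="inner")
    model_data = reg_mod.prepare_model_frame(sex_analysis_filter(analysis))
    counts["n_model_rows"] = int(len(model_data))
    counts["n_lq2_defined"] = int(model_data["lq2"].notna().sum())

    corr = reg_mod.correlation_matrix(analysis, CONTINUOUS_DESCRIPTIVES, group="all")
    corr_by_sex = reg_mod.correlation_matrix(
        model_data, CONTINUOUS_DESCRIPTIVES, group="by_sex"
    )
    for name, mats in {**corr, **corr_by_sex}.items():
        mats["r"].to_csv(out / f"correlations_{name}_r.csv", float_format="%.17g")
        mats["p"].to_csv(out / f"correlations_{name}_p.csv", float_format="%.17g")

    results = {}
    bma_results = {}
    for i, outcome in enumerate(("lq1", "lq2"), start=1):
        res = reg_mod.fit_model(model_data, outcome)
        results[outcome] = res
        _float_csv(res.coefficients, out / f"model_{i}_coefficients.csv")
        (out / f"model_{i}_fit.json").write_text(json.dumps(res.fit_dict(), indent=2))
        (out / f"model_{i}_diagnostics.json").write_text(
            json.dumps(res.diagnostics, indent=2)
        )
        b = bma_mod.run_bma(
            model_data.dropna(subset=[outcome]),
            outcome,
            reg_mod.MAIN_TERMS,
            reg_mod.INTERACTION_TERMS,
        )
        bma_results[outcome] = b
        _float_csv(b.terms, out / f"bma_{i}.csv")
        _float_csv(b.models, out / f"bma_models_{i}.csv")

    # scatter data for the headline relationships
    _float_csv(
        model_data[["participant_id", "ehi_score", "lq1"]],
        out / "scatter_ehi_lq1.csv",
    )
    _float_csv(
        model_data[["participant_id", "attention_switching", "lq2"]].dropna(),
        out / "scatter_attention_switching_lq2.csv",
    )
    _float_csv(
        model_data[["participant_id", "imagination", "sex", "lq2"]].dropna(),
        out / "scatter_imagination_sex_lq2.csv",
    )

    artifacts: Dict[str, object] = {
        "participants": participants,
        "scored": scored,
        "clean_participants": clean_p,
        "clean_trials": clean_t,
        "cleaning_report": report,
        "laterality": lat,
        "analysis": analysis,
        "model_data": model_data,
        "correlations": {**corr, **corr_by_sex},
        "models": results,
        "bma": bma_results,
        "alphas": subscale_alphas(clean_p),
    }
    tables = render_report(artifacts)
    for name, table in tables.items():
        _float_csv(table, out / f"report_{name}.csv")

    counts["alphas"] = {k: round(v, 4) for k, v in artifacts["alphas"].items()}
    (out / "run_log.json").write_text(json.dumps(counts, indent=2))
    (out / "resolved_config.json").write_text(config.model_dump_json(indent=2))
    artifacts["counts"] = counts
    return artifacts


def _descriptives(frame: pd.DataFrame, label: str) -> pd.DataFrame:
    rows = []
    for var in CONTINUOUS_DESCRIPTIVES:
        if var not in frame.columns:
            continue
        s = frame[var].dropna()
        rows.append(
            {
                "group": label,
                "variable": var,
                "n": int(len(s)),
                "mean": s.mean(),
                "sd": s.std(ddof=1),
                "min": s.min(),
                "max": s.max(),
            }
        )
    return pd.DataFrame(rows)


def render_report(artifacts: Dict[str, object]) -> Dict[str, pd.DataFrame]:
    """Descriptives and combined frequentist + Bayesian coefficient tables.

    Raises if any stage output is absent or a model table is empty.
    """
    needed = ["analysis", "model_data", "models", "bma"]
    absent = [k for k in needed if k not in artifacts]
    if absent:
        raise ValueError(f"cannot render report; missing stage outputs: {absent}")

    analysis: pd.DataFrame = artifacts["analysis"]  # type: ignore[assignment]
    model_data: pd.DataFrame = artifacts["model_data"]  # type: ignore[assignment]
    if model_data.empty:
        raise ValueError("model table is empty; nothing to report")

    desc = pd.concat(
        [
            _descriptives(analysis, "total"),
            _descriptives(model_data[model_data["sex"] == "male"], "male"),
            _descriptives(model_data[model_data["sex"] == "female"], "female"),
        ],
        ignore_index=True,
    )

    tables: Dict[str, pd.DataFrame] = {"descriptives": desc}
    for i, outcome in enumerate(("lq1", "lq2"), start=1):
        res = artifacts["models"][outcome]  # type: ignore[index]
        b = artifacts["bma"][outcome]  # type: ignore[index]
        merged = res.coefficients.merge(
            b.terms[["term", "prior_incl", "posterior_incl", "bf_inclusion", "evidence"]],
            on="term",
            how="left",
        )
        if merged.empty:
            raise ValueError(f"empty coefficient table for {outcome}")
        tables[f"model_{i}"] = merged[REPORT_COLUMNS]
    return tables


def write_tables(tables: Dict[str, pd.DataFrame], out_dir: Path | str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        _float_csv(table, out / f"report_{name}.csv")
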