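"""Pipeline orchestration: simulate (or load) → validate → score → report.

The pipeline mirrors a validation-study flow: a cohort enters, records
failing schema validation abort the run (nothing is silently dropped),
scores and strata are computed, follow-up attrition partitions the cohort
into completers and dropouts, and the statistical validation battery is
run on completers.  Outputs are a scored cohort CSV, a JSON validation
report, a human-readable run log and a machine-readable exclusion ledger.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats as vstats
from .cohort_io import read_cohort_csv, write_cohort_csv
from .domain import AGILE_ITEMS, validate_record
from .cohort_io import frame_to_records
from .scoring import AGILE_SCHEMES, item_code_frame, score_frame
from .synthetic import (
    CohortConfig,
    OUTCOMES,
    generate_cohort_frame,
    generate_rater_pair,
    resolve_item_intercepts,
)

OUTCOME_COLUMN = {
    "mortality": "died",
    "disability": "incident_disability",
    "hospitalization": "hospitalized",
}


class PipelineError(RuntimeError):
    """A pipeline run aborted; the message carries the violation list."""


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    scheme: str = "methods"
    out_dir: Optional[Path] = None
    input_csv: Optional[Path] = None  # load instead of simulating
    formats: Sequence[str] = ("json", "csv")
    make_plots: bool = False


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the full chain and return the validation report dict.

    When ``config.out_dir`` is set, writes ``cohort_scored.csv``,
    ``report.json``, ``run.log`` and ``exclusions.json`` there.
    """
    log: List[str] = []
    scheme = AGILE_SCHEMES[config.scheme]

    if config.input_csv is not None:
        df = read_cohort_csv(config.input_csv)
        log.append(f"loaded cohort from {config.input_csv} (n={len(df)})")
    else:
        df = generate_cohort_frame(dataclasses.replace(config.cohort, scheme=config.scheme))
        log.append(f"simulated cohort (n={len(df)}, seed={config.cohort.seed})")

    violations = []
    for rec in frame_to_records(df):
        for v in validate_record(rec):
            violations.append(f"{rec.subject_id}: {v}")
    if violations:
        raise PipelineError(
            "cohort failed schema validation:\n" + "\n".join(violations)
        )
    log.append("schema validation passed for every record")

    if "agile_score" not in df.columns:
        df = score_frame(df, scheme=scheme)

    exclusions = {"enrolled": int(len(df))}
    completed = df["completed_followup"].astype(bool)
    exclusions["lost_to_followup"] = int((~completed).sum())
    exclusions["completed"] = int(completed.sum())
    completers = df[completed]
    if len(completers) == 0:
        raise PipelineError("no subjects completed follow-up; nothing to validate")
    log.append(
        f"follow-up: {exclusions['completed']}/{exclusions['enrolled']} completed "
        f"({100 * exclusions['completed'] / exclusions['enrolled']:.1f}%)"
    )

    report = build_validation_report(df, completers, config)
    report["counts"] = {
        **exclusions,
        "completion_fraction": exclusions["completed"] / exclusions["enrolled"],
    }
    report["config"] = _jsonable(dataclasses.asdict(config.cohort))
    report["scheme"] = config.scheme

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / "cohort_scored.csv"
        write_cohort_csv(df, csv_path)
        report["provenance"] = {"cohort_sha256": _sha256(csv_path)}
        (out / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n"
        )
        (out / "exclusions.json").write_text(json.dumps(exclusions, indent=2) + "\n")
        log.append(f"artifacts written to {out}")
        (out / "run.log").write_text("\n".join(log) + "\n")
        if config.make_plots:
            _write_roc_plot(report, out / "roc.png")
    return report


def build_validation_report(
    df: pd.DataFrame, completers: pd.DataFrame, config: PipelineConfig
) -> Dict:
    """The statistical battery: agreement, tables, models, ROC."""
    report: Dict = {}

    # agreement / reliability
    a, b = generate_rater_pair(df, config.cohort.rater_disagreement, seed=config.cohort.seed + 1)
    kap = vstats.cohens_kappa(a.to_numpy().ravel(), b.to_numpy().ravel())
    alpha = vstats.cronbach_alpha(item_code_frame(df).to_numpy())
    report["agreement"] = {
        "interrater_kappa": {"kappa": kap.kappa, "p_value": kap.p_value, "n": kap.n},
        "cronbach_alpha_agile": alpha.alpha,
    }
    if "ifi_score" in df.columns:
        report["agreement"]["lin_ccc_agile_vs_ifi_rescaled"] = vstats.lin_ccc(
            df["agile_score"], df["ifi_score"] * 10.0 / 40.0
        )
        report["agreement"]["lin_ccc_agile_vs_ifi_raw"] = vstats.lin_ccc(
            df["agile_score"], df["ifi_score"]
        )

    # item-prevalence table across strata
    codes = item_code_frame(df)
    table_df = pd.concat([codes, df[["agile_stratum"]]], axis=1)
    strata_order = [lbl for _, lbl in AGILE_SCHEMES[config.scheme].boundaries]
    report["item_prevalence_by_stratum"] = vstats.stratum_summary(
        table_df, strata_order=strata_order, binary=list(AGILE_ITEMS)
    )

    # outcome prevalence by stratum (completers only)
    comp_codes = completers.copy()
    report["outcome_prevalence_by_stratum"] = vstats.stratum_summary(
        comp_codes,
        strata_order=strata_order,
        binary=[OUTCOME_COLUMN[o] for o in OUTCOMES],
    )

    # per-unit and per-item adjusted logistic models; ROC
    report["per_unit_effects"] = {}
    report["per_item_effects"] = {}
    report["roc"] = {}
    instruments = {"AGILE": "agile_score"}
    if "ifi_score" in completers.columns:
        instruments["IFi"] = "ifi_score"
    for outcome in OUTCOMES:
        ycol = OUTCOME_COLUMN[outcome]
        report["per_unit_effects"][outcome] = {}
        report["roc"][outcome] = {}
        for name, col in instruments.items():
            try:
                est = vstats.fit_outcome_model(completers, ycol, col, label=f"{name} per unit")
                report["per_unit_effects"][outcome][name] = dataclasses.asdict(est)
            except (ValueError, RuntimeError) as exc:
                report["per_unit_effects"][outcome][name] = {"error": str(exc)}
            try:
                roc = vstats.roc_auc(completers[col], completers[ycol].astype(int))
                report["roc"][outcome][name] = {"auc": roc.auc, "points": list(roc.points)}
            except ValueError as exc:
                report["roc"][outcome][name] = {"error": str(exc)}
        item_codes_comp = item_code_frame(completers)
        per_item = {}
        model_df = completers[["age", "sex", ycol]].copy()
        for item in AGILE_ITEMS:
            model_df[item] = item_codes_comp[item]
            try:
                est = vstats.fit_outcome_model(model_df, ycol, item, label=item)
                per_item[item] = dataclasses.asdict(est)
            except (ValueError, RuntimeError) as exc:
                per_item[item] = {"error": str(exc)}
        report["per_item_effects"][outcome] = per_item

    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def _write_roc_plot(report: Dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outcomes = list(report["roc"])
    fig, axes = plt.subplots(1, len(outcomes), figsize=(4 * len(outcomes), 4))
    axes = np.atleast_1d(axes)
    for ax, outcome in zip(axes, outcomes):
        for name, entry in report["roc"][outcome].items():
            if "points" not in entry:
                continue
            pts = np.array(entry["points"])
            ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (AUC {entry['auc']:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_title(outcome)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
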