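"""Assembly of per-participant analysis tables and human-readable reports."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import AnalysisPlan, CorrelationResult, HierarchicalResult, encode_binary

__all__ = [
    "ReportError",
    "build_analysis_table",
    "default_plans",
    "run_report",
    "TRAIT_COLUMNS",
    "INDEX_COLUMNS",
]


class ReportError(ValueError):
    """Raised when a report stage is missing its inputs."""


INDEX_COLUMNS = ("ab1_ms", "am_away_ms", "am_towards_ms", "am_overall_ms")
TRAIT_COLUMNS = ("pcs_total", "dass_anxiety", "dass_depression", "dass_stress")

_INDEX_LABELS = {
    "ab1_ms": "AB_Baseline",
    "am_away_ms": "AM_Away",
    "am_towards_ms": "AM_Towards",
    "am_overall_ms": "AM_Overall",
}


def build_analysis_table(
    indices: pd.DataFrame,
    participants: pd.DataFrame,
    questionnaire_scores: pd.DataFrame | None = None,
    rir_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge scored stages into one per-participant analysis table.

    Gender is coded as a female=1 indicator (``gender_female``); RIR
    interference columns are prefixed ``rir_``.  Participants missing from
    ``indices`` (excluded during cleaning) are omitted.
    """
    table = indices.merge(participants, on="participant_id", how="left")
    if "training_order" in participants.columns and "training_order_x" in table.columns:
        table = table.rename(columns={"training_order_x": "training_order"}).drop(
            columns=["training_order_y"]
        )
    table["gender_female"] = encode_binary(table["gender"], one="female")
    if questionnaire_scores is not None:
        table = table.merge(questionnaire_scores, on="participant_id", how="left")
    if rir_scores is not None:
        keep = rir_scores[["participant_id", "delta_rt_ms", "delta_error_pct"]].rename(
            columns={"delta_rt_ms": "rir_delta_rt_ms", "delta_error_pct": "rir_delta_error_pct"}
        )
        table = table.merge(keep, on="participant_id", how="left")
    return table


_AM_PREDICTORS = ("am_towards_ms", "am_away_ms", "am_overall_ms")


def default_plans(columns) -> list[AnalysisPlan]:
    """The standard regression battery, adapted to the columns present.

    Laboratory-style outcomes (attention to pain, pain threshold/tolerance,
    RIR interference) are controlled for gender and baseline AB; the
    chronic-pain outcomes (GCPS intensity/disability) additionally for age.
    Each outcome is tested once per malleability index (family size 3).
    """
    columns = set(columns)
    plans: list[AnalysisPlan] = []
    lab = ("gender_female", "ab1_ms")
    clinical = ("gender_female", "age", "ab1_ms")
    for outcome, controls in (
        ("attention_to_pain", lab),
        ("pain_threshold_c", lab),
        ("pain_tolerance_c", lab),
        ("rir_delta_rt_ms", lab),
        ("rir_delta_error_pct", lab),
        ("gcps_intensity", clinical),
        ("gcps_disability", clinical),
    ):
        if outcome in columns and all(c in columns for c in controls):
            plans.extend(
                AnalysisPlan(outcome=outcome, controls=controls, predictor=p)
                for p in _AM_PREDICTORS
            )
    return plans


def _fmt(x: float, nd: int = 2) -> str:
    return "nan" if pd.isna(x) else f"{x:.{nd}f}"


def run_report(
    descriptives: pd.DataFrame,
    correlations: CorrelationResult,
    regressions: list[HierarchicalResult],
    calibration: dict | None = None,
) -> tuple[str, dict]:
    """Render the cohort results as plain text plus a JSON-ready dict.

    Sections: (a) attention-index descriptives (mean (SD) per index row),
    (b) index-by-trait correlation matrix with significance stars,
    (c) one block per hierarchical regression, (d) optionally a simulation
    calibration section (empirical type-I rate of the engine).
    """
    missing = [
        name
        for name, val in (
            ("descriptives", descriptives),
            ("correlations", correlations),
            ("regressions", regressions),
        )
        if val is None
    ]
    if missing:
        raise ReportError(f"missing stage output(s): {missing}")

    lines: list[str] = []
    lines.append("Attention index descriptives")
    for _, row in descriptives.iterrows():
        lines.append(
            f"  {row['index']:<12} {_fmt(row['mean'])} ({_fmt(row['sd'])})  [n={int(row['n'])}]"
        )

    lines.append("")
    lines.append("Correlations with individual-difference measures")
    stars = correlations.stars()
    header = "  " + " " * 13 + "".join(f"{c:>18}" for c in correlations.r.columns)
    lines.append(header)
    for idx in correlations.r.index:
        label = _INDEX_LABELS.get(idx, idx)
        cells = "".join(
            f"{_fmt(correlations.r.loc[idx, c]) + stars.loc[idx, c]:>18}"
            for c in correlations.r.columns
        )
        lines.append(f"  {label:<13}{cells}")

    lines.append("")
    lines.append("Hierarchical regressions (step 2: focal predictor added to controls)")
    for res in regressions:
        sig = "significant" if res.bonferroni_significant else "ns"
        lines.append(
            f"  {res.outcome} ~ ... + {res.predictor}: "
            f"dR2 = {_fmt(res.delta_r2)}, F({res.df1},{res.df2}) = {_fmt(res.f_change)}, "
            f"p = {_fmt(res.p_change)}, f2 = {_fmt(res.f2)}, b* = {_fmt(res.b_std)} "
            f"[Bonferroni: {sig}]"
        )

    if calibration is not None:
        lines.append("")
        lines.append("Calibration")
        lines.append(
            f"  null rejection rate at alpha={calibration.get('alpha')}: "
            f"{_fmt(calibration.get('rejection_rate'), 4)} "
            f"({calibration.get('replicates')} replicates, n={calibration.get('n')})"
        )

    payload = {
        "descriptives": descriptives.to_dict(orient="records"),
        "correlations": {
            "r": correlations.r.round(6).to_dict(),
            "p": correlations.p.round(6).to_dict(),
            "n": correlations.n.to_dict(),
        },
        "regressions": [r.to_dict() for r in regressions],
    }
    if calibration is not None:
        payload["calibration"] = calibration
    return "\n".join(lines) + "\n", payload
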