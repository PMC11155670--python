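"""Scoring of the four self-report instruments.

* PCS — Pain Catastrophizing Scale: 13 items rated 0-4; total 0-52 with
  rumination, magnification and helplessness subscales (Sullivan's original
  item mapping).
* DASS-21 — Depression Anxiety Stress Scales, short form: 21 items rated
  0-3; three raw 7-item sums (0-21 each, not doubled to the DASS-42 scale).
* GCPS — Graded Chronic Pain Scale: three 0-10 pain-intensity items and
  three 0-10 disability items, each averaged and multiplied by 10 to a
  0-100 score, plus a disability-days count.
* Attention to pain — two 0-10 items, the second reverse-scored, averaged.

No missing-item imputation is performed: a missing or out-of-range response
raises ``ItemError``.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemError",
    "PCSScores",
    "DASSScores",
    "GCPSScores",
    "score_pcs",
    "score_dass21",
    "score_gcps",
    "score_attention_to_pain",
    "score_item_table",
    "PCS_RUMINATION_ITEMS",
    "PCS_MAGNIFICATION_ITEMS",
    "PCS_HELPLESSNESS_ITEMS",
    "DASS_DEPRESSION_ITEMS",
    "DASS_ANXIETY_ITEMS",
    "DASS_STRESS_ITEMS",
]

# 1-based item positions (original instrument keys)
PCS_RUMINATION_ITEMS = (8, 9, 10, 11)
PCS_MAGNIFICATION_ITEMS = (6, 7, 13)
PCS_HELPLESSNESS_ITEMS = (1, 2, 3, 4, 5, 12)

DASS_DEPRESSION_ITEMS = (3, 5, 10, 13, 16, 17, 21)
DASS_ANXIETY_ITEMS = (2, 4, 7, 9, 15, 19, 20)
DASS_STRESS_ITEMS = (1, 6, 8, 11, 12, 14, 18)


class ItemError(ValueError):
    """Raised for missing, extra or out-of-range item responses."""


def _check_items(items: Sequence, n: int, lo: int, hi: int, name: str) -> np.ndarray:
    arr = list(items)
    if len(arr) != n:
        raise ItemError(f"{name} requires exactly {n} item responses, got {len(arr)}")
    for i, v in enumerate(arr, start=1):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ItemError(f"{name} item {i} is missing")
        if not float(v) == int(v) or not lo <= int(v) <= hi:
            raise ItemError(f"{name} item {i} must be an integer in [{lo}, {hi}], got {v!r}")
    return np.asarray([int(v) for v in arr])


@dataclasses.dataclass(frozen=True)
class PCSScores:
    total: int
    rumination: int
    magnification: int
    helplessness: int


@dataclasses.dataclass(frozen=True)
class DASSScores:
    depression: int
    anxiety: int
    stress: int


@dataclasses.dataclass(frozen=True)
class GCPSScores:
    intensity: float
    disability: float
    disability_days: int


def score_pcs(items: Sequence[int]) -> PCSScores:
    """Score the 13-item PCS: total sum plus the three subscale sums."""
    arr = _check_items(items, 13, 0, 4, "PCS")
    pick = lambda idx: int(arr[np.asarray(idx) - 1].sum())
    return PCSScores(
        total=int(arr.sum()),
        rumination=pick(PCS_RUMINATION_ITEMS),
        magnification=pick(PCS_MAGNIFICATION_ITEMS),
        helplessness=pick(PCS_HELPLESSNESS_ITEMS),
    )


def score_dass21(items: Sequence[int]) -> DASSScores:
    """Score the DASS-21 into raw 0-21 depression/anxiety/stress sums."""
    arr = _check_items(items, 21, 0, 3, "DASS-21")
    pick = lambda idx: int(arr[np.asarray(idx) - 1].sum())
    return DASSScores(
        depression=pick(DASS_DEPRESSION_ITEMS),
        anxiety=pick(DASS_ANXIETY_ITEMS),
        stress=pick(DASS_STRESS_ITEMS),
    )


def score_gcps(items: Sequence[int], disability_days: int) -> GCPSScores:
    """Score the GCPS: items 1-3 -> intensity, items 4-6 -> disability (0-100)."""
    arr = _check_items(items, 6, 0, 10, "GCPS")
    days = int(disability_days)
    if days < 0:
        raise ItemError("GCPS disability days must be non-negative")
    return GCPSScores(
        intensity=float(arr[:3].mean() * 10.0),
        disability=float(arr[3:].mean() * 10.0),
        disability_days=days,
    )


def score_attention_to_pain(item_a: int, item_b_raw: int) -> float:
    """Average an attention item with its reverse-scored companion (0-10)."""
    a = _check_items([item_a], 1, 0, 10, "attention-to-pain")[0]
    b = _check_items([item_b_raw], 1, 0, 10, "attention-to-pain")[0]
    return float((a + (10 - b)) / 2.0)


def score_item_table(items: pd.DataFrame) -> pd.DataFrame:
    """Score a per-participant item table into one row of scale scores each.

    Expects columns named ``pcs_01``..``pcs_13``, ``dass_01``..``dass_21``,
    ``gcps_01``..``gcps_06`` + ``gcps_days``, and ``atp_01``/``atp_02``
    (the second reverse-scored), alongside ``participant_id``.  Instruments
    whose columns are absent are skipped; partially present instruments
    raise ``ItemError``.
    """
    if "participant_id" not in items.columns:
        raise ItemError("item table requires a participant_id column")
    groups = {
        "pcs": [f"pcs_{i:02d}" for i in range(1, 14)],
        "dass": [f"dass_{i:02d}" for i in range(1, 22)],
        "gcps": [f"gcps_{i:02d}" for i in range(1, 7)] + ["gcps_days"],
        "atp": ["atp_01", "atp_02"],
    }
    present = {}
    for name, cols in groups.items():
        have = [c for c in cols if c in items.columns]
        if have and len(have) != len(cols):
            missing = sorted(set(cols) - set(have))
            raise ItemError(f"incomplete {name} items: missing {missing}")
        present[name] = bool(have)

    rows = []
    for _, r in items.iterrows():
        row: dict = {"participant_id": r["participant_id"]}
        if present["pcs"]:
            s = score_pcs([r[c] for c in groups["pcs"]])
            row |= {
                "pcs_total": s.total,
                "pcs_rumination": s.rumination,
                "pcs_magnification": s.magnification,
                "pcs_helplessness": s.helplessness,
            }
        if present["dass"]:
            s = score_dass21([r[c] for c in groups["dass"]])
            row |= {
                "dass_depression": s.depression,
                "dass_anxiety": s.anxiety,
                "dass_stress": s.stress,
            }
        if present["gcps"]:
            s = score_gcps([r[c] for c in groups["gcps"][:6]], r["gcps_days"])
            row |= {
                "gcps_intensity": s.intensity,
                "gcps_disability": s.disability,
                "gcps_disability_days": s.disability_days,
            }
        if present["atp"]:
            row["attention_to_pain"] = score_attention_to_pain(r["atp_01"], r["atp_02"])
        rows.append(row)
    return pd.DataFrame(rows)
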