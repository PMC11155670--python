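"""Cleaning and pain-interference scoring of RIR tone-detection data.

For the RT analysis, each participant's data lose: anticipations (presses
earlier than 100 ms after tone onset), omissions, the first and last tone
of every pain/no-pain episode, and timed RTs more than 3 SD above the
participant's mean (one-sided upper rule; mean and SD computed over the
participant's timed RTs after anticipation/omission removal).  The error
rate counts anticipations and omissions over tones presented, excluding the
episode-endpoint tones, without the RT-outlier rule.

Pain interference is the pain-minus-no-pain difference in mean RT and in
error percentage.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "RIRError",
    "RIRCleaningReport",
    "InterferenceScores",
    "clean_rir",
    "compute_interference",
    "score_rir_cohort",
]

_REQUIRED = ("participant_id", "tone_index", "episode_index", "pain", "response_class", "rt_ms")
ANTICIPATION_CUTOFF_MS = 100.0


class RIRError(ValueError):
    """Raised for invalid RIR scoring input."""


@dataclasses.dataclass
class RIRCleaningReport:
    """Per-participant, per-rule removal counts for the RT analysis set.

    Counts are disjoint (a trial is tallied under the first rule that
    removes it: anticipation/omission, then episode endpoint, then the 3-SD
    outlier rule), so removals plus ``n_retained`` equal ``n_input``.
    """

    per_participant: pd.DataFrame
    sd_rule_skipped: list[str]

    def to_dict(self) -> dict:
        return {
            "per_participant": self.per_participant.to_dict(orient="records"),
            "sd_rule_skipped": list(self.sd_rule_skipped),
        }


@dataclasses.dataclass(frozen=True)
class InterferenceScores:
    """Pain-interference statistics for one participant."""

    participant_id: str
    delta_rt_ms: float
    delta_error_pct: float
    pain_rt_ms: float
    nopain_rt_ms: float
    pain_error_pct: float
    nopain_error_pct: float


def _validate(trials: pd.DataFrame) -> pd.DataFrame:
    if trials is None or len(trials) == 0:
        raise RIRError("no RIR trials supplied")
    missing = [c for c in _REQUIRED if c not in trials.columns]
    if missing:
        raise RIRError(f"RIR table missing columns: {missing}")
    return trials.reset_index(drop=True)


def clean_rir(trials: pd.DataFrame) -> tuple[pd.DataFrame, RIRCleaningReport]:
    """Produce the RT analysis set and a per-rule cleaning report.

    A timed response recorded faster than 100 ms is reclassified as an
    anticipation before any other rule applies.  Participants with fewer
    than two timed responses keep all timed trials (the SD rule cannot be
    computed) and are listed in ``sd_rule_skipped``.
    """
    t = _validate(trials)
    rt = t["rt_ms"].astype(float)
    cls = t["response_class"].astype(str).to_numpy().copy()
    cls[(cls == "timed") & (rt.to_numpy() < ANTICIPATION_CUTOFF_MS)] = "anticipation"
    t = t.assign(response_class=cls)
    timed = t["response_class"] == "timed"

    first = t.groupby(["participant_id", "episode_index"])["tone_index"].transform("min")
    last = t.groupby(["participant_id", "episode_index"])["tone_index"].transform("max")
    endpoint = (t["tone_index"] == first) | (t["tone_index"] == last)

    stats = t.loc[timed].groupby("participant_id")["rt_ms"].agg(["mean", "std", "count"])
    skipped = [str(p) for p in stats.index[stats["count"] < 2]]
    bound = (stats["mean"] + 3.0 * stats["std"]).where(stats["count"] >= 2, np.inf)
    bound_per_trial = t["participant_id"].map(bound).astype(float)
    outlier = timed & (t["rt_ms"].astype(float) > bound_per_trial)

    keep = timed & ~endpoint & ~outlier
    clean = t[keep].copy()

    agg = t.assign(
        _anticip=t["response_class"] == "anticipation",
        _omit=t["response_class"] == "omission",
        _endpoint=timed & endpoint,
        _outlier=outlier & ~endpoint,
        _kept=keep,
    ).groupby("participant_id", sort=True)
    per_participant = agg.agg(
        n_input=("_kept", "size"),
        n_anticipation=("_anticip", "sum"),
        n_omission=("_omit", "sum"),
        n_endpoint=("_endpoint", "sum"),
        n_outlier=("_outlier", "sum"),
        n_retained=("_kept", "sum"),
    ).reset_index()
    return clean, RIRCleaningReport(per_participant=per_participant, sd_rule_skipped=skipped)


def compute_interference(
    clean_trials: pd.DataFrame, all_trials: pd.DataFrame
) -> InterferenceScores:
    """Pain-interference scores for one participant.

    ``clean_trials`` is that participant's RT analysis set from
    :func:`clean_rir`; ``all_trials`` their full (pre-cleaning) trial list,
    used for the error rates (anticipations + omissions over tones,
    excluding episode-endpoint tones).
    """
    t = _validate(all_trials)
    pids = t["participant_id"].unique()
    if len(pids) != 1:
        raise RIRError("compute_interference expects a single participant")
    pid = str(pids[0])

    pain_rt = clean_trials.loc[clean_trials["pain"].astype(bool), "rt_ms"]
    nopain_rt = clean_trials.loc[~clean_trials["pain"].astype(bool), "rt_ms"]
    if len(pain_rt) == 0 or len(nopain_rt) == 0:
        cond = "pain" if len(pain_rt) == 0 else "no-pain"
        raise RIRError(f"participant {pid}: no usable {cond} trials for the RT analysis")

    rt = t["rt_ms"].astype(float)
    cls = t["response_class"].astype(str).to_numpy().copy()
    cls[(cls == "timed") & (rt.to_numpy() < ANTICIPATION_CUTOFF_MS)] = "anticipation"
    first = t.groupby("episode_index")["tone_index"].transform("min")
    last = t.groupby("episode_index")["tone_index"].transform("max")
    inner = ~((t["tone_index"] == first) | (t["tone_index"] == last))
    err = pd.Series((cls == "anticipation") | (cls == "omission"), index=t.index)
    pain = t["pain"].astype(bool)
    n_pain = int((inner & pain).sum())
    n_nopain = int((inner & ~pain).sum())
    if n_pain == 0 or n_nopain == 0:
        cond = "pain" if n_pain == 0 else "no-pain"
        raise RIRError(f"participant {pid}: no {cond} tones for the error analysis")
    pain_err = 100.0 * err[inner & pain].mean()
    nopain_err = 100.0 * err[inner & ~pain].mean()

    return InterferenceScores(
        participant_id=pid,
        delta_rt_ms=float(pain_rt.mean() - nopain_rt.mean()),
        delta_error_pct=float(pain_err - nopain_err),
        pain_rt_ms=float(pain_rt.mean()),
        nopain_rt_ms=float(nopain_rt.mean()),
        pain_error_pct=float(pain_err),
        nopain_error_pct=float(nopain_err),
    )


def score_rir_cohort(
    trials: pd.DataFrame,
) -> tuple[pd.DataFrame, RIRCleaningReport]:
    """Clean a multi-participant RIR table and score interference per participant."""
    clean, report = clean_rir(trials)
    clean_by_pid = dict(tuple(clean.groupby("participant_id", sort=True)))
    empty = clean.iloc[0:0]
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        scores = compute_interference(clean_by_pid.get(pid, empty), sub)
        rows.append(dataclasses.asdict(scores))
    return pd.DataFrame(rows), report
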