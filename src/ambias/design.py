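"""Experimental design: the 5-block dot-probe malleability paradigm and the RIR tone schedule.

The attention-bias-malleability (AM) paradigm interleaves three *assessment*
blocks (no probe/word contingency; the classic dot-probe measurement
condition) with two *training* blocks in which the probe location is fully
contingent on the pain word (training attention *towards* pain) or on the
neutral word (training *away*).  Three word-pair lists rotate through the
blocks so that no word is re-used across assessments: list 1 serves
assessment 1 and training 1, list 2 serves assessment 2 and training 2, and
list 3 serves the final assessment.

The Random Interval Repetition (RIR) task is a speeded tone-detection task
whose tones are separated by one of two inter-onset intervals in equal
numbers and random order, overlaid with alternating fixed-length pain /
no-pain episodes.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "ParadigmDesign",
    "RIRSchedule",
    "make_paradigm_schedule",
    "make_rir_schedule",
    "BLOCK_SEQUENCE",
    "ASSESSMENT_BLOCKS",
    "TRAINING_BLOCKS",
]

#: Fixed block order of the paradigm (block_index 1..5).
BLOCK_SEQUENCE: tuple[str, ...] = (
    "assessment",
    "training",
    "assessment",
    "training",
    "assessment",
)
ASSESSMENT_BLOCKS: tuple[int, ...] = (1, 3, 5)
TRAINING_BLOCKS: tuple[int, ...] = (2, 4)

TRAINING_ORDERS = ("towards_first", "away_first")


class DesignError(ValueError):
    """Raised for structurally invalid paradigm or RIR-schedule configurations."""


def _rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclasses.dataclass(frozen=True)
class ParadigmDesign:
    """Structural parameters of the 5-block AM paradigm.

    Each word pair appears 4 times in its assessment block and 12 times in
    its training block, so block lengths are fully determined by
    ``n_pairs_per_list`` (default 24 pairs -> 96-trial assessments and
    288-trial trainings).
    """

    n_pairs_per_list: int = 24
    n_assessment_trials: int = 96
    n_training_trials: int = 288
    training_order: str = "towards_first"
    #: permutation of (1, 2, 3): which word list serves block slot 1, 2, 3
    list_order: tuple[int, int, int] = (1, 2, 3)
    fixation_ms: int = 500
    stimulus_ms: int = 500
    iti_ms: int = 500

    def __post_init__(self) -> None:
        if self.n_pairs_per_list < 1:
            raise DesignError("n_pairs_per_list must be >= 1")
        if self.n_assessment_trials != 4 * self.n_pairs_per_list:
            raise DesignError(
                f"n_assessment_trials must be 4 x n_pairs_per_list "
                f"({4 * self.n_pairs_per_list}), got {self.n_assessment_trials}"
            )
        if self.n_training_trials != 12 * self.n_pairs_per_list:
            raise DesignError(
                f"n_training_trials must be 12 x n_pairs_per_list "
                f"({12 * self.n_pairs_per_list}), got {self.n_training_trials}"
            )
        if self.training_order not in TRAINING_ORDERS:
            raise DesignError(f"training_order must be one of {TRAINING_ORDERS}")
        if sorted(self.list_order) != [1, 2, 3]:
            raise DesignError("list_order must be a permutation of (1, 2, 3)")
        for field in ("fixation_ms", "stimulus_ms", "iti_ms"):
            if getattr(self, field) < 0:
                raise DesignError(f"{field} must be non-negative")

    @property
    def block_sequence(self) -> tuple[str, ...]:
        return BLOCK_SEQUENCE

    @property
    def block_lengths(self) -> tuple[int, ...]:
        return tuple(
            self.n_assessment_trials if kind == "assessment" else self.n_training_trials
            for kind in BLOCK_SEQUENCE
        )

    def training_direction(self, block_index: int) -> str:
        """Contingency direction ('towards'/'away') of training block 2 or 4."""
        if block_index not in TRAINING_BLOCKS:
            raise DesignError(f"block {block_index} is not a training block")
        first, second = (
            ("towards", "away")
            if self.training_order == "towards_first"
            else ("away", "towards")
        )
        return first if block_index == 2 else second

    def list_for_block(self, block_index: int) -> int:
        """Word list serving a block: slot 1 = blocks 1-2, slot 2 = blocks 3-4, slot 3 = block 5."""
        slot = {1: 0, 2: 0, 3: 1, 4: 1, 5: 2}[block_index]
        return self.list_order[slot]


def _block_templates(
    design: ParadigmDesign, block_index: int, rng: np.random.Generator | None
) -> dict[str, np.ndarray]:
    """Template arrays for one block, shuffled in presentation order (rng=None: design order)."""
    kind = BLOCK_SEQUENCE[block_index - 1]
    word_list = design.list_for_block(block_index)
    n_pairs = design.n_pairs_per_list
    if kind == "assessment":
        reps = 4
        contingency = "none"
        # per pair: fully crossed pain-word position x congruency (2 x 2),
        # so both factors are balanced within every pair and every block
        pos = np.tile(np.array(["top", "top", "bottom", "bottom"]), n_pairs)
        congruent = np.tile(np.array([True, False, True, False]), n_pairs)
    else:
        reps = 12
        contingency = design.training_direction(block_index)
        pos = np.tile(np.array(["top"] * 6 + ["bottom"] * 6), n_pairs)
        congruent = np.full(12 * n_pairs, contingency == "towards")
    pair_id = np.repeat(
        np.array([f"L{word_list}P{p:02d}" for p in range(1, n_pairs + 1)]), reps
    )
    order = rng.permutation(pair_id.size) if rng is not None else np.arange(pair_id.size)
    pos = pos[order]
    congruent = congruent[order]
    probe = np.where(
        congruent, pos, np.where(pos == "top", "bottom", "top")
    )
    return {
        "block_index": np.full(pair_id.size, block_index, dtype=np.int64),
        "block_type": np.full(pair_id.size, kind, dtype=object),
        "trial_index": np.arange(1, pair_id.size + 1, dtype=np.int64),
        "pair_id": pair_id[order],
        "pain_word_position": pos,
        "probe_position": probe,
        "congruent": congruent,
        "contingency": np.full(pair_id.size, contingency, dtype=object),
    }


def make_paradigm_schedule(
    design: ParadigmDesign | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build the full ordered trial schedule of the 5-block AM paradigm.

    Returns one row per trial with columns ``block_index``, ``block_type``,
    ``trial_index`` (1-based within block), ``pair_id``,
    ``pain_word_position``, ``probe_position``, ``congruent`` and
    ``contingency`` ('none' in assessment blocks, 'towards'/'away' in
    training blocks).  Within-block presentation order is randomised by the
    seed; the structural counts are deterministic.
    """
    design = design if design is not None else ParadigmDesign()
    gen = _rng(seed, rng)
    blocks = [_block_templates(design, b, gen) for b in range(1, 6)]
    data = {
        key: np.concatenate([blk[key] for blk in blocks]) for key in blocks[0]
    }
    df = pd.DataFrame(data)
    df["congruent"] = df["congruent"].astype(bool)
    return df


@dataclasses.dataclass(frozen=True)
class RIRSchedule:
    """Tone-onset schedule of the RIR task with pain/no-pain episode tags.

    ``onsets_ms`` has one entry per tone (tone count = interval count + 1,
    starting at 0); ``episode_index`` and ``pain`` tag the fixed-length
    episode containing each onset (an onset falling exactly on the session
    end is assigned to the last episode).
    """

    onsets_ms: np.ndarray
    intervals_ms: np.ndarray
    episode_ms: int
    total_ms: int
    pain_first: bool

    @property
    def n_episodes(self) -> int:
        return self.total_ms // self.episode_ms

    @property
    def episode_index(self) -> np.ndarray:
        idx = self.onsets_ms // self.episode_ms
        return np.minimum(idx, self.n_episodes - 1).astype(np.int64)

    @property
    def pain(self) -> np.ndarray:
        even = self.episode_index % 2 == 0
        return even if self.pain_first else ~even

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tone_index": np.arange(1, self.onsets_ms.size + 1, dtype=np.int64),
                "onset_ms": self.onsets_ms.astype(np.int64),
                "episode_index": self.episode_index,
                "pain": self.pain,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "episode_ms": int(self.episode_ms),
                "total_ms": int(self.total_ms),
                "pain_first": bool(self.pain_first),
                "intervals_ms": [int(v) for v in self.intervals_ms],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "RIRSchedule":
        obj = json.loads(payload)
        intervals = np.asarray(obj["intervals_ms"], dtype=np.int64)
        onsets = np.concatenate([[0], np.cumsum(intervals)])
        return cls(
            onsets_ms=onsets,
            intervals_ms=intervals,
            episode_ms=int(obj["episode_ms"]),
            total_ms=int(obj["total_ms"]),
            pain_first=bool(obj["pain_first"]),
        )


def make_rir_schedule(
    total_ms: int = 240_000,
    interval_values_ms: Sequence[int] = (900, 1500),
    episode_ms: int = 24_000,
    pain_first: bool = True,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RIRSchedule:
    """Build an RIR tone schedule: equal counts of each interval in random order.

    The default configuration (240 s, 900/1500-ms intervals, 24-s episodes)
    yields 100 + 100 intervals, hence 201 tones, over 10 alternating pain /
    no-pain episodes.
    """
    if len(interval_values_ms) != 2:
        raise DesignError("interval_values_ms must contain exactly two values")
    v1, v2 = (int(v) for v in interval_values_ms)
    if v1 <= 0 or v2 <= 0 or episode_ms <= 0 or total_ms <= 0:
        raise DesignError("durations must be positive")
    if total_ms % episode_ms != 0:
        raise DesignError(
            f"total_ms ({total_ms}) must be a whole number of {episode_ms}-ms episodes"
        )
    pair_sum = v1 + v2
    if total_ms % pair_sum != 0:
        raise DesignError(
            f"total_ms ({total_ms}) cannot be tiled by equal counts of "
            f"{v1}-ms and {v2}-ms intervals"
        )
    n_each = total_ms // pair_sum
    gen = _rng(seed, rng)
    intervals = np.array([v1] * n_each + [v2] * n_each, dtype=np.int64)
    intervals = gen.permutation(intervals)
    onsets = np.concatenate([[0], np.cumsum(intervals)])
    return RIRSchedule(
        onsets_ms=onsets,
        intervals_ms=intervals,
        episode_ms=int(episode_ms),
        total_ms=int(total_ms),
        pain_first=bool(pain_first),
    )
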