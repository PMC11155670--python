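import numpy as np
import pandas as pd
import pytest

from ambias import CohortConfig, ParadigmDesign


@pytest.fixture
def small_design() -> ParadigmDesign:
    """A 4-pair paradigm: blocks of 16/48/16/48/16 trials, fast to simulate."""
    return ParadigmDesign(
        n_pairs_per_list=4, n_assessment_trials=16, n_training_trials=48
    )


@pytest.fixture
def small_cohort_config(small_design) -> CohortConfig:
    return CohortConfig(n_participants=8, seed=123, design=small_design)


def make_dotprobe_trials(
    rts,
    congruent,
    correct=None,
    block_index=1,
    block_type="assessment",
    participant_id="P1",
) -> pd.DataFrame:
    """Hand-build a minimal dot-probe trial table for unit tests."""
    rts = np.asarray(rts, dtype=float)
    congruent = np.asarray(congruent, dtype=bool)
    correct = np.ones(len(rts), bool) if correct is None else np.asarray(correct, bool)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "block_index": block_index,
            "block_type": block_type,
            "trial_index": np.arange(1, len(rts) + 1),
            "congruent": congruent,
            "correct": correct,
            "rt_ms": rts,
        }
    )


def make_rir_trials(
    rt_ms,
    pain,
    response_class=None,
    episode_index=None,
    participant_id="P1",
) -> pd.DataFrame:
    """Hand-build a minimal RIR trial table for unit tests."""
    rt = np.asarray(rt_ms, dtype=float)
    pain = np.asarray(pain, dtype=bool)
    n = len(rt)
    if response_class is None:
        response_class = np.where(np.isnan(rt), "omission", "timed")
    if episode_index is None:
        episode_index = pain.astype(int)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "tone_index": np.arange(1, n + 1),
            "episode_index": np.asarray(episode_index, dtype=int),
            "pain": pain,
            "response_class": response_class,
            "rt_ms": rt,
        }
    )
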