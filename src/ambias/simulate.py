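"""Synthetic participants and cohorts with known ground truth.

Response times follow an ex-Gaussian model (normal + exponential), the
standard descriptive model for RT distributions.  A participant's
attentional bias enters as an opposite half-shift of the RT location by
congruency (congruent trials -b/2, incongruent +b/2), so that the dot-probe
bias index (mean incongruent - mean congruent) recovers ``b`` by
construction.  Contingency training changes ``b`` as a step after each
training block, scaled by the participant's malleability, and the change
persists through the remaining blocks.

``simulate_cohort`` produces a complete study dataset — dot-probe trials,
RIR tone-detection trials, questionnaire item matrices and outcome
variables — plus a ground-truth table, so the scoring and inference layers
can be validated by parameter recovery.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .design import ParadigmDesign, RIRSchedule, make_rir_schedule
from . import questionnaires as q

__all__ = [
    "ParticipantParams",
    "CohortConfig",
    "CohortDataset",
    "simulate_dotprobe_rts",
    "simulate_rir_responses",
    "simulate_cohort",
]

_LIST_ORDERS = (
    (1, 2, 3),
    (2, 3, 1),
    (3, 1, 2),
    (1, 3, 2),
    (2, 1, 3),
    (3, 2, 1),
)


@dataclasses.dataclass
class ParticipantParams:
    """Person-level generative parameters.

    mu/sigma/tau are the ex-Gaussian RT components in ms; ``ab_base_ms`` is
    the true baseline attentional bias (expected incongruent - congruent
    difference); ``malleability`` scales the training-induced bias shifts
    ``shift_towards_ms`` / ``shift_away_ms``; the RIR parameters govern the
    tone-detection task, with ``interference_ms`` the true pain-minus-no-pain
    RT increment.
    """

    participant_id: str
    mu_ms: float = 450.0
    sigma_ms: float = 50.0
    tau_ms: float = 100.0
    ab_base_ms: float = 0.0
    malleability: float = 1.0
    shift_towards_ms: float = 0.0
    shift_away_ms: float = 0.0
    error_rate: float = 0.05
    rir_base_ms: float = 300.0
    interference_ms: float = 20.0
    anticipation_rate: float = 0.02
    omission_rate: float = 0.03
    gender: str = "female"
    age: float = 30.0

    def __post_init__(self) -> None:
        if self.mu_ms <= 0:
            raise ValueError("mu_ms must be positive")
        if self.sigma_ms < 0 or self.tau_ms < 0:
            raise ValueError("sigma_ms and tau_ms must be non-negative")
        if self.malleability < 0:
            raise ValueError("malleability must be non-negative")
        for name in ("error_rate", "anticipation_rate", "omission_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.anticipation_rate + self.omission_rate > 1.0:
            raise ValueError("anticipation_rate + omission_rate must be <= 1")

    @property
    def true_am_towards_ms(self) -> float:
        return self.malleability * self.shift_towards_ms

    @property
    def true_am_away_ms(self) -> float:
        return self.malleability * self.shift_away_ms

    @property
    def true_am_overall_ms(self) -> float:
        return abs(self.true_am_towards_ms) + abs(self.true_am_away_ms)


def _rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _ex_gaussian(
    rng: np.random.Generator, mu: float, sigma: float, tau: float, size: int
) -> np.ndarray:
    out = rng.normal(mu, sigma, size) if sigma > 0 else np.full(size, float(mu))
    if tau > 0:
        out = out + rng.exponential(tau, size)
    return out


def simulate_dotprobe_rts(
    schedule: pd.DataFrame,
    params: ParticipantParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach responses and RTs to a paradigm schedule for one participant.

    The effective bias is ``ab_base_ms`` in blocks 1-2, gains
    ``malleability * shift`` of the first training after block 2, and the
    second training's shift after block 4 (cumulative, persistent).
    """
    gen = _rng(seed, rng)
    n = len(schedule)
    block = schedule["block_index"].to_numpy()
    congruent = schedule["congruent"].to_numpy(dtype=bool)

    shift_of = {
        "towards": params.true_am_towards_ms,
        "away": params.true_am_away_ms,
    }
    bias_by_block = {1: params.ab_base_ms, 2: params.ab_base_ms}
    for b in (2, 4):
        cont = schedule.loc[block == b, "contingency"]
        delta = shift_of[cont.iloc[0]] if len(cont) else 0.0
        prev = bias_by_block[b]
        bias_by_block[b + 1] = prev + delta
        if b + 2 <= 5:
            bias_by_block[b + 2] = bias_by_block[b + 1]
    bias = np.vectorize(bias_by_block.__getitem__)(block).astype(float)

    rt = _ex_gaussian(gen, params.mu_ms, params.sigma_ms, params.tau_ms, n)
    rt = rt + np.where(congruent, -bias / 2.0, bias / 2.0)
    rt = np.maximum(rt, 0.0)
    correct = gen.random(n) >= params.error_rate

    out = schedule.copy()
    out.insert(0, "participant_id", params.participant_id)
    out["correct"] = correct
    out["rt_ms"] = rt
    return out


def simulate_rir_responses(
    schedule: RIRSchedule,
    params: ParticipantParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate tone-detection responses for one participant.

    Each tone yields exactly one of: a timed response (ex-Gaussian RT with
    Gaussian location ``rir_base_ms``, plus ``interference_ms`` during pain
    episodes), an anticipation (press earlier than 100 ms after onset), or
    an omission.  A timed draw landing below 100 ms is classified as an
    anticipation, keeping the classification consistent with the latency.
    """
    gen = _rng(seed, rng)
    frame = schedule.to_frame()
    n = len(frame)
    pain = frame["pain"].to_numpy(dtype=bool)

    u = gen.random(n)
    anticip = u < params.anticipation_rate
    omit = (~anticip) & (u < params.anticipation_rate + params.omission_rate)
    timed = ~(anticip | omit)

    rt = np.full(n, np.nan)
    draws = _ex_gaussian(gen, params.rir_base_ms, params.sigma_ms, params.tau_ms, n)
    draws = draws + np.where(pain, params.interference_ms, 0.0)
    rt[timed] = draws[timed]
    # anticipations are presses at uniform 0-99 ms after onset
    rt[anticip] = gen.integers(0, 100, anticip.sum()).astype(float)
    early = timed & (rt < 100.0)
    timed &= ~early
    anticip |= early

    cls = np.where(timed, "timed", np.where(anticip, "anticipation", "omission"))
    rt[~timed] = np.nan

    out = frame
    out.insert(0, "participant_id", params.participant_id)
    out["response_class"] = cls
    out["rt_ms"] = rt
    return out


@dataclasses.dataclass
class CohortConfig:
    """Population-level configuration of a simulated study.

    Person-level parameters are drawn from normal populations (truncated to
    their valid ranges); questionnaire scale scores are generated to follow
    the configured means/SDs; the pain-intensity and pain-disability
    outcomes are linear in each participant's true overall malleability
    (``beta_*`` in outcome points per ms of true AM_Overall) plus Gaussian
    noise.  Training order, word-list order and the RIR pain-first flag are
    counterbalanced deterministically across participant index.
    """

    n_participants: int = 71
    seed: int = 0
    design: ParadigmDesign = dataclasses.field(default_factory=ParadigmDesign)

    # ex-Gaussian RT population
    mu_mean: float = 450.0
    mu_sd: float = 30.0
    sigma_mean: float = 50.0
    sigma_sd: float = 10.0
    tau_mean: float = 100.0
    tau_sd: float = 25.0
    ab_base_mean: float = 0.0
    ab_base_sd: float = 15.0
    malleability_mean: float = 1.0
    malleability_sd: float = 0.5
    shift_towards_mean: float = 5.0
    shift_towards_sd: float = 10.0
    shift_away_mean: float = -5.0
    shift_away_sd: float = 10.0
    error_rate_mean: float = 0.05
    error_rate_sd: float = 0.03

    # RIR task
    include_rir: bool = True
    rir_total_ms: int = 240_000
    rir_interval_values_ms: tuple[int, int] = (900, 1500)
    rir_episode_ms: int = 24_000
    rir_base_mean: float = 300.0
    rir_base_sd: float = 40.0
    interference_mean: float = 20.0
    interference_sd: float = 15.0
    anticipation_rate: float = 0.02
    omission_rate: float = 0.03

    # questionnaires
    pcs_mean: float = 18.07
    pcs_sd: float = 13.11
    dass_depression_mean: float = 15.75
    dass_depression_sd: float = 11.62
    dass_anxiety_mean: float = 10.14
    dass_anxiety_sd: float = 8.93
    dass_stress_mean: float = 17.13
    dass_stress_sd: float = 10.64
    gcps_days_mean: float = 40.0
    gcps_days_sd: float = 45.0
    attention_to_pain_mean: float = 5.0
    attention_to_pain_sd: float = 2.0

    # outcomes
    intensity_mean: float = 51.36
    disability_mean: float = 41.92
    beta_intensity: float = 0.10
    beta_disability: float = 0.25
    outcome_noise_sd: float = 16.0
    pain_threshold_mean: float = 44.0
    pain_threshold_sd: float = 2.0
    pain_tolerance_mean: float = 46.0
    pain_tolerance_sd: float = 1.5

    # demographics
    p_female: float = 43 / 71
    age_mean: float = 41.55
    age_sd: float = 14.83

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for f in dataclasses.fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must lie in [0, 1]")


@dataclasses.dataclass
class CohortDataset:
    """A complete simulated study with retained ground truth."""

    config: CohortConfig
    participants: pd.DataFrame
    dotprobe: pd.DataFrame
    questionnaire_items: pd.DataFrame
    truth: pd.DataFrame
    rir: pd.DataFrame | None = None
    rir_meta: dict | None = None


def _draw_params(config: CohortConfig, rng: np.random.Generator) -> list[ParticipantParams]:
    n = config.n_participants
    mu = np.clip(rng.normal(config.mu_mean, config.mu_sd, n), 150.0, None)
    sigma = np.clip(rng.normal(config.sigma_mean, config.sigma_sd, n), 0.0, None)
    tau = np.clip(rng.normal(config.tau_mean, config.tau_sd, n), 0.0, None)
    ab = rng.normal(config.ab_base_mean, config.ab_base_sd, n)
    mall = np.clip(rng.normal(config.malleability_mean, config.malleability_sd, n), 0.0, None)
    s_tow = rng.normal(config.shift_towards_mean, config.shift_towards_sd, n)
    s_away = rng.normal(config.shift_away_mean, config.shift_away_sd, n)
    err = np.clip(rng.normal(config.error_rate_mean, config.error_rate_sd, n), 0.0, 0.3)
    rbase = np.clip(rng.normal(config.rir_base_mean, config.rir_base_sd, n), 120.0, None)
    interf = rng.normal(config.interference_mean, config.interference_sd, n)
    female = rng.random(n) < config.p_female
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 90.0)
    width = max(3, len(str(n)))
    return [
        ParticipantParams(
            participant_id=f"P{i + 1:0{width}d}",
            mu_ms=float(mu[i]),
            sigma_ms=float(sigma[i]),
            tau_ms=float(tau[i]),
            ab_base_ms=float(ab[i]),
            malleability=float(mall[i]),
            shift_towards_ms=float(s_tow[i]),
            shift_away_ms=float(s_away[i]),
            error_rate=float(err[i]),
            rir_base_ms=float(rbase[i]),
            interference_ms=float(interf[i]),
            anticipation_rate=config.anticipation_rate,
            omission_rate=config.omission_rate,
            gender="female" if female[i] else "male",
            age=float(round(age[i])),
        )
        for i in range(n)
    ]


def _scale_target(rng, mean: float, sd: float, lo: float, hi: float) -> int:
    return int(np.clip(np.round(rng.normal(mean, sd)), lo, hi))


def _distribute_items(
    total: int, n_items: int, max_item: int, rng: np.random.Generator
) -> np.ndarray:
    """Spread an integer scale total across items, each in [0, max_item].

    Items receive the floor share; the remainder is added to a random
    subset, so the item sum equals ``total`` exactly.
    """
    if not 0 <= total <= n_items * max_item:
        raise ValueError("total outside the representable range")
    base, rem = divmod(total, n_items)
    items = np.full(n_items, base, dtype=int)
    items[rng.choice(n_items, size=rem, replace=False)] += 1
    return items


def _questionnaire_row(
    config: CohortConfig,
    rng: np.random.Generator,
    intensity_target: float,
    disability_target: float,
) -> dict[str, int]:
    row: dict[str, int] = {}
    pcs = _distribute_items(
        _scale_target(rng, config.pcs_mean, config.pcs_sd, 0, 52), 13, 4, rng
    )
    for i, v in enumerate(pcs, start=1):
        row[f"pcs_{i:02d}"] = int(v)
    dass = np.zeros(21, dtype=int)
    for items, mean, sd in (
        (q.DASS_DEPRESSION_ITEMS, config.dass_depression_mean, config.dass_depression_sd),
        (q.DASS_ANXIETY_ITEMS, config.dass_anxiety_mean, config.dass_anxiety_sd),
        (q.DASS_STRESS_ITEMS, config.dass_stress_mean, config.dass_stress_sd),
    ):
        vals = _distribute_items(_scale_target(rng, mean, sd, 0, 21), 7, 3, rng)
        dass[np.asarray(items) - 1] = vals
    for i, v in enumerate(dass, start=1):
        row[f"dass_{i:02d}"] = int(v)
    for offset, target in ((0, intensity_target), (3, disability_target)):
        total = int(np.clip(np.round(3 * target / 10.0), 0, 30))
        vals = _distribute_items(total, 3, 10, rng)
        for j, v in enumerate(vals, start=1):
            row[f"gcps_{offset + j:02d}"] = int(v)
    row["gcps_days"] = _scale_target(rng, config.gcps_days_mean, config.gcps_days_sd, 0, 180)
    t = float(np.clip(rng.normal(config.attention_to_pain_mean, config.attention_to_pain_sd), 0, 10))
    row["atp_01"] = int(np.clip(np.round(t + rng.normal(0, 1)), 0, 10))
    row["atp_02"] = int(np.clip(np.round(10 - t + rng.normal(0, 1)), 0, 10))
    return row


def _encode_template(design: ParadigmDesign) -> dict:
    """Integer-coded, unshuffled schedule template for one design variant.

    Cohort simulation shares one template per (training_order, list_order)
    variant and applies only a cheap per-participant within-block
    permutation, instead of rebuilding string-typed schedule frames.
    """
    from .design import _block_templates

    blocks = [_block_templates(design, b, None) for b in range(1, 6)]
    tmpl = {k: np.concatenate([blk[k] for blk in blocks]) for k in blocks[0]}
    lengths = np.asarray(design.block_lengths)
    stops = np.cumsum(lengths)
    n_pairs = design.n_pairs_per_list
    pair_cats = [f"L{l}P{p:02d}" for l in (1, 2, 3) for p in range(1, n_pairs + 1)]
    return {
        "n": int(lengths.sum()),
        "lengths": lengths,
        "slices": [(int(stop - ln), int(stop)) for stop, ln in zip(stops, lengths)],
        "dirs": (design.training_direction(2), design.training_direction(4)),
        "pair_cats": pair_cats,
        "block_index": tmpl["block_index"].astype(np.int64),
        "trial_index": tmpl["trial_index"].astype(np.int64),
        "btype_code": (tmpl["block_type"] == "training").astype(np.int8),
        "pair_code": pd.Categorical(tmpl["pair_id"], categories=pair_cats).codes,
        "pos_code": (tmpl["pain_word_position"] == "bottom").astype(np.int8),
        "probe_code": (tmpl["probe_position"] == "bottom").astype(np.int8),
        "cont_code": pd.Categorical(
            tmpl["contingency"], categories=["none", "towards", "away"]
        ).codes,
        "congruent": tmpl["congruent"].astype(bool),
    }


def _bias_by_block(p: ParticipantParams, dirs: tuple[str, str]) -> np.ndarray:
    """Effective bias in blocks 1..5: baseline, stepped after each training."""
    shift = {"towards": p.true_am_towards_ms, "away": p.true_am_away_ms}
    b1 = p.ab_base_ms
    b3 = b1 + shift[dirs[0]]
    b5 = b3 + shift[dirs[1]]
    return np.array([b1, b1, b3, b3, b5])


def simulate_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Simulate a full study cohort from a single seeded configuration.

    Training order, word-list order and (when the RIR task is included) the
    pain-first flag are assigned deterministically from the participant
    index; identical configs reproduce identical datasets byte for byte.
    """
    config = config if config is not None else CohortConfig()
    root = np.random.SeedSequence(config.seed)
    ss_params, ss_trials, ss_rir, ss_quest, ss_outcome = root.spawn(5)
    params = _draw_params(config, np.random.default_rng(ss_params))

    true_am = np.array([p.true_am_overall_ms for p in params])
    rng_out = np.random.default_rng(ss_outcome)
    centred = true_am - true_am.mean()
    intensity = np.clip(
        config.intensity_mean
        + config.beta_intensity * centred
        + rng_out.normal(0, config.outcome_noise_sd, len(params)),
        0,
        100,
    )
    disability = np.clip(
        config.disability_mean
        + config.beta_disability * centred
        + rng_out.normal(0, config.outcome_noise_sd, len(params)),
        0,
        100,
    )
    threshold = np.clip(
        rng_out.normal(config.pain_threshold_mean, config.pain_threshold_sd, len(params)),
        38.0,
        48.0,
    )
    tolerance = np.clip(
        rng_out.normal(config.pain_tolerance_mean, config.pain_tolerance_sd, len(params)),
        threshold,
        48.0,
    )

    trial_seeds = ss_trials.spawn(len(params))
    rir_seeds = ss_rir.spawn(len(params))
    quest_rng = np.random.default_rng(ss_quest)

    templates: dict[tuple, dict] = {}
    perms, congs, rts, corrects, variant_of = [], [], [], [], []
    rir_frames, part_rows, quest_rows, truth_rows = [], [], [], []
    for i, p in enumerate(params):
        training_order = "towards_first" if i % 2 == 0 else "away_first"
        list_order = _LIST_ORDERS[i % len(_LIST_ORDERS)]
        pain_first = i % 2 == 0
        key = (training_order, list_order)
        if key not in templates:
            design = dataclasses.replace(
                config.design, training_order=training_order, list_order=list_order
            )
            templates[key] = _encode_template(design)
        tm = templates[key]
        gen = np.random.default_rng(trial_seeds[i])
        perm = np.concatenate([lo + gen.permutation(hi - lo) for lo, hi in tm["slices"]])
        cong = tm["congruent"][perm]
        bias = np.repeat(_bias_by_block(p, tm["dirs"]), tm["lengths"])
        rt = _ex_gaussian(gen, p.mu_ms, p.sigma_ms, p.tau_ms, tm["n"])
        rt = np.maximum(rt + np.where(cong, -bias / 2.0, bias / 2.0), 0.0)
        correct = gen.random(tm["n"]) >= p.error_rate
        perms.append(perm)
        congs.append(cong)
        rts.append(rt)
        corrects.append(correct)
        variant_of.append(key)

        if config.include_rir:
            rgen = np.random.default_rng(rir_seeds[i])
            rsched = make_rir_schedule(
                total_ms=config.rir_total_ms,
                interval_values_ms=config.rir_interval_values_ms,
                episode_ms=config.rir_episode_ms,
                pain_first=pain_first,
                rng=rgen,
            )
            rir_frames.append(simulate_rir_responses(rsched, p, rng=rgen))

        quest_rows.append(
            {"participant_id": p.participant_id}
            | _questionnaire_row(config, quest_rng, intensity[i], disability[i])
        )
        part_rows.append(
            {
                "participant_id": p.participant_id,
                "gender": p.gender,
                "age": p.age,
                "training_order": training_order,
                "list_order": "".join(str(v) for v in list_order),
                "pain_first": pain_first,
                "pain_threshold_c": float(np.round(threshold[i] * 2) / 2),
                "pain_tolerance_c": float(np.round(tolerance[i] * 2) / 2),
            }
        )
        truth_rows.append(
            {
                "participant_id": p.participant_id,
                "mu_ms": p.mu_ms,
                "sigma_ms": p.sigma_ms,
                "tau_ms": p.tau_ms,
                "ab_base_ms": p.ab_base_ms,
                "malleability": p.malleability,
                "shift_towards_ms": p.shift_towards_ms,
                "shift_away_ms": p.shift_away_ms,
                "error_rate": p.error_rate,
                "rir_base_ms": p.rir_base_ms,
                "interference_ms": p.interference_ms,
                "true_am_towards_ms": p.true_am_towards_ms,
                "true_am_away_ms": p.true_am_away_ms,
                "true_am_overall_ms": p.true_am_overall_ms,
                "intensity_target": float(intensity[i]),
                "disability_target": float(disability[i]),
            }
        )

    n_trials = templates[variant_of[0]]["n"]
    pair_cats = templates[variant_of[0]]["pair_cats"]
    ids = [p.participant_id for p in params]

    def gather(field: str) -> np.ndarray:
        return np.concatenate(
            [templates[v][field][perm] for v, perm in zip(variant_of, perms)]
        )

    pos_cats = ["top", "bottom"]
    dotprobe = pd.DataFrame(
        {
            "participant_id": pd.Categorical.from_codes(
                np.repeat(np.arange(len(params)), n_trials), categories=ids
            ),
            "block_index": gather("block_index"),
            "block_type": pd.Categorical.from_codes(
                gather("btype_code"), categories=["assessment", "training"]
            ),
            "trial_index": np.tile(templates[variant_of[0]]["trial_index"], len(params)),
            "pair_id": pd.Categorical.from_codes(gather("pair_code"), categories=pair_cats),
            "pain_word_position": pd.Categorical.from_codes(
                gather("pos_code"), categories=pos_cats
            ),
            "probe_position": pd.Categorical.from_codes(
                gather("probe_code"), categories=pos_cats
            ),
            "congruent": np.concatenate(congs),
            "contingency": pd.Categorical.from_codes(
                gather("cont_code"), categories=["none", "towards", "away"]
            ),
            "correct": np.concatenate(corrects),
            "rt_ms": np.concatenate(rts),
        }
    )

    rir_meta = None
    rir = None
    if config.include_rir:
        rir = pd.concat(rir_frames, ignore_index=True)
        rir_meta = {
            "total_ms": config.rir_total_ms,
            "interval_values_ms": list(config.rir_interval_values_ms),
            "episode_ms": config.rir_episode_ms,
        }
    return CohortDataset(
        config=config,
        participants=pd.DataFrame(part_rows),
        dotprobe=dotprobe,
        questionnaire_items=pd.DataFrame(quest_rows),
        truth=pd.DataFrame(truth_rows),
        rir=rir,
        rir_meta=rir_meta,
    )
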