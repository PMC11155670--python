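# Methods

## The measurement model

Each dot-probe trial presents a pain word and a neutral word, then a probe
at one word's location.  A trial is *congruent* when the probe replaces the
pain word.  The attention-bias index of an assessment block is

    AB = mean RT(incongruent) − mean RT(congruent)   [ms]

so positive values mean faster responding at the pain word's location.
The paradigm is five blocks — assessment, training, assessment, training,
assessment — with 96-trial assessments (48 congruent / 48 incongruent) and
288-trial fully contingent trainings.  One training block makes the probe
always follow the pain word (*towards*), the other always the neutral word
(*away*); block order is counterbalanced.  Three 24-pair word lists rotate
so each list serves one assessment (4 presentations per pair) and, for the
first two lists, the following training block (12 per pair).

Malleability indices are post-minus-pre AB differences across each
training, labelled by the training's direction, and

    AM_Overall = |AB2 − AB1| + |AB3 − AB2|.

The prose convention "subtract the AB after training from the AB before
training" is ambiguous; the post-minus-pre reading is adopted because it is
the only one consistent with the printed overall formula and with positive
mean towards-indices / negative away-indices in the descriptive tables.

Pain interference comes from the RIR tone-detection task: 201 tones at
random 900/1500-ms inter-onset intervals (100 of each) over 240 s, tiled by
ten 24-s episodes alternating pain and no pain.  Interference is the
pain-minus-no-pain difference in mean RT and in error percentage
(anticipations + omissions over tones).

## Generative model of the simulator

RTs are ex-Gaussian: `RT = N(mu, sigma) + Exp(tau)`, the standard
right-skewed description of response latencies.  Defaults per participant
population: mu = 450 ± 30, sigma = 50 ± 10, tau = 100 ± 25 ms.  A
participant's bias `b` enters as a half-shift by congruency (−b/2 congruent,
+b/2 incongruent), so the AB estimator is unbiased for `b` by construction.
`b` starts at `ab_base_ms` (population 0 ± 15 ms) and steps by
`malleability × shift` after each training block, cumulatively and
persistently (the literature is silent on carry-over; step-and-persist is
this package's modelling choice).  True directional malleability is
therefore `malleability × shift_towards` (resp. `shift_away`); defaults
malleability 1 ± 0.5 (truncated at 0), shifts +5/−5 ± 10 ms.  Probe errors
are Bernoulli with rate 0.05 ± 0.03.

RIR responses: each tone is an anticipation (press 0–99 ms after onset,
rate 0.02), an omission (rate 0.03), or a timed ex-Gaussian response whose
Gaussian component is centred on `rir_base_ms` (300 ± 40 ms) plus
`interference_ms` (20 ± 15 ms) during pain episodes.  A timed draw below
100 ms is reclassified as an anticipation so classification always matches
latency.

Questionnaire items are generated backwards from a target scale score drawn
from the configured population (PCS 18.07 ± 13.11; DASS depression/anxiety/
stress 15.75 ± 11.62 / 10.14 ± 8.93 / 17.13 ± 10.64; GCPS means 51.36 /
41.92; attention to pain 5 ± 2): the integer target is spread uniformly
across the instrument's items, so item sums reproduce the target exactly and
scale scores follow the configured moments up to range clipping and item
rounding.  The pain-intensity and pain-disability outcomes are linear in
true overall malleability — `outcome = mean + beta × (AM_true − ĀM_true) +
N(0, 16)` with default betas 0.10 and 0.25 points/ms — so regression
recovery can be tested against a configured effect.  Pain threshold and
tolerance are independent draws (44 ± 2 °C and 46 ± 1.5 °C, rounded to the
0.5 °C a staircase procedure would deliver) with no configured link to
malleability.  Training order, word-list order and the pain-first flag of
the RIR episode sequence alternate deterministically with participant
index.

What the simulator does **not** emulate: lexical properties of word stimuli
(pair labels are synthetic tokens), sequential effects and fatigue,
speed-accuracy trade-offs, item-level questionnaire covariance structure
(items within a scale are exchangeable by construction), and any
psychophysics of heat pain beyond numeric threshold/tolerance values.
Passing recovery tests therefore validates the scoring arithmetic and
cleaning pipeline under a plausible RT model — not the psychometrics of
real dot-probe data, whose reliability problems are well documented.

## Cleaning rules

Dot-probe, in order: (1) drop incorrect responses; (2) drop RTs outside
[200, 2000] ms; (3) within each participant × assessment block, drop RTs
deviating from the block median by more than `2.5 × 1.4826 × MAD` (raw
median absolute deviation; the 1.4826 normal-consistency factor is the
default of R's `mad()`, the tool this rule comes from — with the ex-Gaussian
defaults it removes ~5% of assessment trials, keeping total assessment loss
near 10%, where the unscaled rule would remove ~12% and visibly attenuate
difference scores; `mad_scale=1.0` restores the raw criterion); (4) exclude
participants below 75% accuracy over all paradigm trials.  A block whose
MAD is 0 skips step 3 (the rule would otherwise delete every non-median
trial).  The MAD filter applies to assessment blocks only; training trials
matter only for accuracy.  Every removal is tallied per participant × block
× rule, and a participant left with an empty congruency cell is flagged and
surfaced as a named error at scoring — cohort summaries never shrink
silently.

The MAD filter is single-pass by definition: re-deriving the median and MAD
on already-filtered data shrinks the bound and can remove more trials, so
cleaning is *not* idempotent in the strict sense; the correctness, window
and accuracy rules are.

RIR, for the RT set: drop anticipations and omissions, the first and last
tone of every episode ("block" endpoints are read as episode endpoints,
ten per session), and timed RTs above the participant's mean + 3 SD
(one-sided, as stated; mean and SD over the participant's timed RTs after
anticipation/omission removal, sample SD).  Participants with fewer than
two timed responses skip the SD rule with a warning flag.  Error rates use
the pre-cleaning classifications, excluding endpoint tones, with tones
presented as the denominator.

Both outlier rules truncate the exponential tail asymmetrically between
conditions and therefore attenuate difference scores slightly: ±40-ms
training shifts are recovered at ≈ 35–37 ms (within 3 SEs at n = 200), and
a 50-ms interference at ≈ 45 ms (within 3 Monte-Carlo SEs at 10⁴ tones).
This is a property of the published cleaning procedure, not of the
implementation.

## The noise floor of AM_Overall

Under a zero-effect configuration (no bias, no shifts), each per-block AB
estimate is approximately `N(0, σ_AB²)`, so each |post − pre| difference is
folded-normal with mean `√2·σ_AB·√(2/π)` and

    E[AM_Overall] = 2·√2·σ_AB·√(2/π)  ≈ 2.26·σ_AB.

The acceptance check simulates 2000 zero-effect participants through the
full pipeline and compares the mean AM_Overall with this prediction, using
the empirical SD of the pooled per-block ABs as σ_AB (the MAD filter
changes the estimator's variance, so the analytic ex-Gaussian value would
be wrong; the folded-normal identity itself is what is under test).  With
the default generator, σ_AB ≈ 16 ms gives a noise floor near 36 ms — the
bulk of a typical observed AM_Overall mean, which is why the index should
never be interpreted without this reference point.

## Statistical conventions

Hierarchical OLS: step 1 = controls (gender coded female = 1, plus age for
the chronic-pain battery, plus baseline AB), step 2 adds one AM index.

    ΔR² = R²_full − R²_step1
    F_change = (ΔR²/df1) / ((1 − R²_full)/df2),   df2 = n − p_full − 1
    f² = ΔR² / (1 − R²_full)

`p_change` comes from F(df1, df2); the reported `b_std` is the focal
predictor's coefficient after z-scoring all variables (n−1 denominator),
`t` and its df from the full model's residual df.  Bonferroni control uses
family size 3 — the three AM indices tested per outcome.  Complete-case
analysis throughout; rank deficiency among controls is an error naming the
collinear columns, while a focal predictor collinear with the controls
returns ΔR² = 0, F = 0, p = 1 (it adds no information).  Correlations are
pairwise-complete Pearson with two-sided p from the t transform; cells with
a zero-variance member are flagged undefined rather than reported as 0.

Questionnaire scoring: PCS total 0–52 with Sullivan's subscale keys
(rumination 8–11, magnification 6/7/13, helplessness 1–5/12); DASS-21 as
raw 0–21 sums (not doubled to DASS-42 equivalents); GCPS intensity and
disability as 10 × the mean of their three 0–10 items; attention to pain as
the mean of one direct and one reverse-scored 0–10 item.  No imputation:
missing or out-of-range items raise.

## Numerical and design notes

- RTs are stored in delimited files as decimal milliseconds and parsed with
  correctly-rounded `float()`, so write-then-read round trips are
  bit-exact and noise-free identities (AB equals the configured bias,
  including half-millisecond congruency offsets) survive serialization.
- All randomness flows from `numpy` `SeedSequence` spawning: one cohort
  seed determines parameter draws, per-participant trial streams,
  questionnaires and outcomes independently; identical configurations
  reproduce byte-identical datasets, reports and manifest digests.
- The zero-residual-variance guard in the regression engine triggers at
  `SSR ≤ 1e-13 × TSS`; a degenerate fit is an error, never a silent
  `R² = 1`.
- Problem sizes used by the validation harnesses: 2000 participants for the
  noise floor, 200 for shift recovery, 100 random datasets for the
  F-change oracle, 2000 replicates (n = 70) for null calibration and 500
  replicates (n = 71) for ΔR² recovery — sizes at which binomial/Monte-
  Carlo tolerances are tight enough to be informative while a full run
  stays under a minute.

## Known limitations

- Raw difference scores are noisy (see the noise floor above); no
  reliability-corrected or split-half disattenuated indices are provided.
- The step-and-persist training dynamic is an assumption; if training
  effects decay within a block, directional indices under-recover.
- The accuracy exclusion is computed over all paradigm trials; computing it
  over assessment blocks only would change marginal cases.
- The generator's exchangeable-item questionnaires cannot test subscale-
  level psychometrics.
- Raw data from real studies can be adapted via the documented column
  schemas (`ambias.io.SCHEMAS`), but no importer for any specific vendor
  export format is included.
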