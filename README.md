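# ambias

Simulation, scoring and inference for **attention-bias malleability (AM)** in
pain research.

Dot-probe experiments quantify a person's *attentional bias* (AB) towards
pain-related words: probes replacing a pain word are identified faster than
probes replacing a neutral word when attention is drawn to pain.  A newer
question is not where attention sits at baseline, but how readily it can be
*pushed around* — attention-bias **malleability**.  The paradigm implemented
here interleaves three no-contingency assessment blocks with two fully
contingent training blocks (one training attention towards pain words, one
away), and summarises each participant with:

- `AB_k  = mean RT(incongruent) − mean RT(congruent)` for assessment block *k*
- `AM_Towards / AM_Away = AB(post-training) − AB(pre-training)` for the
  corresponding training block
- `AM_Overall = |AB2 − AB1| + |AB3 − AB2|`

alongside pain interference from a Random Interval Repetition (RIR)
tone-detection task performed under alternating pain / no-pain episodes
(ΔRT and Δ% errors, pain minus no pain), questionnaire scores (PCS, DASS-21,
GCPS, attention to pain), and a hierarchical-regression layer
(ΔR², F-change, standardized *b*, Cohen's *f²*, Bonferroni control) relating
the AM indices to pain outcomes.

Because raw participant data for such studies are rarely redistributable,
the package ships a first-class synthetic-data module: ex-Gaussian RT
generators with known person-level bias, malleability and interference, so
every stage of the pipeline — cleaning rules included — can be validated by
parameter recovery against ground truth.

Who is it for: researchers running or re-analysing dot-probe / RIR
paradigms who want the index definitions, trial-cleaning rules and
regression conventions pinned down in tested code rather than scattered
across analysis scripts.

## Worked example

Simulate a 71-person cohort, clean it, score every stage and run the full
regression battery:

```sh
ambias full --seed 1 --out demo_run
```

The run writes trial tables, per-stage scores, an analysis table, a JSON
report and a manifest into `demo_run/`, and prints the report, which begins:

```
Attention index descriptives
  AB_Baseline  2.96 (23.29)  [n=71]
  AM_Away      -8.26 (27.50)  [n=71]
  AM_Towards   3.44 (24.99)  [n=71]
  AM_Overall   41.41 (26.87)  [n=71]
```

Mean baseline AB is near zero with a ~23-ms spread (measurement noise plus
true individual differences), the directional malleability indices are
small and opposite in sign, and `AM_Overall` is large and strictly positive
— difference-score noise alone produces a sizeable overall-malleability
mean, which is why the package also reports the zero-effect noise floor
(see `docs/methods.md`).  Each regression line reads like

```
gcps_disability ~ ... + am_overall_ms: dR2 = 0.05, F(1,66) = 3.71, p = 0.06, f2 = 0.06, b* = 0.24 [Bonferroni: ns]
```

i.e. adding overall malleability to gender, age and baseline AB explains a
further 5% of the variance in pain disability for this simulated cohort,
not significant after Bonferroni correction over the three AM indices.

The same stages are available as a library (`simulate_cohort`,
`clean_dotprobe`, `score_am_cohort`, `score_rir_cohort`, `score_item_table`,
`hierarchical_regression`, …) and as staged subcommands
(`simulate`, `score-am`, `score-rir`, `score-questionnaires`, `analyze`,
`calibrate`).

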