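# propmort

Stage-specific **proportional mortality** analysis for cancer registry
cohorts: among people diagnosed with a first primary cancer, what do they
eventually die of — the index cancer itself, a subsequent (non-index)
cancer, or a non-cancer cause — and how does that depend on stage at
diagnosis?

Because the endpoint is the *final cause of death* rather than survival
time, the analysis is immune to lead-time bias: detecting a cancer
earlier cannot change the answer unless it actually changes the cause of
death. That makes stage-specific cause-of-death distributions a clean way
to reason about what population-wide earlier detection (for example a
multi-cancer early detection blood test) could plausibly achieve.

The package is aimed at cancer epidemiologists and modellers working with
SEER-style case listings, and at anyone who wants to reproduce or stress
the published headline numbers from the packaged table transcriptions.

## The method

1. **Classification.** Every death with a known certificate cause is
   classified as *index* (fatal cancer at the index anatomic site),
   *non-index cancer* (subsequent primary at another site, kept at site
   resolution), or *non-cancer* (26 standard registry causes collapsed
   into grouped labels: heart disease, COPD, "other circulatory
   diseases", …). Deaths with unknown cause are excluded up front, with
   the excluded fraction logged.

2. **Allocation ("followed until death by observation or
   extrapolation").** Within each stratum *(site group × stage)* each
   case receives a weight vector **w** ≥ 0, Σw = 1, over cause
   categories:

   - died in follow-up → weight 1 on the classified cause;
   - lost to follow-up in year *t* → the stratum's observed cause
     distribution among deaths in follow-up year *t*;
   - alive at the administrative end → the stratum's cause distribution
     over the final 48 months of attainable follow-up (justified by the
     plateau — "statistical cure" — in index-cancer death risk roughly
     10 years after diagnosis).

   Empty cells fall back along a logged chain (adjacent years → stratum
   pooled → site group → global). Allocated "counts" are sums of weights,
   so every column of every table adds up to the number of cases.

3. **Stage-shift counterfactuals.** For site group *g*, source stage *s*
   with N<sub>g,s</sub> cases (= allocated deaths) of which
   D<sub>g,s</sub> are index deaths, and shift weights w(s→t):

   averted<sub>g,s</sub> = D<sub>g,s</sub> − N<sub>g,s</sub> · Σ<sub>t</sub> w(s→t) · p<sub>index</sub>(g,t)

   where p<sub>index</sub>(g,t) is the target stage's index-death
   proportion in the same table. Scenarios are computed per type and
   summed — never on the pooled all-types row.

A seeded synthetic-cohort generator (competing-cause discrete-time
hazards with a cure plateau, age-increasing non-cancer mortality, and
administrative + random censoring) provides ground truth for validating
the whole pipeline by parameter recovery; see `docs/methods.md`.

## Worked example

```sh
propmort simulate --out results/synthetic --n-cases 11545 --seed 1234
propmort run --listing results/synthetic/case_listing.csv --out results/pipeline
```

(Equivalently `python analysis/01_simulate_cohort.py` and
`…/02_allocate_and_tabulate.py`.) On the default synthetic cohort this
prints, among other things:

```
cases read: 11545, excluded for unknown cause: 60 (0.5%)

provenance of allocated causes by stage (fractions):
         observed  imputed_lost  extrapolated_alive
stage
I           0.573         0.040               0.387
II          0.594         0.040               0.365
III         0.813         0.028               0.159
IV          0.984         0.004               0.012

all-types cause-of-death percentages by stage:
cause    index  non_cancer  non_index_cancer
stage
I         14.0        83.0               3.0
III       53.0        45.0               2.0
IV        87.0        12.0               1.0
```

Reading: at stage I most of the cause-of-death mass must be extrapolated
(39%) because most early-stage patients outlive follow-up, whereas stage
IV is almost entirely observed (98%); and the index cancer accounts for
14% of eventual deaths after a stage I diagnosis but 87% after stage IV —
the stage gradient the analysis is built to expose. `results/pipeline/`
then contains the tidy major-cause, detailed-cause and stratified tables
plus per-scenario CSVs.

`propmort reproduce-paper` recomputes every published headline quantity
from the packaged table transcriptions (cohort size 1,154,515; survivor
fractions 60/32/9% at stages I–II/III/IV; all-types cause percentages;
the 41% stage-IV share of index deaths; thyroid 5% vs pancreas 86%
early-stage index mortality; the three scenario reductions) and exits
nonzero on any mismatch.

## Layout

- `src/propmort/` — the library: `vocab`, `cohort_model`,
  `synthetic_cohort`, `cod_allocation`, `mortality_tables`,
  `stage_shift`, `fixtures`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `src/propmort/data/` — transcribed published tables (counts only;
  percentages are always recomputed) and the cause vocabulary.
- `docs/methods.md` — model, parameters, design decisions, limitations.
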