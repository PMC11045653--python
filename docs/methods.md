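# Methods

## The estimand and why cause of death

For a cohort of first primary cancer cases, the quantity of interest is
the distribution of *eventual* cause of death — index cancer, non-index
(subsequent primary) cancer, or non-cancer — by cancer type and stage at
diagnosis. Survival-time comparisons across stages are contaminated by
lead-time bias (earlier diagnosis mechanically lengthens survival);
final cause of death is not. The price is censoring: in a cohort with
10–15 years of follow-up most early-stage patients are still alive, and
the probability of observing a death depends strongly on stage and
cause (index-cancer deaths cluster early, non-cancer deaths late).
Ignoring censored cases would therefore bias the cause mix. The
allocation engine removes this selection by following every case to a
death — observed, imputed, or extrapolated.

## Classification

Deaths are classified against a closed cause vocabulary
(`src/propmort/data/cause_vocabulary.csv`): 22 cancer-site causes and
the 26 standard registry non-cancer causes. Non-cancer causes are
collapsed to grouped labels: tuberculosis, syphilis and other
infectious/parasitic diseases become "Other Infectious Diseases"
(septicemia stays separate); hypertension without heart disease,
atherosclerosis, aortic aneurysm/dissection and other arterial disease
become "Other Circulatory Diseases" (heart disease and cerebrovascular
disease stay separate); accidents and homicide combine to
"Accidents/External Causes" (suicide stays separate); and a seven-cause
residual becomes "Other". An index death is a cancer death whose site
matches the case's *parent* site group, so a lung-cancer death after
small-cell lung cancer is an index death. Same-site second primaries do
not exist in registry convention and are never emitted by the
generator. Deaths with unknown cause are excluded before analysis and
the excluded fraction is logged.

Breast cases are refined to hormone-receptor (HR) subtypes — HR-positive
if ER or PR is positive, HR-negative if both negative, HR-unknown
otherwise — and lung to small-cell vs non-small-cell by morphology code.
The packaged small-cell set (8041–8045) is a placeholder for a
registry-specific list. Subtype rows are reported alongside parent rows
and never enter "All Types" aggregates.

## Allocation

Strata are (site group × stage); follow-up year *k* covers months
12(k−1) < m ≤ 12k, with month 0 in year 1.

- **Observed** deaths get weight 1 on their classified cause; on the
  observed subset, allocated counts equal classified counts exactly.
- **Lost** cases get the stratum's observed cause distribution in the
  loss year. The source text is ambiguous about whether "the
  corresponding year" means the loss year's distribution or a
  forward-looking mixture; both are implemented
  (`lost_mode='loss_year'|'forward'`), with the literal loss-year
  reading as default.
- **Alive** cases get the stratum's pooled cause distribution over
  deaths in the final `tail_window_months` (default 48) before the
  maximum attainable follow-up month, measured dataset-wide. The
  justification is the cure plateau: index-cancer death risk flattens
  roughly 10 years after diagnosis, so the late-window cause mixture is
  approximately stationary and no future death dates need modelling.

Allocation is performed at detail resolution (non-index sites, grouped
non-cancer causes); major-category results are marginals of the same
weights. Fractional weights are the default because they are
reproducible and expectation-exact; a seeded single-draw mode
(`mode='sampled'`) exists for sensitivity checks.

Empty cells trigger a logged fallback chain: loss year → adjacent years
(±1) → stratum pooled over years → site group pooled over stages →
global; for tails: stratum tail → stratum all years → global tail →
global. Exhausting the chain raises an error naming the stratum — never
silent zeros. At the global level "index" pools across sites and a
case's own site can appear as a non-index cause; this last-resort
heterogeneity is accepted and logged.

## Tables and scenarios

Tables carry real-valued allocated counts; within-cell percentages are
computed from unrounded counts, and half-up rounding to whole percent is
presentation-only (it reproduces every spot-checked printed cell,
including rows summing to 101%). "All Types" sums the mutually exclusive
partition (parent sites + "Other Types"). The stage distribution of
index deaths uses known stages only.

Scenarios redistribute source-stage cases onto target-stage mixtures and
price them at the target stage's index-death proportion from the same
table, per type, then sum. The percent reduction divides by the scope's
total index deaths across all stages *including unknown stage* — the
denominator consistent with the published headline percentages (the
pooled all-types row gives the same rounded values). The expected
non-index and non-cancer mix of shifted cases is recomputed from the
target-stage proportions and reported alongside. Target cells with no
cases either raise (default) or fall back to the site's known-stage
pooled proportions (`zero_cell='pooled'`).

Running a scenario on the pooled "All Types" row instead of per type
changes the answer by thousands of deaths (a Simpson-type aggregation
effect); the per-type summation is the definition used everywhere.

## Packaged table transcriptions

`table1_characteristics.csv` (cohort characteristics by stage) and
`table2_cause_by_type_stage.csv` (cause counts by type and stage)
transcribe the published tables, counts only. The transcription is
pinned by identities tested in `tests/test_fixtures.py`: every
characteristic partitions each stage column into the same totals
(268,840 / 326,023 / 152,476 / 202,583 / 204,593, summing to 1,154,515),
and cause rows match case counts within printed rounding. Two
peculiarities of the published tables are preserved as printed: the
cause table folds the unstaged-only types (brain/CNS, leukemia, myeloma)
into "Other Types", and its "All Types" rows are not exactly the sum of
the printed per-type rows. The per-type rows are what the scenario
arithmetic uses, and they reproduce the published averted-death counts
to within 0.01–0.02%.

## The synthetic cohort generator

The generator emulates the *structure* of a registry case listing, not
any real registry's rates. Causes compete in discrete yearly draws:
each cause has a constant yearly death probability; the index-cancer
probability drops to a reduced constant after a plateau year (default
year 10, 15% of the pre-plateau level), modelling statistical cure;
non-cancer probabilities scale multiplicatively per 5-year age band
(slopes 1.2–1.8 by cause). Death months are uniform within the drawn
year. Administrative censoring reflects a fixed study end: the maximum
attainable follow-up (default 179 months) shrinks with later diagnosis
year/month. Loss to follow-up is an independent yearly geometric draw;
within a year death is drawn before loss. A fraction of deaths
(default 0.8%) gets an unknown-cause code to exercise the eligibility
step.

Default study conditions (`default_params`) mimic the published cohort
at 1/100 scale (~11,545 cases): the (site × stage) mixture and the
age/sex/race margins come from the packaged characteristics table
(breast and lung drawn at subtype resolution); hazard magnitudes are
round numbers ordered like the published lethality gradient (stage
probabilities 0.02/0.035/0.10/0.40/0.08 for I/II/III/IV/unknown, site
factors 0.15 for thyroid up to 2.5 for pancreas, capped at 0.8/year).
Sex is forced for sex-specific sites; demographics are otherwise drawn
independently of site and stage, and hazards do not differ by sex or
race — stratified-table tests that need demographic contrasts construct
them explicitly.

Every case's latent death cause and month are simulated regardless of
censoring and written to a separate truth file the pipeline never
reads. What passing recovery tests show is that the *engine* is
consistent: when censoring is independent of cause and the yearly cause
mixture is stationary, allocated proportions converge to the truth.
They do not show that real-registry extrapolation is unbiased — with
real data the tail window and loss-year distributions are
approximations whose quality depends on the cure plateau actually
holding.

## Validation design and numerical choices

- Recovery tests use compact conditions (3 sites × 4 stages, n=20,000,
  time-constant hazards) where imputation and extrapolation are exactly
  unbiased, so any systematic deviation indicates a defect. The
  comparison's standard error accounts for the shared sampling noise of
  the empirical tail and loss-year distributions, not just binomial
  noise in the truth.
- Censoring-ignorability is checked within stratum; pooled across
  strata observed deaths legitimately over-represent early-dying
  strata — the very bias the extrapolation corrects.
- The generator's cause-mixture check uses a brute-force per-year
  probability recursion as an independent oracle.
- Allocation is checked against an explicit per-case enumeration oracle
  on hand-built cohorts (exact equality) and on random small cohorts.
- Problem sizes in the default suite (up to 40,000 simulated cases)
  keep the full run under ~10 seconds.
- Rounding: half-up to whole percent for display, chosen because it
  reproduces all spot-checked printed cells; banker's rounding does not.

## Limitations

- The generator's censoring model (independent geometric loss) is a
  stand-in; real loss-to-follow-up mechanisms in registries are not
  described by the source and may be informative.
- Morphology and hormone-receptor mappings are configurable
  placeholders, not the full registry recode.
- No standardized mortality ratios, competing-risks quantities,
  life-years, or inference on table cells (no CIs) — out of scope by
  design; the analysis is purely proportional.
- Stratum distributions default to (site group × stage); whether the
  published computation used exactly this resolution is not stated, and
  the fallback chain is this package's own construction.
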