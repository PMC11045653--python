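import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import hand_cohort, simple_params
from propmort import cohort_model, vocab
from propmort.cod_allocation import (PROV_EXTRAPOLATED, PROV_IMPUTED,
                                     PROV_OBSERVED, AllocationConfig,
                                     allocate_case, allocate_cohort,
                                     cause_label, followup_year,
                                     split_cause_label, tail_distribution,
                                     yearly_distributions)
from propmort.synthetic_cohort import simulate_cohort


def brute_force_allocate(classified: pd.DataFrame, window: int = 48) -> dict:
    """Independent allocation oracle: explicit per-case dict arithmetic."""
    dead = classified[classified["vital_status"] == "dead"]
    deaths = [
        (r.site_group, r.stage, max(1, math.ceil(r.followup_months / 12)),
         r.followup_months,
         "index" if r.major == "index" else f"{r.major}|{r.detail}")
        for r in dead.itertuples()
    ]
    max_m = int(classified["followup_months"].max())

    def norm(items):
        total = len(items)
        out: dict[str, float] = {}
        for c in items:
            out[c] = out.get(c, 0.0) + 1.0 / total
        return out

    result = {}
    for r in classified.itertuples():
        if r.vital_status == "dead":
            label = "index" if r.major == "index" else f"{r.major}|{r.detail}"
            result[r.case_id] = ({label: 1.0}, PROV_OBSERVED)
        elif r.vital_status == "lost":
            year = max(1, math.ceil(r.followup_months / 12))
            for pick in [
                [c for s, g, y, m, c in deaths
                 if s == r.site_group and g == r.stage and y == year],
                [c for s, g, y, m, c in deaths
                 if s == r.site_group and g == r.stage and abs(y - year) <= 1],
                [c for s, g, y, m, c in deaths
                 if s == r.site_group and g == r.stage],
                [c for s, g, y, m, c in deaths if s == r.site_group],
                [c for s, g, y, m, c in deaths],
            ]:
                if pick:
                    result[r.case_id] = (norm(pick), PROV_IMPUTED)
                    break
        else:  # alive at administrative end
            for pick in [
                [c for s, g, y, m, c in deaths
                 if s == r.site_group and g == r.stage and m > max_m - window],
                [c for s, g, y, m, c in deaths
                 if s == r.site_group and g == r.stage],
                [c for s, g, y, m, c in deaths if m > max_m - window],
                [c for s, g, y, m, c in deaths],
            ]:
                if pick:
                    result[r.case_id] = (norm(pick), PROV_EXTRAPOLATED)
                    break
    return result


def test_followup_year_binning():
    assert followup_year(0) == 1
    assert followup_year(1) == 1
    assert followup_year(12) == 1
    assert followup_year(13) == 2
    assert followup_year(24) == 2
    assert list(followup_year(np.array([0, 12, 25]))) == [1, 1, 3]


def test_cause_label_roundtrip():
    for major, detail in [("index", None), ("non_index_cancer", "Lung"),
                          ("non_cancer", "Heart Disease")]:
        assert split_cause_label(cause_label(major, detail)) == (major, detail)


def test_yearly_distribution_normalization(tiny_classified):
    ydists = yearly_distributions(tiny_classified, ("Breast, All", "I"))
    # deaths at months 30, 30, 28 fall in year 3; 6 in year 1; 95, 90 in year 8
    assert set(ydists) == {1, 3, 8}
    y3 = ydists[3].proportions
    assert y3 == {"index": pytest.approx(1 / 3),
                  "non_cancer|Heart Disease": pytest.approx(1 / 3),
                  "non_index_cancer|Lung": pytest.approx(1 / 3)}
    assert sum(ydists[1].proportions.values()) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="unknown stratum"):
        yearly_distributions(tiny_classified, ("Appendix", "I"))
    empty = yearly_distributions(tiny_classified, ("Thyroid", "I"))
    assert empty == {}


def test_tail_distribution_and_fallbacks(tiny_classified):
    # max attainable follow-up is 100 months; the default 48-month window
    # keeps deaths after month 52: a07 (95, heart), a08 (90, breast)
    tail = tail_distribution(tiny_classified, ("Breast, All", "I"))
    assert tail.fallback is None
    assert tail.proportions == {"non_cancer|Heart Disease": 0.5, "index": 0.5}
    # a window covering the whole follow-up equals the overall distribution
    wide = tail_distribution(tiny_classified, ("Breast, All", "I"), 100)
    overall = (tiny_classified.query(
        "site_group == 'Breast, All' and vital_status == 'dead'"))
    assert sum(wide.counts.values()) == len(overall)
    # stratum with no tail deaths (Lung IV deaths all before cutoff)
    lung = tail_distribution(tiny_classified, ("Lung, All", "IV"))
    assert lung.fallback == "stratum_all_years"
    assert sum(lung.counts.values()) == 3
    # stratum with no deaths at all falls back globally, flagged
    none = tail_distribution(tiny_classified, ("Thyroid", "II"))
    assert none.fallback in ("global_tail", "global_all_years")


def test_allocate_case_examples(tiny_classified):
    stratum = ("Breast, All", "I")
    ydists = yearly_distributions(tiny_classified, stratum)
    tail = tail_distribution(tiny_classified, stratum)
    dead = tiny_classified.iloc[0]
    w, prov = allocate_case(dead, ydists, tail)
    assert prov == PROV_OBSERVED and w == {"index": 1.0}
    lost = tiny_classified.iloc[4]  # lost at month 30 -> year 3
    w, prov = allocate_case(lost, ydists, tail, tiny_classified)
    assert prov == PROV_IMPUTED
    assert w == ydists[3].proportions
    alive = tiny_classified.iloc[5]
    w, prov = allocate_case(alive, ydists, tail, tiny_classified)
    assert prov == PROV_EXTRAPOLATED
    assert w == tail.proportions


def test_allocate_cohort_matches_brute_force_oracle(tiny_classified):
    alloc = allocate_cohort(tiny_classified)
    oracle = brute_force_allocate(tiny_classified)
    for cid, (w_exp, prov_exp) in oracle.items():
        assert alloc.provenance[cid] == prov_exp
        got = alloc.weights.loc[cid]
        got = got[got > 0].to_dict()
        assert got == w_exp, cid


def test_zero_censoring_equals_classification():
    cases, _ = simulate_cohort(
        simple_params(2_000, seed=47, loss_prob=0.0, max_followup_months=2400))
    classified = cohort_model.classify_cohort(cases)
    alloc = allocate_cohort(classified)
    assert (alloc.provenance == PROV_OBSERVED).all()
    # aggregate weights equal raw classified death counts exactly
    agg = alloc.weights.sum(axis=0)
    counts = classified.assign(
        label=[cause_label(m, None if pd.isna(d) else d)
               for m, d in zip(classified["major"], classified["detail"])]
    )["label"].value_counts()
    for label, total in agg.items():
        assert total == counts[label]


def test_mass_conservation_and_provenance_summary(small_classified):
    classified, _ = small_classified
    alloc = allocate_cohort(classified)
    n = len(classified)
    assert alloc.weights.to_numpy().sum() == pytest.approx(n, abs=1e-6)
    per_case = alloc.weights.sum(axis=1)
    assert np.allclose(per_case, 1.0)
    # conservation within every stratum
    strata = classified.set_index("case_id")[["site_group", "stage"]]
    joined = alloc.weights.join(strata)
    for (_, _), grp in joined.groupby(["site_group", "stage"]):
        w = grp.drop(columns=["site_group", "stage"]).to_numpy().sum()
        assert w == pytest.approx(len(grp), abs=1e-9)
    summary = alloc.provenance_summary(classified)
    assert np.allclose(summary.sum(axis=1), 1.0)
    assert (summary[PROV_OBSERVED] > 0).all()


def test_sampled_mode_is_seeded_one_hot(small_classified):
    classified, _ = small_classified
    cfg = AllocationConfig(mode="sampled", seed=5)
    a = allocate_cohort(classified, cfg)
    b = allocate_cohort(classified, cfg)
    pd.testing.assert_frame_equal(a.weights, b.weights)
    assert set(np.unique(a.weights.to_numpy())) <= {0.0, 1.0}
    assert np.allclose(a.weights.sum(axis=1), 1.0)


def test_forward_lost_mode(tiny_classified):
    cfg = AllocationConfig(lost_mode="forward")
    alloc = allocate_cohort(tiny_classified, cfg)
    # lost at month 30 (year 3): forward pool = deaths in years >= 3
    w = alloc.weights.loc["a05"]
    w = w[w > 0].to_dict()
    # stratum deaths in years >= 3: months 30, 30, 28 (year 3), 95, 90 (year 8)
    assert w == {"index": pytest.approx(2 / 5),
                 "non_index_cancer|Lung": pytest.approx(1 / 5),
                 "non_cancer|Heart Disease": pytest.approx(2 / 5)}


def test_allocation_error_when_no_deaths_anywhere():
    df = hand_cohort().assign(vital_status="alive", cod_code=None)
    classified = cohort_model.classify_cohort(df)
    from propmort.cod_allocation import AllocationError

    with pytest.raises(AllocationError):
        allocate_cohort(classified)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(
    st.tuples(
        st.sampled_from(["Breast, All", "Lung, All"]),
        st.sampled_from(["I", "IV"]),
        st.integers(min_value=0, max_value=120),
        st.sampled_from(["dead", "alive", "lost"]),
        st.sampled_from(["Breast", "Lung", "Diseases of Heart", "Tuberculosis"]),
    ),
    min_size=1, max_size=30,
))
def test_allocation_invariants_on_random_cohorts(rows):
    """Mass conservation and observed-subset fidelity hold on arbitrary
    cohorts, as long as at least one death is observed."""
    df = pd.DataFrame({
        "case_id": [f"c{i}" for i in range(len(rows))],
        "site_group": [r[0] for r in rows],
        "stage": [r[1] for r in rows],
        "age_group": "60-64", "sex": "Female", "race_ethnicity": "Hispanic",
        "dx_year": 2006,
        "followup_months": [r[2] for r in rows],
        "vital_status": [r[3] for r in rows],
        "cod_code": [r[4] if r[3] == "dead" else None for r in rows],
    })
    classified = cohort_model.classify_cohort(df)
    if not (classified["vital_status"] == "dead").any():
        return
    alloc = allocate_cohort(classified)
    assert alloc.weights.to_numpy().sum() == pytest.approx(len(df), abs=1e-9)
    dead = classified[classified["vital_status"] == "dead"]
    for r in dead.itertuples():
        label = cause_label(r.major, None if pd.isna(r.detail) else r.detail)
        assert alloc.weights.loc[r.case_id, label] == 1.0
    oracle = brute_force_allocate(classified)
    for cid, (w_exp, _) in oracle.items():
        got = alloc.weights.loc[cid]
        got = got[got > 0].to_dict()
        assert got == pytest.approx(w_exp)
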