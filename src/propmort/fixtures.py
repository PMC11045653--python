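"""Packaged transcriptions of the published cohort-characteristics and
cause-of-death tables, plus the headline summaries derived from them.

Counts only are stored; all percentages are recomputed. The transcriptions
are verified in the test suite by row/column-sum identities (every
characteristic partitions each stage column into the same stage totals,
which sum to the cohort size).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from . import vocab
from .mortality_tables import MortalityTable, round_half_up

COHORT_SIZE = 1_154_515

# Rows of the published cause table that are not part of the mutually
# exclusive per-type partition.
AGGREGATE_ROW = "All Types"
SUBTYPE_ROWS = [
    "Breast, HR-Positive", "Breast, HR-Negative", "Breast, HR-Unknown",
    "Lung, Non-Small-Cell", "Lung, Small-Cell",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("propmort.data").joinpath(name).open() as f:
        return pd.read_csv(f)


def load_table1() -> pd.DataFrame:
    """Cohort characteristics by stage: characteristic, level, stage, n."""
    return _read("table1_characteristics.csv")


def load_table2() -> pd.DataFrame:
    """Cause-of-death counts by site group and stage (wide, one row per cell)."""
    return _read("table2_cause_by_type_stage.csv")


def table2_mortality_table() -> MortalityTable:
    """The published cause table as a major-cause MortalityTable."""
    wide = load_table2()
    long = wide.melt(
        id_vars=["site_group", "stage"],
        value_vars=["index_n", "non_index_n", "non_cancer_n"],
        var_name="cause", value_name="count",
    )
    long["cause"] = long["cause"].map({
        "index_n": vocab.MAJOR_INDEX,
        "non_index_n": vocab.MAJOR_NON_INDEX,
        "non_cancer_n": vocab.MAJOR_NON_CANCER,
    })
    return MortalityTable(data=long, level="major")


def site_stage_case_counts() -> pd.DataFrame:
    """Case counts per (site_group, stage) from the characteristics table."""
    t1 = load_table1()
    return t1[t1["characteristic"] == "site_group"][["level", "stage", "n"]].rename(
        columns={"level": "site_group"}
    )


def headline_numbers() -> dict:
    """Published summary quantities recomputed from the packaged tables.

    Returns a dict with the cohort size, stage-specific fractions still
    alive at the end of observed follow-up, the all-types major-cause
    percentages by stage, the stage distribution of index-cancer deaths,
    and per-type early-stage (I-II) index-death percentages.
    """
    t1 = load_table1()
    vital = t1[t1["characteristic"] == "vital_status"].pivot_table(
        index="level", columns="stage", values="n"
    )
    stage_totals = vital.sum(axis=0)
    alive = vital.loc["Alive"]
    survivor_pct = {
        "I-II": round_half_up(
            100 * (alive["I"] + alive["II"]) / (stage_totals["I"] + stage_totals["II"])
        ),
        "III": round_half_up(100 * alive["III"] / stage_totals["III"]),
        "IV": round_half_up(100 * alive["IV"] / stage_totals["IV"]),
    }

    table = table2_mortality_table()
    pct = table.with_percentages()
    all_types = pct[pct["site_group"] == AGGREGATE_ROW]
    all_types_pct = {
        (r.stage, r.cause): round_half_up(r.pct) for r in all_types.itertuples()
    }

    from .mortality_tables import summarize_stage_of_index_deaths

    stage_dist = summarize_stage_of_index_deaths(table)

    t2 = load_table2()
    early = t2[t2["stage"].isin(["I", "II"])].groupby("site_group").sum(numeric_only=True)
    early_pct = {
        g: round_half_up(
            100 * row["index_n"]
            / (row["index_n"] + row["non_index_n"] + row["non_cancer_n"])
        )
        for g, row in early.iterrows()
    }

    return {
        "cohort_size": int(stage_totals.sum()),
        "survivor_pct": survivor_pct,
        "all_types_pct": all_types_pct,
        "stage_dist_of_index_deaths_pct": stage_dist,
        "early_stage_index_pct": early_pct,
    }
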