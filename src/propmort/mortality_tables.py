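"""Aggregation of allocation weights into cause-of-death tables.

Tables hold real-valued allocated counts per (site group x stage x cause)
with within-cell percentages computed from the unrounded counts.
Half-up rounding to whole percent is applied only at presentation time;
all downstream computation (scenarios, summaries) uses unrounded values.
Subtype rows (breast hormone-receptor status, lung small / non-small
cell) are reported in addition to their parent rows and never enter the
"All Types" aggregate, which sums the mutually exclusive site partition.
"""
from __future__ import annotations

import dataclasses
import math

import pandas as pd

from . import vocab
from .cod_allocation import AllocationResult, split_cause_label

ALL_TYPES = "All Types"


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclasses.dataclass
class MortalityTable:
    """Tidy allocated-count table.

    ``data`` columns: optional stratifier level column, then
    ``site_group``, ``stage``, ``cause``, ``count``. ``level`` is
    ``"major"`` or ``"detail"``.
    """

    data: pd.DataFrame
    level: str = "major"
    stratifier: str | None = None

    def _group_cols(self) -> list[str]:
        cols = ["site_group", "stage"]
        if self.stratifier:
            cols = [self.stratifier] + cols
        return cols

    def with_percentages(self) -> pd.DataFrame:
        """Data plus within-(row, stage) percentages, unrounded and half-up."""
        df = self.data.copy()
        totals = df.groupby(self._group_cols())["count"].transform("sum")
        df["pct"] = 100.0 * df["count"] / totals.where(totals > 0)
        df["pct_rounded"] = df["pct"].map(
            lambda p: round_half_up(p) if pd.notna(p) else pd.NA
        )
        return df

    def cell(self, site_group: str, stage: str, cause: str, **strat) -> float:
        df = self.data
        mask = (df["site_group"] == site_group) & (df["stage"] == stage) \
            & (df["cause"] == cause)
        for k, v in strat.items():
            mask &= df[k] == v
        return float(df.loc[mask, "count"].sum())

    def wide(self, value: str = "count") -> pd.DataFrame:
        """Site-by-stage layout with one column block per cause."""
        df = self.with_percentages() if value != "count" else self.data
        return df.pivot_table(index=self._group_cols()[:-1] + ["site_group"],
                              columns=["stage", "cause"], values=value,
                              aggfunc="sum", sort=False)

    def to_tidy_csv(self, path) -> None:
        self.with_percentages().to_csv(path, index=False)


def _weights_by_case(alloc: AllocationResult, cases: pd.DataFrame) -> pd.DataFrame:
    if not alloc.weights.index.equals(pd.Index(cases["case_id"], name="case_id")):
        if set(alloc.weights.index) != set(cases["case_id"]):
            raise ValueError("allocations and cases do not cover the same case_ids")
    meta = cases.set_index("case_id").loc[alloc.weights.index]
    return alloc.weights, meta


def _aggregate(weights: pd.DataFrame, meta: pd.DataFrame,
               cause_of: dict[str, str], keys: list[str],
               restrict: list[str] | None = None) -> pd.DataFrame:
    cols = weights.columns if restrict is None else [c for c in weights.columns
                                                    if c in restrict]
    long = weights[list(cols)].copy()
    for k in keys:
        long[k] = meta[k].to_numpy()
    summed = long.groupby(keys).sum()
    summed.columns = [cause_of[c] for c in summed.columns]
    summed = summed.T.groupby(level=0).sum().T  # merge labels mapping to one cause
    tidy = summed.stack().rename("count").reset_index()
    tidy.columns = keys + ["cause", "count"]
    return tidy


def _add_parent_and_all_types(tidy: pd.DataFrame, extra_keys: list[str]) -> pd.DataFrame:
    """Expand per-label rows with parent-site rows and the All Types row."""
    tidy = tidy.copy()
    tidy["parent"] = tidy["site_group"].map(
        {s: vocab.parent_site(s) for s in vocab.SITE_GROUPS}
    )
    keys = extra_keys + ["stage", "cause"]
    parent_rows = (tidy.groupby(["parent"] + keys)["count"].sum().reset_index()
                   .rename(columns={"parent": "site_group"}))
    all_rows = tidy.groupby(keys)["count"].sum().reset_index()
    all_rows["site_group"] = ALL_TYPES
    subtype_rows = tidy[tidy["site_group"].isin(vocab.SUBTYPE_PARENT)]
    out = pd.concat(
        [all_rows, parent_rows, subtype_rows[["site_group"] + keys + ["count"]]],
        ignore_index=True,
    )
    return out[extra_keys + ["site_group", "stage", "cause", "count"]]


def tabulate_major(alloc: AllocationResult, cases: pd.DataFrame) -> MortalityTable:
    """Allocated counts per (site group x stage) at index / non-index /
    non-cancer resolution, with parent and All Types aggregate rows."""
    weights, meta = _weights_by_case(alloc, cases)
    cause_of = {c: split_cause_label(c)[0] for c in weights.columns}
    tidy = _aggregate(weights, meta, cause_of, ["site_group", "stage"])
    out = _add_parent_and_all_types(tidy, [])
    return MortalityTable(data=out, level="major")


def tabulate_detail(alloc: AllocationResult, cases: pd.DataFrame,
                    major: str) -> MortalityTable:
    """Within-stage distribution across detailed causes of one major
    category (non-index cancer sites, or grouped non-cancer causes).

    Causes are ordered by their stage-I frequency in the All Types rows.
    """
    if major not in (vocab.MAJOR_NON_INDEX, vocab.MAJOR_NON_CANCER):
        raise ValueError("detail tables exist for non_index_cancer or non_cancer")
    weights, meta = _weights_by_case(alloc, cases)
    restrict = [c for c in weights.columns if split_cause_label(c)[0] == major]
    cause_of = {c: split_cause_label(c)[1] for c in restrict}
    tidy = _aggregate(weights, meta, cause_of, ["site_group", "stage"], restrict)
    out = _add_parent_and_all_types(tidy, [])
    order = (out[(out["site_group"] == ALL_TYPES) & (out["stage"] == "I")]
             .sort_values("count", ascending=False)["cause"].tolist())
    out["cause"] = pd.Categorical(out["cause"], categories=order, ordered=True)
    out = out.sort_values(["site_group", "stage", "cause"]).reset_index(drop=True)
    out["cause"] = out["cause"].astype(str)
    return MortalityTable(data=out, level="detail")


def tabulate_stratified(alloc: AllocationResult, cases: pd.DataFrame,
                        stratifier: str,
                        exclude_sex_specific: bool = False) -> MortalityTable:
    """All-Types major-cause table per level of a demographic stratifier.

    ``exclude_sex_specific`` (for sex stratification) drops breast and the
    sex-specific genital sites from the aggregate before tabulating.
    """
    if stratifier not in ("age_group", "sex", "race_ethnicity"):
        raise ValueError(f"unknown stratifier {stratifier!r}")
    weights, meta = _weights_by_case(alloc, cases)
    if exclude_sex_specific:
        parents = meta["site_group"].map(
            {s: vocab.parent_site(s) for s in vocab.SITE_GROUPS})
        keep = ~parents.isin(vocab.SEX_SPECIFIC_SITES)
        weights, meta = weights[keep.to_numpy()], meta[keep.to_numpy()]
    cause_of = {c: split_cause_label(c)[0] for c in weights.columns}
    tidy = _aggregate(weights, meta, cause_of, [stratifier, "stage"])
    tidy["site_group"] = ALL_TYPES
    tidy = tidy[[stratifier, "site_group", "stage", "cause", "count"]]
    return MortalityTable(data=tidy, level="major", stratifier=stratifier)


def summarize_stage_of_index_deaths(table: MortalityTable) -> dict[str, int]:
    """Distribution of index-cancer deaths across known stages I-IV.

    Uses the All Types rows when present, otherwise sums the mutually
    exclusive site partition. Unknown-stage deaths are excluded, matching
    the known-stage convention.
    """
    df = table.data
    rows = df[df["site_group"] == ALL_TYPES]
    if rows.empty:
        rows = df[df["site_group"].isin(vocab.PARENT_SITE_GROUPS)]
    idx = rows[(rows["cause"] == vocab.MAJOR_INDEX)
               & (rows["stage"].isin(vocab.KNOWN_STAGES))]
    by_stage = idx.groupby("stage")["count"].sum()
    total = by_stage.sum()
    if total == 0:
        return {s: 0 for s in vocab.KNOWN_STAGES}
    return {s: round_half_up(100 * by_stage.get(s, 0.0) / total)
            for s in vocab.KNOWN_STAGES}
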