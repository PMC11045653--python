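"""Counterfactual stage-shift scenarios.

A scenario redistributes the stage-at-diagnosis of cases (e.g. all stage
IV detected at stage III, as an idealized universal-screening program
would do) and recomputes expected index-cancer deaths using the *target*
stage's observed index-death proportion. For site group g, source stage s
with N_gs allocated deaths (= cases, since everyone is followed to death)
of which D_gs are index deaths, and shift weights w(s->t):

    counterfactual_gs = N_gs * sum_t w(s->t) * p_index(g, t)
    averted_gs        = D_gs - counterfactual_gs

Scenarios are computed separately per cancer type and summed over the
mutually exclusive site partition — never on the pooled All-Types row,
whose stage mix differs by type (a Simpson-type aggregation effect).
Unknown-stage cases are never redistributed, but their index deaths stay
in the denominator of the reported percent reduction.
"""
from __future__ import annotations

import dataclasses

import pandas as pd

from . import vocab
from .mortality_tables import ALL_TYPES, MortalityTable


class ScenarioError(RuntimeError):
    """A target cell needed by the scenario has no cases."""


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """Named redistribution of source stages onto target-stage mixtures."""

    name: str
    shifts: dict[str, dict[str, float]]  # source stage -> {target stage: weight}
    scope: tuple[str, ...] | None = None  # site groups; None = all parent groups

    def __post_init__(self) -> None:
        for src, targets in self.shifts.items():
            if src == "Unknown" or any(t == "Unknown" for t in targets):
                raise ValueError("unknown-stage cases are never redistributed")
            if src not in vocab.KNOWN_STAGES:
                raise ValueError(f"unknown source stage {src!r}")
            total = sum(targets.values())
            if abs(total - 1.0) > 1e-9 or any(w < 0 for w in targets.values()):
                raise ValueError(
                    f"shift weights for stage {src} must be nonnegative and sum to 1")


@dataclasses.dataclass
class ScenarioResult:
    """Per-type and summed deaths averted under one scenario."""

    spec: ScenarioSpec
    per_type: pd.DataFrame  # site_group, baseline_index_deaths, shifted_index_deaths,
    #                         counterfactual_index_deaths, averted
    counterfactual_majors: pd.DataFrame  # expected major-cause mix of shifted cases

    @property
    def total_averted(self) -> float:
        return float(self.per_type["averted"].sum())

    @property
    def total_baseline_index_deaths(self) -> float:
        return float(self.per_type["baseline_index_deaths"].sum())

    @property
    def percent_reduction(self) -> float:
        return 100.0 * self.total_averted / self.total_baseline_index_deaths

    @property
    def percent_reduction_rounded(self) -> int:
        from .mortality_tables import round_half_up

        return round_half_up(self.percent_reduction)


def builtin_scenarios() -> list[ScenarioSpec]:
    """The three canonical screening scenarios."""
    return [
        ScenarioSpec("shift_IV_to_III", {"IV": {"III": 1.0}}),
        ScenarioSpec("shift_IV_to_I_II_III_equal",
                     {"IV": {"I": 1 / 3, "II": 1 / 3, "III": 1 / 3}}),
        ScenarioSpec("shift_all_to_I",
                     {"II": {"I": 1.0}, "III": {"I": 1.0}, "IV": {"I": 1.0}}),
    ]


def _cell_counts(df: pd.DataFrame, site: str, stage: str) -> tuple[float, dict[str, float]]:
    sub = df[(df["site_group"] == site) & (df["stage"] == stage)]
    by_cause = sub.groupby("cause")["count"].sum().to_dict()
    return float(sum(by_cause.values())), by_cause


def run_scenario(table: MortalityTable, spec: ScenarioSpec,
                 zero_cell: str = "error") -> ScenarioResult:
    """Evaluate a stage-shift scenario on a major-cause mortality table.

    ``zero_cell`` controls target cells with no cases: ``"error"`` raises
    a ScenarioError naming the cell; ``"pooled"`` substitutes the site
    group's known-stage pooled cause proportions.
    """
    if table.level != "major":
        raise ValueError("scenarios run on major-cause tables")
    if zero_cell not in ("error", "pooled"):
        raise ValueError("zero_cell must be 'error' or 'pooled'")
    df = table.data
    present = set(df["site_group"])
    if spec.scope is not None:
        scope = [g for g in spec.scope]
    else:
        scope = [g for g in vocab.PARENT_SITE_GROUPS if g in present]
    missing = [g for g in scope if g not in present]
    if missing:
        raise ScenarioError(f"site groups absent from table: {missing}")

    def proportions(g: str, t: str) -> dict[str, float]:
        total, by_cause = _cell_counts(df, g, t)
        if total == 0:
            if zero_cell == "error":
                raise ScenarioError(
                    f"target cell ({g}, stage {t}) has no cases and no fallback")
            sub = df[(df["site_group"] == g) & (df["stage"].isin(vocab.KNOWN_STAGES))]
            total = sub["count"].sum()
            if total == 0:
                raise ScenarioError(f"site group {g} has no known-stage cases")
            by_cause = sub.groupby("cause")["count"].sum().to_dict()
        return {c: n / total for c, n in by_cause.items()}

    rows = []
    cf_rows = []
    for g in scope:
        baseline = df[(df["site_group"] == g) & (df["cause"] == vocab.MAJOR_INDEX)][
            "count"].sum()
        shifted_d = 0.0
        counterfactual = 0.0
        cf_major = {m: 0.0 for m in vocab.MAJORS}
        for src, targets in spec.shifts.items():
            n_src, by_cause = _cell_counts(df, g, src)
            if n_src == 0:
                continue
            shifted_d += by_cause.get(vocab.MAJOR_INDEX, 0.0)
            for t, w in targets.items():
                p = proportions(g, t)
                counterfactual += n_src * w * p.get(vocab.MAJOR_INDEX, 0.0)
                for m in vocab.MAJORS:
                    cf_major[m] += n_src * w * p.get(m, 0.0)
        rows.append({
            "site_group": g,
            "baseline_index_deaths": float(baseline),
            "shifted_index_deaths": shifted_d,
            "counterfactual_index_deaths": counterfactual,
            "averted": shifted_d - counterfactual,
        })
        cf_rows.append({"site_group": g, **cf_major})
    return ScenarioResult(
        spec=spec,
        per_type=pd.DataFrame(rows),
        counterfactual_majors=pd.DataFrame(cf_rows),
    )


def run_builtin_scenarios(table: MortalityTable,
                          zero_cell: str = "error") -> dict[str, ScenarioResult]:
    return {s.name: run_scenario(table, s, zero_cell) for s in builtin_scenarios()}
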