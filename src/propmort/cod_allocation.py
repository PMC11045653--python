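"""Fractional allocation of causes of death to an entire cohort.

Every eligible case receives a nonnegative weight vector over cause
categories summing to one, so the whole cohort is followed "until death"
either by observation or by extrapolation:

* **observed** — the case died in follow-up: weight 1 on its classified
  cause;
* **imputed_lost** — the case was lost to follow-up: weights equal to the
  observed cause-of-death distribution of its stratum in the follow-up
  year in which it was lost;
* **extrapolated_alive** — the case was alive at the administrative end of
  follow-up: weights equal to the observed cause distribution in the tail
  window (last 48 months by default) of the stratum's follow-up.

The rationale for the flat tail extrapolation is the plateau in
index-cancer death risk roughly a decade after diagnosis: beyond it the
cause mixture among deaths is approximately stationary, so no explicit
modelling of future death dates is needed.

Strata are (site_group x stage). Cells with no observed deaths fall back
along a configurable chain (year +-1, stratum pooled over years, site
group pooled over stages, global); every fallback is logged.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import vocab

PROV_OBSERVED = "observed"
PROV_IMPUTED = "imputed_lost"
PROV_EXTRAPOLATED = "extrapolated_alive"

INDEX_LABEL = "index"
_SEP = "|"


class AllocationError(RuntimeError):
    """No cause distribution available for a stratum after all fallbacks."""


def cause_label(major: str, detail: str | None) -> str:
    """Flat string label for a cause at detail resolution."""
    if major == vocab.MAJOR_INDEX:
        return INDEX_LABEL
    return f"{major}{_SEP}{detail}"


def split_cause_label(label: str) -> tuple[str, str | None]:
    if label == INDEX_LABEL:
        return vocab.MAJOR_INDEX, None
    major, detail = label.split(_SEP, 1)
    return major, detail


def followup_year(months) -> int | np.ndarray:
    """Follow-up year k covering months 12(k-1) < m <= 12k; month 0 -> year 1."""
    arr = np.maximum(1, np.ceil(np.asarray(months, dtype=float) / 12.0)).astype(int)
    return arr if arr.ndim else int(arr)


@dataclasses.dataclass
class AllocationConfig:
    """Options for the allocation engine.

    ``lost_mode='loss_year'`` imputes lost cases from the cause
    distribution of the year of loss (the literal procedure);
    ``'forward'`` uses the pooled distribution of observed deaths in the
    loss year and all later years.
    """

    tail_window_months: int = 48
    mode: str = "fractional"  # or "sampled"
    seed: int = 0
    lost_mode: str = "loss_year"  # or "forward"

    def __post_init__(self) -> None:
        if self.tail_window_months <= 0:
            raise ValueError("tail_window_months must be positive")
        if self.mode not in ("fractional", "sampled"):
            raise ValueError("mode must be 'fractional' or 'sampled'")
        if self.lost_mode not in ("loss_year", "forward"):
            raise ValueError("lost_mode must be 'loss_year' or 'forward'")


@dataclasses.dataclass(frozen=True)
class YearlyCodDistribution:
    """Observed cause-of-death counts and proportions for one stratum-year."""

    stratum: tuple[str, str]
    year: int
    counts: dict[str, int]

    @property
    def proportions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {c: n / total for c, n in self.counts.items()}


@dataclasses.dataclass(frozen=True)
class TailDistribution:
    """Pooled cause distribution over the final window of follow-up."""

    stratum: tuple[str, str]
    window_months: int
    counts: dict[str, int]
    fallback: str | None = None  # None when the stratum's own tail was used

    @property
    def proportions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {c: n / total for c, n in self.counts.items()}


@dataclasses.dataclass
class AllocationResult:
    """Per-case allocation weights plus provenance."""

    weights: pd.DataFrame  # index case_id, columns cause labels, rows sum to 1
    provenance: pd.Series  # case_id -> observed | imputed_lost | extrapolated_alive
    fallback_log: pd.DataFrame  # stratum, year, provenance, level, n_cases

    def to_long(self) -> pd.DataFrame:
        long = self.weights.stack().rename("weight").reset_index()
        long.columns = ["case_id", "cause", "weight"]
        return long[long["weight"] > 0].reset_index(drop=True)

    def provenance_summary(self, cases: pd.DataFrame) -> pd.DataFrame:
        """Fraction of cause-of-death mass observed / imputed / extrapolated, by stage."""
        df = pd.DataFrame({
            "stage": cases.set_index("case_id").loc[self.weights.index, "stage"],
            "provenance": self.provenance,
        })
        out = (df.groupby(["stage", "provenance"]).size().unstack(fill_value=0)
                 .reindex(columns=[PROV_OBSERVED, PROV_IMPUTED, PROV_EXTRAPOLATED],
                          fill_value=0))
        return out.div(out.sum(axis=1), axis=0)


def _classified_deaths(classified: pd.DataFrame) -> pd.DataFrame:
    dead = classified[classified["vital_status"] == "dead"].copy()
    if dead.empty:
        dead["cause"] = pd.Series(dtype=object)
        dead["year"] = pd.Series(dtype=int)
        return dead
    dead["cause"] = [
        cause_label(m, d) for m, d in zip(dead["major"], dead["detail"])
    ]
    dead["year"] = followup_year(dead["followup_months"].to_numpy())
    return dead


def yearly_distributions(
    classified: pd.DataFrame, stratum: tuple[str, str]
) -> dict[int, YearlyCodDistribution]:
    """Observed cause distribution per follow-up year in one stratum.

    Years with no observed deaths are absent; the fallback chain handles
    them at allocation time.
    """
    site, stage = stratum
    if site not in vocab.SITE_GROUPS or stage not in vocab.STAGES:
        raise ValueError(f"unknown stratum {stratum}")
    dead = _classified_deaths(classified)
    sub = dead[(dead["site_group"] == site) & (dead["stage"] == stage)]
    out: dict[int, YearlyCodDistribution] = {}
    for year, grp in sub.groupby("year"):
        out[int(year)] = YearlyCodDistribution(
            stratum=stratum, year=int(year),
            counts=grp["cause"].value_counts().to_dict(),
        )
    return out


def tail_distribution(
    classified: pd.DataFrame, stratum: tuple[str, str], window_months: int = 48
) -> TailDistribution:
    """Pooled cause distribution over deaths in the final follow-up window.

    The window is anchored to the maximum attainable follow-up month in
    the dataset (observed over all cases, censored or not). An empty tail
    returns the stratum's all-years distribution, flagged in ``fallback``.
    """
    if window_months <= 0:
        raise ValueError("window_months must be positive")
    site, stage = stratum
    dead = _classified_deaths(classified)
    cutoff = int(classified["followup_months"].max()) - window_months
    sub = dead[(dead["site_group"] == site) & (dead["stage"] == stage)]
    tail = sub[sub["followup_months"] > cutoff]
    if len(tail):
        return TailDistribution(stratum, window_months,
                                tail["cause"].value_counts().to_dict())
    if len(sub):
        return TailDistribution(stratum, window_months,
                                sub["cause"].value_counts().to_dict(),
                                fallback="stratum_all_years")
    glob = dead[dead["followup_months"] > cutoff]
    if len(glob):
        return TailDistribution(stratum, window_months,
                                glob["cause"].value_counts().to_dict(),
                                fallback="global_tail")
    if len(dead):
        return TailDistribution(stratum, window_months,
                                dead["cause"].value_counts().to_dict(),
                                fallback="global_all_years")
    raise AllocationError(f"no observed deaths anywhere; cannot extrapolate {stratum}")


def _lookup_yearly(dead: pd.DataFrame, site: str, stage: str, year: int,
                   forward: bool) -> tuple[dict[str, int], str] | None:
    """Fallback chain for the imputation distribution of a lost case."""
    stratum = dead[(dead["site_group"] == site) & (dead["stage"] == stage)]
    if forward:
        hit = stratum[stratum["year"] >= year]
        if len(hit):
            return hit["cause"].value_counts().to_dict(), "stratum_forward_years"
    else:
        hit = stratum[stratum["year"] == year]
        if len(hit):
            return hit["cause"].value_counts().to_dict(), "stratum_year"
        hit = stratum[stratum["year"].between(year - 1, year + 1)]
        if len(hit):
            return hit["cause"].value_counts().to_dict(), "stratum_adjacent_years"
    if len(stratum):
        return stratum["cause"].value_counts().to_dict(), "stratum_all_years"
    site_pool = dead[dead["site_group"] == site]
    if len(site_pool):
        return site_pool["cause"].value_counts().to_dict(), "site_group_all_stages"
    if len(dead):
        return dead["cause"].value_counts().to_dict(), "global"
    return None


def allocate_case(case: pd.Series | dict,
                  yearly: dict[int, YearlyCodDistribution],
                  tail: TailDistribution,
                  classified: pd.DataFrame | None = None,
                  config: AllocationConfig | None = None) -> tuple[dict[str, float], str]:
    """Allocation weights for a single case.

    Returns ``(weights, provenance)``. ``classified`` is needed only when
    the case is lost and its loss year has no entry in ``yearly`` (the
    fallback chain then consults the wider cohort).
    """
    config = config or AllocationConfig()
    status = case["vital_status"]
    if status == "dead":
        label = cause_label(case["major"], case.get("detail") if isinstance(case, dict)
                            else case["detail"])
        return {label: 1.0}, PROV_OBSERVED
    if status == "alive":
        return dict(tail.proportions), PROV_EXTRAPOLATED
    if status != "lost":
        raise ValueError(f"unknown vital_status {status!r}")
    year = followup_year(case["followup_months"])
    if config.lost_mode == "loss_year" and year in yearly:
        return dict(yearly[year].proportions), PROV_IMPUTED
    if classified is None:
        raise AllocationError(
            f"no observed deaths in year {year} of stratum "
            f"{(case['site_group'], case['stage'])} and no cohort for fallback")
    dead = _classified_deaths(classified)
    hit = _lookup_yearly(dead, case["site_group"], case["stage"], year,
                         forward=config.lost_mode == "forward")
    if hit is None:
        raise AllocationError(
            f"no distribution available for lost case in stratum "
            f"{(case['site_group'], case['stage'])}, year {year}")
    counts, _level = hit
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()}, PROV_IMPUTED


def allocate_cohort(classified: pd.DataFrame,
                    config: AllocationConfig | None = None) -> AllocationResult:
    """Allocate a cause-of-death weight vector to every case in the cohort."""
    if classified.empty:
        raise ValueError("cannot allocate an empty cohort")
    config = config or AllocationConfig()
    dead = _classified_deaths(classified)
    labels = sorted(dead["cause"].unique())
    if not labels:
        raise AllocationError("no observed deaths in the cohort; nothing to extrapolate from")
    col = {c: j for j, c in enumerate(labels)}
    n = len(classified)
    W = np.zeros((n, len(labels)))
    prov = np.empty(n, dtype=object)
    pos = {cid: i for i, cid in enumerate(classified["case_id"])}
    log_rows: list[dict] = []

    # Observed deaths: degenerate weights on the classified cause.
    for cid, cause in zip(dead["case_id"], dead["cause"]):
        i = pos[cid]
        W[i, col[cause]] = 1.0
        prov[i] = PROV_OBSERVED

    # Lost cases, grouped by (stratum, loss year).
    lost = classified[classified["vital_status"] == "lost"]
    if len(lost):
        years = followup_year(lost["followup_months"].to_numpy())
        for (site, stage, year), grp in lost.groupby(
            [lost["site_group"], lost["stage"], years]
        ):
            hit = _lookup_yearly(dead, site, stage, int(year),
                                 forward=config.lost_mode == "forward")
            if hit is None:
                raise AllocationError(
                    f"no distribution available for lost cases in stratum "
                    f"{(site, stage)}, year {year}")
            counts, level = hit
            total = sum(counts.values())
            w = np.zeros(len(labels))
            for c, cnt in counts.items():
                w[col[c]] = cnt / total
            for cid in grp["case_id"]:
                W[pos[cid]] = w
                prov[pos[cid]] = PROV_IMPUTED
            log_rows.append({"site_group": site, "stage": stage, "year": int(year),
                             "provenance": PROV_IMPUTED, "level": level,
                             "n_cases": len(grp)})

    # Survivors at administrative end: tail distribution per stratum.
    alive = classified[classified["vital_status"] == "alive"]
    if len(alive):
        for (site, stage), grp in alive.groupby(["site_group", "stage"]):
            tail = tail_distribution(classified, (site, stage),
                                     config.tail_window_months)
            w = np.zeros(len(labels))
            for c, p in tail.proportions.items():
                w[col[c]] = p
            for cid in grp["case_id"]:
                W[pos[cid]] = w
                prov[pos[cid]] = PROV_EXTRAPOLATED
            log_rows.append({"site_group": site, "stage": stage, "year": -1,
                             "provenance": PROV_EXTRAPOLATED,
                             "level": tail.fallback or "stratum_tail",
                             "n_cases": len(grp)})

    if config.mode == "sampled":
        rng = np.random.default_rng(config.seed)
        censored = np.flatnonzero(prov != PROV_OBSERVED)
        for i in censored:
            j = rng.choice(len(labels), p=W[i] / W[i].sum())
            W[i] = 0.0
            W[i, j] = 1.0

    assert np.allclose(W.sum(axis=1), 1.0), "allocation weights must sum to 1 per case"
    weights = pd.DataFrame(W, index=pd.Index(classified["case_id"], name="case_id"),
                           columns=labels)
    return AllocationResult(
        weights=weights,
        provenance=pd.Series(prov, index=weights.index, name="provenance"),
        fallback_log=pd.DataFrame(
            log_rows, columns=["site_group", "stage", "year", "provenance",
                               "level", "n_cases"]),
    )
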