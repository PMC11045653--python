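"""Case-listing ingestion, eligibility, and cause-of-death classification.

A case listing has one row per first primary cancer case. Deaths carry a
detailed cause-of-death code; every death is classified three ways:

* **index** — the fatal cancer is at the same anatomic site as the index
  cancer (subtype labels match at the parent-site level, so a lung-cancer
  death after small-cell lung cancer is an index death);
* **non_index_cancer** — a subsequent primary cancer at a different site,
  with that site kept as the detail label;
* **non_cancer** — any non-neoplastic cause, recorded at the grouped
  cause resolution (heart disease, COPD, ...).

Same-site second primaries are impossible by construction: the registry
convention never attributes a death to a second primary at the index site.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab

REQUIRED_COLUMNS = [
    "case_id", "site_group", "stage", "age_group", "sex", "race_ethnicity",
    "dx_year", "followup_months", "vital_status", "cod_code",
]
VITAL_STATUSES = ["dead", "alive", "lost"]


class SchemaError(ValueError):
    """The file does not match the case-listing schema."""


class ValidationError(ValueError):
    """One or more rows violate a case-listing invariant."""


@dataclasses.dataclass(frozen=True)
class CaseRecord:
    """One registry case."""

    case_id: str
    site_group: str
    stage: str
    age_group: str
    sex: str
    race_ethnicity: str
    dx_year: int
    followup_months: int
    vital_status: str
    cod_code: str | None = None


@dataclasses.dataclass(frozen=True)
class ExclusionLog:
    """Accounting for cases dropped by the eligibility rules."""

    n_input: int
    n_excluded_unknown_cod: int

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded_unknown_cod / self.n_input if self.n_input else 0.0


@dataclasses.dataclass(frozen=True)
class SubtypeRule:
    """Refinement of breast and lung parent sites into reporting subtypes.

    Breast cancer is hormone-receptor (HR)-positive if either the estrogen
    or the progesterone receptor is positive, HR-negative if both are
    negative, and HR-unknown otherwise. Lung cancer is small-cell if its
    morphology code falls in ``small_cell_morphologies`` and non-small-cell
    otherwise. The default small-cell set (804x small cell carcinoma codes)
    is a documented placeholder for a registry-specific code list.
    """

    small_cell_morphologies: frozenset[int] = frozenset(
        {8041, 8042, 8043, 8044, 8045}
    )

    def breast_subtype(self, er_status: str, pr_status: str) -> str:
        er, pr = er_status.lower(), pr_status.lower()
        if "positive" in (er, pr):
            return "Breast, HR-Positive"
        if er == "negative" and pr == "negative":
            return "Breast, HR-Negative"
        return "Breast, HR-Unknown"

    def lung_subtype(self, morphology_code: int) -> str:
        if int(morphology_code) in self.small_cell_morphologies:
            return "Lung, Small-Cell"
        return "Lung, Non-Small-Cell"


def read_case_listing(path: str | Path) -> pd.DataFrame:
    """Read and validate a case-listing CSV.

    Returns a DataFrame with one validated row per case. Malformed rows are
    reported with their (1-based, header-exclusive) row numbers.
    """
    df = pd.read_csv(path, dtype={"case_id": str, "cod_code": str}, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[REQUIRED_COLUMNS + [c for c in df.columns if c not in REQUIRED_COLUMNS]]
    df["cod_code"] = df["cod_code"].replace("", None)
    df["dx_year"] = pd.to_numeric(df["dx_year"], errors="coerce")
    df["followup_months"] = pd.to_numeric(df["followup_months"], errors="coerce")
    _validate(df)
    return df.reset_index(drop=True)


def validate_cases(df: pd.DataFrame) -> None:
    """Validate an in-memory case listing against the schema invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    _validate(df)


def _validate(df: pd.DataFrame) -> None:
    problems: list[str] = []

    def flag(mask: pd.Series, message: str) -> None:
        if mask.any():
            rows = (np.flatnonzero(mask.to_numpy()) + 1)[:5]
            problems.append(f"{message} (rows {', '.join(map(str, rows))}"
                            + ("..." if mask.sum() > 5 else "") + ")")

    flag(~df["stage"].isin(vocab.STAGES),
         f"unknown stage label; legal values: {', '.join(vocab.STAGES)}")
    flag(~df["site_group"].isin(vocab.SITE_GROUPS), "unknown site_group label")
    flag(~df["age_group"].isin(vocab.AGE_GROUPS),
         f"age_group outside 50-84 bands ({', '.join(vocab.AGE_GROUPS)})")
    flag(~df["sex"].isin(vocab.SEXES), "unknown sex label")
    flag(~df["race_ethnicity"].isin(vocab.RACE_ETHNICITIES), "unknown race_ethnicity")
    flag(~df["vital_status"].isin(VITAL_STATUSES), "unknown vital_status")
    flag(df["followup_months"].isna() | (df["followup_months"] < 0),
         "followup_months must be a non-negative integer")
    dead = df["vital_status"] == "dead"
    flag(dead & df["cod_code"].isna(), "dead case without cod_code")
    flag(~dead & df["cod_code"].notna(), "cod_code present for non-death")
    known = set(vocab.CANCER_CAUSE_TO_SITE) | set(vocab.NONCANCER_GROUPING) | {vocab.UNKNOWN_COD}
    flag(df["cod_code"].notna() & ~df["cod_code"].isin(known),
         "cod_code outside cause vocabulary")
    flag(df["case_id"].duplicated(), "duplicate case_id")
    if problems:
        raise ValidationError("; ".join(problems))


def to_records(df: pd.DataFrame) -> list[CaseRecord]:
    """Materialize a validated case listing as CaseRecord objects."""
    return [
        CaseRecord(
            case_id=r.case_id, site_group=r.site_group, stage=r.stage,
            age_group=r.age_group, sex=r.sex, race_ethnicity=r.race_ethnicity,
            dx_year=int(r.dx_year), followup_months=int(r.followup_months),
            vital_status=r.vital_status,
            cod_code=None if pd.isna(r.cod_code) else r.cod_code,
        )
        for r in df.itertuples(index=False)
    ]


def apply_eligibility(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop deaths with a missing/unknown cause of death, with accounting."""
    unknown = (df["vital_status"] == "dead") & (df["cod_code"] == vocab.UNKNOWN_COD)
    log = ExclusionLog(n_input=len(df), n_excluded_unknown_cod=int(unknown.sum()))
    eligible = df.loc[~unknown].reset_index(drop=True)
    if eligible.empty and len(df):
        import warnings

        warnings.warn("all cases excluded by eligibility rules", stacklevel=2)
    return eligible, log


def classify_cause(cod_code: str | None, site_group: str) -> tuple[str, str | None]:
    """Classify a death's cause relative to its index site.

    Returns ``(major, detail)`` where major is one of
    ``index | non_index_cancer | non_cancer``; detail is the non-index
    cancer site or the grouped non-cancer cause (None for index deaths).
    """
    if cod_code is None:
        raise ValueError("classify_cause requires a death with a known cod_code")
    kind = vocab.cause_kind(cod_code)
    if kind == "unknown":
        raise ValueError("cannot classify an unknown cause of death; "
                         "apply eligibility rules first")
    if kind == "cancer":
        cause_site = vocab.CANCER_CAUSE_TO_SITE[cod_code]
        if cause_site == vocab.parent_site(site_group):
            return vocab.MAJOR_INDEX, None
        return vocab.MAJOR_NON_INDEX, cod_code
    return vocab.MAJOR_NON_CANCER, vocab.group_noncancer(cod_code)


def classify_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``major`` and ``detail`` cause columns for every death.

    Non-deaths get NA in both columns. The mapping is vectorized over the
    closed cause vocabulary.
    """
    out = df.copy()
    out["major"] = pd.NA
    out["detail"] = pd.NA
    dead = out["vital_status"] == "dead"
    if (dead & out["cod_code"].isna()).any():
        raise ValidationError("dead case without cod_code")
    if (dead & (out["cod_code"] == vocab.UNKNOWN_COD)).any():
        raise ValidationError("unknown-cause deaths present; apply_eligibility first")
    codes = out.loc[dead, "cod_code"]
    parents = out.loc[dead, "site_group"].map(
        {s: vocab.parent_site(s) for s in vocab.SITE_GROUPS}
    )
    cause_site = codes.map(vocab.CANCER_CAUSE_TO_SITE)
    is_cancer = cause_site.notna()
    is_index = is_cancer & (cause_site == parents)
    major = pd.Series(vocab.MAJOR_NON_CANCER, index=codes.index)
    major[is_cancer] = vocab.MAJOR_NON_INDEX
    major[is_index] = vocab.MAJOR_INDEX
    detail = pd.Series(pd.NA, index=codes.index, dtype=object)
    detail[is_cancer & ~is_index] = codes[is_cancer & ~is_index]
    noncancer = ~is_cancer
    detail[noncancer] = codes[noncancer].map(vocab.NONCANCER_GROUPING)
    if detail[noncancer].isna().any():
        bad = codes[noncancer][detail[noncancer].isna()].unique()
        raise ValidationError(f"cod_code outside cause vocabulary: {bad[:5]}")
    out.loc[dead, "major"] = major
    out.loc[dead, "detail"] = detail
    return out


def assign_subtype(case: CaseRecord, rule: SubtypeRule, *,
                   er_status: str | None = None, pr_status: str | None = None,
                   morphology_code: int | None = None) -> str:
    """Refined site_group for a breast or lung case from raw tumor fields."""
    parent = vocab.parent_site(case.site_group)
    if parent == "Breast, All":
        if er_status is None or pr_status is None:
            raise ValueError("breast subtype assignment needs ER and PR status")
        return rule.breast_subtype(er_status, pr_status)
    if parent == "Lung, All":
        if morphology_code is None:
            raise ValueError("lung subtype assignment needs a morphology code")
        return rule.lung_subtype(morphology_code)
    raise ValueError(f"subtype rules apply only to breast and lung cases, not {parent!r}")
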