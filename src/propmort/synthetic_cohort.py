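"""Seeded generator of registry-like case listings with known ground truth.

The generator emulates the structure of a cancer-registry case listing: a
mixture of cases over (site group x stage) cells, demographic labels, and a
discrete-time competing-cause death process. Each cause of death has a
constant yearly probability; the index-cancer hazard may drop to a reduced
constant after a "plateau" year (statistical cure, observed in registry
data roughly 10 years after diagnosis), and non-cancer hazards rise
multiplicatively across 5-year age bands. Censoring is administrative
(diagnosis-year dependent follow-up horizon) plus an independent yearly
loss-to-follow-up draw; within a year, death is drawn before loss.

Every case's *latent* death cause and month are simulated regardless of
censoring and written to a truth side channel that the analysis pipeline
never reads; validation compares allocated causes against it.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab

INDEX_CAUSE = "index"  # sentinel resolved per cell to the index site's cause code

_YEAR_CAP = 150  # simulation horizon; hazards guarantee death long before


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclasses.dataclass(frozen=True)
class HazardSpec:
    """Constant yearly death probability for one cause category.

    ``cause`` is either the ``"index"`` sentinel or a cause-of-death code
    from the vocabulary. ``plateau_year`` (index cause only) is the last
    follow-up year at the full probability; from the next year on the
    probability is ``plateau_prob``. ``age_slope`` multiplies the
    probability once per 5-year age band above 50-54.
    """

    cause: str
    yearly_prob: float
    plateau_year: int | None = None
    plateau_prob: float | None = None
    age_slope: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.yearly_prob <= 1.0:
            raise ParameterError(f"yearly_prob must be in [0,1], got {self.yearly_prob}")
        if self.plateau_year is not None:
            if self.plateau_year < 1:
                raise ParameterError("plateau_year must be >= 1")
            if self.plateau_prob is None or not 0.0 <= self.plateau_prob <= 1.0:
                raise ParameterError("plateau_prob in [0,1] required with plateau_year")
        if self.age_slope <= 0:
            raise ParameterError("age_slope must be positive")

    def prob(self, year: int, age_band: int) -> float:
        p = self.yearly_prob
        if self.plateau_year is not None and year > self.plateau_year:
            p = self.plateau_prob
        return min(1.0, p * self.age_slope**age_band)


@dataclasses.dataclass
class CohortParams:
    """Study conditions for one simulated cohort."""

    n_cases: int
    mixture: dict[tuple[str, str], float]  # (site_group, stage) -> weight
    hazards: dict[tuple[str, str], list[HazardSpec]]
    age_dist: dict[str, float]
    sex_dist: dict[str, float]
    race_dist: dict[str, float]
    max_followup_months: int = 179
    loss_prob: float = 0.0
    unknown_cause_prob: float = 0.0
    dx_years: tuple[int, int] = (2006, 2010)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ParameterError("n_cases must be positive")
        w = np.array(list(self.mixture.values()), dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ParameterError("mixture weights must be nonnegative and sum to 1")
        if self.max_followup_months <= 0:
            raise ParameterError("max_followup_months must be positive")
        if not 0.0 <= self.loss_prob < 1.0:
            raise ParameterError("loss_prob must be in [0,1)")
        if not 0.0 <= self.unknown_cause_prob < 1.0:
            raise ParameterError("unknown_cause_prob must be in [0,1)")
        for dist_name in ("age_dist", "sex_dist", "race_dist"):
            d = np.array(list(getattr(self, dist_name).values()), dtype=float)
            if (d < 0).any() or not np.isclose(d.sum(), 1.0):
                raise ParameterError(f"{dist_name} must be a probability distribution")
        for cell in self.mixture:
            if cell not in self.hazards:
                raise ParameterError(f"no hazards for cell {cell}")
            site, stage = cell
            parent = vocab.parent_site(site)
            if stage not in vocab.STAGES:
                raise ParameterError(f"unknown stage in cell {cell}")
            total = 0.0
            for spec in self.hazards[cell]:
                if spec.cause != INDEX_CAUSE:
                    kind = vocab.cause_kind(spec.cause)
                    if kind == "cancer" and vocab.CANCER_CAUSE_TO_SITE[spec.cause] == parent:
                        raise ParameterError(
                            f"cell {cell}: non-index cancer cause {spec.cause!r} "
                            "matches the index site (same-site second primaries "
                            "are never emitted)")
                total += spec.yearly_prob
            if total <= 0:
                raise ParameterError(f"cell {cell}: total yearly death probability is 0")
            for band in (0, len(vocab.AGE_GROUPS) - 1):
                for year in (1, _YEAR_CAP):
                    s = sum(spec.prob(year, band) for spec in self.hazards[cell])
                    if s > 1.0 + 1e-12:
                        raise ParameterError(
                            f"cell {cell}: yearly cause probabilities sum to {s:.3f} "
                            f"> 1 at age band {band}, year {year}")


# Default hazards: stage drives the index-cancer yearly death probability,
# modulated by a site lethality factor (thyroid/melanoma/prostate at the
# benign end, pancreas/liver/esophagus at the lethal end); the index hazard
# plateaus at a reduced level after year 10 (statistical cure). Non-cancer
# hazards rise across 5-year age bands. Values are round numbers chosen to
# be of realistic magnitude, not calibrated to any registry.
_STAGE_INDEX_PROB = {"I": 0.02, "II": 0.035, "III": 0.10, "IV": 0.40, "Unknown": 0.08}
_SITE_LETHALITY = {
    "Thyroid": 0.15, "Melanoma": 0.3, "Prostate": 0.35, "Uterus": 0.35,
    "Breast, All": 0.5, "Breast, HR-Positive": 0.45, "Breast, HR-Negative": 0.7,
    "Breast, HR-Unknown": 0.5, "Kidney": 0.7, "Bladder": 0.8, "Cervix": 0.9,
    "Larynx": 0.9, "Lymphoma": 0.9, "Oral Cavity/Pharynx": 0.9, "Ovary": 1.2,
    "Colon/Rectum": 1.0, "Leukemia": 1.2, "Myeloma": 1.1, "Other Types": 1.0,
    "Brain/Other Nervous System": 2.0, "Stomach": 1.7, "Lung, All": 1.8,
    "Lung, Non-Small-Cell": 1.7, "Lung, Small-Cell": 2.2,
    "Esophagus": 2.0, "Liver/Intrahepatic Bile Duct": 2.2, "Pancreas": 2.5,
}
_NON_INDEX_PROBS = {
    "Lung": 0.0016, "Pancreas": 0.0005, "Colon/Rectum": 0.0005,
    "Leukemia": 0.0003, "Liver/Intrahepatic Bile Duct": 0.0003,
    "Breast": 0.0002, "Prostate": 0.0002,
}
_NON_CANCER_PROBS = {  # raw detailed cause -> (yearly prob at ages 50-54, age slope)
    "Diseases of Heart": (0.008, 1.35),
    "Chronic Obstructive Pulmonary Disease and Allied Conditions": (0.003, 1.25),
    "Cerebrovascular Diseases": (0.002, 1.4),
    "Alzheimer Disease": (0.0008, 1.8),
    "Diabetes Mellitus": (0.0012, 1.2),
    "Pneumonia and Influenza": (0.001, 1.4),
    "Septicemia": (0.0005, 1.3),
    "Chronic Liver Disease and Cirrhosis": (0.0008, 1.0),
    "Nephritis, Nephrotic Syndrome and Nephrosis": (0.0005, 1.3),
    "Accidents and Adverse Effects": (0.0008, 1.0),
    "Suicide and Self-Inflicted Injury": (0.0002, 1.0),
    "Hypertension without Heart Disease": (0.0003, 1.4),
    "Atherosclerosis": (0.0001, 1.5),
    "Aortic Aneurysm and Dissection": (0.0003, 1.3),
    "Other Infectious and Parasitic Diseases": (0.0003, 1.2),
    "Tuberculosis": (0.00005, 1.0),
    "Other Cause of Death": (0.003, 1.3),
}


def default_hazards(site: str, stage: str) -> list[HazardSpec]:
    """Default competing-cause hazards for one (site group, stage) cell."""
    parent = vocab.parent_site(site)
    p_index = min(0.8, _STAGE_INDEX_PROB[stage] * _SITE_LETHALITY.get(site, 1.0))
    specs = [HazardSpec(INDEX_CAUSE, p_index, plateau_year=10,
                        plateau_prob=min(p_index, 0.15 * p_index))]
    for cause, p in _NON_INDEX_PROBS.items():
        if vocab.CANCER_CAUSE_TO_SITE[cause] != parent:
            specs.append(HazardSpec(cause, p))
    for cause, (p, slope) in _NON_CANCER_PROBS.items():
        specs.append(HazardSpec(cause, p, age_slope=slope))
    return specs


def default_params(n_cases: int = 11_545, seed: int = 0,
                   loss_prob: float = 0.005,
                   unknown_cause_prob: float = 0.008) -> CohortParams:
    """Study conditions mimicking the published cohort at 1/100 scale.

    The (site group x stage) mixture and the demographic margins are taken
    from the packaged cohort-characteristics table; breast and lung cases
    are drawn at subtype resolution (breast cases not covered by the
    printed HR-positive/negative rows are labelled HR-unknown, lung cases
    outside the small/non-small-cell rows stay at the parent label).
    """
    from . import fixtures

    t1 = fixtures.load_table1()

    def margin(characteristic: str) -> dict[str, float]:
        sub = t1[t1["characteristic"] == characteristic]
        tot = sub.groupby("level")["n"].sum()
        return (tot / tot.sum()).to_dict()

    counts = fixtures.site_stage_case_counts().pivot_table(
        index="site_group", columns="stage", values="n"
    )
    mixture: dict[tuple[str, str], float] = {}
    for stage in vocab.STAGES:
        col = counts[stage]
        for site in counts.index:
            n = int(col.get(site, 0))
            if n == 0:
                continue
            if site == "Breast, All":
                hr_unknown = n - int(col["Breast, HR-Positive"]) - int(
                    col["Breast, HR-Negative"])
                if hr_unknown > 0:
                    mixture[("Breast, HR-Unknown", stage)] = hr_unknown
                continue
            if site == "Lung, All":
                n = n - int(col["Lung, Non-Small-Cell"]) - int(col["Lung, Small-Cell"])
                if n <= 0:
                    continue
            mixture[(site, stage)] = n
    total = sum(mixture.values())
    mixture = {cell: n / total for cell, n in mixture.items()}
    hazards = {cell: default_hazards(*cell) for cell in mixture}
    return CohortParams(
        n_cases=n_cases,
        mixture=mixture,
        hazards=hazards,
        age_dist=margin("age_group"),
        sex_dist=margin("sex"),
        race_dist=margin("race_ethnicity"),
        max_followup_months=179,
        loss_prob=loss_prob,
        unknown_cause_prob=unknown_cause_prob,
        seed=seed,
    )


def simulate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a case listing and its latent-truth side channel.

    Returns ``(cases, truth)``. ``cases`` follows the case-listing schema;
    ``truth`` has ``case_id``, ``true_cod_code`` and ``true_death_month``
    for every case, censored or not. Identical params (including seed)
    give identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_cases

    cells = sorted(params.mixture)
    cell_w = np.array([params.mixture[c] for c in cells], dtype=float)
    cell_idx = rng.choice(len(cells), size=n, p=cell_w / cell_w.sum())

    ages = list(params.age_dist)
    age_idx = rng.choice(len(ages), size=n, p=np.array(list(params.age_dist.values())))
    sexes = list(params.sex_dist)
    sex_idx = rng.choice(len(sexes), size=n, p=np.array(list(params.sex_dist.values())))
    races = list(params.race_dist)
    race_idx = rng.choice(len(races), size=n, p=np.array(list(params.race_dist.values())))
    y0, y1 = params.dx_years
    dx_year = rng.integers(y0, y1 + 1, size=n)
    dx_month = rng.integers(1, 13, size=n)

    # Per-case cause-probability matrices, pre- and post-plateau.
    causes = sorted({s.cause for specs in params.hazards.values() for s in specs})
    c_of = {c: j for j, c in enumerate(causes)}
    pre = np.zeros((n, len(causes)))
    post = np.zeros((n, len(causes)))
    plateau = np.full(n, _YEAR_CAP + 1)
    for k, cell in enumerate(cells):
        members = np.flatnonzero(cell_idx == k)
        if members.size == 0:
            continue
        mult = np.ones((members.size, len(causes)))
        base = np.zeros(len(causes))
        base_post = np.zeros(len(causes))
        for spec in params.hazards[cell]:
            j = c_of[spec.cause]
            base[j] = spec.yearly_prob
            base_post[j] = spec.yearly_prob
            if spec.age_slope != 1.0:
                mult[:, j] = spec.age_slope ** age_idx[members]
            if spec.plateau_year is not None:
                base_post[j] = spec.plateau_prob
                plateau[members] = spec.plateau_year
        pre[members] = np.minimum(1.0, base * mult)
        post[members] = np.minimum(1.0, base_post * mult)

    # Latent death process: year-by-year competing draws, no censoring.
    death_year = np.zeros(n, dtype=int)
    death_cause = np.zeros(n, dtype=int)
    alive = np.arange(n)
    for year in range(1, _YEAR_CAP + 1):
        if alive.size == 0:
            break
        P = np.where((year > plateau[alive])[:, None], post[alive], pre[alive])
        ptot = P.sum(axis=1)
        u = rng.random(alive.size)
        dies = u < ptot
        idx = alive[dies]
        if idx.size:
            cum = np.cumsum(P[dies], axis=1)
            v = rng.random(idx.size) * ptot[dies]
            death_cause[idx] = (cum < v[:, None]).sum(axis=1)
            death_year[idx] = year
        alive = alive[~dies]
    if alive.size:  # residual mass at the horizon: assign proportionally
        P = np.where((_YEAR_CAP > plateau[alive])[:, None], post[alive], pre[alive])
        cum = np.cumsum(P, axis=1)
        v = rng.random(alive.size) * P.sum(axis=1)
        death_cause[alive] = (cum < v[:, None]).sum(axis=1)
        death_year[alive] = _YEAR_CAP
    death_month = 12 * (death_year - 1) + rng.integers(1, 13, size=n)

    # Censoring: administrative horizon anchored to the earliest diagnosis
    # date, then independent yearly loss to follow-up (death drawn first
    # within a year).
    admin = params.max_followup_months - 12 * (dx_year - y0) - (dx_month - 1)
    if params.loss_prob > 0:
        loss_year = rng.geometric(params.loss_prob, size=n)
    else:
        loss_year = np.full(n, _YEAR_CAP + 10)
    loss_month = 12 * (loss_year - 1) + rng.integers(1, 13, size=n)

    dead = (death_year <= loss_year) & (death_month <= admin)
    lost = ~dead & (loss_year < death_year) & (loss_month <= admin)
    status = np.where(dead, "dead", np.where(lost, "lost", "alive"))
    followup = np.where(dead, death_month, np.where(lost, loss_month, admin))

    site = np.array([cells[k][0] for k in cell_idx])
    stage = np.array([cells[k][1] for k in cell_idx])
    # Sex is drawn from the margin, then forced for sex-specific sites.
    sex_arr = np.array(sexes, dtype=object)[sex_idx]
    parent_arr = np.array([vocab.parent_site(s) for s in site], dtype=object)
    sex_arr[np.isin(parent_arr, ["Breast, All", "Cervix", "Ovary", "Uterus"])] = "Female"
    sex_arr[parent_arr == "Prostate"] = "Male"
    index_code = np.array(
        [vocab.SITE_TO_CANCER_CAUSE[vocab.parent_site(cells[k][0])] for k in cell_idx]
    )
    cause_code = np.array(causes, dtype=object)[death_cause]
    cause_code = np.where(cause_code == INDEX_CAUSE, index_code, cause_code)

    cod = np.where(dead, cause_code, None)
    if params.unknown_cause_prob > 0:
        masked = dead & (rng.random(n) < params.unknown_cause_prob)
        cod = np.where(masked, vocab.UNKNOWN_COD, cod)

    width = len(str(n))
    case_id = np.array([f"case-{i:0{width}d}" for i in range(n)])
    cases = pd.DataFrame({
        "case_id": case_id,
        "site_group": site,
        "stage": stage,
        "age_group": np.array(ages, dtype=object)[age_idx],
        "sex": sex_arr,
        "race_ethnicity": np.array(races, dtype=object)[race_idx],
        "dx_year": dx_year,
        "followup_months": followup.astype(int),
        "vital_status": status,
        "cod_code": cod,
    })
    truth = pd.DataFrame({
        "case_id": case_id,
        "true_cod_code": cause_code,
        "true_death_month": death_month.astype(int),
    })
    return cases, truth


def write_case_listing(cases: pd.DataFrame, path: str | Path) -> None:
    """Write a case listing CSV in the schema read_case_listing consumes."""
    if cases is None or len(cases) == 0:
        raise ValueError("refusing to write an empty case listing")
    cases.to_csv(path, index=False)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Write the latent-truth side channel (never read by the pipeline)."""
    if truth is None or len(truth) == 0:
        raise ValueError("refusing to write an empty truth table")
    truth.to_csv(path, index=False)


def eventual_cause_distribution(
    specs: list[HazardSpec], age_band: int = 0, horizon: int = 5000
) -> dict[str, float]:
    """Closed-form eventual cause-of-death distribution for one cell.

    Brute-force per-year probability recursion: P(cause c) =
    sum_y S(y-1) p_c(y) with S the year-by-year survival product. Used as
    the independent check that the simulator's empirical cause mixture
    matches the hazards it was given.
    """
    probs = {s.cause: 0.0 for s in specs}
    surv = 1.0
    for year in range(1, horizon + 1):
        p = {s.cause: s.prob(year, age_band) for s in specs}
        ptot = sum(p.values())
        for c, pc in p.items():
            probs[c] += surv * pc
        surv *= 1.0 - ptot
        if surv < 1e-14:
            break
    if surv > 1e-9:  # distribute residual mass by the plateau-era mixture
        p = {s.cause: s.prob(horizon, age_band) for s in specs}
        ptot = sum(p.values())
        if ptot > 0:
            for c, pc in p.items():
                probs[c] += surv * pc / ptot
    return probs
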