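"""Closed vocabularies: stages, site groups, cause-of-death codes and groupings.

The cause-of-death vocabulary mirrors the SEER cause-of-death recode at the
resolution used throughout the analysis: cancer causes are anatomic site
groups, and the 26 standard non-cancer causes are collapsed into a smaller
set of grouped labels (infectious causes other than septicemia pooled,
four circulatory conditions other than heart and cerebrovascular disease
pooled, accidents pooled with homicide, and a seven-cause residual "Other").
Registry-specific raw codes can be mapped onto this vocabulary via the
packaged ``cause_vocabulary.csv`` without touching analysis code.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

STAGES = ["I", "II", "III", "IV", "Unknown"]
KNOWN_STAGES = ["I", "II", "III", "IV"]

AGE_GROUPS = ["50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84"]
SEXES = ["Male", "Female"]
RACE_ETHNICITIES = [
    "White, Non-Hispanic",
    "Black, Non-Hispanic",
    "Hispanic",
    "Asian American/Pacific Islander, Non-Hispanic",
    "American Indian/Alaska Native, Non-Hispanic",
    "Other/Unknown, Non-Hispanic",
]

# Mutually exclusive index site groups (a case belongs to exactly one).
PARENT_SITE_GROUPS = [
    "Bladder",
    "Breast, All",
    "Brain/Other Nervous System",
    "Cervix",
    "Colon/Rectum",
    "Esophagus",
    "Kidney",
    "Larynx",
    "Leukemia",
    "Liver/Intrahepatic Bile Duct",
    "Lung, All",
    "Lymphoma",
    "Melanoma",
    "Myeloma",
    "Oral Cavity/Pharynx",
    "Ovary",
    "Pancreas",
    "Prostate",
    "Stomach",
    "Thyroid",
    "Uterus",
    "Other Types",
]

# Refined subtype labels reported alongside (never instead of) parent rows.
SUBTYPE_PARENT = {
    "Breast, HR-Positive": "Breast, All",
    "Breast, HR-Negative": "Breast, All",
    "Breast, HR-Unknown": "Breast, All",
    "Lung, Non-Small-Cell": "Lung, All",
    "Lung, Small-Cell": "Lung, All",
}
SITE_GROUPS = PARENT_SITE_GROUPS + list(SUBTYPE_PARENT)

# Sites dropped from sex-stratified aggregates (breast plus sex-specific sites).
SEX_SPECIFIC_SITES = ["Breast, All", "Cervix", "Ovary", "Uterus", "Prostate"]

# Cancer cause-of-death codes (anatomic site of the fatal cancer) and the
# index site group each one matches at the parent level.
CANCER_CAUSE_TO_SITE = {
    "Bladder": "Bladder",
    "Breast": "Breast, All",
    "Brain/Other Nervous System": "Brain/Other Nervous System",
    "Cervix": "Cervix",
    "Colon/Rectum": "Colon/Rectum",
    "Esophagus": "Esophagus",
    "Kidney": "Kidney",
    "Larynx": "Larynx",
    "Leukemia": "Leukemia",
    "Liver/Intrahepatic Bile Duct": "Liver/Intrahepatic Bile Duct",
    "Lung": "Lung, All",
    "Lymphoma": "Lymphoma",
    "Melanoma": "Melanoma",
    "Myeloma": "Myeloma",
    "Oral Cavity/Pharynx": "Oral Cavity/Pharynx",
    "Ovary": "Ovary",
    "Pancreas": "Pancreas",
    "Prostate": "Prostate",
    "Stomach": "Stomach",
    "Thyroid": "Thyroid",
    "Uterus": "Uterus",
    "Other Cancer": "Other Types",
}
SITE_TO_CANCER_CAUSE = {v: k for k, v in CANCER_CAUSE_TO_SITE.items()}

# The 26 standard non-cancer causes of death -> grouped label.
NONCANCER_GROUPING = {
    "Tuberculosis": "Other Infectious Diseases",
    "Syphilis": "Other Infectious Diseases",
    "Other Infectious and Parasitic Diseases": "Other Infectious Diseases",
    "Septicemia": "Septicemia",
    "Diabetes Mellitus": "Diabetes",
    "Alzheimer Disease": "Alzheimer Disease",
    "Diseases of Heart": "Heart Disease",
    "Hypertension without Heart Disease": "Other Circulatory Diseases",
    "Cerebrovascular Diseases": "Cerebrovascular Disease",
    "Atherosclerosis": "Other Circulatory Diseases",
    "Aortic Aneurysm and Dissection": "Other Circulatory Diseases",
    "Other Diseases of Arteries, Arterioles, Capillaries": "Other Circulatory Diseases",
    "Pneumonia and Influenza": "Pneumonia/Influenza",
    "Chronic Obstructive Pulmonary Disease and Allied Conditions": "COPD",
    "Stomach and Duodenal Ulcers": "Other",
    "Chronic Liver Disease and Cirrhosis": "Chronic Liver Disease/Cirrhosis",
    "Nephritis, Nephrotic Syndrome and Nephrosis": "Nephritis/Nephrosis",
    "Complications of Pregnancy, Childbirth, Puerperium": "Other",
    "Congenital Anomalies": "Other",
    "Certain Conditions Originating in Perinatal Period": "Other",
    "Symptoms, Signs and Ill-Defined Conditions": "Other",
    "Accidents and Adverse Effects": "Accidents/External Causes",
    "Suicide and Self-Inflicted Injury": "Suicide/Self-Injury",
    "Homicide and Legal Intervention": "Accidents/External Causes",
    "Other Cause of Death": "Other",
    "In Situ, Benign or Unknown Behavior Neoplasm": "Other",
}
GROUPED_NONCANCER_CAUSES = sorted(set(NONCANCER_GROUPING.values()))

# Cause code used for deaths with a death certificate but no usable cause.
UNKNOWN_COD = "Unknown/Missing Cause"

MAJOR_INDEX = "index"
MAJOR_NON_INDEX = "non_index_cancer"
MAJOR_NON_CANCER = "non_cancer"
MAJORS = [MAJOR_INDEX, MAJOR_NON_INDEX, MAJOR_NON_CANCER]


def parent_site(site_group: str) -> str:
    """Parent-level site group for a (possibly subtype-level) label."""
    if site_group in SUBTYPE_PARENT:
        return SUBTYPE_PARENT[site_group]
    if site_group not in PARENT_SITE_GROUPS:
        raise ValueError(f"unknown site group: {site_group!r}")
    return site_group


def group_noncancer(detailed_cause: str) -> str:
    """Grouped label for one of the 26 standard non-cancer causes."""
    try:
        return NONCANCER_GROUPING[detailed_cause]
    except KeyError:
        raise ValueError(
            f"unknown non-cancer cause {detailed_cause!r}; expected one of the "
            f"{len(NONCANCER_GROUPING)} standard causes"
        ) from None


def load_cause_vocabulary() -> pd.DataFrame:
    """Packaged cause vocabulary (cod_code, kind, detail_label)."""
    with resources.files("propmort.data").joinpath("cause_vocabulary.csv").open() as f:
        return pd.read_csv(f)


def cause_kind(cod_code: str) -> str:
    """'cancer', 'noncancer' or 'unknown' for a cause-of-death code."""
    if cod_code in CANCER_CAUSE_TO_SITE:
        return "cancer"
    if cod_code in NONCANCER_GROUPING:
        return "noncancer"
    if cod_code == UNKNOWN_COD:
        return "unknown"
    raise ValueError(f"cause-of-death code {cod_code!r} not in vocabulary")
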