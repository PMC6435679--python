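"""Per-patient cohort table schema, encodings, and CSV I/O.

A cohort table holds one row per patient: disease-specific survival (time in
months + death-from-disease indicator), the seven tumour-budding features
(columns named exactly as in :data:`budquant.features.FEATURE_NAMES`), and
the clinicopathological covariates.  Ordinal clinical stages are encoded
numerically for cut-off scanning (TNM II=1, IIIA=2, IIIB=3, IV=4; pT
2a..4b=1..6; nodes N0..N2=0..2; grade G2<G2-3<G3); growth pattern, treatment
and gender are strictly categorical and are split one-vs-rest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .stats import DegenerateDataError

TIME_COL = "time_months"
EVENT_COL = "event"

TNM_LEVELS = {"II": 1, "IIIA": 2, "IIIB": 3, "IV": 4}
PT_LEVELS = {"2a": 1, "2b": 2, "3a": 3, "3b": 4, "4a": 5, "4b": 6}
NODE_LEVELS = {"N0": 0, "N1": 1, "N2": 2}
GRADE_LEVELS = {"G2": 1, "G2-3": 2, "G3": 3}

GROWTH_CATEGORIES = ("Solid", "Solid/Papillary", "Papillary", "Other")
TREATMENT_CATEGORIES = ("Tr1", "Tr2", "Tr3", "Tr4", "Tr5", "Other")
GENDER_CATEGORIES = ("Male", "Female")

#: Clinical feature scan order (cohort-description order), before the
#: budding features; used for deterministic tie-breaking in split search.
CLINICAL_FEATURES = (
    "age_years",
    "gender",
    "tnm_stage",
    "pt_stage",
    "metastasis",
    "nodes",
    "treatment",
    "grade",
    "growth_pattern",
)

CATEGORICAL_FEATURES = {"gender", "growth_pattern", "treatment"}

#: Full split-search order: clinical first, then the seven budding features.
ALL_FEATURES = CLINICAL_FEATURES + FEATURE_NAMES

REQUIRED_COLUMNS = (TIME_COL, EVENT_COL) + ALL_FEATURES

_ORDINAL_MAPS = {
    "tnm_stage": TNM_LEVELS,
    "pt_stage": PT_LEVELS,
    "nodes": NODE_LEVELS,
    "grade": GRADE_LEVELS,
}


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema, vocabularies and basic invariants; returns ``df``."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    if len(df) < 8:
        raise DegenerateDataError("cohort must have at least 8 patients")
    if df[TIME_COL].isna().any() or df[EVENT_COL].isna().any():
        raise ValueError("missing survival time or event indicator")
    if not (df[TIME_COL] > 0).all():
        raise ValueError("survival times must be positive")
    if not df[EVENT_COL].isin((0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    for col, levels in _ORDINAL_MAPS.items():
        bad = set(df[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"{col}: unknown categories {sorted(bad)}")
    for col, cats in (
        ("growth_pattern", GROWTH_CATEGORIES),
        ("treatment", TREATMENT_CATEGORIES),
        ("gender", GENDER_CATEGORIES),
    ):
        bad = set(df[col].unique()) - set(cats)
        if bad:
            raise ValueError(f"{col}: unknown categories {sorted(bad)}")
    return df


def encode_feature(df: pd.DataFrame, name: str):
    """Return ``("numeric", values)`` or ``("categorical", values)``.

    Ordinal clinical stages are mapped to their numeric codes so a cut-off
    scan expresses splits such as (II+III) vs IV.
    """
    if name in CATEGORICAL_FEATURES:
        return "categorical", df[name].to_numpy()
    if name in _ORDINAL_MAPS:
        return "numeric", df[name].map(_ORDINAL_MAPS[name]).to_numpy(float)
    return "numeric", df[name].to_numpy(float)


def read_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def survival_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return df[TIME_COL].to_numpy(float), df[EVENT_COL].to_numpy(int)
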