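"""Shared confounder design matrix for the Cox and GAM stages.

The adjustment set is: age, sex, etiology (HBV reference), overt ascites,
gastrointestinal bleeding (dropped for the advanced-fibrosis group, where it
is essentially absent), bacterial infection, HE grade (not-overt reference),
INR, creatinine, ln(ALT), and serum sodium.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RAW_CONFOUNDERS = [
    "age",
    "sex",
    "etiology",
    "ascites",
    "gi_bleeding",
    "infection",
    "he_grade",
    "inr",
    "creatinine",
    "alt",
    "sodium",
]


def required_columns(include_gib: bool = True) -> list[str]:
    cols = list(RAW_CONFOUNDERS)
    if not include_gib:
        cols.remove("gi_bleeding")
    return cols


def complete_cases(
    cohort: pd.DataFrame, extra: list[str], include_gib: bool = True
) -> pd.DataFrame:
    """Rows with every adjustment covariate plus `extra` columns present."""
    cols = required_columns(include_gib) + list(extra)
    return cohort.dropna(subset=cols)


def drop_invariant(X: pd.DataFrame, min_count: int = 5) -> pd.DataFrame:
    """Drop zero-variance and near-empty dummy columns.

    A 0/1 column with fewer than `min_count` carriers (or non-carriers)
    cannot support a stable coefficient — e.g. an HE-grade-4 dummy with two
    carriers both of whom died makes the likelihood unbounded.
    """
    keep = []
    for c in X.columns:
        col = X[c]
        if col.nunique(dropna=True) <= 1:
            continue
        vals = set(col.dropna().unique())
        if vals <= {0.0, 1.0}:
            k = col.sum()
            if k < min_count or (len(col) - k) < min_count:
                continue
        keep.append(c)
    return X[keep]


def confounder_design(cohort: pd.DataFrame, include_gib: bool = True) -> pd.DataFrame:
    """Numeric design matrix (no intercept) for the adjustment set."""
    etio = cohort["etiology"].astype(str)
    he = cohort["he_grade"].astype(float)
    X = pd.DataFrame(index=cohort.index)
    X["age"] = cohort["age"].astype(float)
    X["male"] = cohort["sex"].astype(float)
    X["etio_alcoholic"] = (etio == "alcoholic").astype(float)
    X["etio_other"] = (etio == "other").astype(float)
    X["ascites"] = cohort["ascites"].astype(float)
    if include_gib:
        X["gi_bleeding"] = cohort["gi_bleeding"].astype(float)
    X["infection"] = cohort["infection"].astype(float)
    X["he_2"] = (he == 2).astype(float)
    X["he_3"] = (he == 3).astype(float)
    X["he_4"] = (he == 4).astype(float)
    X["inr"] = cohort["inr"].astype(float)
    X["creatinine"] = cohort["creatinine"].astype(float)
    X["log_alt"] = np.log(cohort["alt"].astype(float))
    X["sodium"] = cohort["sodium"].astype(float)
    return X
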