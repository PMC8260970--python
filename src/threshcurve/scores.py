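"""Hepatology severity scores and the total-bilirubin bin scheme.

Implements the canonical published forms of FIB-4, MELD (UNOS variant with
clamping), MELD-Na, and Child-Turcotte-Pugh, plus the seven-bin total
bilirubin (TB) categorisation used throughout the cohort analysis
(<2, 2-5, 5-8, 8-12, 12-16, 16-20, >20 mg/dL, upper-inclusive edges).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "TB_BIN_EDGES",
    "TB_BIN_LABELS",
    "fib4",
    "meld",
    "meld_na",
    "ctp",
    "tb_bin",
    "tb_bin_index",
    "add_score_panel",
]

#: Interior bin edges; intervals are (lo, hi], the top bin is unbounded.
TB_BIN_EDGES = (2.0, 5.0, 8.0, 12.0, 16.0, 20.0)
TB_BIN_LABELS = ("0-2", "2-5", "5-8", "8-12", "12-16", "16-20", ">20")


def fib4(age: float, ast: float, alt: float, platelets: float) -> float:
    """Fibrosis-4 index: age * AST / (platelets * sqrt(ALT)).

    Parameters
    ----------
    age : years
    ast, alt : IU/L
    platelets : 10^9/L
    """
    if min(age, ast, alt, platelets) <= 0:
        raise ValueError("fib4 requires strictly positive age/AST/ALT/platelets")
    return age * ast / (platelets * math.sqrt(alt))


def meld(tb: float, inr: float, creatinine: float) -> float:
    """MELD score (UNOS convention).

    3.78*ln(TB) + 11.2*ln(INR) + 9.57*ln(Cr) + 6.43, with every input
    clamped below at 1.0 and creatinine capped at 4.0 mg/dL.
    """
    if min(tb, inr, creatinine) <= 0:
        raise ValueError("meld requires strictly positive TB/INR/creatinine")
    tb = max(tb, 1.0)
    inr = max(inr, 1.0)
    creatinine = min(max(creatinine, 1.0), 4.0)
    return 3.78 * math.log(tb) + 11.2 * math.log(inr) + 9.57 * math.log(creatinine) + 6.43


def meld_na(meld_score: float, sodium: float) -> float:
    """MELD-Na: MELD + 1.32*(137-Na) - 0.033*MELD*(137-Na), Na clipped to [125, 137]."""
    if meld_score < 0:
        raise ValueError("meld_na requires meld >= 0")
    na = min(max(sodium, 125.0), 137.0)
    deficit = 137.0 - na
    return meld_score + 1.32 * deficit - 0.033 * meld_score * deficit


_ASCITES_POINTS = {"none": 1, "mild": 2, "moderate-severe": 3}
# HE grading here is "not overt"(0) / 2 / 3 / 4; CTP scores grade I-II as 2
# points and III-IV as 3.  Overt grade 2 -> 2 pts, grades 3-4 -> 3 pts.
_HE_POINTS = {0: 1, 2: 2, 3: 3, 4: 3}


def ctp(
    tb: float,
    albumin: float,
    inr: float,
    ascites_grade: str = "none",
    he_grade: int = 0,
) -> int:
    """Child-Turcotte-Pugh points (5-15).

    Component cutpoints: bilirubin 2/3 mg/dL, albumin 35/28 g/L,
    INR 1.7/2.3, plus the ascites and encephalopathy categories.
    """
    if ascites_grade not in _ASCITES_POINTS:
        raise ValueError(f"unknown ascites grade {ascites_grade!r}")
    if he_grade not in _HE_POINTS:
        raise ValueError(f"unknown HE grade {he_grade!r}")
    pts = _ASCITES_POINTS[ascites_grade] + _HE_POINTS[he_grade]
    pts += 1 if tb < 2.0 else (2 if tb <= 3.0 else 3)
    pts += 1 if albumin > 35.0 else (2 if albumin >= 28.0 else 3)
    pts += 1 if inr < 1.7 else (2 if inr <= 2.3 else 3)
    return pts


def tb_bin_index(tb) -> np.ndarray | int:
    """0-based bin index for TB value(s); edges are upper-inclusive."""
    arr = np.asarray(tb, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("tb must be non-negative")
    # side='left' puts the edge value itself in the lower bin: (lo, hi]
    idx = np.searchsorted(np.asarray(TB_BIN_EDGES), arr, side="left")
    if np.ndim(tb) == 0:
        return int(idx)
    return idx


def tb_bin(tb: float) -> str:
    """Bin label for a single TB value (mg/dL)."""
    return TB_BIN_LABELS[tb_bin_index(float(tb))]


def add_score_panel(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append fib4/meld/meld_na/ctp/tb_bin columns to a cohort table.

    Rows with missing inputs for a given score get NaN for that score.
    Ascites in the cohort table is a flag; it is mapped to the CTP
    "moderate-severe" category when present.
    """
    out = cohort.copy()

    def _rowwise(fn, cols):
        def safe(row):
            vals = [row[c] for c in cols]
            if any(pd.isna(v) for v in vals):
                return np.nan
            try:
                return fn(*vals)
            except ValueError:
                return np.nan

        return out.apply(safe, axis=1)

    out["fib4"] = _rowwise(fib4, ["age", "ast", "alt", "platelets"])
    out["meld"] = _rowwise(meld, ["tb", "inr", "creatinine"])
    out["meld_na"] = _rowwise(
        lambda m, na: meld_na(m, na), ["meld", "sodium"]
    )
    out["ctp"] = _rowwise(
        lambda tb_, alb, inr_, asc, he: ctp(
            tb_, alb, inr_, "moderate-severe" if asc else "none", int(he)
        ),
        ["tb", "albumin", "inr", "ascites", "he_grade"],
    )
    out["tb_bin"] = [
        TB_BIN_LABELS[tb_bin_index(v)] if not pd.isna(v) else np.nan
        for v in out["tb"]
    ]
    return out
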