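"""Inclusion screening, analysis-group assignment, and cohort exclusions.

Inclusion requires either an acute decompensation (overt ascites, GI
bleeding, overt hepatic encephalopathy, bacterial infection, or jaundice
with TB > 5 mg/dL) or acute liver injury (ALT or AST above 3x the upper
limit of normal, or TB above 2x ULN).

The analysis cohort then excludes, in a fixed precedence order: patients
transplanted within 90 days, patients with missing TB, non-cirrhotic
patients with missing FIB-4 inputs, and non-cirrhotic patients with
FIB-4 <= 1.45 (mild or no fibrosis).  Cirrhotic patients split into
compensated vs decompensated by a precomputed prior-decompensation flag
(a first-ever decompensation at admission still counts as compensated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scores import fib4

__all__ = [
    "ULN_ALT_AST",
    "ULN_TB",
    "FIB4_THRESHOLD",
    "FilterReport",
    "check_inclusion",
    "assign_group",
    "apply_exclusions",
]

ULN_ALT_AST = 40.0  # IU/L
ULN_TB = 1.2  # mg/dL
FIB4_THRESHOLD = 1.45

# disposition labels
ANALYSIS_GROUPS = (
    "cirrhosis-compensated",
    "cirrhosis-decompensated",
    "advanced-fibrosis",
)
EXCLUSIONS = (
    "excluded-lt",
    "excluded-missing-tb",
    "excluded-missing-fib4",
    "excluded-mild-fibrosis",
)


def check_inclusion(
    record: pd.Series | dict,
    uln_alt_ast: float = ULN_ALT_AST,
    uln_tb: float = ULN_TB,
) -> tuple[bool | None, str]:
    """Hospitalization-criteria check for one record.

    Returns (flag, reason); flag is None ("indeterminate") when every field
    needed for the decision is missing.
    """
    r = dict(record) if not isinstance(record, dict) else record

    def present(k):
        return k in r and not pd.isna(r[k])

    any_field = False
    for flag, reason in [
        ("ascites", "acute decompensation: overt ascites"),
        ("gi_bleeding", "acute decompensation: gastrointestinal bleeding"),
        ("infection", "acute decompensation: bacterial infection"),
    ]:
        if present(flag):
            any_field = True
            if r[flag]:
                return True, reason
    if present("he_grade"):
        any_field = True
        if r["he_grade"] in (2, 3, 4):
            return True, "acute decompensation: overt hepatic encephalopathy"
    if present("tb"):
        any_field = True
        if r["tb"] > 5.0:
            return True, "acute decompensation: jaundice (TB > 5 mg/dL)"
        if r["tb"] > 2.0 * uln_tb:
            return True, "acute liver injury: TB > 2x ULN"
    for lab in ("alt", "ast"):
        if present(lab):
            any_field = True
            if r[lab] > 3.0 * uln_alt_ast:
                return True, f"acute liver injury: {lab.upper()} > 3x ULN"
    if not any_field:
        return None, "indeterminate: all criteria fields missing"
    return False, "no qualifying criterion"


def _record_fib4(r: pd.Series) -> float:
    inputs = [r.get(k, np.nan) for k in ("age", "ast", "alt", "platelets")]
    if any(pd.isna(v) for v in inputs):
        return np.nan
    try:
        return fib4(*inputs)
    except ValueError:
        return np.nan


def assign_group(record: pd.Series | dict) -> str:
    """Disposition of one record, ignoring LT/missing-TB exclusions."""
    r = pd.Series(record) if isinstance(record, dict) else record
    status = r.get("cirrhosis_status", "none")
    if status in ("compensated", "decompensated"):
        return (
            "cirrhosis-decompensated"
            if r.get("prior_decompensation_flag", 0)
            else "cirrhosis-compensated"
        )
    f = r.get("fib4", np.nan)
    if pd.isna(f):
        f = _record_fib4(r)
    if pd.isna(f):
        return "excluded-missing-fib4"
    return "advanced-fibrosis" if f > FIB4_THRESHOLD else "excluded-mild-fibrosis"


@dataclass
class FilterReport:
    """Accounting of the exclusion cascade; dispositions partition the input."""

    n_input: int
    n_excluded_lt: int
    n_excluded_missing_tb: int
    n_excluded_missing_fib4: int
    n_excluded_mild_fibrosis: int
    n_cirrhosis_compensated: int
    n_cirrhosis_decompensated: int
    n_advanced_fibrosis: int
    dispositions: pd.Series = field(repr=False, default=None)

    @property
    def n_analysis(self) -> int:
        return (
            self.n_cirrhosis_compensated
            + self.n_cirrhosis_decompensated
            + self.n_advanced_fibrosis
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_lt": self.n_excluded_lt,
            "n_excluded_missing_tb": self.n_excluded_missing_tb,
            "n_excluded_missing_fib4": self.n_excluded_missing_fib4,
            "n_excluded_mild_fibrosis": self.n_excluded_mild_fibrosis,
            "n_cirrhosis_compensated": self.n_cirrhosis_compensated,
            "n_cirrhosis_decompensated": self.n_cirrhosis_decompensated,
            "n_advanced_fibrosis": self.n_advanced_fibrosis,
            "n_analysis": self.n_analysis,
        }


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the exclusion cascade; returns (analysis cohort, report).

    Precedence: LT within 90 days, then missing TB, then the FIB-4 rules for
    non-cirrhotic patients.  The returned cohort keeps only records with an
    analysis-group disposition, recorded in a new ``group`` column.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    disp = pd.Series(index=cohort.index, dtype=object)

    lt = cohort.get("lt_within_90", pd.Series(0, index=cohort.index)).fillna(0).astype(bool)
    disp[lt] = "excluded-lt"

    missing_tb = cohort["tb"].isna() & ~lt
    disp[missing_tb] = "excluded-missing-tb"

    rest = disp.isna()
    disp[rest] = cohort.loc[rest].apply(assign_group, axis=1)

    counts = disp.value_counts()
    report = FilterReport(
        n_input=len(cohort),
        n_excluded_lt=int(counts.get("excluded-lt", 0)),
        n_excluded_missing_tb=int(counts.get("excluded-missing-tb", 0)),
        n_excluded_missing_fib4=int(counts.get("excluded-missing-fib4", 0)),
        n_excluded_mild_fibrosis=int(counts.get("excluded-mild-fibrosis", 0)),
        n_cirrhosis_compensated=int(counts.get("cirrhosis-compensated", 0)),
        n_cirrhosis_decompensated=int(counts.get("cirrhosis-decompensated", 0)),
        n_advanced_fibrosis=int(counts.get("advanced-fibrosis", 0)),
        dispositions=disp,
    )
    analysis = cohort.loc[disp.isin(ANALYSIS_GROUPS)].copy()
    analysis["group"] = disp.loc[analysis.index]
    return analysis, report
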