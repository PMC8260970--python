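"""Bin-level summary tables and end-to-end pipeline orchestration."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cutoffs as co
from .cox import TBCoxModel
from .filters import apply_exclusions
from .riskcurve import AdjustedMortalityGAM, default_grid
from .scores import TB_BIN_LABELS, add_score_panel, tb_bin_index
from .simulate import SimulationConfig, generate_cohort

__all__ = [
    "BinSummaryTable",
    "build_bin_table",
    "run_pipeline",
    "round_pct",
    "synthetic_bin_cohort",
]

log = logging.getLogger("threshcurve")


def round_pct(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to one decimal (table style)."""
    if denominator == 0:
        return float("nan")
    raw = Decimal(100 * numerator) / Decimal(denominator)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def synthetic_bin_cohort(bin_n, deaths_90, deaths_28) -> pd.DataFrame:
    """Synthetic cohort realizing exact per-bin sizes and death counts.

    Builds a minimal schema-complete table whose TB values sit at bin
    midpoints (26 mg/dL for the unbounded top bin) with the requested
    28-/90-day death counts per bin — useful for verifying bin-table
    arithmetic against published count data.
    """
    mids = [1.0, 3.5, 6.5, 10.0, 14.0, 18.0, 26.0]
    rows_tb, rows_d90, rows_d28 = [], [], []
    for mid, n, d90, d28 in zip(mids, bin_n, deaths_90, deaths_28):
        if not (0 <= d28 <= d90 <= n):
            raise ValueError("need 0 <= deaths_28 <= deaths_90 <= n in every bin")
        rows_tb += [mid] * n
        rows_d90 += [1] * d90 + [0] * (n - d90)
        rows_d28 += [1] * d28 + [0] * (d90 - d28) + [0] * (n - d90)
    n_total = len(rows_tb)
    d90 = np.array(rows_d90, dtype=int)
    d28 = np.array(rows_d28, dtype=int)
    return pd.DataFrame(
        {
            "id": np.arange(1, n_total + 1),
            "age": 50.0,
            "sex": 1,
            "etiology": "HBV",
            "ascites": 0,
            "gi_bleeding": 0,
            "infection": 0,
            "he_grade": 0,
            "tb": np.array(rows_tb, dtype=float),
            "inr": 1.5,
            "creatinine": 0.8,
            "alt": 60.0,
            "ast": 80.0,
            "sodium": 138.0,
            "albumin": 30.0,
            "platelets": 80.0,
            "hemoglobin": 110.0,
            "time_to_death": np.where(d28 == 1, 14.0, np.where(d90 == 1, 60.0, 200.0)),
            "death_90": d90,
            "death_28": d28,
            "lt_within_90": 0,
            "lt_day": np.nan,
        }
    )


@dataclass
class BinSummaryTable:
    """Baseline characteristics and 28/90-day mortality per TB bin."""

    counts: pd.DataFrame  # numeric: one row per bin + totals row
    table: pd.DataFrame  # formatted analog (one column per bin)

    @property
    def overall_mortality90_pct(self) -> float:
        return float(self.counts.loc["overall", "pct_death_90"])

    @property
    def overall_mortality28_pct(self) -> float:
        return float(self.counts.loc["overall", "pct_death_28"])


def _fmt_mean_sd(x: pd.Series) -> str:
    x = x.dropna()
    if len(x) == 0:
        return ""
    return f"{x.mean():.1f} ({x.std(ddof=1):.1f})" if len(x) > 1 else f"{x.mean():.1f} (—)"


def _fmt_median_iqr(x: pd.Series) -> str:
    x = x.dropna()
    if len(x) == 0:
        return ""
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def _fmt_n_pct(k: int, n: int) -> str:
    return f"{k} ({round_pct(k, n):.1f})" if n else "0"


def build_bin_table(cohort: pd.DataFrame) -> BinSummaryTable:
    """Summarize a filtered, scored cohort by TB bin.

    Categorical variables as No. (%), age and severity scores as mean (SD),
    laboratory values as median (IQR); percentages rounded half-up to one
    decimal.  Empty bins get n=0 columns with blank summaries.
    """
    df = cohort.dropna(subset=["tb"]).copy()
    df["_bin"] = np.asarray(tb_bin_index(df["tb"].to_numpy(dtype=float)))

    rows_counts = []
    cols_table: dict[str, dict] = {}
    for b, label in enumerate(TB_BIN_LABELS):
        sub = df[df["_bin"] == b]
        n = len(sub)
        d28 = int(sub["death_28"].sum()) if n else 0
        d90 = int(sub["death_90"].sum()) if n else 0
        rows_counts.append(
            {
                "bin": label,
                "n": n,
                "death_28": d28,
                "death_90": d90,
                "pct_death_28": round_pct(d28, n) if n else np.nan,
                "pct_death_90": round_pct(d90, n) if n else np.nan,
            }
        )
        col = {"N": str(n)}
        if n:
            col["Age, mean (SD)"] = _fmt_mean_sd(sub["age"])
            col["Male, No. (%)"] = _fmt_n_pct(int(sub["sex"].sum()), n)
            for e in ("HBV", "alcoholic", "other"):
                col[f"Etiology {e}, No. (%)"] = _fmt_n_pct(
                    int((sub["etiology"] == e).sum()), n
                )
            for c, name in [
                ("ascites", "Ascites"),
                ("gi_bleeding", "Gastrointestinal bleeding"),
                ("infection", "Bacterial infection"),
            ]:
                col[f"{name}, No. (%)"] = _fmt_n_pct(int(sub[c].fillna(0).sum()), n)
            for g, name in [(0, "HE not overt"), (2, "HE grade 2"), (3, "HE grade 3"), (4, "HE grade 4")]:
                col[f"{name}, No. (%)"] = _fmt_n_pct(int((sub["he_grade"] == g).sum()), n)
            for lab, name in [
                ("hemoglobin", "Hemoglobin, g/L"),
                ("platelets", "Platelet, 10^9/L"),
                ("inr", "International normalized ratio"),
                ("creatinine", "Creatinine, mg/dL"),
                ("albumin", "Albumin, g/L"),
                ("alt", "Alanine transaminase, IU/L"),
                ("ast", "Aspartate transaminase, IU/L"),
                ("sodium", "Sodium, mmol/L"),
            ]:
                col[f"{name}, median (IQR)"] = _fmt_median_iqr(sub[lab])
            for score in ("meld", "meld_na", "ctp"):
                if score in sub.columns:
                    col[f"{score.upper()}, mean (SD)"] = _fmt_mean_sd(sub[score])
            col["28-day mortality, No. (%)"] = _fmt_n_pct(d28, n)
            col["90-day mortality, No. (%)"] = _fmt_n_pct(d90, n)
        cols_table[label] = col

    counts = pd.DataFrame(rows_counts).set_index("bin")
    overall = {
        "n": int(counts["n"].sum()),
        "death_28": int(counts["death_28"].sum()),
        "death_90": int(counts["death_90"].sum()),
    }
    overall["pct_death_28"] = round_pct(overall["death_28"], overall["n"])
    overall["pct_death_90"] = round_pct(overall["death_90"], overall["n"])
    counts.loc["overall"] = overall
    return BinSummaryTable(counts=counts, table=pd.DataFrame(cols_table))


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

_GROUP_SETS = {
    "cirrhosis": ("cirrhosis-compensated", "cirrhosis-decompensated"),
    "compensated": ("cirrhosis-compensated",),
    "decompensated": ("cirrhosis-decompensated",),
    "fibrosis": ("advanced-fibrosis",),
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def simulation_config_from_dict(sim: dict, seed: int, group: str) -> SimulationConfig:
    """Build a SimulationConfig from the pipeline config's `simulate` block."""
    from .simulate import TBLink

    maker = (
        SimulationConfig.fibrosis_like
        if group == "fibrosis"
        else SimulationConfig.cirrhosis_like
    )
    overrides = {}
    if "link" in sim:
        overrides["link"] = TBLink(sim["link"]["shape"], dict(sim["link"].get("params", {})))
    for key in ("baseline_hazard", "lt_rate", "horizon_days", "weibull_shape", "tb_tail_scale"):
        if key in sim:
            overrides[key] = sim[key]
    return maker(n=int(sim.get("n", 2592 if group != "fibrosis" else 940)), seed=seed, **overrides)


def run_pipeline(config, outdir: str | Path | None = None) -> dict:
    """Run simulate/ingest -> filter -> score -> cox -> curves -> cutoffs -> tables.

    `config` is a YAML path or a dict with keys: seed, group
    (cirrhosis|fibrosis|compensated|decompensated), and either a `simulate`
    block or `input_csv`; optional `horizons` (subset of [28, 90]),
    `grid_step`, `outdir`.  Returns the artifact bundle as a dict; writes
    CSV/JSON artifacts when an output directory is given.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    group = cfg.get("group", "cirrhosis")
    if group not in _GROUP_SETS:
        raise ValueError(f"unknown group {group!r}")
    horizons = list(cfg.get("horizons", [28, 90]))
    grid = default_grid(float(cfg.get("grid_step", 0.1)))
    outdir = Path(outdir or cfg.get("outdir")) if (outdir or cfg.get("outdir")) else None
    include_gib = group != "fibrosis"
    stages: dict[str, float] = {}
    artifacts: dict = {"config_hash": _config_hash(cfg), "seed": seed, "group": group}

    def stage(name):
        t0 = time.perf_counter()

        def done(n=None):
            stages[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs%s", name, stages[name], f" (n={n})" if n else "")

        return done

    d = stage("ingest")
    if "input_csv" in cfg and cfg["input_csv"]:
        cohort = pd.read_csv(cfg["input_csv"])
    else:
        sim_cfg = simulation_config_from_dict(cfg.get("simulate", {}), seed, group)
        cohort = generate_cohort(sim_cfg)
    d(len(cohort))

    d = stage("filter")
    analysis, report = apply_exclusions(cohort)
    analysis = analysis[analysis["group"].isin(_GROUP_SETS[group])]
    d(len(analysis))
    artifacts["filter_report"] = report.to_dict()

    d = stage("score")
    analysis = add_score_panel(analysis)
    d(len(analysis))

    d = stage("cox")
    cox_out = {}
    for mode in ("continuous", "categorical"):
        for adjusted in (True, False):
            key = f"{mode}_{'adjusted' if adjusted else 'unadjusted'}"
            res = TBCoxModel(
                analysis, exposure_mode=mode, adjusted=adjusted, include_gib=include_gib
            ).fit()
            tab = res.summary()
            if mode == "categorical" and adjusted:
                tab.attrs["trend_p"] = res.trend_p
            cox_out[key] = tab
    d()
    artifacts["cox"] = cox_out

    d = stage("curves")
    curves = {}
    fits = {}
    for h in horizons:
        fit = AdjustedMortalityGAM(analysis, horizon=h, include_gib=include_gib).fit()
        fits[h] = fit
        curves[h] = fit.predict_curve(grid)
    d()
    artifacts["curves"] = curves
    artifacts["gam_summaries"] = {h: fits[h].summary() for h in horizons}

    d = stage("cutoffs")
    cuts: dict[str, float | None] = {}
    acc = None
    if 90 in curves:
        acc = co.second_derivative(curves[90])
        peak, valley = co.find_inflections(acc)
        cuts["mathematical"] = peak
        cuts["valley"] = valley
    if 28 in curves:
        cuts["clinical"] = co.clinical_cutoff(curves[28])
    cutoff_report = co.summarize_cutoffs(
        analysis, curves.get(28), curves.get(90), cuts, group=group
    )
    d()
    artifacts["acceleration"] = acc
    artifacts["cutoff_report"] = cutoff_report

    d = stage("tables")
    artifacts["bin_table"] = build_bin_table(analysis)
    d()
    artifacts["stage_seconds"] = stages
    artifacts["cohort"] = cohort
    artifacts["analysis_cohort"] = analysis

    if outdir is not None:
        _write_artifacts(artifacts, outdir, cfg)
    return artifacts


def _write_artifacts(artifacts: dict, outdir: Path, cfg: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts["cohort"].to_csv(outdir / "cohort.csv", index=False)
    artifacts["analysis_cohort"].to_csv(outdir / "analysis_cohort.csv", index=False)
    with open(outdir / "filter_report.json", "w") as fh:
        json.dump(artifacts["filter_report"], fh, indent=2)
    for key, tab in artifacts["cox"].items():
        tab.to_csv(outdir / f"cox_{key}.csv", index=False)
    for h, curve in artifacts["curves"].items():
        curve.to_frame().to_csv(outdir / f"curve_{h}d.csv", index=False)
    if artifacts.get("acceleration") is not None:
        artifacts["acceleration"].to_frame().to_csv(
            outdir / "acceleration_90d.csv", index=False
        )
    artifacts["cutoff_report"].to_frame().to_csv(outdir / "cutoffs.csv", index=False)
    artifacts["bin_table"].table.to_csv(outdir / "bin_table.csv")
    artifacts["bin_table"].counts.to_csv(outdir / "bin_counts.csv")
    meta = {
        "config_hash": artifacts["config_hash"],
        "seed": artifacts["seed"],
        "group": artifacts["group"],
        "stage_seconds": artifacts["stage_seconds"],
        "config": {k: v for k, v in cfg.items()},
    }
    with open(outdir / "run.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
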