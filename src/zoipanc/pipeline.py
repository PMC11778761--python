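"""End-to-end analysis orchestration and report serialization.

Runs the full sequence on a conforming table: validate -> (recode) ->
complete-case filter -> per-year descriptives -> percent distributions ->
group means with Kruskal-Wallis / Mann-Whitney screening -> inflation
score test -> ZOIP regression -> interaction contrasts.  Every stage is
logged with row counts and timings, each stage is also callable on its
own through the library modules, and a fixed seed makes reruns
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bivariate import analyze_covariate, group_mean_table, mean_ci, percent_distribution
from .data_model import (
    COVARIATES,
    OUTCOME,
    YEAR,
    YEAR_LEVELS,
    build_design_matrix,
    complete_case_filter,
    recode_covariates,
    validate_dataset,
)
from .fit import ZOIPFitResult, fit_zoip, initialize_parameters, mean_ratio_frame
from .score_test import ScoreTestResult, score_test_zero_one
from .trends import ContrastRatio, rural_urban_trend_table

logger = logging.getLogger(__name__)

__all__ = ["AnalysisReport", "run_full_analysis", "write_tables", "report_to_dict"]

TABLE_FILES = ["table1.csv", "table2.csv", "table3.csv", "table4.csv",
               "fig1.csv", "fig2.csv", "report.json"]


@dataclass
class AnalysisReport:
    """All analysis outputs plus provenance, one attribute per stage."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    score_test: ScoreTestResult
    table4: pd.DataFrame
    fit: ZOIPFitResult
    fig1: list[ContrastRatio] | None
    fig2: list[ContrastRatio] | None
    provenance: dict = field(default_factory=dict)
    dropped: int = 0


def _stage(name):
    logger.info("stage: %s", name)
    return time.perf_counter()


def _table1(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for year in YEAR_LEVELS:
        y = df.loc[df[YEAR] == year, OUTCOME].to_numpy(dtype=float)
        if len(y) < 2:
            continue
        mean, sd, lo, hi = mean_ci(y)
        rows.append({"survey_year": year, "n": len(y), "mean": mean, "sd": sd,
                     "ci_low": lo, "ci_high": hi})
    y = df[OUTCOME].to_numpy(dtype=float)
    mean, sd, lo, hi = mean_ci(y)
    rows.append({"survey_year": "pooled", "n": len(y), "mean": mean, "sd": sd,
                 "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def _table2(df: pd.DataFrame) -> pd.DataFrame:
    frames = []
    for cov in COVARIATES:
        t = percent_distribution(df, cov).reset_index(names="level")
        t.insert(0, "covariate", cov)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def _table3(df: pd.DataFrame, alpha: float, bonferroni: bool) -> pd.DataFrame:
    rows = []
    for cov in COVARIATES:
        means = group_mean_table(df, cov)
        screen = analyze_covariate(df, cov, alpha=alpha, bonferroni=bonferroni)
        pw = {pair: p for pair, _, p in screen.pairwise}
        for level in means.index:
            row = {"covariate": cov, "level": level}
            row.update({f"mean_{c}": means.loc[level, c] for c in means.columns})
            row["kw_p"] = screen.kw_p
            row["pairwise"] = "; ".join(
                f"{a}-{b}: {p:.4g}" for (a, b), p in pw.items() if level in (a, b))
            rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(table, *, raw_mode: bool = False, alpha: float = 0.05,
                      bonferroni: bool = False, seed: int = 0) -> AnalysisReport:
    """Execute the whole analysis on a CSV path or DataFrame.

    ``raw_mode`` validates the pre-recode schema and applies the covariate
    recoding first.  The trend stage is skipped (with a warning) when the
    data cover a single survey year.
    """
    t0 = _stage("validate")
    df = validate_dataset(table, raw=raw_mode)
    if raw_mode:
        _stage("recode")
        df = recode_covariates(df)
    _stage("complete-case filter")
    df, dropped = complete_case_filter(df)
    if len(df) == 0:
        raise ValueError("no complete cases remain after filtering")

    _stage("descriptives")
    table1 = _table1(df)
    table2 = _table2(df)
    _stage("bivariate screening")
    table3 = _table3(df, alpha, bonferroni)

    _stage("inflation score test")
    st = score_test_zero_one(df[OUTCOME].to_numpy(dtype=int))
    logger.info("score test: statistic=%.3f, df=%d, p=%.3g",
                st.statistic, st.df, st.p_value)

    _stage("ZOIP regression")
    design = build_design_matrix(df)
    n_years = df[YEAR].nunique()
    if n_years == 1:
        # a single survey wave makes the year code constant and the
        # interaction collinear with the rural dummy; drop both columns
        logger.warning("single survey year: year and interaction terms "
                       "removed from the regression")
        design.X = design.X[:, :-2]
        design.column_labels = design.column_labels[:-2]
    fit = fit_zoip(design, init=initialize_parameters(design))
    table4 = mean_ratio_frame(fit)

    if n_years > 1:
        _stage("trend contrasts")
        fig1, fig2 = rural_urban_trend_table(fit)
    else:
        logger.warning("single survey year observed; trend stage skipped")
        fig1 = fig2 = None

    provenance = {
        "input": str(table) if not isinstance(table, pd.DataFrame) else "<in-memory>",
        "raw_mode": raw_mode, "alpha": alpha, "bonferroni": bonferroni,
        "seed": seed, "software_version": __version__,
        "n_input": int(len(df) + dropped), "n_complete": int(len(df)),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    return AnalysisReport(table1=table1, table2=table2, table3=table3,
                          score_test=st, table4=table4, fit=fit,
                          fig1=fig1, fig2=fig2, provenance=provenance,
                          dropped=dropped)


def _contrasts_frame(contrasts: list[ContrastRatio] | None) -> pd.DataFrame:
    if contrasts is None:
        return pd.DataFrame(columns=["description", "ratio", "se", "ci_low", "ci_high"])
    return pd.DataFrame(
        {"description": [c.description for c in contrasts],
         "ratio": [c.ratio for c in contrasts],
         "se": [c.se for c in contrasts],
         "ci_low": [c.ci_low for c in contrasts],
         "ci_high": [c.ci_high for c in contrasts]})


def _round_df(df: pd.DataFrame, decimals: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, d in decimals.items():
        if col in out.columns:
            out[col] = out[col].astype(float).round(d)
    return out


def report_to_dict(report: AnalysisReport) -> dict:
    """JSON-serialisable view of a report (floats rounded to 6 digits)."""
    def recs(df):
        out = df.copy()
        for c in out.columns:
            if out[c].dtype.kind == "f":
                out[c] = out[c].round(6)
        return json.loads(out.to_json(orient="records"))

    st = report.score_test
    return {
        "table1": recs(report.table1),
        "table2": recs(report.table2),
        "table3": recs(report.table3.drop(columns=["pairwise"]).assign(
            pairwise=report.table3["pairwise"])),
        "score_test": {"statistic": round(st.statistic, 6), "df": st.df,
                       "p_value": float(f"{st.p_value:.6g}"), "n": st.n,
                       "lambda_null": round(st.lambda_null, 6)},
        "table4": recs(report.table4),
        "fig1": recs(_contrasts_frame(report.fig1)),
        "fig2": recs(_contrasts_frame(report.fig2)),
        "convergence": {"converged": report.fit.converged,
                        "n_iter": report.fit.n_iter,
                        "gradient_norm": float(f"{report.fit.gradient_norm:.6g}"),
                        "loglik": round(report.fit.loglik, 6),
                        "boundary": report.fit.boundary},
        "provenance": {k: v for k, v in report.provenance.items() if k != "elapsed_s"},
        "dropped": report.dropped,
    }


def write_tables(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Emit the seven report files (tables 1-4, both contrast CSVs, JSON).

    Rounding follows the report conventions: two decimals for means and
    percentages, three for coefficients and ratios.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    t1 = _round_df(report.table1, {"mean": 2, "sd": 2, "ci_low": 2, "ci_high": 2})
    t2 = _round_df(report.table2, {c: 1 for c in report.table2.columns
                                   if c not in ("covariate", "level")})
    t3 = _round_df(report.table3, {c: 2 for c in report.table3.columns
                                   if c.startswith("mean_")} | {"kw_p": 4})
    t4 = _round_df(report.table4, {"estimate": 3, "se": 3, "mean_ratio": 3,
                                   "p_value": 4})
    t4 = t4.rename(columns={"label": "Covariate", "estimate": "Estimate",
                            "se": "SE", "mean_ratio": "Mean ratio",
                            "p_value": "p-value"})
    f1 = _round_df(_contrasts_frame(report.fig1),
                   {"ratio": 3, "se": 3, "ci_low": 3, "ci_high": 3})
    f2 = _round_df(_contrasts_frame(report.fig2),
                   {"ratio": 3, "se": 3, "ci_low": 3, "ci_high": 3})
    for name, frame in zip(TABLE_FILES[:6], [t1, t2, t3, t4, f1, f2]):
        path = out_dir / name
        frame.to_csv(path, index=False)
        paths.append(path)

    path = out_dir / "report.json"
    path.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True))
    paths.append(path)
    logger.info("wrote %d report files to %s", len(paths), out_dir)
    return paths
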