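"""Record schema, covariate recoding, and design-matrix construction.

The analysis dataset carries one row per mother: the number of skilled
antenatal care (SANC) visits at her last birth, a survey-year label, and
twelve categorical covariates.  Two CSV schemas are supported:

* **analysis mode** — covariates already collapsed to the analysis
  categories (the schema listed in :data:`ANALYSIS_COLUMNS`);
* **raw mode** — DHS-style source variables (five-level wealth index,
  three media-use frequencies, three decision-participation indicators,
  five wife-beating-opinion indicators, three-level pregnancy intention)
  that :func:`recode_covariates` collapses to the analysis categories.

Missing values may appear as an empty string or ``NA`` in CSV input; they
are normalised to :data:`pandas.NA` at parse time and propagate through
recoding until :func:`complete_case_filter` drops the affected rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "OUTCOME",
    "YEAR",
    "YEAR_LEVELS",
    "YEAR_CODE",
    "LEVELS",
    "COVARIATES",
    "ANALYSIS_COLUMNS",
    "RAW_LEVELS",
    "RAW_COLUMNS",
    "DESIGN_COLUMNS",
    "DesignMatrix",
    "validate_dataset",
    "recode_covariates",
    "lift_to_raw",
    "complete_case_filter",
    "build_design_matrix",
]


class SchemaError(ValueError):
    """The input table violates the documented CSV schema."""


OUTCOME = "sanc_visits"
YEAR = "survey_year"

YEAR_LEVELS = ["2011", "2014", "2017-18", "2022"]
#: Survey year entered in the regression as a quantitative variable.
YEAR_CODE = {"2011": 1, "2014": 2, "2017-18": 3, "2022": 4}
# accept the en-dash spelling that appears in survey reports
_YEAR_ALIASES = {"2017–18": "2017-18", "2017_18": "2017-18"}

#: Analysis-mode levels per covariate; the first level of each list is the
#: regression reference category.
LEVELS: dict[str, list[str]] = {
    "residence": ["urban", "rural"],
    "maternal_age": ["<20", "20-34", ">34"],
    "maternal_edu": ["none", "primary", "secondary", "higher"],
    "paternal_edu": ["none", "primary", "secondary", "higher"],
    "wealth": ["poor", "middle", "rich"],
    "birth_order": ["first", "second_third", "above_third"],
    "working": ["non_working", "working"],
    "media": ["non_exposed", "exposed"],
    "decision": ["no", "yes"],
    "violence_opinion": ["non_justified", "justified"],
    "wanted_pregnancy": ["no", "yes"],
    "terminated_pregnancy": ["no", "yes"],
}
COVARIATES = list(LEVELS)
ANALYSIS_COLUMNS = [OUTCOME, YEAR] + COVARIATES

_MEDIA_FREQ = ["not_at_all", "less_than_weekly", "at_least_weekly"]
_YESNO = ["no", "yes"]

#: Raw-mode levels for the source variables that get recoded.
RAW_LEVELS: dict[str, list[str]] = {
    "wealth5": ["poorest", "poorer", "middle", "richer", "richest"],
    "media_newspaper": _MEDIA_FREQ,
    "media_tv": _MEDIA_FREQ,
    "media_radio": _MEDIA_FREQ,
    "decision_health": _YESNO,
    "decision_purchases": _YESNO,
    "decision_visits": _YESNO,
    "beat_argue": _YESNO,
    "beat_neglect": _YESNO,
    "beat_goout": _YESNO,
    "beat_refuse": _YESNO,
    "beat_burn": _YESNO,
    "wanted3": ["then", "later", "no_more"],
}

#: Covariates that pass through recoding unchanged.
_RAW_PASSTHROUGH = [
    "residence",
    "maternal_age",
    "maternal_edu",
    "paternal_edu",
    "birth_order",
    "working",
    "terminated_pregnancy",
]
RAW_COLUMNS = [OUTCOME, YEAR] + _RAW_PASSTHROUGH + list(RAW_LEVELS)

# ---------------------------------------------------------------------------
# Design matrix layout (fixed so coefficient vectors are comparable across
# runs).  Dummy labels follow the patsy "covariate[level]" convention; the
# final two columns are the quantitative year code and its product with the
# rural indicator.
# ---------------------------------------------------------------------------

_DUMMIES: list[tuple[str, str]] = [
    (cov, level) for cov in COVARIATES for level in LEVELS[cov][1:]
]
DESIGN_COLUMNS: list[str] = (
    ["Intercept"]
    + [f"{cov}[{level}]" for cov, level in _DUMMIES]
    + [YEAR, f"{YEAR}:residence[rural]"]
)


@dataclass
class DesignMatrix:
    """Outcome vector and regressor matrix for the ZOIP regression."""

    y: np.ndarray | None
    X: np.ndarray
    column_labels: list[str]
    reference_map: dict[str, str] = field(default_factory=dict)
    year_code: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# Parsing and validation
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", "<NA>"}


def _normalize_missing(df: pd.DataFrame) -> pd.DataFrame:
    return df.apply(lambda s: s.map(lambda v: pd.NA if (pd.isna(v) or str(v).strip() in _MISSING_TOKENS) else str(v).strip()))


def validate_dataset(table, raw: bool = False) -> pd.DataFrame:
    """Parse and validate a table of mother-level records.

    Parameters
    ----------
    table : DataFrame or path-like
        Either an in-memory table or a path to a CSV file with the
        analysis-mode (or, with ``raw=True``, the raw-mode) columns.
    raw : bool
        Expect the raw-mode schema; recoding is *not* applied here.

    Returns
    -------
    DataFrame with a nullable-integer outcome, validated categorical
    covariates, and missing markers normalised to :data:`pandas.NA`.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        df = df.astype(object)
    else:
        df = pd.read_csv(table, dtype=str, keep_default_na=False)
    required = RAW_COLUMNS if raw else ANALYSIS_COLUMNS
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")
    df = df[required]
    df = _normalize_missing(df)

    # outcome: non-negative integer or missing
    def _to_count(v):
        if v is pd.NA:
            return pd.NA
        try:
            f = float(v)
        except (TypeError, ValueError):
            raise SchemaError(f"non-numeric outcome value {v!r} in column {OUTCOME!r}")
        if f != int(f) or f < 0:
            raise SchemaError(f"outcome must be a non-negative integer, got {v!r}")
        return int(f)

    df[OUTCOME] = df[OUTCOME].map(_to_count).astype("Int64")

    df[YEAR] = df[YEAR].map(lambda v: _YEAR_ALIASES.get(v, v) if v is not pd.NA else v)
    level_map = dict(LEVELS) if not raw else {
        **{c: LEVELS[c] for c in _RAW_PASSTHROUGH},
        **RAW_LEVELS,
    }
    level_map = {YEAR: YEAR_LEVELS, **level_map}
    bad: list[str] = []
    for col, levels in level_map.items():
        ok = df[col].isna() | df[col].isin(levels)
        if not ok.all():
            rows = df.index[~ok].tolist()[:5]
            vals = sorted(set(df.loc[~ok, col]))[:5]
            bad.append(f"column {col!r}: unknown level(s) {vals} at rows {rows}")
    if bad:
        raise SchemaError("; ".join(bad))

    counts = df[YEAR].value_counts().reindex(YEAR_LEVELS, fill_value=0)
    logger.info("validated %d records (per survey year: %s)", len(df), counts.to_dict())
    return df


# ---------------------------------------------------------------------------
# Recoding
# ---------------------------------------------------------------------------

_WEALTH_MAP = {"poorest": "poor", "poorer": "poor", "middle": "middle",
               "richer": "rich", "richest": "rich"}
_WANTED_MAP = {"then": "yes", "later": "yes", "no_more": "no"}


def _any_indicator(df: pd.DataFrame, cols: list[str], hit: str,
                   yes: str, no: str) -> pd.Series:
    """Disjunction over indicator columns with three-valued missing logic.

    A single ``hit`` value decides the derived field even if other
    indicators are missing; otherwise any missing source leaves the
    derived field missing.
    """
    any_hit = pd.Series(False, index=df.index)
    any_na = pd.Series(False, index=df.index)
    for c in cols:
        any_hit |= (df[c] == hit).fillna(False)
        any_na |= df[c].isna()
    out = pd.Series(no, index=df.index, dtype=object)
    out[any_hit] = yes
    out[~any_hit & any_na] = pd.NA
    return out


def recode_covariates(raw_df: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw-mode source variables to the analysis categories.

    Rules: the five-level wealth index merges poorest/poorer into *poor*
    and richer/richest into *rich*; a mother is media *exposed* if she uses
    newspaper, TV or radio at least weekly; decision participation and the
    violence opinion are disjunctions over their indicator sets; pregnancy
    intentions *then*/*later* merge into *yes*.  Missing source values
    propagate to the derived field.
    """
    unknown = {}
    for col, levels in RAW_LEVELS.items():
        bad = raw_df[col].dropna()[~raw_df[col].dropna().isin(levels)]
        if len(bad):
            unknown[col] = sorted(set(bad))
    if unknown:
        raise SchemaError(f"unknown source level(s): {unknown}")

    out = pd.DataFrame(index=raw_df.index)
    out[OUTCOME] = raw_df[OUTCOME]
    out[YEAR] = raw_df[YEAR]
    for c in _RAW_PASSTHROUGH:
        out[c] = raw_df[c]
    out["wealth"] = raw_df["wealth5"].map(_WEALTH_MAP, na_action="ignore")
    out["media"] = _any_indicator(
        raw_df, ["media_newspaper", "media_tv", "media_radio"],
        hit="at_least_weekly", yes="exposed", no="non_exposed")
    out["decision"] = _any_indicator(
        raw_df, ["decision_health", "decision_purchases", "decision_visits"],
        hit="yes", yes="yes", no="no")
    out["violence_opinion"] = _any_indicator(
        raw_df, ["beat_argue", "beat_neglect", "beat_goout", "beat_refuse", "beat_burn"],
        hit="yes", yes="justified", no="non_justified")
    out["wanted_pregnancy"] = raw_df["wanted3"].map(_WANTED_MAP, na_action="ignore")
    return out[ANALYSIS_COLUMNS]


#: Canonical raw representative of each recoded level, used by
#: :func:`lift_to_raw`.  Any source level mapping back to the same analysis
#: category would do; these are fixed so that lift-then-recode is identity.
def lift_to_raw(df: pd.DataFrame) -> pd.DataFrame:
    """Lift an analysis-mode table to a raw-mode representative.

    ``recode_covariates(lift_to_raw(df))`` equals ``df`` row for row, which
    makes recoding idempotent through the lift and lets the synthetic
    generator emit raw-mode files.
    """
    out = pd.DataFrame(index=df.index)
    out[OUTCOME] = df[OUTCOME]
    out[YEAR] = df[YEAR]
    for c in _RAW_PASSTHROUGH:
        out[c] = df[c]
    out["wealth5"] = df["wealth"].map(
        {"poor": "poorer", "middle": "middle", "rich": "richer"}, na_action="ignore")
    exposed = df["media"]
    out["media_tv"] = exposed.map(
        {"exposed": "at_least_weekly", "non_exposed": "not_at_all"}, na_action="ignore")
    out["media_newspaper"] = exposed.map(
        {"exposed": "not_at_all", "non_exposed": "not_at_all"}, na_action="ignore")
    out["media_radio"] = out["media_newspaper"]
    dec = df["decision"]
    out["decision_health"] = dec
    out["decision_purchases"] = dec.map({"yes": "no", "no": "no"}, na_action="ignore")
    out["decision_visits"] = out["decision_purchases"]
    just = df["violence_opinion"].map(
        {"justified": "yes", "non_justified": "no"}, na_action="ignore")
    out["beat_argue"] = just
    for c in ["beat_neglect", "beat_goout", "beat_refuse", "beat_burn"]:
        out[c] = just.map({"yes": "no", "no": "no"}, na_action="ignore")
    out["wanted3"] = df["wanted_pregnancy"].map(
        {"yes": "then", "no": "no_more"}, na_action="ignore")
    return out[RAW_COLUMNS]


# ---------------------------------------------------------------------------
# Complete-case filter and design matrix
# ---------------------------------------------------------------------------

def complete_case_filter(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records with any missing outcome or covariate value.

    Returns the kept records (input order preserved) and the number of
    dropped rows.  Valid under the assumption that missingness is
    completely at random.
    """
    kept = df.dropna(subset=[c for c in ANALYSIS_COLUMNS if c in df.columns])
    dropped = len(df) - len(kept)
    logger.info("complete-case filter kept %d of %d records (dropped %d)",
                len(kept), len(df), dropped)
    return kept.reset_index(drop=True), dropped


def build_design_matrix(df: pd.DataFrame, require_outcome: bool = True) -> DesignMatrix:
    """Build the regression design matrix with fixed column order.

    Coding: intercept; one 0/1 dummy per non-reference level of each
    covariate (reference levels are the first entries of :data:`LEVELS`);
    the survey year as the quantitative code 1–4; and the product of the
    year code with the rural indicator as the final interaction column.
    """
    if len(df) == 0:
        raise ValueError("cannot build a design matrix from an empty record list")
    cols = [c for c in ANALYSIS_COLUMNS if require_outcome or c != OUTCOME]
    if df[cols].isna().any().any():
        raise ValueError("design matrix requires complete cases; run complete_case_filter first")
    single = [c for c in COVARIATES if df[c].nunique() < 2]
    if single and len(df) > 1:
        logger.warning("covariate(s) with a single observed level: %s "
                       "(their dummy columns will be constant)", single)

    n = len(df)
    X = np.empty((n, len(DESIGN_COLUMNS)))
    X[:, 0] = 1.0
    for j, (cov, level) in enumerate(_DUMMIES, start=1):
        X[:, j] = (df[cov] == level).to_numpy(dtype=float)
    year_code = df[YEAR].map(YEAR_CODE).to_numpy(dtype=float)
    rural = (df["residence"] == "rural").to_numpy(dtype=float)
    X[:, -2] = year_code
    X[:, -1] = year_code * rural

    y = None
    if require_outcome:
        y = df[OUTCOME].to_numpy(dtype=int)
        if (y < 0).any():
            raise ValueError("outcome contains negative counts")
    return DesignMatrix(
        y=y,
        X=X,
        column_labels=list(DESIGN_COLUMNS),
        reference_map={cov: levels[0] for cov, levels in LEVELS.items()},
        year_code=year_code,
    )
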