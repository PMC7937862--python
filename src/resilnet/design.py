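"""Shared term algebra for the resilience model design matrix.

The resilience model relates a longitudinal cognitive outcome (COG) to time
from baseline (T), baseline pathology measures (PATH: amyloid PET, CSF tau,
white-matter hyperintensity volume) and a candidate resilience factor (RES:
structural network efficiency):

    COG ~ T + PATH + RES + T*PATH + T*RES + T*RES*PATH + RES*PATH
          + covariates (age, gender, education, APOE4)

All continuous variables are z-scored on full analysis-sample moments before
interactions are formed, so interaction columns are products of standardized
components and fitted coefficients are standardized regression coefficients.
Binary covariates are coded 0/1 and left unscaled.

Both the synthetic generator and the inference preprocessing build their
design columns through this module, which guarantees that the generative
model and the fitted model agree term by term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# factor name -> standardized analysis column
FACTOR_COLUMNS = {
    "T": "t_z",
    "RES": "sne_z",
    "AV45": "av45_z",
    "TAU": "tau_z",
    "WMHV": "wmhv_z",
    "AGE": "age_z",
    "EDUC": "educ_z",
    "GENDER": "gender",
    "APOE4": "apoe4",
}

PATHOLOGIES = ("AV45", "TAU", "WMHV")

#: fixed terms present in every model of the selection group
BASE_TERMS = (
    "1",
    "T",
    "RES",
    "AV45",
    "TAU",
    "WMHV",
    "T*AV45",
    "T*TAU",
    "T*WMHV",
    "RES*AV45",
    "RES*TAU",
    "RES*WMHV",
    "AGE",
    "GENDER",
    "EDUC",
    "APOE4",
)

#: resilience terms toggled on/off during model-group enumeration, in
#: canonical order: general resilience, then pathology-dependent terms
RESILIENCE_TERMS = ("T*RES", "T*RES*AV45", "T*RES*TAU", "T*RES*WMHV")

OUTCOMES = ("adas_cog", "cdr_sob", "mmse")


def zscore(x: np.ndarray | pd.Series) -> np.ndarray:
    """Standardize with sample (ddof=1) moments; constant input is an error."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot z-score a constant or degenerate column")
    return (x - x.mean()) / sd


def term_factors(term: str) -> tuple[str, ...]:
    """Parse a term label like ``"T*RES*AV45"`` into its factors."""
    if term == "1":
        return ()
    return tuple(term.split("*"))


def term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    """Evaluate one model term as the product of its factor columns."""
    factors = term_factors(term)
    if not factors:
        return np.ones(len(df))
    col = np.ones(len(df))
    for f in factors:
        try:
            col = col * df[FACTOR_COLUMNS[f]].to_numpy(dtype=float)
        except KeyError as exc:
            raise KeyError(f"unknown factor or missing column for term {term!r}") from exc
    return col


def build_design(df: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    """Stack model terms into an n x p design matrix (column order = terms)."""
    return np.column_stack([term_column(df, t) for t in terms])


def wmhv_predictor(wmhv: np.ndarray, tiv: np.ndarray) -> np.ndarray:
    """TIV-normalized, log-transformed WMHV: ``log(WMHV / TIV)``.

    Raises on nonpositive volumes (the log is undefined there).
    """
    wmhv = np.asarray(wmhv, dtype=float)
    tiv = np.asarray(tiv, dtype=float)
    bad = ~((wmhv > 0) & (tiv > 0))
    if bad.any():
        raise ValueError(f"nonpositive WMHV or TIV in {int(bad.sum())} row(s)")
    return np.log(wmhv / tiv)


def standardize_baseline(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add z-scored baseline predictor columns to a subject-level table.

    Baseline variables are standardized at the subject level (one row per
    subject) so that subjects with more visits do not get extra weight in
    the moments.
    """
    out = cohort.copy()
    out["sne_z"] = zscore(out["sne"])
    out["av45_z"] = zscore(out["av45"])
    out["tau_z"] = zscore(out["tau"])
    out["wmhv_z"] = zscore(wmhv_predictor(out["wmhv"], out["tiv"]))
    out["age_z"] = zscore(out["age"])
    out["educ_z"] = zscore(out["education"])
    out["gender"] = out["gender"].astype(int)
    out["apoe4"] = out["apoe4"].astype(int)
    return out
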