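"""Resilience inference: mixed-model group selection and significance testing.

Pipeline, per cognitive outcome:

1. preprocess the baseline/visit tables (ADAS-cog inversion, WMHV
   log-ratio transform, exclusion of subjects with fewer than two visits,
   z-scoring on full analysis-sample moments);
2. enumerate the 16-member model group toggling the four resilience terms
   (T*RES and T*RES*PATH for the three pathology measures) on a fixed base
   model with random intercepts for subject and clinical status;
3. rank models by conditional AIC; models within delta-cAIC < 2 of the best
   are retained;
4. test only the resilience terms common to all retained models, with a
   maximum-likelihood likelihood-ratio test and a parametric bootstrap;
5. pool the term p-values across outcomes and control the false discovery
   rate with Benjamini-Hochberg at q = 0.05.

The report mirrors a per-outcome, per-term table of standardized
coefficients, chi-square statistics and p-values, plus marginal R-squared
and variance-inflation diagnostics of each best model.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

from . import design
from .lmm import (
    ConvergenceError,
    LmmError,
    LmmFit,
    LmmWorkspace,
    conditional_aic,
    marginal_r2,
    simulate_from_fit,
)

__all__ = [
    "preprocess",
    "ModelSpec",
    "enumerate_models",
    "fit_lmm",
    "select_retained",
    "common_resilience_terms",
    "lrt_test",
    "parametric_bootstrap_p",
    "BootstrapResult",
    "bh_fdr",
    "vif",
    "descriptives",
    "run_resilience_analysis",
    "ResilienceReport",
]

LOGLIK_TOL = 1e-6


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(cohort: pd.DataFrame, visits: pd.DataFrame):
    """Join, transform and standardize the analysis tables.

    Applies the analysis conventions: ADAS-cog is sign-inverted so that
    higher means better performance; WMHV becomes ``log(WMHV / TIV)``;
    subjects with fewer than two visits are excluded; continuous predictors
    and outcomes are z-scored on full analysis-sample moments (baseline
    variables at the subject level, time and outcomes at the visit level).

    Returns ``(analysis_table, info)`` where ``info`` records dropped
    subjects and sample sizes.
    """
    orphan = set(visits["subject_id"]) - set(cohort["subject_id"])
    if orphan:
        raise ValueError(f"visits reference unknown subjects: {sorted(orphan)[:5]}")
    counts = visits.groupby("subject_id").size()
    keep_ids = counts[counts >= 2].index
    dropped = sorted(set(cohort["subject_id"]) - set(keep_ids))
    cohort_kept = cohort[cohort["subject_id"].isin(keep_ids)].reset_index(drop=True)
    if len(cohort_kept) < 2:
        raise ValueError("fewer than two subjects with >= 2 visits")
    visits_kept = visits[visits["subject_id"].isin(keep_ids)].reset_index(drop=True)

    base = design.standardize_baseline(cohort_kept)
    df = visits_kept.merge(base, on="subject_id", how="left", validate="many_to_one")
    df["t_z"] = design.zscore(df["months"])
    for outcome in design.OUTCOMES:
        if outcome not in df.columns:
            continue
        raw = df[outcome].to_numpy(dtype=float)
        if outcome == "adas_cog":  # higher raw score = worse performance
            raw = -raw
        df[outcome + "_z"] = design.zscore(raw)
    df["subject_code"] = pd.Categorical(
        df["subject_id"], categories=cohort_kept["subject_id"]
    ).codes
    df["status_code"] = (df["status"].to_numpy() == "MCI").astype(int)
    info = {
        "n_subjects": int(len(cohort_kept)),
        "n_visits": int(len(df)),
        "dropped_subjects": dropped,
    }
    return df, info


# ---------------------------------------------------------------------------
# model group
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect specification within the resilience model group.

    Every spec shares the base terms (intercept, T, RES, the three
    pathology mains, T*PATH, RES*PATH, covariates); ``resilience`` toggles
    the subset of resilience terms present.  The three-way terms do not
    force T*RES in: the general-resilience term is a separately toggled
    hypothesis, while the two-way T*PATH / RES*PATH children of each
    three-way term are always in the base, so marginality over the base
    lattice holds for every member.
    """

    outcome: str
    resilience: frozenset = frozenset()

    def __post_init__(self):
        extra = set(self.resilience) - set(design.RESILIENCE_TERMS)
        if extra:
            raise ValueError(f"unknown resilience terms: {sorted(extra)}")

    @property
    def terms(self) -> tuple:
        return design.BASE_TERMS + tuple(
            t for t in design.RESILIENCE_TERMS if t in self.resilience
        )

    @property
    def outcome_column(self) -> str:
        return self.outcome + "_z"

    def without(self, term: str) -> "ModelSpec":
        if term not in self.resilience:
            raise ValueError(f"{term} not in spec")
        return ModelSpec(self.outcome, self.resilience - {term})

    def label(self) -> str:
        toggles = "+".join(t for t in design.RESILIENCE_TERMS if t in self.resilience)
        return f"{self.outcome} ~ base" + (f" + {toggles}" if toggles else "")


def enumerate_models(outcome: str) -> list[ModelSpec]:
    """All 16 on/off combinations of the four resilience terms."""
    specs = []
    for r in range(len(design.RESILIENCE_TERMS) + 1):
        for combo in itertools.combinations(design.RESILIENCE_TERMS, r):
            specs.append(ModelSpec(outcome, frozenset(combo)))
    return specs


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def make_workspace(
    spec: ModelSpec, data: pd.DataFrame, status_random: bool = True
) -> LmmWorkspace:
    X = design.build_design(data, spec.terms)
    factors = [data["subject_code"].to_numpy()]
    if status_random:
        factors.append(data["status_code"].to_numpy())
    return LmmWorkspace(X, factors)


def fit_lmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    criterion: str = "ML",
    status_random: bool = True,
    start: np.ndarray | None = None,
    workspace: LmmWorkspace | None = None,
) -> LmmFit:
    """Fit one model of the group by (restricted) maximum likelihood.

    ``status_random`` demotes the two-level clinical-status intercept to
    nothing when False (status enters only through the random structure by
    default; the base fixed terms are unchanged either way).
    """
    ws = workspace if workspace is not None else make_workspace(spec, data, status_random)
    fit = ws.fit(data[spec.outcome_column].to_numpy(), criterion=criterion, start=start)
    fit.spec = spec
    fit.terms = spec.terms
    return fit


def select_retained(fits: Sequence[LmmFit]):
    """cAIC ranking: best model plus all fits with delta-cAIC < 2.

    Non-converged fits are excluded (with a warning).  Ties on cAIC break
    toward the model with fewer toggled resilience terms.
    """
    usable = [f for f in fits if f.converged]
    if len(usable) < len(list(fits)):
        warnings.warn(
            f"{len(list(fits)) - len(usable)} non-converged fit(s) excluded "
            "from cAIC selection"
        )
    if not usable:
        raise ConvergenceError("no converged fits to select from")
    for f in usable:
        if "caic" not in f.extra:
            f.extra["caic"] = conditional_aic(f)
    usable = sorted(
        usable, key=lambda f: (f.extra["caic"], len(f.spec.resilience))
    )
    best = usable[0]
    retained = [f for f in usable if f.extra["caic"] - best.extra["caic"] < 2.0]
    return best, retained


def common_resilience_terms(retained: Sequence[LmmFit]) -> list[str]:
    """Resilience terms present in every retained model (canonical order)."""
    if not retained:
        raise ValueError("empty retained set")
    common = set(design.RESILIENCE_TERMS)
    for f in retained:
        common &= f.spec.resilience
    return [t for t in design.RESILIENCE_TERMS if t in common]


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------

def lrt_test(full: LmmFit, reduced: LmmFit):
    """Likelihood-ratio test of nested ML fits.

    Returns ``(chi2, df, p)`` with the statistic clipped at zero and the
    p-value from the chi-square upper tail at df = difference in
    fixed-effect count.  If the full model's optimizer landed marginally
    below the reduced one, the full model is refit warm-started from the
    reduced variance ratios before the statistic is formed.
    """
    if full.criterion != "ML" or reduced.criterion != "ML":
        raise LmmError("fixed-effect LRT requires ML fits")
    if full.terms is None or reduced.terms is None or not (
        set(reduced.terms) <= set(full.terms)
    ):
        raise LmmError("reduced model is not nested in the full model")
    df = full.p - reduced.p
    if df <= 0:
        raise LmmError("full model has no extra fixed effects")
    llf, llr = full.loglik, reduced.loglik
    if llf < llr:
        refit = full.workspace.fit(full.y, "ML", start=reduced.gamma)
        llf = max(llf, refit.loglik)
    chi2 = max(0.0, 2.0 * (llf - llr))
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass
class BootstrapResult:
    """Parametric-bootstrap LRT p-value and bookkeeping."""

    p: float
    lrt_observed: float
    df: int
    n_exceed: int
    n_effective: int
    n_dropped: int


def parametric_bootstrap_p(
    full_spec: ModelSpec,
    reduced_spec: ModelSpec,
    data: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
    status_random: bool = True,
) -> BootstrapResult:
    """Parametric-bootstrap p-value for the LRT of nested model specs.

    ``B`` datasets are simulated from the reduced fit's estimated fixed
    effects and variance components; both models are refit on each (warm
    started at the generating variance ratios) and the p-value is
    ``(1 + #{LRT* >= LRT_obs}) / (B + 1)``.  Replicates where either refit
    fails to converge are dropped and counted; a warning is raised if more
    than 10% drop.  Deterministic given the seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not (set(reduced_spec.terms) <= set(full_spec.terms)):
        raise LmmError("reduced spec is not nested in the full spec")
    ws_full = make_workspace(full_spec, data, status_random)
    ws_red = make_workspace(reduced_spec, data, status_random)
    y = data[full_spec.outcome_column].to_numpy()
    fit_full = ws_full.fit(y, "ML")
    fit_red = ws_red.fit(y, "ML")
    fit_full.terms, fit_red.terms = full_spec.terms, reduced_spec.terms
    chi2_obs, df, _ = lrt_test(fit_full, fit_red)

    rng = np.random.default_rng(seed)
    n_exceed = n_dropped = 0
    kept = 0
    # replicate refits are warm-started at the generating variance ratios;
    # slightly relaxed optimizer tolerances cost < 1e-5 in log-likelihood
    tol = {"xatol": 1e-3, "fatol": 1e-7}
    for _ in range(B):
        y_star = simulate_from_fit(fit_red, rng)
        bf = ws_full.fit(y_star, "ML", start=fit_red.gamma, **tol)
        br = ws_red.fit(y_star, "ML", start=fit_red.gamma, **tol)
        if not (bf.converged and br.converged):
            n_dropped += 1
            continue
        llf = bf.loglik
        if llf < br.loglik:
            llf = max(llf, ws_full.fit(y_star, "ML", start=br.gamma, **tol).loglik)
        kept += 1
        if 2.0 * max(0.0, llf - br.loglik) >= chi2_obs - 1e-12:
            n_exceed += 1
    if B and n_dropped > 0.1 * B:
        warnings.warn(f"{n_dropped}/{B} bootstrap replicates dropped (non-convergence)")
    if kept == 0:
        raise ConvergenceError("all bootstrap replicates failed to converge")
    p = (1.0 + n_exceed) / (kept + 1.0)
    return BootstrapResult(
        p=float(p), lrt_observed=chi2_obs, df=df,
        n_exceed=n_exceed, n_effective=kept, n_dropped=n_dropped,
    )


def bh_fdr(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions at FDR level q."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def vif(X: np.ndarray, names: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factors for each non-constant design column.

    ``VIF_j = 1 / (1 - R2_j)`` from regressing column j on the remaining
    columns; constant (intercept) columns are excluded from scoring but
    kept in the regressions.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two predictors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    out = {}
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            continue  # intercept / constant column
        out[names[j]] = float(variance_inflation_factor(X, j))
    return pd.Series(out)


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

_CONTINUOUS_DESC = ("age", "education", "sne", "av45", "tau", "wmhv")
_CATEGORICAL_DESC = ("gender", "apoe4")


def descriptives(cohort: pd.DataFrame, visits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group-comparison summary (CN vs MCI), one row per variable.

    Continuous variables: mean and SD per group plus a two-sided
    Mann-Whitney p-value; binary variables: group proportions plus a
    continuity-corrected Pearson chi-squared p-value.  If a visit table is
    given, baseline (first-visit) cognitive scores are summarized too.
    """
    groups = cohort.groupby("status")
    sizes = groups.size()
    if not {"CN", "MCI"} <= set(sizes.index) or (sizes < 2).any():
        raise ValueError("need both CN and MCI groups with >= 2 members")
    df = cohort.copy()
    if visits is not None:
        first = visits.sort_values("months").groupby("subject_id").first()
        df = df.merge(
            first[[c for c in design.OUTCOMES if c in first.columns]],
            left_on="subject_id", right_index=True, how="left",
        )
    rows = []
    cont = [c for c in _CONTINUOUS_DESC + design.OUTCOMES if c in df.columns]
    for var in cont:
        cn = df.loc[df["status"] == "CN", var].dropna()
        mci = df.loc[df["status"] == "MCI", var].dropna()
        _, p = stats.mannwhitneyu(cn, mci, alternative="two-sided", method="asymptotic")
        rows.append({
            "variable": var, "test": "mann-whitney",
            "cn_mean": cn.mean(), "cn_sd": cn.std(ddof=1),
            "mci_mean": mci.mean(), "mci_sd": mci.std(ddof=1),
            "total_mean": df[var].mean(), "total_sd": df[var].std(ddof=1),
            "p_value": float(p),
        })
    for var in _CATEGORICAL_DESC:
        if var not in df.columns:
            continue
        table = pd.crosstab(df[var], df["status"]).reindex(
            index=[1, 0], columns=["CN", "MCI"], fill_value=0
        )
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=True)
        rows.append({
            "variable": var, "test": "chi-squared",
            "cn_mean": df.loc[df["status"] == "CN", var].mean(), "cn_sd": np.nan,
            "mci_mean": df.loc[df["status"] == "MCI", var].mean(), "mci_sd": np.nan,
            "total_mean": df[var].mean(), "total_sd": np.nan,
            "p_value": float(p),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

_DISPLAY = {"RES": "SNE"}


def _display_term(term: str) -> str:
    return "*".join(_DISPLAY.get(f, f) for f in design.term_factors(term))


@dataclass
class ResilienceReport:
    """Per-outcome, per-resilience-term results plus model diagnostics."""

    table: pd.DataFrame
    best_models: dict
    retained: dict
    marginal_r2: dict
    vif: dict
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "results": self.table.to_dict(orient="records"),
            "best_models": self.best_models,
            "retained": self.retained,
            "marginal_r2": self.marginal_r2,
            "vif": {k: v.to_dict() for k, v in self.vif.items()},
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_resilience_analysis(
    cohort: pd.DataFrame,
    visits: pd.DataFrame,
    outcomes: Sequence[str] = design.OUTCOMES,
    B: int = 1000,
    q: float = 0.05,
    seed: int | None = None,
    status_random: bool = True,
) -> ResilienceReport:
    """End-to-end resilience analysis over the cognitive outcomes.

    For each outcome: fit the 16-member model group by ML, rank by cAIC,
    retain delta-cAIC < 2, and test the resilience terms common to all
    retained models with the LRT and a B-replicate parametric bootstrap
    (full model = best model; reduced = best minus the tested term).  Term
    p-values (LRT) are pooled across outcomes into one Benjamini-Hochberg
    family at rate ``q``.  Deterministic given the seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    data, info = preprocess(cohort, visits)
    rng = np.random.default_rng(seed)
    rows = []
    best_models, retained_out, r2_out, vif_out = {}, {}, {}, {}
    n_nonconverged = 0
    for outcome in outcomes:
        specs = enumerate_models(outcome)
        fits = [fit_lmm(s, data, "ML", status_random=status_random) for s in specs]
        n_nonconverged += sum(not f.converged for f in fits)
        best, retained = select_retained(fits)
        best_models[outcome] = {
            "resilience_terms": [_display_term(t) for t in sorted(best.spec.resilience)],
            "caic": best.extra["caic"],
            "loglik": best.loglik,
        }
        retained_out[outcome] = [
            {
                "resilience_terms": [_display_term(t) for t in sorted(f.spec.resilience)],
                "delta_caic": f.extra["caic"] - best.extra["caic"],
            }
            for f in retained
        ]
        r2_out[outcome] = marginal_r2(best)
        vif_out[outcome] = vif(
            best.workspace.X, names=[_display_term(t) for t in best.spec.terms]
        )
        fits_by_res = {f.spec.resilience: f for f in fits if f.converged}
        for term in common_resilience_terms(retained):
            reduced_spec = best.spec.without(term)
            reduced = fits_by_res[reduced_spec.resilience]
            chi2, dfree, p_lrt = lrt_test(best, reduced)
            boot = parametric_bootstrap_p(
                best.spec, reduced_spec, data, B=B,
                seed=int(rng.integers(2**31 - 1)), status_random=status_random,
            )
            idx = best.spec.terms.index(term)
            rows.append({
                "outcome": outcome,
                "term": _display_term(term),
                "std_beta": float(best.beta[idx]),
                "se": float(best.se[idx]),
                "chi2": chi2,
                "df": dfree,
                "p_lrt": p_lrt,
                "p_boot": boot.p,
                "boot_dropped": boot.n_dropped,
            })
    table = pd.DataFrame(
        rows,
        columns=["outcome", "term", "std_beta", "se", "chi2", "df",
                 "p_lrt", "p_boot", "boot_dropped"],
    )
    if len(table):
        table["fdr_reject"] = bh_fdr(table["p_lrt"].to_numpy(), q=q)
    else:
        table["fdr_reject"] = pd.Series(dtype=bool)
    metadata = {
        "seed": seed, "B": B, "q": q, "outcomes": list(outcomes),
        "status_random": status_random,
        "n_nonconverged_fits": n_nonconverged, **info,
    }
    return ResilienceReport(
        table=table, best_models=best_models, retained=retained_out,
        marginal_r2=r2_out, vif=vif_out, metadata=metadata,
    )
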