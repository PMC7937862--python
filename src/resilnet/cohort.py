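"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of an elderly at-risk cohort (cognitively
normal and MCI participants) observed longitudinally: a baseline table of
demographics, pathology markers (amyloid PET SUVR, CSF total tau, WMHV) and
structural network efficiency, plus visit-level cognitive outcomes generated
from the resilience model

    COG ~ T + PATH + RES + T*PATH + T*RES + T*RES*PATH + RES*PATH + covariates
          + random intercepts (subject, clinical status) + Gaussian noise

with user-specified standardized coefficients, so every inference stage can
be validated against known parameters.  Baseline marginals default to the
cohort summary of the motivating study (n = 85; e.g. network efficiency
250.6 +/- 16.8, AV45 SUVR 1.19 +/- 0.22) and visits default to a 12-month
schedule over four years.

Continuous baseline variables are drawn from truncated normal distributions
(pathology markers are kept positive); this matches the published means and
SDs but not the visible skew of real tau/WMHV distributions.  Pathology
variables are independent by default; an optional correlation matrix can
couple them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import design
from .connectome import ConnectivityMatrix, DEFAULT_THRESHOLD, compute_sne

__all__ = [
    "CohortConfig",
    "TrueParameters",
    "CohortConfigError",
    "SneTargetError",
    "generate_baseline",
    "generate_connectome_with_target_sne",
    "generate_longitudinal",
    "simulate_cohort",
    "table2_preset",
    "default_base_betas",
]


class CohortConfigError(ValueError):
    """Invalid generator configuration."""


class SneTargetError(RuntimeError):
    """Target efficiency unreachable under integer/threshold constraints."""


#: baseline marginals (mean, SD, lower truncation, upper truncation)
_DEFAULT_MARGINALS = {
    "age": (72.6, 6.5, 45.0, 100.0),
    "education": (16.1, 2.7, 6.0, 26.0),
    "sne": (250.6, 16.8, 1.0, np.inf),
    "av45": (1.19, 0.22, 0.5, np.inf),
    "tau": (83.50, 52.68, 5.0, np.inf),
    "wmhv": (0.53, 0.49, 0.01, np.inf),
    # total intracranial volume (cm^3); not part of the published summary
    # table, set to a typical adult mean
    "tiv": (1400.0, 130.0, 900.0, np.inf),
}


@dataclass
class CohortConfig:
    """Cohort size, visit schedule, and baseline marginal moments."""

    n_subjects: int = 85
    visit_months: tuple = (0, 12, 24, 36, 48)
    marginals: Mapping[str, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_MARGINALS)
    )
    prop_female: float = 34 / 85
    prop_apoe4: float = 41 / 85
    prop_mci: float = 51 / 85
    dropout: float = 0.0  # per-visit drop probability after the 2nd visit
    pathology_corr: np.ndarray | None = None  # optional 3x3 (av45, tau, wmhv)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise CohortConfigError("n_subjects must be >= 2")
        if len(self.visit_months) < 2 or any(m < 0 for m in self.visit_months):
            raise CohortConfigError("need >= 2 nonnegative visit months")
        for name, spec in self.marginals.items():
            mean, sd = spec[0], spec[1]
            if not np.isfinite(mean):
                raise CohortConfigError(f"{name}: mean must be finite")
            if not (sd > 0):
                raise CohortConfigError(f"{name}: SD must be > 0")
        for pname, p in (
            ("prop_female", self.prop_female),
            ("prop_apoe4", self.prop_apoe4),
            ("prop_mci", self.prop_mci),
        ):
            if not (0.0 <= p <= 1.0):
                raise CohortConfigError(f"{pname} must be in [0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise CohortConfigError("dropout must be in [0, 1)")


def _truncated_normal(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_baseline(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a subject-level baseline table.

    Columns: subject_id, age, gender (1 = female), education, apoe4,
    status (CN/MCI), av45, tau, wmhv, tiv, sne.  Deterministic given the
    seed (argument overrides ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    out = {"subject_id": [f"S{i:04d}" for i in range(1, n + 1)]}
    # pad (mean, sd) or (mean, sd, lo) specs with default truncation bounds
    marg = {}
    for k, v in config.marginals.items():
        v = tuple(v)
        if len(v) == 2:
            v = v + (-np.inf, np.inf)
        elif len(v) == 3:
            v = v + (np.inf,)
        marg[k] = v
    for name in ("age", "education", "sne", "tiv"):
        mean, sd, lo, hi = marg[name]
        out[name] = _truncated_normal(mean, sd, lo, hi, n, rng)
    if config.pathology_corr is not None:
        corr = np.asarray(config.pathology_corr, dtype=float)
        zs = rng.multivariate_normal(np.zeros(3), corr, size=n)
        for j, name in enumerate(("av45", "tau", "wmhv")):
            mean, sd, lo, hi = marg[name]
            # Gaussian copula through the truncated-normal marginal
            u = stats.norm.cdf(zs[:, j])
            a, b = (lo - mean) / sd, (hi - mean) / sd
            out[name] = stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
    else:
        for name in ("av45", "tau", "wmhv"):
            mean, sd, lo, hi = marg[name]
            out[name] = _truncated_normal(mean, sd, lo, hi, n, rng)
    out["gender"] = (rng.random(n) < config.prop_female).astype(int)
    out["apoe4"] = (rng.random(n) < config.prop_apoe4).astype(int)
    out["status"] = np.where(rng.random(n) < config.prop_mci, "MCI", "CN")
    cols = [
        "subject_id", "age", "gender", "education", "apoe4", "status",
        "av45", "tau", "wmhv", "tiv", "sne",
    ]
    return pd.DataFrame(out)[cols]


def generate_connectome_with_target_sne(
    target_sne: float,
    n_nodes: int = 106,
    density: float = 0.3,
    seed: int | None = None,
    min_streamlines: int = DEFAULT_THRESHOLD,
    base_count_range: tuple = (3, 20),
    rel_tol: float = 0.02,
    base_counts: np.ndarray | None = None,
) -> ConnectivityMatrix:
    """Random connectome whose efficiency lands near ``target_sne``.

    Draws an Erdos-Renyi support at the requested density with integer
    counts (or uses ``base_counts`` if supplied), then rescales all counts
    by ``target / SNE(base)`` (exact under the linear-scaling property of
    the efficiency measure) and rounds.  A target equal to the base
    efficiency therefore returns the base matrix unchanged.  Raises
    :class:`SneTargetError` if rounding/threshold constraints leave the
    achieved efficiency more than ``rel_tol`` away from the target.
    """
    if not (target_sne > 0):
        raise CohortConfigError("target_sne must be > 0")
    if not (0 < density <= 1):
        raise CohortConfigError("density must be in (0, 1]")
    if base_counts is not None:
        counts = np.asarray(base_counts)
    else:
        rng = np.random.default_rng(seed)
        upper = np.triu(rng.random((n_nodes, n_nodes)) < density, k=1)
        counts = np.where(
            upper, rng.integers(base_count_range[0], base_count_range[1] + 1,
                                size=(n_nodes, n_nodes)), 0
        )
        counts = counts + counts.T
    base = ConnectivityMatrix(counts)
    base_sne = compute_sne(base).sne
    if base_sne <= 0:
        raise SneTargetError("base support has no edges; increase density")
    scale = target_sne / base_sne
    scaled = np.rint(counts * scale).astype(np.int64)
    scaled[(counts > 0) & (scaled < min_streamlines)] = min_streamlines
    scaled[counts == 0] = 0
    result = ConnectivityMatrix(scaled)
    achieved = compute_sne(result).sne
    if abs(achieved - target_sne) / target_sne > rel_tol:
        raise SneTargetError(
            f"achieved SNE {achieved:.3f} misses target {target_sne:.3f} "
            f"by more than {rel_tol:.0%} (integer/threshold constraints)"
        )
    return result


@dataclass
class TrueParameters:
    """Ground-truth generative parameters on the standardized scale.

    ``betas`` maps model-term labels (see :mod:`resilnet.design`) to fixed
    standardized coefficients; omitted terms are zero.  Random-intercept
    SDs apply to the subject and clinical-status factors; ``sd_resid`` is
    the residual SD.
    """

    betas: Mapping[str, float] = field(default_factory=dict)
    sd_subject: float = 0.5
    sd_status: float = 0.2
    sd_resid: float = 0.6

    def validate(self) -> None:
        for sd in (self.sd_subject, self.sd_status, self.sd_resid):
            if sd < 0:
                raise CohortConfigError("SDs must be >= 0")
        known = set(design.BASE_TERMS) | set(design.RESILIENCE_TERMS)
        unknown = set(self.betas) - known
        if unknown:
            raise CohortConfigError(f"unknown model terms: {sorted(unknown)}")

    def beta_vector(self, terms: Sequence[str]) -> np.ndarray:
        return np.array([float(self.betas.get(t, 0.0)) for t in terms])


def default_base_betas() -> dict:
    """Plausible standardized base-term effects for an at-risk elderly cohort:

    cognition declines with time, pathology lowers the level and steepens
    the decline, education and network efficiency raise the level, APOE4
    and age lower it.  Resilience terms are zero here; presets add them.
    """
    return {
        "T": -0.30,
        "RES": 0.10,
        "AV45": -0.20,
        "TAU": -0.15,
        "WMHV": -0.05,
        "T*AV45": -0.10,
        "T*TAU": -0.05,
        "T*WMHV": -0.02,
        "RES*AV45": 0.02,
        "RES*TAU": 0.02,
        "RES*WMHV": 0.0,
        "AGE": -0.10,
        "GENDER": 0.05,
        "EDUC": 0.10,
        "APOE4": -0.10,
    }


#: published standardized resilience-term estimates per cognitive outcome
_TABLE2_RESILIENCE = {
    "adas_cog": {"T*RES": -0.004, "T*RES*AV45": 0.088, "T*RES*TAU": -0.074},
    "cdr_sob": {
        "T*RES": 0.098,
        "T*RES*AV45": 0.276,
        "T*RES*TAU": -0.069,
        "T*RES*WMHV": -0.058,
    },
    "mmse": {"T*RES": 0.074, "T*RES*AV45": 0.024, "T*RES*TAU": -0.030},
}


def table2_preset(outcome: str, **overrides) -> TrueParameters:
    """Ground truth presetting the published resilience-term magnitudes.

    The resilience coefficients for ``outcome`` ('adas_cog', 'cdr_sob',
    'mmse') are set to the published standardized estimates on top of
    :func:`default_base_betas`; keyword overrides replace individual betas.
    """
    if outcome not in _TABLE2_RESILIENCE:
        raise CohortConfigError(f"unknown outcome {outcome!r}")
    betas = default_base_betas()
    betas.update(_TABLE2_RESILIENCE[outcome])
    betas.update(overrides)
    return TrueParameters(betas=betas)


def _visit_skeleton(cohort, visit_months, dropout, rng) -> pd.DataFrame:
    rows = []
    months = list(visit_months)
    for sid in cohort["subject_id"]:
        keep = months[:2] + [m for m in months[2:] if rng.random() >= dropout]
        rows.extend((sid, m) for m in keep)
    return pd.DataFrame(rows, columns=["subject_id", "months"])


def generate_longitudinal(
    cohort: pd.DataFrame,
    params: TrueParameters | Mapping[str, TrueParameters],
    outcomes: Sequence[str] = design.OUTCOMES,
    seed: int | None = None,
    visit_months: Sequence[float] = (0, 12, 24, 36, 48),
    dropout: float = 0.0,
) -> pd.DataFrame:
    """Generate a visit-level table of cognitive outcomes.

    For each subject and visit the outcome is the standardized linear
    predictor of the resilience model plus a subject random intercept, a
    clinical-status random intercept, and residual noise.  Predictors are
    standardized with the cohort's own sample moments — the same convention
    the inference preprocessing applies — so fitted standardized
    coefficients are directly comparable to the generating betas (up to the
    outcome's own scale).  The stored ``adas_cog`` column is negated
    relative to the model scale, mirroring the real instrument where higher
    ADAS-cog means worse performance; the analysis re-inverts it.

    ``params`` is one :class:`TrueParameters` for all outcomes or a mapping
    outcome -> parameters.  Deterministic given the seed.
    """
    if cohort.empty:
        raise CohortConfigError("cohort is empty")
    required = {"subject_id", "age", "gender", "education", "apoe4", "status",
                "av45", "tau", "wmhv", "tiv", "sne"}
    missing = required - set(cohort.columns)
    if missing:
        raise CohortConfigError(f"cohort table missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    base = design.standardize_baseline(cohort)
    visits = _visit_skeleton(cohort, visit_months, dropout, rng)
    df = visits.merge(base, on="subject_id", how="left", validate="many_to_one")
    df["t_z"] = design.zscore(df["months"])

    terms = tuple(design.BASE_TERMS) + tuple(design.RESILIENCE_TERMS)
    X = design.build_design(df, terms)
    sub_codes = pd.Categorical(
        df["subject_id"], categories=cohort["subject_id"]
    ).codes
    status_codes = (df["status"].to_numpy() == "MCI").astype(int)
    n_sub = len(cohort)

    out = visits.copy()
    for outcome in outcomes:
        p = params[outcome] if isinstance(params, Mapping) else params
        p.validate()
        lp = X @ p.beta_vector(terms)
        b_sub = rng.normal(0.0, p.sd_subject, n_sub) if p.sd_subject > 0 else np.zeros(n_sub)
        b_sta = rng.normal(0.0, p.sd_status, 2) if p.sd_status > 0 else np.zeros(2)
        eps = rng.normal(0.0, p.sd_resid, len(df)) if p.sd_resid > 0 else 0.0
        y = lp + b_sub[sub_codes] + b_sta[status_codes] + eps
        out[outcome] = -y if outcome == "adas_cog" else y
    return out


def simulate_cohort(
    config: CohortConfig,
    params: TrueParameters | Mapping[str, TrueParameters] | None = None,
    outcomes: Sequence[str] = design.OUTCOMES,
    seed: int | None = None,
):
    """Convenience wrapper: baseline + longitudinal tables in one call."""
    seed = config.seed if seed is None else seed
    if params is None:
        params = {o: table2_preset(o) for o in outcomes}
    cohort = generate_baseline(config, seed=seed)
    sub_seed = None if seed is None else seed + 1
    visits = generate_longitudinal(
        cohort, params, outcomes=outcomes, seed=sub_seed,
        visit_months=config.visit_months, dropout=config.dropout,
    )
    return cohort, visits
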