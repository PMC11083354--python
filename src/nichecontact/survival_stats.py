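"""Kaplan-Meier estimation, log-rank comparison, collinearity screening and
the two multivariable Cox proportional-hazards models.

Model A uses the relative tumor fractions in SVZ, SGZ and cortex; model B
swaps them for the minimal center-of-mass distances to SVZ and SGZ.  The two
are kept separate because fraction and distance for the same zone are, by
construction, strongly collinear; the screen below makes that explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io_core import CohortTable, ValidationError

MODEL_A = ["core_volume_mm3", "age_years", "resection_bin", "mgmt_bin", "kps",
           "multifocal_preop", "frac_svz_pct", "frac_sgz_pct", "frac_cortex_pct"]
MODEL_B = ["core_volume_mm3", "age_years", "resection_bin", "mgmt_bin", "kps",
           "multifocal_preop", "dist_svz_mm", "dist_sgz_mm"]


@dataclass
class KMResult:
    """Product-limit survival estimate for one stratum."""

    times: np.ndarray
    survival: np.ndarray
    median: float | None
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Per-covariate hazard ratios with 95% CIs from a fitted Cox model."""

    summary: pd.DataFrame       # coef, hr, ci_low, ci_high, p per covariate
    log_likelihood: float
    n: int
    n_events: int
    model: str = ""

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])


def km_estimate(times, events, label: str = "") -> KMResult:
    """Kaplan-Meier product-limit estimator with right censoring.

    The median is the earliest time with S(t) <= 0.5, None if the curve
    never reaches 0.5.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.size == 0:
        raise ValidationError("empty survival sample")
    if np.any(times < 0):
        raise ValidationError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or None)
    grid = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    below = np.where(surv <= 0.5)[0]
    median = float(grid[below[0]]) if below.size else None
    return KMResult(times=grid, survival=surv, median=median, label=label)


def logrank_p(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank test p-value (chi-square, 1 df)."""
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return float(res.p_value)


def collinearity_screen(covariates: pd.DataFrame, threshold: float = 0.7):
    """Pearson correlation screen over a covariate matrix.

    Returns ``(corr, flags)`` where flags is a list of
    ``(name_a, name_b, r)`` for |r| >= threshold, plus degenerate
    (constant) covariates flagged as ``(name, name, nan)``.
    """
    if covariates.shape[1] < 2:
        raise ValidationError("need at least two covariates to screen")
    num = covariates.astype(float)
    flags = []
    for col in num.columns:
        if num[col].std(ddof=0) == 0:
            flags.append((col, col, float("nan")))
    corr = num.corr()
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                flags.append((a, b, float(r)))
    return corr, flags


def _model_frame(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    df = cohort.merged if isinstance(cohort, CohortTable) else cohort.copy()
    # patients with unknown resection or unevaluated MGMT cannot enter models
    # that use those covariates; no imputation is attempted
    df = df[(df["resection"] != "unknown") & (df["mgmt"] != "not_evaluated")].copy()
    df["resection_bin"] = (df["resection"] == "resection").astype(float)
    df["mgmt_bin"] = (df["mgmt"] == "methylated").astype(float)
    if "multifocal_preop" in df.columns:
        df["multifocal_preop"] = df["multifocal_preop"].astype(float)
    return df


def fit_cox_model(cohort: CohortTable | pd.DataFrame, model: str = "B",
                  covariates: list[str] | None = None) -> CoxFit:
    """Fit one of the two multivariable proportional-hazards models.

    Model "A" uses zone fractions, model "B" zone distances; an explicit
    ``covariates`` list overrides both.  Ties are handled by Efron's method;
    non-convergence is raised, never silently swallowed.
    """
    df = _model_frame(cohort)
    if covariates is None:
        if model not in ("A", "B"):
            raise ValidationError("model must be 'A' or 'B'")
        covariates = MODEL_A if model == "A" else MODEL_B
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValidationError(f"missing covariates: {missing}")
    n_events = int(df["event"].sum())
    if n_events < len(covariates) + 5:
        raise ValidationError(
            f"too few events ({n_events}) for {len(covariates)} covariates"
        )
    fit_df = df[covariates + ["os_months", "event"]].astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col="os_months", event_col="event")
    except Exception as exc:   # lifelines raises ConvergenceError subclasses
        raise ValidationError(f"Cox model did not converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxFit(summary=summary, log_likelihood=float(cph.log_likelihood_),
                  n=len(fit_df), n_events=n_events, model=model)


def check_model_separation(cohort: CohortTable | pd.DataFrame,
                           threshold: float = 0.7) -> dict:
    """Pipeline-level assertion that neither model mixes a flagged pair.

    Screens the union of model A and B covariates and verifies that every
    flagged collinear pair is split across the two models (e.g. frac_svz_pct
    with dist_svz_mm).  Returns the flags; raises when a model contains a
    flagged pair internally.
    """
    df = _model_frame(cohort)
    cols = sorted(set(MODEL_A) | set(MODEL_B))
    _, flags = collinearity_screen(df[cols], threshold)
    for a, b, r in flags:
        if a == b:
            continue
        for name, cov in (("A", MODEL_A), ("B", MODEL_B)):
            if a in cov and b in cov:
                raise ValidationError(
                    f"model {name} contains collinear pair ({a}, {b}, r={r:.2f})"
                )
    return {"flags": flags}
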