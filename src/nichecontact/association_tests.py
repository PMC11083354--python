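"""Contact-group association tests and the grouped summary table.

The cohort is split by binary contact with each zone (SVZ, SGZ, cortex) and
compared on clinical variables: 2x2 contingency chi-square with a clamped
continuity correction for categorical variables (seizures, multifocality,
MGMT methylation, Ki-67 category, with not-evaluated rows excluded from the
molecular tests), Mann-Whitney U for the ordinal KPS score, and log-rank /
Kaplan-Meier medians for overall survival.

The continuity correction shrinks each |O - E| toward zero by
min(0.5, |O - E|) before squaring, so cells already closer than 0.5 to
their expectation contribute exactly zero — a nearly independent table
yields statistic 0 and p = 1 rather than a spurious positive statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CohortTable, ValidationError
from .survival_stats import km_estimate, logrank_p


@dataclass
class ContingencyResult:
    """Continuity-corrected 2x2 chi-square outcome."""

    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    p: float
    correction: np.ndarray      # per-cell correction magnitude applied
    df: int = 1


def chi2_2x2_corrected(counts) -> ContingencyResult:
    """2x2 contingency chi-square with clamped Yates continuity correction.

    statistic = sum over cells of (max(|O - E| - min(0.5, |O - E|), 0))^2 / E,
    referred to the chi-square law with one degree of freedom.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0) or not np.allclose(obs, np.rint(obs)):
        raise ValidationError("counts must be non-negative integers")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValidationError("both margins must be positive")
    expected = row @ col / n
    dev = np.abs(obs - expected)
    correction = np.minimum(0.5, dev)
    stat = float((np.maximum(dev - correction, 0.0) ** 2 / expected).sum())
    return ContingencyResult(
        observed=obs.astype(int), expected=expected, statistic=stat,
        p=float(stats.chi2.sf(stat, 1)), correction=correction,
    )


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U with midrank tie handling, two-sided p.

    Small tie-free samples get the exact null distribution; otherwise the
    normal approximation with tie-corrected variance and continuity
    correction is used.  A comparison with zero rank variance (all values
    identical) reports p = 1 with a warning.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all values identical across groups; p set to 1")
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Generic two-sample Welch t test (unequal variances), two-sided."""
    res = stats.ttest_ind(np.asarray(group_a, float), np.asarray(group_b, float),
                          equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupSummary:
    """Per-zone contact-vs-no-contact summary with test p-values."""

    zone: str
    n_contact: int
    n_no_contact: int
    rows: pd.DataFrame          # variable, contact value, no-contact value, p
    skipped: list = field(default_factory=list)


def _contingency_from_flags(df, flag_col, var_col, positive) -> np.ndarray | None:
    """2x2 counts (contact status x variable), None on an empty margin."""
    counts = np.array([
        [int(((df[flag_col]) & (df[var_col] == positive)).sum()),
         int(((df[flag_col]) & (df[var_col] != positive)).sum())],
        [int((~df[flag_col] & (df[var_col] == positive)).sum()),
         int((~df[flag_col] & (df[var_col] != positive)).sum())],
    ])
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        return None
    return counts


def build_group_summary(cohort: CohortTable | pd.DataFrame, zone: str) -> GroupSummary:
    """Summarize and test one zone's contact split.

    Chi-square (clamped continuity correction) on seizures and
    multifocality; the same on MGMT and Ki-67 with ``not_evaluated`` rows
    excluded; Mann-Whitney on KPS; log-rank with KM medians for OS.  Tests
    whose split is degenerate (empty subgroup or margin) are skipped and
    listed explicitly.
    """
    if zone not in ("svz", "sgz", "cortex"):
        raise ValidationError(f"unknown zone {zone!r}")
    df = cohort.merged if isinstance(cohort, CohortTable) else cohort
    flag = f"contact_{zone}"
    contact = df[df[flag].astype(bool)]
    no_contact = df[~df[flag].astype(bool)]

    rows, skipped = [], []

    def add(variable, val_c, val_nc, p):
        rows.append({"variable": variable, "contact": val_c,
                     "no_contact": val_nc, "p": p})

    if len(contact) == 0 or len(no_contact) == 0:
        skipped = ["all tests: one contact subgroup is empty"]
        for variable in ("os_median", "multifocal_preop", "multifocal_total",
                         "mgmt_methylated", "ki67_gt30", "kps_median", "seizures"):
            add(variable, None, None, None)
        return GroupSummary(zone=zone, n_contact=len(contact),
                            n_no_contact=len(no_contact),
                            rows=pd.DataFrame(rows), skipped=skipped)

    km_c = km_estimate(contact["os_months"], contact["event"], label="contact")
    km_nc = km_estimate(no_contact["os_months"], no_contact["event"], label="no contact")
    p_os = logrank_p(contact["os_months"], contact["event"],
                     no_contact["os_months"], no_contact["event"])
    add("os_median", km_c.median, km_nc.median, p_os)

    dfb = df.assign(**{flag: df[flag].astype(bool)})
    for variable, col, positive in (
        ("multifocal_preop", "multifocal_preop", True),
        ("multifocal_total", "multifocal_total", True),
        ("seizures", "preop_seizures", True),
    ):
        counts = _contingency_from_flags(dfb, flag, col, positive)
        if counts is None:
            skipped.append(variable)
            add(variable, int(contact[col].sum()), int(no_contact[col].sum()), None)
        else:
            res = chi2_2x2_corrected(counts)
            add(variable, int(counts[0, 0]), int(counts[1, 0]), res.p)

    for variable, col, positive in (("mgmt_methylated", "mgmt", "methylated"),
                                    ("ki67_gt30", "ki67", "gt30")):
        sub = dfb[dfb[col] != "not_evaluated"]
        counts = _contingency_from_flags(sub, flag, col, positive)
        if counts is None:
            skipped.append(variable)
            add(variable, None, None, None)
        else:
            res = chi2_2x2_corrected(counts)
            add(variable, int(counts[0, 0]), int(counts[1, 0]), res.p)

    try:
        _, p_kps = mann_whitney_u(contact["kps"], no_contact["kps"])
    except ValidationError:
        p_kps, _ = None, skipped.append("kps")
    add("kps_median", float(contact["kps"].median()),
        float(no_contact["kps"].median()), p_kps)

    return GroupSummary(zone=zone, n_contact=len(contact),
                        n_no_contact=len(no_contact),
                        rows=pd.DataFrame(rows), skipped=skipped)
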