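"""Maximally selected rank statistics for survival cutpoints.

Given a continuous covariate x (e.g. minimal distance of the tumor's center
of mass to the SVZ) and a right-censored survival endpoint, every observed
covariate value within quantile bounds (eps_low, eps_high) is a candidate
cutpoint mu.  Each candidate splits the cohort into x <= mu versus x > mu;
the two groups are compared with the standardized log-rank statistic

    Z(mu) = (O - E) / sqrt(V)

where O, E and V come from the usual two-group log-rank decomposition over
risk sets with hypergeometric variance (tied event times reduce the risk set
simultaneously).  The selected cutpoint mu* maximizes |Z(mu)|; because the
maximum is taken over many correlated splits, the naive minimal p-value is
anti-conservative, and the reported p-value is instead Monte-Carlo adjusted:
the covariate is permuted across subjects B times, the maximal statistic M
is recomputed each time, and

    p = (1 + #{M_b >= M_obs}) / (B + 1).

The scan is O(events x candidates) per permutation via a linear-score
decomposition of O - E (the log-rank scores are the martingale residuals
delta_i - Nelson-Aalen(t_i)) and a 2D histogram for the per-candidate
risk-set counts that enter V.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import ValidationError


@dataclass
class MaxstatResult:
    """Outcome of a maximally-selected log-rank scan."""

    cutpoint: float
    max_stat: float
    p_adjusted: float | None
    per_cutpoint: np.ndarray          # (n_candidates, 2): candidate value, Z
    n_candidates: int
    settings: dict = field(default_factory=dict)


def candidate_cutpoints(x, eps_low: float = 0.1, eps_high: float = 0.9) -> np.ndarray:
    """Distinct observed values mu with eps_low <= mean(x <= mu) <= eps_high."""
    x = np.asarray(x, dtype=float)
    if not 0 < eps_low < eps_high < 1:
        raise ValidationError(f"need 0 < eps_low < eps_high < 1, got {eps_low}, {eps_high}")
    values = np.unique(x)
    frac_below = np.searchsorted(np.sort(x), values, side="right") / x.size
    keep = (frac_below >= eps_low) & (frac_below <= eps_high)
    candidates = values[keep]
    if candidates.size == 0:
        raise ValidationError("no admissible candidate cutpoint in the quantile bounds")
    return candidates


def _validate_survival(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape or times.ndim != 1:
        raise ValidationError("times and events must be 1D arrays of equal length")
    if np.any(times < 0):
        raise ValidationError("negative survival times")
    if not events.any():
        raise ValidationError("at least one event is required")
    return times, events


def logrank_standardized(times, events, group) -> float:
    """Standardized two-group log-rank statistic (O - E)/sqrt(V) for ``group``.

    ``group`` is the boolean indicator of group 1 (conventionally x <= mu);
    O, E and V refer to that group.  Ties are handled by reducing the risk
    set simultaneously at the tied event time; V uses the hypergeometric
    variance of the deaths among group-1 subjects at risk.
    """
    times, events = _validate_survival(times, events)
    group = np.asarray(group, dtype=bool)
    if not group.any() or group.all():
        raise ValidationError("degenerate grouping: one side is empty")

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        dead = events & (times == t)
        d = int(dead.sum())
        d1 = int((dead & group).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        raise ValidationError("log-rank variance is zero (no between-group information)")
    return o_minus_e / np.sqrt(var)


class _ScanEngine:
    """Precomputed risk-set structure for fast per-candidate log-rank scans.

    All arrays are laid out in time-sorted subject order; a scan for any
    assignment of covariate values to subjects only needs the candidate-bin
    index of each subject.
    """

    def __init__(self, times, events):
        times, events = _validate_survival(times, events)
        self.n = times.size
        self.order = np.argsort(times, kind="stable")
        t = times[self.order]
        e = events[self.order]

        uniq, first = np.unique(t, return_index=True)
        inv = np.searchsorted(uniq, t)
        deaths = np.bincount(inv, weights=e.astype(float), minlength=uniq.size)
        ev = deaths > 0
        self.event_times = uniq[ev]
        self.d = deaths[ev]                              # deaths per event time
        self.n_risk = self.n - first[ev].astype(float)   # at-risk totals
        # Nelson-Aalen at each subject's own time -> log-rank scores
        cumhaz = np.cumsum(self.d / self.n_risk)
        k_i = np.searchsorted(self.event_times, t, side="right") - 1
        lam = np.where(k_i >= 0, cumhaz[np.clip(k_i, 0, None)], 0.0)
        self.scores = e.astype(float) - lam              # time-sorted order
        # risk-set membership: subject i belongs to risk sets 0..k_last(i)
        self.k_last = np.searchsorted(self.event_times, t, side="right") - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = self.d * (self.n_risk - self.d) / ((self.n_risk - 1) * self.n_risk ** 2)
        self.var_coef = np.where(self.n_risk > 1, a, 0.0)
        self.n_event_times = self.event_times.size

    def stats(self, bins: np.ndarray, n_candidates: int) -> np.ndarray:
        """Standardized statistics for all candidates and P assignments.

        ``bins`` is (P, n) in time-sorted subject order: bins[p, i] = index of
        the smallest candidate >= x of subject i (== n_candidates when x is
        above every candidate, i.e. the subject is never in the low group).
        Returns (P, n_candidates).
        """
        P, n = bins.shape
        C = n_candidates
        K = self.n_event_times
        # O - E: cumulative sums of log-rank scores over candidate bins
        flat = (np.arange(P)[:, None] * (C + 1) + bins).ravel()
        num = np.bincount(flat, weights=np.broadcast_to(self.scores, (P, n)).ravel(),
                          minlength=P * (C + 1)).reshape(P, C + 1)
        o_minus_e = np.cumsum(num, axis=1)[:, :C]
        # V: per-candidate group sizes in every risk set via 2D histogram
        kl = np.clip(self.k_last, 0, None)
        flat2 = (np.arange(P)[:, None] * ((K + 1) * (C + 1))
                 + kl * (C + 1) + bins).ravel()
        in_any = (self.k_last >= 0).astype(float)        # subjects past all event times drop out
        hist = np.bincount(flat2, weights=np.broadcast_to(in_any, (P, n)).ravel(),
                           minlength=P * (K + 1) * (C + 1)).reshape(P, K + 1, C + 1)
        hist = np.cumsum(hist, axis=2)[:, :, :C]         # over candidate bins
        n1 = np.flip(np.cumsum(np.flip(hist, axis=1), axis=1), axis=1)[:, :K, :]
        var = np.einsum("k,pkc->pc", self.var_coef * self.n_risk ** 2,
                        (n1 / self.n_risk[None, :, None])
                        * (1 - n1 / self.n_risk[None, :, None]))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = o_minus_e / np.sqrt(var)
        return np.where(var > 0, z, 0.0)


def _bins_for(engine: _ScanEngine, x: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Candidate-bin index per subject, time-sorted order, shape (1, n)."""
    return np.searchsorted(candidates, x[engine.order], side="left")[None, :]


def maxstat_scan(x, times, events, candidates) -> np.ndarray:
    """Standardized log-rank statistic at every candidate cutpoint."""
    x = np.asarray(x, dtype=float)
    candidates = np.asarray(candidates, dtype=float)
    engine = _ScanEngine(times, events)
    return engine.stats(_bins_for(engine, x, candidates), candidates.size)[0]


def maxstat_cutpoint(x, times, events, eps_low: float = 0.1, eps_high: float = 0.9):
    """Select the cutpoint maximizing |Z|; ties resolved to the smallest mu.

    Returns ``(mu_star, max_stat, per_cutpoint)`` with ``per_cutpoint`` an
    (n_candidates, 2) array of (candidate, Z).
    """
    x = np.asarray(x, dtype=float)
    candidates = candidate_cutpoints(x, eps_low, eps_high)
    stats = maxstat_scan(x, times, events, candidates)
    best = int(np.argmax(np.abs(stats)))   # first max -> smallest candidate
    per_cutpoint = np.column_stack([candidates, stats])
    return float(candidates[best]), float(np.abs(stats[best])), per_cutpoint


def mc_adjusted_p(x, times, events, eps_low: float = 0.1, eps_high: float = 0.9,
                  B: int = 9999, seed: int | np.random.Generator = 0,
                  block: int = 16) -> float:
    """Monte-Carlo adjusted p-value for the maximally selected statistic.

    The covariate is permuted across subjects B times; p is the
    add-one-smoothed exceedance rate (1 + #{M_b >= M_obs}) / (B + 1).
    Subjects are canonically re-ordered before drawing permutations so the
    result does not depend on the input row order.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    canon = np.lexsort((x, events, times))
    x, times, events = x[canon], times[canon], events[canon]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    candidates = candidate_cutpoints(x, eps_low, eps_high)
    engine = _ScanEngine(times, events)
    C = candidates.size
    m_obs = np.abs(engine.stats(_bins_for(engine, x, candidates), C)[0]).max()

    bins_base = np.searchsorted(candidates, x, side="left")
    exceed = 0
    done = 0
    while done < B:
        p = min(block, B - done)
        perms = np.argsort(rng.random((p, x.size)), axis=1)
        bins = bins_base[perms][:, engine.order]
        m_b = np.abs(engine.stats(bins, C)).max(axis=1)
        exceed += int((m_b >= m_obs - 1e-12).sum())
        done += p
    return (1 + exceed) / (B + 1)


def maxstat_test(x, times, events, eps_low: float = 0.1, eps_high: float = 0.9,
                 B: int = 9999, seed: int | np.random.Generator = 0) -> MaxstatResult:
    """Full maximally-selected-rank-statistic analysis of one covariate."""
    mu, m, per_cutpoint = maxstat_cutpoint(x, times, events, eps_low, eps_high)
    p = mc_adjusted_p(x, times, events, eps_low, eps_high, B=B, seed=seed)
    return MaxstatResult(
        cutpoint=mu, max_stat=m, p_adjusted=p, per_cutpoint=per_cutpoint,
        n_candidates=per_cutpoint.shape[0],
        settings={"eps_low": eps_low, "eps_high": eps_high, "replicates": B},
    )
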