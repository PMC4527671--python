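"""Kaplan-Meier estimation, lifespan quantiles, and two-sample survival tests.

The experimental unit throughout is one fly: an age at death in days plus
group metadata (sex, absorbed dose in cGy, replicate).  Cohorts here are
fully followed to death, but every routine honours the event flag so that
right-censored records are handled correctly where the method permits.

Four two-sample tests are provided, matching standard lifespan practice:

* log-rank (Mantel-Cox) — overall survival-curve difference;
* Gehan-Breslow-Wilcoxon — weighted log-rank with weight equal to the pooled
  number at risk, emphasising early deaths (sensitive to median shifts);
* a Kolmogorov-Smirnov-type supremum test on the two Kaplan-Meier curves,
  which for uncensored data reduces exactly to the classical two-sample KS
  statistic;
* the Wang-Allison maximum-lifespan test: a Fisher exact test on the 2x2
  table of subjects dying at-or-before versus surviving beyond the pooled
  90th-percentile death age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import special, stats

__all__ = [
    "LifespanRecord",
    "SurvivalCurve",
    "TestResult",
    "km_estimate",
    "median_lifespan",
    "age_at_90pct_mortality",
    "quantile_age",
    "logrank",
    "gehan_breslow_wilcoxon",
    "modified_ks",
    "wang_allison",
]


@dataclass(frozen=True)
class LifespanRecord:
    """One animal: age at death (or censoring) in days plus group metadata."""

    subject_id: str
    sex: str
    dose_cgy: float
    replicate: str
    age_days: float
    event: bool = True

    def __post_init__(self) -> None:
        if self.age_days <= 0:
            raise ValueError(f"age_days must be > 0, got {self.age_days}")
        if self.dose_cgy < 0:
            raise ValueError(f"dose_cgy must be >= 0, got {self.dose_cgy}")


@dataclass
class SurvivalCurve:
    """Product-limit estimate over the distinct observed event times."""

    times: np.ndarray        # distinct death times, ascending
    survival: np.ndarray     # S(t) at each death time
    at_risk: np.ndarray      # number at risk just before each death time
    deaths: np.ndarray       # deaths at each death time
    n: int                   # total subjects

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class TestResult:
    """Outcome of a two-sample survival test."""

    name: str
    statistic: float
    p_value: float
    groups: tuple[str, str] = ("A", "B")
    df: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _ages_events(records: Iterable[LifespanRecord] | Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    if isinstance(records[0], LifespanRecord):
        ages = np.array([r.age_days for r in records], dtype=float)
        events = np.array([r.event for r in records], dtype=bool)
    else:
        ages = np.asarray(records, dtype=float)
        events = np.ones(len(ages), dtype=bool)
    if np.any(ages <= 0):
        raise ValueError("all ages must be > 0")
    return ages, events


def km_estimate(records: Iterable[LifespanRecord] | Sequence[float]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    Accepts either :class:`LifespanRecord` objects or bare death ages (all
    treated as events).  With no censoring the estimate equals the empirical
    survival fraction exactly.
    """
    ages, events = _ages_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(ages, event_observed=events)
    table = kmf.event_table
    death_rows = table[table["observed"] > 0]
    times = death_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(death_rows.index).to_numpy(dtype=float)
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=death_rows["at_risk"].to_numpy(dtype=float),
        deaths=death_rows["observed"].to_numpy(dtype=float),
        n=len(ages),
    )


def quantile_age(curve: SurvivalCurve, survival_threshold: float) -> float | None:
    """Smallest event time with S(t) <= threshold; None if never reached."""
    below = curve.survival <= survival_threshold + 1e-12
    if not below.any():
        return None
    return float(curve.times[int(np.argmax(below))])


def median_lifespan(curve: SurvivalCurve) -> float | None:
    """Median lifespan: smallest death age with S <= 0.5 (None if unreached)."""
    return quantile_age(curve, 0.5)


def age_at_90pct_mortality(curve: SurvivalCurve) -> float | None:
    """Age of 90% mortality ("maximum lifespan"): smallest age with S <= 0.1."""
    return quantile_age(curve, 0.1)


# ---------------------------------------------------------------------------
# weighted log-rank machinery (shared by log-rank and Gehan-Breslow-Wilcoxon)
# ---------------------------------------------------------------------------

def _weighted_logrank_z(ages_a, events_a, ages_b, events_b, weight: str) -> float:
    """Signed Z of a weighted log-rank test.

    weight='logrank' uses w=1; weight='gehan' uses w = pooled number at risk.
    Positive Z means group A dies earlier (observed deaths in A exceed
    expectation).
    """
    ages = np.concatenate([ages_a, ages_b])
    events = np.concatenate([events_a, events_b])
    is_a = np.concatenate([np.ones(len(ages_a), bool), np.zeros(len(ages_b), bool)])

    death_times = np.unique(ages[events])
    num = 0.0
    den = 0.0
    for t in death_times:
        at_risk = ages >= t
        n = at_risk.sum()
        n1 = (at_risk & is_a).sum()
        dying = at_risk & events & (ages == t)
        d = dying.sum()
        d1 = (dying & is_a).sum()
        if n <= 1 or d == 0:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
        w = float(n) if weight == "gehan" else 1.0
        num += w * (d1 - e1)
        den += w * w * v
    if den <= 0:
        return 0.0
    return num / math.sqrt(den)


def _two_sample_test(
    records_a, records_b, weight: str, name: str,
    groups=("A", "B"), method: str = "asymptotic", max_permutations: int = 200_000,
) -> TestResult:
    ages_a, events_a = _ages_events(records_a)
    ages_b, events_b = _ages_events(records_b)
    if not events_a.any() or not events_b.any():
        raise ValueError("each group must contain at least one event")
    z = _weighted_logrank_z(ages_a, events_a, ages_b, events_b, weight)

    if method == "asymptotic":
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(p, 1.0)
    elif method == "permutation":
        ages = np.concatenate([ages_a, ages_b])
        events = np.concatenate([events_a, events_b])
        n, na = len(ages), len(ages_a)
        if math.comb(n, na) > max_permutations:
            raise ValueError(
                f"exact permutation infeasible: C({n},{na}) > {max_permutations}"
            )
        count = 0
        total = 0
        for idx in combinations(range(n), na):
            sel = np.zeros(n, bool)
            sel[list(idx)] = True
            zp = _weighted_logrank_z(ages[sel], events[sel], ages[~sel], events[~sel], weight)
            if abs(zp) >= abs(z) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(name=name, statistic=float(z), p_value=p, groups=tuple(groups),
                      extra={"method": method})


def logrank(records_a, records_b, groups=("A", "B"), method="asymptotic") -> TestResult:
    """Log-rank (Mantel-Cox) test; signed Z, two-sided p."""
    return _two_sample_test(records_a, records_b, "logrank", "log-rank", groups, method)


def gehan_breslow_wilcoxon(records_a, records_b, groups=("A", "B"), method="asymptotic") -> TestResult:
    """Gehan-Breslow-Wilcoxon test (weight = pooled number at risk)."""
    return _two_sample_test(records_a, records_b, "gehan", "Gehan-Breslow-Wilcoxon", groups, method)


def modified_ks(records_a, records_b, groups=("A", "B")) -> TestResult:
    """Supremum (KS-type) distance between the two Kaplan-Meier curves.

    The statistic is D = sup_t |S_a(t) - S_b(t)| over the pooled event times,
    computed on the product-limit estimates so censored records contribute
    through the at-risk sets.  For uncensored data it equals the classical
    two-sample Kolmogorov-Smirnov statistic; the p-value uses the classical
    asymptotic Kolmogorov distribution with effective size
    n_a*n_b/(n_a+n_b) and Stephens' small-sample correction.
    """
    curve_a = km_estimate(records_a)
    curve_b = km_estimate(records_b)
    grid = np.union1d(curve_a.times, curve_b.times)
    d = max(abs(curve_a.survival_at(t) - curve_b.survival_at(t)) for t in grid)
    ne = curve_a.n * curve_b.n / (curve_a.n + curve_b.n)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
    p = float(np.clip(special.kolmogorov(lam), 0.0, 1.0))
    return TestResult(name="modified-KS", statistic=float(d), p_value=p, groups=tuple(groups))


def wang_allison(records_a, records_b, quantile: float = 0.9, groups=("A", "B")) -> TestResult:
    """Wang-Allison maximum-lifespan test.

    Threshold = smallest age by which at least `quantile` of the pooled sample
    has died.  The 2x2 table counts, per group, subjects dying at-or-before
    versus surviving beyond the threshold; p is the two-sided Fisher exact
    probability (sum of hypergeometric masses <= the observed table's mass).
    Requires fully observed (uncensored) data.
    """
    ages_a, events_a = _ages_events(records_a)
    ages_b, events_b = _ages_events(records_b)
    if not (events_a.all() and events_b.all()):
        raise ValueError("Wang-Allison test requires all-events (uncensored) data")
    pooled = np.sort(np.concatenate([ages_a, ages_b]))
    n = len(pooled)
    k = math.ceil(quantile * n)
    threshold = float(pooled[k - 1])
    table = np.array([
        [(ages_a <= threshold).sum(), (ages_a > threshold).sum()],
        [(ages_b <= threshold).sum(), (ages_b > threshold).sum()],
    ])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(
        name="Wang-Allison",
        statistic=float(table[0][1] / len(ages_a) - table[1][1] / len(ages_b)),
        p_value=float(p),
        groups=tuple(groups),
        extra={"threshold": threshold, "table": table.tolist(), "quantile": quantile},
    )
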