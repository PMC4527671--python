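"""Maximum-likelihood Gompertz mortality modelling.

The Gompertz hazard mu(x) = R0 * exp(alpha * x) gives, for fully observed
death ages x_i, the log-likelihood

    l(alpha, R0) = sum_i [ ln R0 + alpha*x_i - (R0/alpha)*(exp(alpha*x_i) - 1) ].

Fitting is done over (ln alpha, ln R0), so the positivity constraints are
implicit and the surface is well scaled; the optimizer is initialised from an
ordinary least-squares regression of the binned log-hazard on age.  The
recorded integer census day is treated as the exact death time, which is
adequate when the census interval (1 day) is small relative to the mortality
rate doubling time MRDT = ln(2)/alpha (7-9 days here).

Also provided: a binned-log-hazard R^2 as a goodness-of-fit summary, a
likelihood-ratio test for differences in mortality intensity between groups,
the Strehler-Mildvan regression ln R0 = gamma - beta*alpha across fits (with
externally studentized residual tests for deviation of single populations
from the line), and lifespan summary-table construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .survival import (
    LifespanRecord,
    TestResult,
    age_at_90pct_mortality,
    gehan_breslow_wilcoxon,
    km_estimate,
    logrank,
    median_lifespan,
    modified_ks,
    wang_allison,
)

__all__ = [
    "GompertzFit",
    "SMRegression",
    "LifespanSummary",
    "gompertz_loglik",
    "fit_gompertz_ml",
    "mrdt",
    "binned_log_hazard",
    "gompertz_r2",
    "lrt_mortality",
    "strehler_mildvan",
    "sm_deviation_test",
    "summarize_lifespan",
]


@dataclass
class GompertzFit:
    alpha: float
    r0: float
    loglik: float
    n: int
    converged: bool
    cov_log: np.ndarray | None = None  # covariance of (ln alpha, ln R0)


class ConvergenceError(RuntimeError):
    """Raised when a required maximum-likelihood fit fails to converge."""


def gompertz_loglik(ages: np.ndarray, alpha: float, r0: float) -> float:
    """Exact-time Gompertz log-likelihood at (alpha, r0)."""
    ages = np.asarray(ages, dtype=float)
    ax = alpha * ages
    return float(np.sum(np.log(r0) + ax - (r0 / alpha) * np.expm1(ax)))


def _negll_and_grad(theta: np.ndarray, ages: np.ndarray) -> tuple[float, np.ndarray]:
    la, lr = theta
    a, r = math.exp(la), math.exp(lr)
    ax = np.clip(a * ages, None, 500.0)
    eax = np.expm1(ax)
    ll = np.sum(lr + ax - (r / a) * eax)
    n = len(ages)
    # d/d(ln r0) = n - (r/a) * sum(expm1(ax))
    dlr = n - (r / a) * np.sum(eax)
    # d/d(alpha) = sum(x) - r * sum( x*e^{ax}/a - expm1(ax)/a^2 ); d/d(ln a) = a * d/da
    dda = np.sum(ages) - r * np.sum(ages * np.exp(ax) / a - eax / a**2)
    dla = a * dda
    return -float(ll), -np.array([dla, dlr])


def binned_log_hazard(ages: Sequence[float], bin_width: float = 5.0) -> pd.DataFrame:
    """Life-table hazard on fixed-width age bins.

    For bin k with n_k subjects alive at the bin start and d_k deaths inside,
    mu_k = d_k / (n_k * bin_width).  Returns midpoints and ln(mu) for bins
    with d_k > 0.
    """
    ages = np.asarray(ages, dtype=float)
    edges = np.arange(0.0, ages.max() + bin_width, bin_width)
    mids, log_mu = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_k = int((ages > lo).sum())
        d_k = int(((ages > lo) & (ages <= hi)).sum())
        if n_k > 0 and d_k > 0:
            mids.append((lo + hi) / 2.0)
            log_mu.append(math.log(d_k / (n_k * bin_width)))
    return pd.DataFrame({"midpoint": mids, "log_hazard": log_mu})


def _init_from_hazard(ages: np.ndarray, bin_width: float = 5.0) -> tuple[float, float]:
    tab = binned_log_hazard(ages, bin_width)
    if len(tab) >= 3:
        slope, intercept = np.polyfit(tab["midpoint"], tab["log_hazard"], 1)
        if slope > 1e-6:
            return float(slope), float(math.exp(intercept))
    # crude moment fallback: alpha from MRDT ~ 10% of max age, r0 from median
    a0 = math.log(2.0) / max(ages.max() / 8.0, 1.0)
    med = float(np.median(ages))
    r0 = -a0 * math.log(0.5) / math.expm1(a0 * med)
    return a0, max(r0, 1e-8)


def fit_gompertz_ml(death_ages: Iterable[float] | Iterable[LifespanRecord],
                    compute_cov: bool = False) -> GompertzFit:
    """Maximum-likelihood Gompertz fit to fully observed death ages."""
    ages = _to_ages(death_ages)
    if len(ages) < 2:
        raise ValueError("need at least 2 death ages")
    if len(ages) < 10:
        warnings.warn(f"fitting Gompertz to only {len(ages)} deaths", stacklevel=2)
    a0, r0 = _init_from_hazard(ages)
    x0 = np.array([math.log(a0), math.log(r0)])
    res = optimize.minimize(_negll_and_grad, x0, args=(ages,), jac=True,
                            method="L-BFGS-B", options={"ftol": 1e-12, "gtol": 1e-10})
    best = res
    # Nelder-Mead polish guards against rare L-BFGS-B stalls on flat surfaces
    res2 = optimize.minimize(lambda th: _negll_and_grad(th, ages)[0], best.x,
                             method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000})
    if res2.fun < best.fun:
        best = res2
    converged = bool(res.success or res2.success)
    la, lr = best.x
    cov = None
    if compute_cov:
        try:
            hess = _numeric_hessian(lambda th: _negll_and_grad(th, ages)[0], best.x)
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = None
    return GompertzFit(alpha=float(math.exp(la)), r0=float(math.exp(lr)),
                       loglik=-float(best.fun), n=len(ages), converged=converged,
                       cov_log=cov)


def _numeric_hessian(f, x, h=1e-5):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            e_i = np.zeros(n); e_i[i] = h
            e_j = np.zeros(n); e_j[j] = h
            H[i, j] = (f(x + e_i + e_j) - f(x + e_i - e_j)
                       - f(x - e_i + e_j) + f(x - e_i - e_j)) / (4 * h * h)
    return (H + H.T) / 2.0


def _to_ages(records) -> np.ndarray:
    records = list(records)
    if records and isinstance(records[0], LifespanRecord):
        if not all(r.event for r in records):
            raise ValueError("Gompertz ML fit requires uncensored death ages")
        return np.array([r.age_days for r in records], dtype=float)
    return np.asarray(records, dtype=float)


def mrdt(alpha: float) -> float:
    """Mortality-rate doubling time ln(2)/alpha, days."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return math.log(2.0) / alpha


def gompertz_r2(death_ages, fit: GompertzFit | None = None, bin_width: float = 5.0) -> float | None:
    """R^2 of the OLS regression of binned ln(hazard) on age-bin midpoints.

    Measures how well the log-hazard is linear in age (the Gompertz
    signature).  Returns None when fewer than 3 informative bins exist.
    """
    if fit is not None and not fit.converged:
        raise ConvergenceError("goodness of fit requested for a non-converged fit")
    ages = _to_ages(death_ages)
    tab = binned_log_hazard(ages, bin_width)
    if len(tab) < 3:
        return None
    x = sm.add_constant(tab["midpoint"].to_numpy())
    model = sm.OLS(tab["log_hazard"].to_numpy(), x).fit()
    return float(model.rsquared)


Constraint = Literal["alpha", "r0", "both"]


def lrt_mortality(records_a, records_b, constraint: Constraint = "both"):
    """Likelihood-ratio test for a difference in mortality intensity.

    Full model: separate (alpha, R0) per group.  Constrained model shares
    the named parameter(s).  2*(l_full - l_constrained) ~ chi2 with df equal
    to the number of constrained parameters.
    """
    ages_a, ages_b = _to_ages(records_a), _to_ages(records_b)
    fit_a, fit_b = fit_gompertz_ml(ages_a), fit_gompertz_ml(ages_b)
    if not (fit_a.converged and fit_b.converged):
        raise ConvergenceError("full-model fit did not converge")
    ll_full = fit_a.loglik + fit_b.loglik

    if constraint == "both":
        pooled = fit_gompertz_ml(np.concatenate([ages_a, ages_b]))
        if not pooled.converged:
            raise ConvergenceError("constrained fit did not converge")
        ll_c, df = pooled.loglik, 2
    elif constraint in ("alpha", "r0"):
        # shared parameter + one free parameter per group
        def negll(theta):
            if constraint == "alpha":
                la, lra, lrb = theta
                return (-gompertz_loglik(ages_a, math.exp(la), math.exp(lra))
                        - gompertz_loglik(ages_b, math.exp(la), math.exp(lrb)))
            lr, laa, lab = theta
            return (-gompertz_loglik(ages_a, math.exp(laa), math.exp(lr))
                    - gompertz_loglik(ages_b, math.exp(lab), math.exp(lr)))

        if constraint == "alpha":
            x0 = [math.log((fit_a.alpha + fit_b.alpha) / 2),
                  math.log(fit_a.r0), math.log(fit_b.r0)]
        else:
            x0 = [math.log(math.sqrt(fit_a.r0 * fit_b.r0)),
                  math.log(fit_a.alpha), math.log(fit_b.alpha)]
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 6000})
        if not res.success:
            raise ConvergenceError("constrained fit did not converge")
        ll_c, df = -float(res.fun), 1
    else:
        raise ValueError(f"unknown constraint {constraint!r}")

    stat = max(0.0, 2.0 * (ll_full - ll_c))
    p = float(stats.chi2.sf(stat, df))
    return TestResult(name=f"LRT[{constraint}]", statistic=stat, p_value=p, df=df,
                      extra={"fit_a": (fit_a.alpha, fit_a.r0), "fit_b": (fit_b.alpha, fit_b.r0)})


# ---------------------------------------------------------------------------
# Strehler-Mildvan regression
# ---------------------------------------------------------------------------

@dataclass
class SMRegression:
    """OLS of ln R0 on alpha with the sign convention ln R0 = gamma - beta*alpha.

    beta (days) is the common intersection age of the hazard lines; for
    populations obeying the correlation it reads as the typical lifespan.
    """

    gamma: float
    beta: float
    beta_se: float
    pearson_r: float
    resid_sd: float
    studentized: np.ndarray
    n: int
    alphas: np.ndarray
    ln_r0: np.ndarray

    def beta_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for beta from the OLS slope standard error."""
        half = stats.t.ppf(0.5 + level / 2, self.n - 2) * self.beta_se
        return self.beta - half, self.beta + half


def strehler_mildvan(fits: Sequence[GompertzFit] | np.ndarray) -> SMRegression:
    """Fit the Strehler-Mildvan regression across Gompertz fits.

    Accepts GompertzFit objects or an array of (alpha, r0) pairs.
    """
    if isinstance(fits, np.ndarray):
        alphas = fits[:, 0].astype(float)
        r0s = fits[:, 1].astype(float)
    else:
        alphas = np.array([f.alpha for f in fits], dtype=float)
        r0s = np.array([f.r0 for f in fits], dtype=float)
    if len(alphas) < 3:
        raise ValueError("need at least 3 fits for the Strehler-Mildvan regression")
    if np.ptp(alphas) <= 0:
        raise ValueError("zero variance in alpha")
    y = np.log(r0s)
    model = sm.OLS(y, sm.add_constant(alphas)).fit()
    gamma = float(model.params[0])
    beta = float(-model.params[1])
    resid = model.resid
    if np.allclose(resid, 0.0, atol=1e-10):
        studentized = np.zeros(len(alphas))
        r = -1.0 if beta > 0 else 1.0
        resid_sd = 0.0
    else:
        studentized = np.asarray(model.get_influence().resid_studentized_external)
        r = float(np.corrcoef(alphas, y)[0, 1])
        resid_sd = float(np.sqrt(model.mse_resid))
    return SMRegression(gamma=gamma, beta=beta, beta_se=float(model.bse[1]),
                        pearson_r=r, resid_sd=resid_sd,
                        studentized=studentized, n=len(alphas), alphas=alphas, ln_r0=y)


def sm_deviation_test(reg: SMRegression, point_index: int):
    """Does one population deviate from the Strehler-Mildvan line?

    Two-sided t-test of the externally studentized residual, df = n - 3.
    """
    if reg.n < 4:
        raise ValueError("deviation test needs at least 4 points")
    if not (0 <= point_index < reg.n):
        raise IndexError(f"point index {point_index} out of range for n={reg.n}")
    t = float(reg.studentized[point_index])
    df = reg.n - 3
    p = float(2.0 * stats.t.sf(abs(t), df)) if t != 0.0 else 1.0
    return TestResult(name="SM-deviation", statistic=t, p_value=min(p, 1.0), df=df,
                      extra={"point_index": point_index})


# ---------------------------------------------------------------------------
# lifespan summary-table construction
# ---------------------------------------------------------------------------

@dataclass
class LifespanSummary:
    group: str
    sex: str
    dose_cgy: float
    median: float | None
    delta_median_pct: float | None
    age90: float | None
    delta_age90_pct: float | None
    mrdt_days: float
    delta_mrdt_pct: float | None
    alpha: float
    r0: float
    r_squared: float | None
    n: int
    p_values: dict = field(default_factory=dict)   # test name -> p (vs control)


def percent_delta(value: float, control: float) -> float:
    """100 * (value - control) / control."""
    return 100.0 * (value - control) / control


def summarize_lifespan(
    table: pd.DataFrame,
    control_map: Mapping[str, str],
    bin_width: float = 5.0,
) -> list[LifespanSummary]:
    """Build per-group lifespan summaries (one row per group label).

    ``table`` must carry columns group, sex, dose_cgy, age_days, event.
    ``control_map`` maps each non-control group label to its control's label;
    control groups are those absent from the map's keys.  For each group the
    summary reports the KM median and 90%-mortality age, the ML Gompertz
    parameters with MRDT = ln2/alpha and the binned-log-hazard R^2, percent
    deltas versus the mapped control, and the p-values of the Gehan (median),
    Wang-Allison (maximum lifespan), KS, log-rank, and alpha-constrained LRT
    (MRDT) comparisons.
    """
    for g in control_map.values():
        if g not in set(table["group"]):
            raise ValueError(f"control group {g!r} not present in the table")

    by_group: dict[str, pd.DataFrame] = {g: sub for g, sub in table.groupby("group")}
    stats_cache: dict[str, dict] = {}
    for label, sub in by_group.items():
        ages = sub["age_days"].to_numpy(dtype=float)
        curve = km_estimate(ages)
        fit = fit_gompertz_ml(ages)
        stats_cache[label] = {
            "ages": ages,
            "median": median_lifespan(curve),
            "age90": age_at_90pct_mortality(curve),
            "fit": fit,
            "r2": gompertz_r2(ages, fit, bin_width),
            "sex": str(sub["sex"].iloc[0]),
            "dose": float(sub["dose_cgy"].iloc[0]),
        }

    out = []
    for label in by_group:
        s = stats_cache[label]
        fit = s["fit"]
        ctrl_label = control_map.get(label)
        deltas = {"median": None, "age90": None, "mrdt": None}
        p_values: dict[str, float] = {}
        if ctrl_label is not None and ctrl_label != label:
            c = stats_cache[ctrl_label]
            if s["median"] is not None and c["median"] is not None:
                deltas["median"] = percent_delta(s["median"], c["median"])
            if s["age90"] is not None and c["age90"] is not None:
                deltas["age90"] = percent_delta(s["age90"], c["age90"])
            deltas["mrdt"] = percent_delta(mrdt(fit.alpha), mrdt(c["fit"].alpha))
            p_values = {
                "gehan": gehan_breslow_wilcoxon(s["ages"], c["ages"]).p_value,
                "logrank": logrank(s["ages"], c["ages"]).p_value,
                "modified_ks": modified_ks(s["ages"], c["ages"]).p_value,
                "wang_allison": wang_allison(s["ages"], c["ages"]).p_value,
                "lrt_alpha": lrt_mortality(s["ages"], c["ages"], "alpha").p_value,
            }
        elif ctrl_label == label:
            deltas = {"median": 0.0, "age90": 0.0, "mrdt": 0.0}
        out.append(LifespanSummary(
            group=label, sex=s["sex"], dose_cgy=s["dose"],
            median=s["median"], delta_median_pct=deltas["median"],
            age90=s["age90"], delta_age90_pct=deltas["age90"],
            mrdt_days=mrdt(fit.alpha), delta_mrdt_pct=deltas["mrdt"],
            alpha=fit.alpha, r0=fit.r0, r_squared=s["r2"], n=fit.n,
            p_values=p_values,
        ))
    return out
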