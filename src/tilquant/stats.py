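"""Survival and correlation statistics.

The log-rank (Mantel–Cox) test is implemented here over pooled risk sets
because the hazard ratio it reports is the O/E-ratio "log-rank HR"
(``(O1/E1)/(O2/E2)`` with CI ``exp(log HR ± 1.96·sqrt(1/E1 + 1/E2))``),
the variant printed next to Kaplan–Meier panels by the common survival
packages. Kaplan–Meier curves and the univariate Cox validation delegate
to lifelines (Efron tie handling for Cox).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps

from tilquant.errors import DegenerateTestError


@dataclass
class SurvCurve:
    """Product-limit estimate: step function S(t) with at-risk counts."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk just before each event time
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass
class SurvTestResult:
    """Log-rank test output for a hi-vs-lo comparison."""

    chi2: float
    p: float
    hr: float  # hi vs lo, O/E-ratio variant
    ci95: tuple[float, float]
    n_hi: int
    n_lo: int
    observed: tuple[float, float] = (np.nan, np.nan)
    expected: tuple[float, float] = (np.nan, np.nan)


@dataclass
class CorrResult:
    r: float
    p: float
    ci95: tuple[float, float]
    n: int


@dataclass
class CoxResult:
    beta: float
    hr: float
    p: float
    ci95: tuple[float, float]
    se: float
    n: int
    n_events: int


def _check_surv(months, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(months, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("event flags must be 0/1")
    return t, e


def km_estimate(months, events) -> SurvCurve:
    """Kaplan–Meier product-limit estimator (ties grouped at equal times)."""
    t, e = _check_surv(months, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    ev_times = np.unique(t[e == 1])
    surv = np.array([float(kmf.survival_function_at_times(ti).iloc[0]) for ti in ev_times])
    at_risk = np.array([(t >= ti).sum() for ti in ev_times])
    return SurvCurve(
        times=ev_times, survival=surv, at_risk=at_risk, censor_times=np.sort(t[e == 0])
    )


def logrank_test(months_hi, events_hi, months_lo, events_lo) -> SurvTestResult:
    """Log-rank (Mantel–Cox) test with the O/E-ratio hazard ratio.

    At each distinct pooled event time t_j with d_j events and n_j at risk
    (n_1j in hi), the hi group contributes expectation ``E_1j = d_j n_1j/n_j``
    and hypergeometric variance; ``chi2 = (O_1−E_1)^2 / V`` on 1 df. The
    hazard ratio is ``(O_1/E_1)/(O_2/E_2)`` (hi vs lo).
    """
    t1, e1 = _check_surv(months_hi, events_hi)
    t2, e2 = _check_surv(months_lo, events_lo)
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.ones_like(t1), np.zeros_like(t2)])
    if e.sum() == 0:
        raise DegenerateTestError("no events in either group")

    o1 = e1_exp = var = 0.0
    o_total = 0.0
    for tj in np.unique(t[e == 1]):
        at = t >= tj
        n_j = at.sum()
        n1 = (at & (g == 1)).sum()
        d_j = ((t == tj) & (e == 1)).sum()
        d1 = ((t == tj) & (e == 1) & (g == 1)).sum()
        o1 += d1
        o_total += d_j
        e1_exp += d_j * n1 / n_j
        if n_j > 1:
            var += d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1)
    o2 = o_total - o1
    e2_exp = o_total - e1_exp
    if var == 0.0:
        raise DegenerateTestError("degenerate log-rank: zero variance")
    chi2 = (o1 - e1_exp) ** 2 / var
    p = float(sps.chi2.sf(chi2, df=1))

    if o1 == 0 or o2 == 0 or e1_exp == 0 or e2_exp == 0:
        warnings.warn("a group has zero observed or expected events; HR is degenerate")
        hr = math.inf if o2 == 0 else 0.0
        ci = (0.0, math.inf)
    else:
        hr = (o1 / e1_exp) / (o2 / e2_exp)
        half = 1.96 * math.sqrt(1.0 / e1_exp + 1.0 / e2_exp)
        ci = (hr * math.exp(-half), hr * math.exp(half))
    return SurvTestResult(
        chi2=float(chi2), p=max(p, np.finfo(float).tiny), hr=float(hr), ci95=ci,
        n_hi=len(t1), n_lo=len(t2),
        observed=(float(o1), float(o2)), expected=(float(e1_exp), float(e2_exp)),
    )


def cox_univariate(months, events, x) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties), Wald p and CI.

    Serves as the validation route alongside the log-rank HR. Non-convergence
    or perfect separation surfaces as :class:`DegenerateTestError` with the
    fitter's diagnostics attached.
    """
    t, e = _check_surv(months, events)
    xv = np.asarray(x, dtype=float)
    if e.sum() < 2:
        raise DegenerateTestError("need >= 2 events for a Cox fit")
    if np.allclose(xv, xv[0]):
        raise DegenerateTestError("covariate is constant")
    df = pd.DataFrame({"months": t, "event": e, "x": xv})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="months", event_col="event")
    except ConvergenceError as exc:
        raise DegenerateTestError(f"Cox fit did not converge: {exc}") from exc
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return CoxResult(
        beta=beta, hr=math.exp(beta), p=float(cph.summary.loc["x", "p"]),
        ci95=(math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)),
        se=se, n=len(t), n_events=int(e.sum()),
    )


def pearson(x, y) -> CorrResult:
    """Pearson r with two-tailed t-based p and Fisher-z 95% CI."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("non-finite values")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise DegenerateTestError("zero variance: r undefined")
    r, p = sps.pearsonr(xv, yv)
    n = xv.size
    if n > 3 and abs(r) < 1:
        z = math.atanh(r)
        half = 1.96 / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (r, r)
    return CorrResult(r=float(r), p=float(p), ci95=ci, n=int(n))


def cumulative_correlation(matrix: pd.DataFrame, marker_set=None) -> pd.DataFrame:
    """Rank markers by their mean pairwise Pearson r with the rest of the set.

    Constant columns are excluded with a warning; ties in the mean r are
    broken alphabetically. Returns a frame (marker, mean_r) sorted descending.
    """
    cols = list(marker_set) if marker_set is not None else list(matrix.columns)
    if len(cols) < 3:
        raise ValueError("need >= 3 markers")
    sub = matrix[cols].astype(float)
    constant = [c for c in cols if sub[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"excluding constant columns: {constant}")
        sub = sub.drop(columns=constant)
    corr = sub.corr(method="pearson")
    np.fill_diagonal(corr.values, np.nan)
    mean_r = corr.mean(axis=1, skipna=True)
    out = (
        mean_r.rename("mean_r").rename_axis("marker").reset_index()
        .sort_values(["mean_r", "marker"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def schoenfeld_power(n: int, hr: float, allocation: float, event_fraction: float,
                     alpha: float = 0.05) -> float:
    """Asymptotic two-sided log-rank power (Schoenfeld's event-count formula)."""
    d = n * event_fraction
    p1 = allocation
    mu = abs(math.log(hr)) * math.sqrt(d * p1 * (1 - p1))
    za = sps.norm.ppf(1 - alpha / 2)
    return float(sps.norm.cdf(mu - za) + sps.norm.cdf(-mu - za))


def logrank_power(
    n: int,
    hr: float,
    allocation: float = 0.5,
    event_fraction: float = 0.8,
    alpha: float = 0.05,
    reps: int = 500,
    seed=None,
) -> dict:
    """Monte-Carlo log-rank power with a Schoenfeld asymptotic cross-check.

    Each replicate draws exponential survival (unit baseline hazard, ``hr``
    in the second group) under administrative censoring at the horizon that
    yields the requested overall event fraction; power is the fraction of
    replicates with log-rank p < alpha.
    """
    if hr <= 0:
        raise ValueError("hr must be > 0")
    if not 0 < event_fraction <= 1:
        raise ValueError("event_fraction must be in (0, 1]")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    n1 = int(round(n * allocation))
    n0 = n - n1

    if event_fraction == 1.0:
        horizon = math.inf
    else:
        p0, p1 = n0 / n, n1 / n

        def frac(c):
            return p0 * (1 - math.exp(-c)) + p1 * (1 - math.exp(-hr * c)) - event_fraction

        from scipy.optimize import brentq

        horizon = brentq(frac, 1e-12, 1e9)

    hits = 0
    for _ in range(reps):
        t0 = rng.exponential(1.0, size=n0)
        t1 = rng.exponential(1.0 / hr, size=n1)
        m0, e0 = np.minimum(t0, horizon), (t0 <= horizon).astype(int)
        m1, e1 = np.minimum(t1, horizon), (t1 <= horizon).astype(int)
        try:
            res = logrank_test(m1, e1, m0, e0)
        except DegenerateTestError:
            continue
        if res.p < alpha:
            hits += 1
    mc = hits / reps
    return {
        "mc_power": mc,
        "mc_se": math.sqrt(mc * (1 - mc) / reps),
        "schoenfeld_power": schoenfeld_power(n, hr, allocation, event_fraction, alpha),
        "reps": reps,
    }
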