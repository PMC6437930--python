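import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tilquant.errors import DegenerateTestError
from tilquant.stats import (
    cox_univariate,
    cumulative_correlation,
    km_estimate,
    logrank_power,
    logrank_test,
    pearson,
    schoenfeld_power,
)


# ---------------------------------------------------------------------------
# independent oracles (implemented from the textbook definitions, sharing no
# code with the package)
# ---------------------------------------------------------------------------

def oracle_logrank(t1, e1, t2, e2):
    """Brute-force Mantel-Cox over explicit risk sets."""
    t = np.concatenate([t1, t2]).astype(float)
    e = np.concatenate([e1, e2]).astype(int)
    g = np.array([1] * len(t1) + [0] * len(t2))
    o1 = exp1 = var = o_all = 0.0
    for tj in sorted(set(t[e == 1])):
        risk = t >= tj
        nj, n1j = risk.sum(), (risk & (g == 1)).sum()
        dj = ((t == tj) & (e == 1)).sum()
        d1j = ((t == tj) & (e == 1) & (g == 1)).sum()
        o1 += d1j
        o_all += dj
        exp1 += dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    chi2 = (o1 - exp1) ** 2 / var
    o2, exp2 = o_all - o1, o_all - exp1
    hr = (o1 / exp1) / (o2 / exp2)
    return chi2, float(sps.chi2.sf(chi2, 1)), hr


def oracle_efron_loglik(beta, t, e, x):
    """Efron partial log-likelihood for one binary/continuous covariate."""
    theta = np.exp(beta * x)
    ll = 0.0
    for tj in sorted(set(t[e == 1])):
        dead = (t == tj) & (e == 1)
        risk = t >= tj
        d = dead.sum()
        sum_risk = theta[risk].sum()
        sum_dead = theta[dead].sum()
        ll += beta * x[dead].sum()
        for l in range(d):
            ll -= math.log(sum_risk - (l / d) * sum_dead)
    return ll


def oracle_km(t, e):
    """Product-limit estimator straight from the definition."""
    out = {}
    s = 1.0
    for tj in sorted(set(t[e == 1])):
        n = (t >= tj).sum()
        d = ((t == tj) & (e == 1)).sum()
        s *= 1 - d / n
        out[tj] = s
    return out


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

TOY = (
    np.array([6.0, 13.0, 21.0, 30.0, 37.0, 80.0]),
    np.array([1, 1, 0, 1, 1, 1]),
    np.array([5.0, 10.0, 17.0, 19.0, 35.0, 60.0]),
    np.array([1, 0, 1, 1, 1, 0]),
)


def test_logrank_matches_bruteforce_oracle():
    res = logrank_test(*TOY)
    chi2, p, hr = oracle_logrank(*TOY)
    assert res.chi2 == pytest.approx(chi2, abs=1e-10)
    assert res.p == pytest.approx(p, abs=1e-10)
    assert res.hr == pytest.approx(hr, abs=1e-10)


def test_logrank_matches_lifelines():
    from lifelines.statistics import logrank_test as ll_logrank

    t1, e1, t2, e2 = TOY
    res = logrank_test(t1, e1, t2, e2)
    ref = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
    assert res.p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_symmetry():
    t1, e1, t2, e2 = TOY
    a = logrank_test(t1, e1, t2, e2)
    b = logrank_test(t2, e2, t1, e1)
    assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)
    assert a.p == pytest.approx(b.p, abs=1e-12)
    assert a.hr == pytest.approx(1.0 / b.hr, rel=1e-12)


def test_logrank_identical_groups_null():
    t = np.array([3.0, 6.0, 9.0, 12.0])
    e = np.array([1, 1, 1, 0])
    res = logrank_test(t, e, t, e)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)
    assert res.hr == pytest.approx(1.0)


def test_logrank_separated_groups_hand_values():
    """Fully separated toy frozen by hand via the risk-set recursion."""
    res = logrank_test([10.0, 12.0, 14.0], [1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1])
    assert res.observed == (3.0, 3.0)
    # lo events at 1,2,3 with hi fully at risk: E_hi = 3/6 + 3/5 + 3/4 = 1.85;
    # hi events at 10,12,14 with only hi at risk: +3 -> E_hi = 4.85, E_lo = 1.15
    assert res.expected == (pytest.approx(4.85, abs=1e-10), pytest.approx(1.15, abs=1e-10))
    assert res.hr == pytest.approx((3 / 4.85) / (3 / 1.15), abs=1e-9)
    assert res.hr < 1.0  # hi (long-lived) is protective


def test_logrank_ci_formula():
    res = logrank_test(*TOY)
    e1, e2 = res.expected
    half = 1.96 * math.sqrt(1 / e1 + 1 / e2)
    assert res.ci95[0] == pytest.approx(res.hr * math.exp(-half))
    assert res.ci95[1] == pytest.approx(res.hr * math.exp(half))
    assert res.ci95[0] < res.hr < res.ci95[1]


def test_logrank_degenerate_inputs():
    with pytest.raises(DegenerateTestError):
        logrank_test([1.0, 2.0], [0, 0], [3.0], [0])
    with pytest.raises(ValueError):
        logrank_test([-1.0], [1], [2.0], [1])
    with pytest.raises(ValueError):
        logrank_test([1.0], [2], [2.0], [1])


def test_logrank_null_pvalues_uniform():
    """Under the null, log-rank p-values over random splits are U(0,1)."""
    rng = np.random.default_rng(0)
    ps = []
    for _ in range(400):
        t = rng.exponential(50.0, size=60)
        e = (t < 100).astype(int)
        t = np.minimum(t, 100.0)
        g = rng.random(60) < 0.5
        try:
            ps.append(logrank_test(t[g], e[g], t[~g], e[~g]).p)
        except DegenerateTestError:
            pass
    ks = sps.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_matches_definition_with_censoring():
    t = np.array([2.0, 3.0, 3.0, 5.0, 7.0, 8.0, 11.0])
    e = np.array([1, 1, 0, 1, 0, 1, 0])
    curve = km_estimate(t, e)
    ref = oracle_km(t, e)
    for ti, si in zip(curve.times, curve.survival):
        assert si == pytest.approx(ref[ti], abs=1e-12)
    # hand example: n=3, events at 1 and 2, censored at 1.5
    c2 = km_estimate([1.0, 1.5, 2.0], [1, 0, 1])
    assert c2.survival == pytest.approx([2 / 3, 0.0])


def test_km_without_censoring_is_one_minus_ecdf():
    rng = np.random.default_rng(5)
    t = rng.exponential(10.0, size=50)
    e = np.ones(50, int)
    curve = km_estimate(t, e)
    for ti, si in zip(curve.times, curve.survival):
        assert si == pytest.approx(1.0 - (t <= ti).mean(), abs=1e-12)


def test_km_monotone_nonincreasing():
    rng = np.random.default_rng(6)
    t = rng.exponential(10.0, size=40)
    e = rng.integers(0, 2, size=40)
    curve = km_estimate(t, e)
    assert (np.diff(curve.survival) <= 1e-12).all()
    assert curve.survival_at(0.0) == 1.0


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def test_cox_matches_efron_grid_oracle():
    """The fitted beta maximises the Efron partial likelihood (grid search
    to 1e-4), on a toy with tied event times."""
    t = np.array([3.0, 3.0, 5.0, 6.0, 8.0, 10.0, 12.0, 15.0])
    e = np.array([1, 1, 1, 0, 1, 1, 0, 1])
    x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0])
    res = cox_univariate(t, e, x)
    grid = np.arange(-3.0, 3.0, 1e-4)
    lls = [oracle_efron_loglik(b, t, e, x) for b in grid]
    beta_star = grid[int(np.argmax(lls))]
    assert res.beta == pytest.approx(beta_star, abs=2e-4)
    assert res.hr == pytest.approx(math.exp(res.beta))
    assert res.ci95[0] < res.hr < res.ci95[1]


def test_cox_agrees_with_logrank_direction():
    rng = np.random.default_rng(8)
    x = rng.integers(0, 2, size=120).astype(float)
    t = rng.exponential(1.0 / (0.02 * np.exp(math.log(0.4) * x)))
    e = np.ones(120, int)
    cox = cox_univariate(t, e, x)
    lr = logrank_test(t[x == 1], e[x == 1], t[x == 0], e[x == 0])
    assert cox.hr < 1 and lr.hr < 1
    assert math.copysign(1, math.log(cox.hr)) == math.copysign(1, math.log(lr.hr))


def test_cox_degenerate_inputs():
    with pytest.raises(DegenerateTestError):
        cox_univariate([1.0, 2.0, 3.0], [1, 0, 0], [0.0, 1.0, 0.0])
    with pytest.raises(DegenerateTestError):
        cox_univariate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [2.0, 2.0, 2.0, 2.0])


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_pearson_matches_scipy_and_ci():
    rng = np.random.default_rng(9)
    x = rng.normal(size=30)
    y = 0.5 * x + rng.normal(size=30)
    res = pearson(x, y)
    r_ref, p_ref = sps.pearsonr(x, y)
    assert res.r == pytest.approx(r_ref)
    assert res.p == pytest.approx(p_ref)
    z = math.atanh(res.r)
    assert res.ci95[0] == pytest.approx(math.tanh(z - 1.96 / math.sqrt(27)))
    assert res.ci95[0] < res.r < res.ci95[1]


def test_pearson_errors():
    with pytest.raises(ValueError):
        pearson([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(DegenerateTestError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


def test_cumulative_correlation_ranks_block_first():
    rng = np.random.default_rng(10)
    f = rng.normal(size=200)
    m = pd.DataFrame({
        "A": f + 0.3 * rng.normal(size=200),
        "B": f + 0.3 * rng.normal(size=200),
        "C": f + 0.3 * rng.normal(size=200),
        "D": rng.normal(size=200),
        "E": rng.normal(size=200),
    })
    out = cumulative_correlation(m)
    assert set(out.loc[:2, "marker"]) == {"A", "B", "C"}
    assert out["mean_r"].is_monotonic_decreasing
    with pytest.warns(UserWarning):
        cumulative_correlation(m.assign(F=1.0))


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def test_schoenfeld_power_reference_value():
    """Sanity anchor: ~62 patients with 80% events at HR 0.45 give ~80%
    power at alpha 0.05 (Schoenfeld's formula evaluated directly)."""
    p = schoenfeld_power(62, 0.45, allocation=0.5, event_fraction=0.8)
    assert 0.70 < p < 0.90
    d = 62 * 0.8
    mu = abs(math.log(0.45)) * math.sqrt(d * 0.25)
    za = sps.norm.ppf(0.975)
    expect = sps.norm.cdf(mu - za) + sps.norm.cdf(-mu - za)
    assert p == pytest.approx(expect, abs=1e-12)


def test_power_monotone_in_n_and_effect():
    assert schoenfeld_power(100, 0.5, 0.5, 0.8) > schoenfeld_power(50, 0.5, 0.5, 0.8)
    assert schoenfeld_power(100, 0.4, 0.5, 0.8) > schoenfeld_power(100, 0.7, 0.5, 0.8)


def test_mc_power_close_to_schoenfeld():
    out = logrank_power(150, 0.5, reps=300, seed=0)
    se = max(out["mc_se"], math.sqrt(out["schoenfeld_power"]
                                     * (1 - out["schoenfeld_power"]) / out["reps"]))
    assert abs(out["mc_power"] - out["schoenfeld_power"]) < 4 * se + 0.02


def test_mc_power_null_is_alpha():
    out = logrank_power(200, 1.0, reps=400, seed=1)
    assert abs(out["mc_power"] - 0.05) < 0.035


def test_power_input_validation():
    with pytest.raises(ValueError):
        logrank_power(100, -0.5)
    with pytest.raises(ValueError):
        logrank_power(100, 0.5, event_fraction=0.0)
    with pytest.raises(ValueError):
        logrank_power(100, 0.5, reps=10)
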