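"""The statistical toolbox used by the analysis, from first principles.

Implements repeated-measures correlation (common within-subject slope with
subject-specific intercepts), paired and one-sample t tests with Cohen's d,
the JZS default-prior Bayes factor, one-way repeated-measures ANOVA with
partial eta squared, Pearson correlation, and Bonferroni adjustment.  SciPy
supplies only distribution CDFs and quadrature; the estimators themselves
are coded here so they can be checked against independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats as st

__all__ = [
    "RmCorrResult",
    "TestResult",
    "rmcorr",
    "paired_t",
    "one_sample_t",
    "two_sample_t",
    "jzs_bf10",
    "one_way_rm_anova",
    "pearson",
    "bonferroni",
    "effect_size_label",
]


@dataclass
class TestResult:
    """A test statistic with df, p, effect size and optional Bayes factor."""

    statistic: float
    df: tuple[float, ...] | float
    p_value: float
    effect_size: float
    bf10: float | None = None


@dataclass
class RmCorrResult:
    """Repeated-measures correlation: one common slope, per-subject intercepts."""

    r_m: float
    df: int
    p_value: float
    common_slope: float
    per_subject_intercepts: dict


def rmcorr(x: np.ndarray, y: np.ndarray, subject: np.ndarray) -> RmCorrResult:
    """Common within-subject linear association across subjects.

    Fits ``y ~ subject-intercepts + common slope * x`` by least squares
    (equivalently an ANCOVA with subject as factor).  The coefficient is
    ``r_m = sign(slope) * sqrt(SS_measure / (SS_measure + SS_error))`` with
    ``df = N - k - 1`` and a p value from the F ratio on (1, df).

    Subjects with constant x contribute no slope information; if every
    subject is constant the fit is undefined and a ValueError is raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subject = np.asarray(subject)
    subjects = list(dict.fromkeys(subject.tolist()))  # keep first-seen order
    k = len(subjects)
    n = len(x)
    if k < 2:
        raise ValueError("need at least two subjects")
    if n != len(y) or n != len(subject):
        raise ValueError("x, y, subject must have equal length")

    # center within subject: removes the intercepts exactly
    xc = np.empty_like(x)
    yc = np.empty_like(y)
    for s in subjects:
        m = subject == s
        xc[m] = x[m] - x[m].mean()
        yc[m] = y[m] - y[m].mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("x is constant within every subject")
    slope = float(xc @ yc) / sxx
    ss_measure = slope**2 * sxx
    resid = yc - slope * xc
    ss_error = float(resid @ resid)
    df = n - k - 1
    if df < 1:
        raise ValueError("not enough observations for the rmcorr df")
    denom = ss_measure + ss_error
    r_m = 0.0 if denom == 0 else math.copysign(
        math.sqrt(ss_measure / denom), slope)
    if ss_error == 0.0:
        p = 0.0
    else:
        f_ratio = ss_measure / (ss_error / df)
        p = float(st.f.sf(f_ratio, 1, df))
    intercepts = {}
    for s in subjects:
        m = subject == s
        intercepts[s] = float(y[m].mean() - slope * x[m].mean())
    return RmCorrResult(r_m=float(np.clip(r_m, -1.0, 1.0)), df=df, p_value=p,
                        common_slope=slope, per_subject_intercepts=intercepts)


def _t_core(diffs: np.ndarray) -> TestResult:
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least two observations")
    if not np.all(np.isfinite(diffs)):
        raise ValueError("non-finite values")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:  # x == y exactly: a defined, null result
            return TestResult(statistic=0.0, df=n - 1, p_value=1.0,
                              effect_size=0.0)
        raise ValueError("zero variance with nonzero mean difference")
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(st.t.sf(abs(t), n - 1))
    d = mean / sd
    res = TestResult(statistic=t, df=n - 1, p_value=p, effect_size=d)
    res.bf10 = jzs_bf10(t, n)
    return res


def paired_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Paired t test on x - y; Cohen's d = mean(diff)/sd(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    return _t_core(x - y)


def one_sample_t(x: np.ndarray, mu0: float = 0.0) -> TestResult:
    """One-sample t test of mean(x) against ``mu0``."""
    return _t_core(np.asarray(x, dtype=float) - mu0)


def two_sample_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Independent two-sample t test (pooled variance), Cohen's d pooled."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if min(nx, ny) < 2:
        raise ValueError("need at least two observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    df = nx + ny - 2
    p = 2.0 * float(st.t.sf(abs(t), df))
    d = (x.mean() - y.mean()) / math.sqrt(sp2)
    return TestResult(statistic=float(t), df=df, p_value=p,
                      effect_size=float(d))


def jzs_bf10(t: float, n: int, cauchy_scale: float = math.sqrt(2) / 2.0) -> float:
    """JZS Bayes factor (H1/H0) for a one/paired-sample t statistic.

    Default Cauchy prior with scale sqrt(2)/2 on the standardized effect;
    the marginal likelihood under H1 integrates over the Cauchy via
    adaptive quadrature.  As the scale shrinks to 0 the prior collapses to
    the null and BF10 -> 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if cauchy_scale == 0.0:
        return 1.0
    nu = n - 1
    t = float(t)
    r = float(cauchy_scale)

    def like(delta: float) -> float:
        return st.nct.pdf(t, nu, delta * math.sqrt(n))

    def integrand(delta: float) -> float:
        prior = st.cauchy.pdf(delta, scale=r)
        return like(delta) * prior

    m1, err = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    if not np.isfinite(m1) or (m1 > 0 and err / m1 > 1e-4):
        raise ArithmeticError("Bayes factor integral did not converge")
    m0 = st.t.pdf(t, nu)
    return float(m1 / m0)


def one_way_rm_anova(values: np.ndarray) -> TestResult:
    """One-way repeated-measures ANOVA on a complete subject x level table.

    ``F = MS_level / MS_(subject x level)`` with df ``(k-1, (n-1)(k-1))``;
    effect size is partial eta squared ``SS_level / (SS_level + SS_error)``.
    No sphericity correction is applied (reported df are uncorrected).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValueError("need a 2-D subject x level table with >= 2 levels")
    if not np.all(np.isfinite(v)):
        raise ValueError("missing cells are not allowed")
    n, k = v.shape
    grand = v.mean()
    ss_level = n * float(((v.mean(axis=0) - grand) ** 2).sum())
    ss_subject = k * float(((v.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((v - grand) ** 2).sum())
    ss_error = ss_total - ss_level - ss_subject
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_error = ss_error / df2
    if ss_level == 0.0:
        return TestResult(statistic=0.0, df=(df1, df2), p_value=1.0,
                          effect_size=0.0)
    if ms_error == 0.0:
        return TestResult(statistic=math.inf, df=(df1, df2), p_value=0.0,
                          effect_size=1.0)
    f_ratio = (ss_level / df1) / ms_error
    p = float(st.f.sf(f_ratio, df1, df2))
    eta_p2 = ss_level / (ss_level + ss_error)
    return TestResult(statistic=float(f_ratio), df=(df1, df2), p_value=p,
                      effect_size=float(eta_p2))


def pearson(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson correlation with a t-based two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or n != len(y):
        raise ValueError("need n >= 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance")
    r = float(xc @ yc) / (sx * sy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r**2))
        p = 2.0 * float(st.t.sf(abs(t), n - 2))
    return TestResult(statistic=r, df=n - 2, p_value=p, effect_size=r)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni-adjusted p values: ``min(1, m * p)`` elementwise."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("m must be >= the number of p values")
    adj = np.minimum(1.0, m * p)
    return float(adj[0]) if np.isscalar(p_values) or np.ndim(p_values) == 0 else adj


def effect_size_label(value: float, kind: str = "d") -> str:
    """Reporting annotation: small/medium/large per conventional cutoffs."""
    v = abs(value)
    if kind == "d":
        cuts = (0.2, 0.5, 0.8)
    elif kind == "bf10":
        cuts = (1.0, 3.0, 10.0)
    elif kind == "eta_p2":
        cuts = (0.01, 0.06, 0.14)
    else:
        raise ValueError(f"unknown effect-size kind {kind!r}")
    if v < cuts[0]:
        return "negligible"
    if v < cuts[1]:
        return "small"
    if v < cuts[2]:
        return "medium"
    return "large"
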