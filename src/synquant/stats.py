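"""Subject-level statistics.

All group comparisons operate on per-subject means (the subject, not the
synapse, is the unit of analysis).  Two-sample tests default to the classical
pooled-variance t test, with Welch available as an option; families of
comparisons are adjusted with the Holm-Bonferroni step-down procedure.
Normality screening uses the Lilliefors-corrected Kolmogorov-Smirnov test for
large samples and Shapiro-Wilk for small ones, and covariate effects (age,
gender, postmortem interval) are assessed by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

from .core import DegenerateInputError, ParameterError

__all__ = [
    "TestResult",
    "CorrelationResult",
    "t_unpaired",
    "t_from_summary",
    "t_paired",
    "holm_bonferroni",
    "spearman",
    "normality",
    "covariate_regression",
    "percent_reduction",
]


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    kind: str
    mean1: float | None = None
    mean2: float | None = None
    sd1: float | None = None
    sd2: float | None = None
    n1: int | None = None
    n2: int | None = None
    p_adjusted: float | None = None
    degenerate: bool = False


@dataclass
class CorrelationResult:
    r_s: float
    p: float
    n: int


def t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    welch: bool = False,
) -> TestResult:
    """Two-sample two-tailed t test from summary statistics (mean, SD, n).

    Pooled-variance by default (df = n1 + n2 - 2); Welch optionally.
    """
    if sd1 < 0 or sd2 < 0:
        raise ParameterError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ParameterError("each sample needs n >= 2")
    v1, v2 = sd1**2, sd2**2
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 > 0:
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = n1 + n2 - 2
    kind = "welch" if welch else "unpaired_pooled"
    if se2 == 0:
        degenerate = mean1 != mean2
        return TestResult(
            statistic=0.0 if not degenerate else np.inf,
            df=df,
            p=1.0 if not degenerate else 0.0,
            kind=kind,
            mean1=mean1,
            mean2=mean2,
            sd1=sd1,
            sd2=sd2,
            n1=n1,
            n2=n2,
            degenerate=degenerate,
        )
    t = (mean1 - mean2) / np.sqrt(se2)
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(
        statistic=float(t),
        df=float(df),
        p=float(p),
        kind=kind,
        mean1=mean1,
        mean2=mean2,
        sd1=sd1,
        sd2=sd2,
        n1=n1,
        n2=n2,
    )


def t_unpaired(a, b, welch: bool = False) -> TestResult:
    """Two-sample two-tailed t test on raw samples (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each sample needs n >= 2")
    return t_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, welch=welch
    )


def t_paired(a, b) -> TestResult:
    """Paired two-tailed t test: one-sample t on the within-pair differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ParameterError("paired samples must have equal lengths")
    if a.size < 2:
        raise ParameterError("need n >= 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        degenerate = d.mean() != 0
        return TestResult(
            statistic=0.0 if not degenerate else np.inf,
            df=n - 1,
            p=1.0 if not degenerate else 0.0,
            kind="paired",
            mean1=float(a.mean()),
            mean2=float(b.mean()),
            n1=n,
            n2=n,
            degenerate=degenerate,
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return TestResult(
        statistic=float(t),
        df=float(n - 1),
        p=float(p),
        kind="paired",
        mean1=float(a.mean()),
        mean2=float(b.mean()),
        sd1=float(a.std(ddof=1)),
        sd2=float(b.std(ddof=1)),
        n1=n,
        n2=n,
    )


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p values, in input order (capped at 1, monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    The p value uses the large-sample t approximation with n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("samples must have equal lengths")
    n = x.size
    if n < 3:
        raise ParameterError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant input; correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r_s=r, p=p, n=n)


def normality(sample, method: str = "SW") -> float:
    """Normality-test p value: ``"KS"`` (Lilliefors-corrected Kolmogorov-
    Smirnov against the fitted normal, n >= 8) or ``"SW"`` (Shapiro-Wilk,
    n >= 3)."""
    x = np.asarray(sample, dtype=float)
    if method == "SW":
        if x.size < 3:
            raise ParameterError("Shapiro-Wilk needs n >= 3")
        if x.std() == 0:
            raise DegenerateInputError("constant sample")
        return float(sps.shapiro(x).pvalue)
    if method == "KS":
        if x.size < 8:
            raise ParameterError("KS normality test needs n >= 8")
        if x.std() == 0:
            raise DegenerateInputError("constant sample")
        return float(lilliefors(x, dist="norm")[1])
    raise ParameterError(f"unknown method {method!r}")


def covariate_regression(
    data: pd.DataFrame,
    y: str,
    covariates: tuple[str, ...] = ("condition", "age_years", "gender", "pmi_hours"),
) -> pd.DataFrame:
    """OLS of a subject measure on condition and nuisance covariates.

    Categorical condition/gender columns are coded as binary indicators.
    Returns one row per coefficient with ``coef``, ``p`` and the model R^2;
    rank-deficient designs raise an error naming the collinear columns.
    """
    X = pd.DataFrame(index=data.index)
    for cov in covariates:
        col = data[cov]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.unique())
            if len(levels) < 2:
                raise ParameterError(f"covariate {cov!r} has a single level")
            X[cov] = (col == levels[-1]).astype(float)
        else:
            X[cov] = col.astype(float)
    if len(data) <= X.shape[1] + 1:
        raise ParameterError("need more subjects than coefficients")
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the offending columns for the caller
        bad = []
        cols = list(Xc.columns)
        for j in range(Xc.shape[1]):
            sub = Xc.drop(columns=[cols[j]])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                bad.append(cols[j])
        raise ParameterError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(data[y].astype(float), Xc).fit()
    out = pd.DataFrame(
        {
            "term": fit.params.index,
            "coef": fit.params.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    out["r_squared"] = fit.rsquared
    return out


def percent_reduction(mean_control: float, mean_case: float) -> int:
    """100 x (control - case) / control, rounded to the nearest integer percent."""
    if mean_control <= 0:
        raise ParameterError("control mean must be > 0")
    return int(round(100.0 * (mean_control - mean_case) / mean_control))
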