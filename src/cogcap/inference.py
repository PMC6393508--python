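"""Correlation-level inference: one-tailed Pearson tests, default Bayes
factors for correlations, evidence-category labelling, and z tests comparing
dependent correlations.

The Bayes factor is the default Jeffreys–Zellner–Siow (JZS) test for a
Pearson correlation: under the alternative, the regression effect carries a
Cauchy prior induced by Zellner's g-prior with an inverse-chi-squared mixing
distribution on g, which reduces the Bayes factor to a one-dimensional
integral depending on (r, n) only,

    BF10 = sqrt(n/2) / Gamma(1/2) *
           Int_0^inf (1+g)^((n-2)/2) (1+(1-r^2) g)^(-(n-1)/2)
                      g^(-3/2) exp(-n/(2g)) dg.

It is symmetric in the sign of r, increasing in |r| at fixed n, and
increasing in n at fixed |r| > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "CorrelationResult",
    "DependentCorrelationTest",
    "pearson_one_tailed",
    "jzs_correlation_bf",
    "interpret_bf",
    "compare_dependent_correlations",
    "correlation_table",
    "render_correlation_matrix",
]

@dataclass
class CorrelationResult:
    r: float
    n: int
    p_one_tailed: float
    bf10: float | None = None
    category: str | None = None


@dataclass
class DependentCorrelationTest:
    r1: float
    r2: float
    r_predictors: float
    n: int
    z: float
    p_one_tailed: float
    method: str


def pearson_one_tailed(x, y) -> CorrelationResult:
    """Pearson correlation with an upper-tail (positive-association) p value.

    p is derived from ``t = r sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees of
    freedom; for r = 0 the p value is 0.5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0 if r > 0 else 1.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(stats.t.sf(t, df=n - 2))
    return CorrelationResult(r=r, n=n, p_one_tailed=p)


def jzs_correlation_bf(r: float, n: int, one_sided: bool = False) -> float:
    """Default JZS Bayes factor BF10 for a Pearson correlation.

    Evaluated by adaptive quadrature of the g-integral; a function of
    (|r|, n) only in the two-sided default.  ``one_sided=True`` applies the
    order-restricted correction for an association in the observed
    direction, multiplying BF10 by twice the (approximate) posterior mass on
    that sign, here taken from the t posterior of the slope.
    """
    n = int(n)
    if n <= 3:
        raise ValueError("need n > 3")
    if not (-1.0 < r < 1.0):
        raise ValueError("need |r| < 1")
    r2 = r * r

    def integrand(g: float) -> float:
        # evaluated in log space: the two power factors overflow separately
        # for large g and n even though their product is bounded
        log_val = (
            (n - 2) / 2.0 * np.log1p(g)
            - (n - 1) / 2.0 * np.log1p((1.0 - r2) * g)
            - 1.5 * np.log(g)
            - n / (2.0 * g)
        )
        return float(np.exp(log_val))

    val, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-4):
        raise ArithmeticError(
            f"JZS quadrature did not converge (value={val}, abserr={err})"
        )
    bf = float(np.sqrt(n / 2.0) / special.gamma(0.5) * val)
    if one_sided:
        # directional correction: twice the posterior mass on the observed
        # sign, approximated by the frequentist one-tailed probability
        t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r2)
        bf *= 2.0 * float(stats.t.cdf(t, df=n - 2))
    return bf


def interpret_bf(bf10: float) -> str:
    """Evidence category for a Bayes factor.

    > 100: decisive evidence for a correlation; > 3: substantial; < 1/3:
    substantial evidence for the null; [1/3, 3]: the data are insensitive.
    Boundary values map to the weaker category.
    """
    if bf10 <= 0:
        raise ValueError("Bayes factor must be positive")
    if bf10 > 100.0:
        return "decisive"
    if bf10 > 3.0:
        return "substantial"
    if bf10 < 1.0 / 3.0:
        return "substantial_null"
    return "insensitive"


def _fisher_z(r: float) -> float:
    return float(np.arctanh(r))


def _check_psd(r1: float, r2: float, rx: float) -> None:
    m = np.array([[1.0, r1, r2], [r1, 1.0, rx], [r2, rx, 1.0]])
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ValueError("inadmissible correlation triple (non-PSD)")


def compare_dependent_correlations(
    r1: float,
    r2: float,
    r_predictors: float,
    n: int,
    method: str = "steiger",
) -> DependentCorrelationTest:
    """z test for two dependent correlations sharing an outcome variable.

    ``r1 = cor(y, a)`` and ``r2 = cor(y, b)`` with ``r_predictors =
    cor(a, b)``.  Steiger's Z1* (default) pools the two correlations when
    estimating the covariance of the Fisher transforms; the
    Meng–Rosenthal–Rubin variant is available as ``method="meng"``.  The
    one-tailed p refers to the hypothesis r1 > r2.
    """
    for r in (r1, r2, r_predictors):
        if not (-1.0 < r < 1.0):
            raise ValueError("all correlations must satisfy |r| < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    _check_psd(r1, r2, r_predictors)
    z1, z2 = _fisher_z(r1), _fisher_z(r2)
    rx = r_predictors

    if method == "meng":
        rbar2 = (r1 * r1 + r2 * r2) / 2.0
        f = min((1.0 - rx) / (2.0 * (1.0 - rbar2)), 1.0)
        h = (1.0 - f * rbar2) / (1.0 - rbar2)
        z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - rx) * h))
    elif method == "steiger":
        rbar = (r1 + r2) / 2.0
        rbar2 = rbar * rbar
        psi = rx * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - rx * rx)
        s = psi / (1.0 - rbar2) ** 2
        z = (z1 - z2) * np.sqrt(n - 3) / np.sqrt(2.0 - 2.0 * s)
    else:
        raise ValueError(f"unknown method {method!r}")

    return DependentCorrelationTest(
        r1=r1,
        r2=r2,
        r_predictors=rx,
        n=n,
        z=float(z),
        p_one_tailed=float(stats.norm.sf(z)),
        method=method,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(
    measures: pd.DataFrame,
    columns: list[str] | None = None,
    round_r: int = 2,
    one_sided_bf: bool = False,
) -> pd.DataFrame:
    """Pairwise one-tailed correlations with Bayes factors, long format.

    Pairwise-complete observations; BFs are computed on r rounded to
    ``round_r`` decimals, so equal printed correlations share identical BFs.
    Columns of the output: ``var1, var2, n, r, p_one_tailed, stars, bf10,
    bf_category``.
    """
    if columns is None:
        columns = [
            c
            for c in measures.columns
            if c not in ("subject_id", "education_years_us")
        ]
    rows = []
    for i in range(1, len(columns)):
        for j in range(i):
            v1, v2 = columns[i], columns[j]
            pair = measures[[v1, v2]].dropna()
            if len(pair) < 4:
                raise ValueError(f"fewer than 4 complete rows for ({v1}, {v2})")
            res = pearson_one_tailed(pair[v1], pair[v2])
            r_rounded = round(res.r, round_r)
            bf = jzs_correlation_bf(r_rounded, res.n, one_sided=one_sided_bf)
            rows.append(
                {
                    "var1": v1,
                    "var2": v2,
                    "n": res.n,
                    "r": res.r,
                    "p_one_tailed": res.p_one_tailed,
                    "stars": _stars(res.p_one_tailed),
                    "bf10": bf,
                    "bf_category": interpret_bf(bf),
                }
            )
    return pd.DataFrame(rows)


def render_correlation_matrix(table: pd.DataFrame) -> str:
    """Lower-triangle text matrix: r with stars, BF beneath (">100" capped)."""
    vars_order: list[str] = []
    for _, row in table.iterrows():
        for v in (row["var2"], row["var1"]):
            if v not in vars_order:
                vars_order.append(v)
    cell: dict[tuple[str, str], str] = {}
    for _, row in table.iterrows():
        bf = row["bf10"]
        bf_str = ">100" if bf > 100 else f"{bf:.2f}"
        cell[(row["var1"], row["var2"])] = f"{row['r']:.2f}{row['stars']} ({bf_str})"
    width = max(len(v) for v in vars_order) + 2
    cw = 18
    lines = [" " * width + "".join(f"{v:>{cw}}" for v in vars_order[:-1])]
    for i, v1 in enumerate(vars_order[1:], start=1):
        entries = []
        for v2 in vars_order[:i]:
            entries.append(cell.get((v1, v2), cell.get((v2, v1), "")))
        lines.append(f"{v1:<{width}}" + "".join(f"{e:>{cw}}" for e in entries))
    return "\n".join(lines)
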