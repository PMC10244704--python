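"""Statistical layer: pooled two-sample t-test and binomial tail probabilities.

The t-test is the classical equal-variance two-tailed test; the two-tailed
p-value is evaluated through the regularized incomplete beta function
(``p = I_{df/(df+t²)}(df/2, 1/2)``). Binomial tails are summed in log space.

For success-count comparisons between two ensembles (k_ref/n_ref vs
k_alt/n_alt) several binomial constructions are defensible; the default here
tests whether the alternative condition produced more successes than expected
under the reference condition's empirical rate, i.e.
``P(X ≥ k_alt | n_alt, p0 = k_ref/n_ref)``. The construction used is always
carried in the result record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, gammaln, logsumexp


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_two_tailed: float


@dataclass(frozen=True)
class BinomialResult:
    k: int
    n: int
    p0: float
    p_upper_tail: float
    construction: str = "upper_tail_alt_at_ref_rate"


def ttest_equal_var_two_tailed(x, y) -> TTestResult:
    """Two-sample t-test assuming equal variances, two-tailed.

    Pooled variance s² = [(n₁−1)s₁² + (n₂−1)s₂²] / (n₁+n₂−2),
    t = (x̄−ȳ) / √(s²(1/n₁+1/n₂)), df = n₁+n₂−2.

    If the pooled variance is zero the test is degenerate: p = 1 when the
    means coincide (t = 0 by convention), otherwise t = ±inf and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if s2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0)
    t = diff / math.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    p = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    return TTestResult(float(t), df, min(max(p, 0.0), 1.0))


def _binom_log_pmf(k: np.ndarray, n: int, p0: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    logp = math.log(p0) if p0 > 0 else -math.inf
    logq = math.log1p(-p0) if p0 < 1 else -math.inf
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    # 0·(-inf) terms are defined as 0 (k=0 with p0=0, etc.)
    term_p = np.zeros_like(k)
    term_p[k > 0] = k[k > 0] * logp
    term_q = np.zeros_like(k)
    term_q[n - k > 0] = (n - k)[n - k > 0] * logq
    return out + term_p + term_q


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X ≥ k) for X ~ Binomial(n, p0), summed stably in log space."""
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, {n}], got {k}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if k == 0:
        return 1.0
    js = np.arange(k, n + 1)
    return float(min(1.0, math.exp(logsumexp(_binom_log_pmf(js, n, p0)))))


def binomial_lower_tail(k: int, n: int, p0: float) -> float:
    """P(X ≤ k) for X ~ Binomial(n, p0)."""
    if k < 0:
        return 0.0
    if k >= n:
        return 1.0
    js = np.arange(0, k + 1)
    return float(min(1.0, math.exp(logsumexp(_binom_log_pmf(js, n, p0)))))


def compare_success_counts(
    k_ref: int,
    n_ref: int,
    k_alt: int,
    n_alt: int,
    construction: str = "upper_tail_alt_at_ref_rate",
) -> BinomialResult:
    """Binomial p-value comparing two success counts.

    Constructions:

    - ``upper_tail_alt_at_ref_rate`` (default): P(X ≥ k_alt | n_alt,
      p0 = k_ref/n_ref) — "did the alternative succeed more often than the
      reference rate predicts".
    - ``upper_tail_alt_at_pooled_rate``: same but p0 = (k_ref+k_alt)/(n_ref+n_alt).
    - ``lower_tail_ref_at_alt_rate``: P(X ≤ k_ref | n_ref, p0 = k_alt/n_alt).

    A zero reference rate is floored at 1/(2·n_ref) with a warning so the
    null is never degenerate.
    """
    for name, k, n in (("reference", k_ref, n_ref), ("alternative", k_alt, n_alt)):
        if not 0 <= k <= n:
            raise ValueError(f"{name} count {k} outside [0, {n}]")
    if construction == "upper_tail_alt_at_ref_rate":
        p0 = k_ref / n_ref
        if p0 == 0.0:
            p0 = 1.0 / (2 * n_ref)
            warnings.warn(
                f"reference success rate is 0; using p0 floor {p0:g}", stacklevel=2
            )
        p = binomial_upper_tail(k_alt, n_alt, p0)
        return BinomialResult(k_alt, n_alt, p0, p, construction)
    if construction == "upper_tail_alt_at_pooled_rate":
        p0 = (k_ref + k_alt) / (n_ref + n_alt)
        if p0 == 0.0:
            p0 = 1.0 / (2 * (n_ref + n_alt))
            warnings.warn(
                f"pooled success rate is 0; using p0 floor {p0:g}", stacklevel=2
            )
        p = binomial_upper_tail(k_alt, n_alt, p0)
        return BinomialResult(k_alt, n_alt, p0, p, construction)
    if construction == "lower_tail_ref_at_alt_rate":
        p0 = k_alt / n_alt
        p = binomial_lower_tail(k_ref, n_ref, p0)
        return BinomialResult(k_ref, n_ref, p0, p, construction)
    raise ValueError(f"unknown construction {construction!r}")
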