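"""Group-level statistics: signed-rank tests, Spearman CIs, normality.

LI distributions are typically non-normal (the peak method induces
bimodality), so the group inferences use Wilcoxon signed-rank tests.
The reported statistic V is the R convention: the sum of the ranks of
the positive deviations, with zeros dropped and ties receiving average
ranks.  Spearman correlations carry a seeded nonparametric bootstrap CI
(resampling participants as pairs); a Fisher-z analytic interval is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io_formats import PipelineConfig, ValidationError

__all__ = [
    "TestResult",
    "signed_rank_one_sample",
    "signed_rank_paired",
    "spearman_ci",
    "normality_check",
]

ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    name: str
    statistic: float
    p: float
    alternative: str
    n: int
    notes: str = ""


def _signed_rank_V(d: np.ndarray) -> float:
    """Sum of ranks of positive deviations (average ranks for ties)."""
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def signed_rank_one_sample(values, mu: float = 0.0, alternative: str = "two_sided") -> TestResult:
    """One-sample Wilcoxon signed-rank test of the median against ``mu``.

    Values equal to ``mu`` are dropped (standard convention).  The exact
    null distribution is used for n ≤ 25 without ties in |deviations|;
    otherwise the normal approximation with continuity correction.
    """
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"unknown alternative {alternative!r}")
    values = np.asarray(values, dtype=float)
    d = values - mu
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return TestResult(
            name="wilcoxon_signed_rank",
            statistic=float("nan"),
            p=float("nan"),
            alternative=alternative,
            n=0,
            notes="degenerate: all values equal the reference",
        )
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(
        d,
        alternative=ALTERNATIVES[alternative],
        method=method,
        correction=(method == "approx"),
    )
    notes = method
    if n < 5:
        notes += "; n < 5, p has little resolution"
    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=_signed_rank_V(d),
        p=float(res.pvalue),
        alternative=alternative,
        n=n,
        notes=notes,
    )


def signed_rank_paired(x, y, alternative: str = "two_sided") -> TestResult:
    """Paired Wilcoxon signed-rank test: one-sample test on x − y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    res = signed_rank_one_sample(x - y, mu=0.0, alternative=alternative)
    res.name = "wilcoxon_signed_rank_paired"
    return res


def spearman_ci(x, y, cfg: PipelineConfig, method: str = "bootstrap") -> tuple[float, float, float]:
    """Spearman rho with a 95 % CI → ``(rho, ci_low, ci_high)``.

    ``method="bootstrap"`` (default): seeded percentile bootstrap over
    pairs with ``cfg.bootstrap_n`` resamples; degenerate resamples
    (constant vectors) are dropped.  ``method="fisher"``: analytic
    Fisher-z interval with the 1.06/(n−3) variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be paired 1-d arrays")
    n = len(x)
    if n < 4:
        raise ValidationError("Spearman CI needs at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("rho undefined for a constant input vector")
    rho = float(sps.spearmanr(x, y).statistic)
    alpha = 1.0 - cfg.ci_level
    if method == "fisher":
        z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
        se = np.sqrt(1.06 / (n - 3))
        zc = sps.norm.ppf(1 - alpha / 2)
        return rho, float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))
    if method != "bootstrap":
        raise ValidationError(f"unknown CI method {method!r}")
    rng = np.random.default_rng(cfg.rng_seed)
    boots = np.empty(cfg.bootstrap_n)
    boots.fill(np.nan)
    for b in range(cfg.bootstrap_n):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            continue
        boots[b] = sps.spearmanr(xb, yb).statistic
    boots = boots[np.isfinite(boots)]
    if len(boots) == 0:
        raise ValidationError("all bootstrap resamples degenerate")
    ci_low, ci_high = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return rho, float(ci_low), float(ci_high)


def normality_check(values) -> TestResult:
    """Shapiro–Wilk test of normality (3 ≤ n ≤ 5000)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3 or n > 5000:
        raise ValidationError("Shapiro–Wilk requires 3 <= n <= 5000")
    w, p = sps.shapiro(values)
    return TestResult(
        name="shapiro_wilk",
        statistic=float(w),
        p=float(p),
        alternative="two_sided",
        n=n,
    )
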