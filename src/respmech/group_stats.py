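"""Two-group comparison battery with normality routing, FDR control and
effect sizes.

Each outcome is compared between two independent groups: Shapiro-Wilk
normality on both groups routes the comparison to a pooled-variance
independent-samples t-test (with Hedges' g and its 95% CI) or to a
Mann-Whitney U test (with the rank-biserial correlation and a bootstrap CI).
p-values are adjusted within comparison families by the Benjamini-Hochberg
step-up procedure; significance is declared at q < 0.05.

The Hedges' g conventions used everywhere:

    s_p = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2))
    d   = (mean1 - mean2) / s_p
    g   = d * J,   J = 1 - 3 / (4 (n1+n2) - 9)
    SE  = sqrt((n1+n2)/(n1 n2) + g^2 / (2 (n1+n2)))
    CI  = g ± 1.96 SE

A noncentral-t based CI and a Welch t-test are available behind flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GroupSample",
    "GroupComparison",
    "route_test",
    "t_test",
    "mann_whitney",
    "hedges_g",
    "hedges_g_from_samples",
    "rank_biserial_ci",
    "bh_fdr",
    "sample_size_two_sample_t",
    "compare_outcomes",
]


@dataclass
class GroupSample:
    """Per-participant trial-mean values of one outcome in one group."""

    outcome: str
    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a group sample needs at least 2 values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.outcome}/{self.group}")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class GroupComparison:
    """One outcome's two-group test result."""

    outcome: str
    family: str
    route: str  # 't' | 'mann_whitney'
    statistic: float
    p: float
    q: float  # BH-FDR within family; NaN until adjusted
    effect_size: float  # Hedges' g or rank-biserial r
    ci_low: float
    ci_high: float
    desc_a: str
    desc_b: str
    notes: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return bool(self.q < 0.05)


# ---------------------------------------------------------------------------
# routing and tests
# ---------------------------------------------------------------------------


def route_test(a: GroupSample, b: GroupSample, alpha: float = 0.05) -> str:
    """Shapiro-Wilk routing: 't' only when both groups look normal.

    Samples smaller than 3 cannot be tested for normality; they fall back to
    the rank-based route with a warning.
    """
    if a.n < 3 or b.n < 3:
        warnings.warn(
            f"{a.outcome}: group with n < 3; routing to Mann-Whitney", stacklevel=2
        )
        return "mann_whitney"
    for s in (a, b):
        if np.ptp(s.values) == 0:  # Shapiro-Wilk undefined on constant data
            return "mann_whitney"
        if stats.shapiro(s.values).pvalue < alpha:
            return "mann_whitney"
    return "t"


def t_test(a: GroupSample, b: GroupSample, welch: bool = False) -> tuple[float, float]:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    x, y = a.values, b.values
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means: p set to 0", stacklevel=2)
        return math.inf, 0.0
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


#: product n1*n2 up to which the exact Mann-Whitney null distribution is used
EXACT_MW_LIMIT = 64


def mann_whitney(a: GroupSample, b: GroupSample) -> tuple[float, float, float]:
    """Mann-Whitney U with rank-biserial effect size.

    Returns ``(U_a, p, r)`` where ``U_a`` counts pairs (x from a, y from b)
    with x > y plus half the ties, and ``r = 2 U_a / (n1 n2) - 1`` in
    [-1, 1].  The p-value is exact (full null enumeration) when
    ``n1*n2 <= 64`` and there are no ties across groups, otherwise the
    normal approximation with tie and continuity corrections.
    """
    x, y = a.values, b.values
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    r = 2.0 * u / (x.size * y.size) - 1.0
    return u, float(res.pvalue), float(r)


def rank_biserial_ci(
    a: GroupSample,
    b: GroupSample,
    n_boot: int = 2000,
    confidence: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the rank-biserial correlation."""
    rng = np.random.default_rng(seed)
    x, y = a.values, b.values
    xb = rng.choice(x, (n_boot, x.size), replace=True)
    yb = rng.choice(y, (n_boot, y.size), replace=True)
    gt = (xb[:, :, None] > yb[:, None, :]).sum(axis=(1, 2))
    eq = (xb[:, :, None] == yb[:, None, :]).sum(axis=(1, 2))
    boots = 2.0 * (gt + 0.5 * eq) / (x.size * y.size) - 1.0
    tail = (1.0 - confidence) / 2.0
    lo, hi = np.percentile(boots, [100 * tail, 100 * (1 - tail)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------


def hedges_g(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    confidence: float = 0.95,
    noncentral_ci: bool = False,
) -> tuple[float, float, float]:
    """Bias-corrected standardized mean difference from group summaries.

    Positive g means group 1 exceeds group 2.  The default CI uses the
    normal-approximation standard error
    ``sqrt((n1+n2)/(n1 n2) + g^2/(2(n1+n2)))``; ``noncentral_ci=True``
    inverts the noncentral-t distribution instead.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    s_p = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if s_p == 0:
        raise ZeroDivisionError("pooled SD is zero")
    d = (mean1 - mean2) / s_p
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = d * j
    if noncentral_ci:
        scale = math.sqrt(n1 * n2 / (n1 + n2))
        t_obs = d * scale
        df = n1 + n2 - 2
        tail = (1.0 - confidence) / 2.0
        lo = _nct_invert(t_obs, df, 1.0 - tail) * j / scale
        hi = _nct_invert(t_obs, df, tail) * j / scale
        return g, lo, hi
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    se = math.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2)))
    return g, g - z * se, g + z * se


def _nct_invert(t_obs: float, df: int, prob: float) -> float:
    """Noncentrality delta with P(T_df,delta <= t_obs) = prob."""
    from scipy.optimize import brentq

    f = lambda delta: stats.nct.cdf(t_obs, df, delta) - prob
    lo, hi = t_obs - 50, t_obs + 50
    return float(brentq(f, lo, hi))


def hedges_g_from_samples(
    a: GroupSample, b: GroupSample, **kwargs
) -> tuple[float, float, float]:
    return hedges_g(
        float(a.values.mean()), float(a.values.std(ddof=1)), a.n,
        float(b.values.mean()), float(b.values.std(ddof=1)), b.n,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# multiplicity and power
# ---------------------------------------------------------------------------


def bh_fdr(pvalues, families=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, computed within families.

    ``q_(i) = min_{j>=i} (p_(j) * m / j)`` capped at 1, with the order
    restored to the input.  ``families`` (optional, same length) partitions
    the p-values into independent correction families.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if families is None:
        families = np.zeros(p.size)
    families = np.asarray(families)
    q = np.empty_like(p)
    for fam in np.unique(families):
        sel = families == fam
        pf = p[sel]
        m = pf.size
        order = np.argsort(pf, kind="stable")
        ranked = pf[order] * m / np.arange(1, m + 1)
        qf = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(qf, 1.0)
        q[sel] = out
    return q


def sample_size_two_sample_t(
    effect: float, alpha: float = 0.05, power: float = 0.8, max_n: int = 100000
) -> tuple[int, int]:
    """Smallest balanced design powering a two-sided two-sample t-test.

    Iterates per-group n upward, computing achieved power from the
    noncentral-t distribution with noncentrality ``effect * sqrt(n/2)``,
    until it reaches the target.  Returns ``(n_per_group, total)``.
    """
    if not effect > 0:
        raise ValueError("effect must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, max_n + 1):
        df = 2 * n - 2
        t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        delta = effect * math.sqrt(n / 2.0)
        achieved = (1.0 - stats.nct.cdf(t_crit, df, delta)) + stats.nct.cdf(-t_crit, df, delta)
        if achieved >= power:
            return n, 2 * n
    raise ValueError(f"power {power} unreachable with n <= {max_n} per group")


# ---------------------------------------------------------------------------
# the battery
# ---------------------------------------------------------------------------


def _descriptive(values: np.ndarray, route: str) -> str:
    if route == "t":
        return f"{values.mean():.2f} ± {values.std(ddof=1):.2f}"
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return f"{q50:.2f} ({q25:.2f},{q75:.2f})"


def compare_outcomes(
    samples: dict[str, tuple[GroupSample, GroupSample]],
    families: dict[str, str] | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    welch: bool = False,
) -> list[GroupComparison]:
    """Run the full routed battery over many outcomes.

    ``samples`` maps outcome name to its (group A, group B) pair; group A is
    reported first and positive effects mean A > B.  ``families`` maps
    outcome name to a correction-family id (movement x category); outcomes
    without one form a single family.  One outcome's failure is recorded in
    its ``notes`` and never aborts the rest.
    """
    families = families or {}
    results: list[GroupComparison] = []
    for outcome in samples:
        a, b = samples[outcome]
        family = families.get(outcome, "all")
        try:
            route = route_test(a, b, alpha=alpha)
            if route == "t":
                statistic, p = t_test(a, b, welch=welch)
                g, lo, hi = hedges_g_from_samples(a, b)
                eff, ci = g, (lo, hi)
            else:
                statistic, p, r = mann_whitney(a, b)
                ci = rank_biserial_ci(a, b, seed=seed)
                eff = r
            results.append(
                GroupComparison(
                    outcome=outcome, family=family, route=route,
                    statistic=statistic, p=p, q=float("nan"),
                    effect_size=eff, ci_low=ci[0], ci_high=ci[1],
                    desc_a=_descriptive(a.values, route),
                    desc_b=_descriptive(b.values, route),
                )
            )
        except Exception as exc:  # keep the battery running
            results.append(
                GroupComparison(
                    outcome=outcome, family=family, route="error",
                    statistic=float("nan"), p=float("nan"), q=float("nan"),
                    effect_size=float("nan"), ci_low=float("nan"),
                    ci_high=float("nan"), desc_a="", desc_b="",
                    notes=[f"{type(exc).__name__}: {exc}"],
                )
            )
    ok = [i for i, r in enumerate(results) if np.isfinite(r.p)]
    if ok:
        q = bh_fdr([results[i].p for i in ok], [results[i].family for i in ok])
        for i, qi in zip(ok, q):
            results[i].q = float(qi)
    return results
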