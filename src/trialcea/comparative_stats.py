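"""Comparative statistics for a two-arm trial.

2x2 contingency tests (Pearson chi-square without continuity correction,
Fisher's exact test), odds ratios with Woolf confidence intervals, rank and t
tests for the score outcomes, and the equivalence-trial sample-size
calculation with a simulation-based verification.

Conventions: a 2x2 table has rows (SH; MLPPH) and first column = event, so
the odds ratio reported is for MLPPH relative to SH.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "OddsRatioResult",
    "EquivalenceDesign",
    "pearson_chi2",
    "fisher_exact",
    "odds_ratio",
    "mann_whitney",
    "two_sample_t",
    "two_sample_t_from_summary",
    "equivalence_sample_size",
    "equivalence_coverage_simulation",
]

#: both samples at or below this size (and tie-free) use exact Mann-Whitney
#: enumeration; larger samples use the tie-corrected normal approximation
MANN_WHITNEY_EXACT_THRESHOLD = 10


class DegenerateTableError(ValueError):
    """A margin of the 2x2 table is zero; the test is undefined."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Event / non-event counts by arm: rows (SH; MLPPH), columns (event; non-event)."""

    a: int  # SH events
    b: int  # SH non-events
    c: int  # MLPPH events
    d: int  # MLPPH non-events

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("at least one count must be positive")

    @classmethod
    def from_events(cls, events_sh: int, n_sh: int, events_mlpph: int, n_mlpph: int):
        return cls(events_sh, n_sh - events_sh, events_mlpph, n_mlpph - events_mlpph)

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def n(self) -> int:
        return int(self.a + self.b + self.c + self.d)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.df is not None and self.df < 1:
            raise ValueError("df must be >= 1 when present")


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    level: float
    #: True when a zero cell required the Haldane-Anscombe 0.5 correction
    continuity_corrected: bool = False


@dataclass(frozen=True)
class EquivalenceDesign:
    """Design of an equivalence trial on two proportions.

    ``delta`` is the equivalence margin on the difference of proportions;
    ``p1``/``p2`` the anticipated proportions feeding the variance term.
    """

    delta: float
    alpha: float = 0.05
    power: float = 0.90
    p1: float = 0.91
    p2: float = 0.68

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("equivalence margin delta must lie in (0, 1)")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if not 0 < self.p1 < 1 or not 0 < self.p2 < 1:
            raise ValueError("anticipated proportions must lie in (0, 1)")


def _check_margins(table: ContingencyTable2x2) -> None:
    t = table.counts
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateTableError("zero row or column margin")


def pearson_chi2(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1.

    Statistic ``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with a two-sided p
    from the chi-square(1) distribution.
    """
    _check_margins(table)
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(statistic=float(stat), p_value=p, df=1, method="Pearson chi-square")


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Fisher's exact test, two-sided by the hypergeometric-summation rule."""
    _check_margins(table)
    res = stats.fisher_exact(table.counts.astype(int), alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="Fisher exact",
    )


def odds_ratio(table: ContingencyTable2x2, level: float = 0.95) -> OddsRatioResult:
    """Odds ratio for MLPPH relative to SH with a Woolf (log-scale) CI.

    A single zero cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell), flagged in the result; both cells of a diagonal being zero
    leaves the OR undefined and raises.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise ValueError("odds ratio undefined: both cells of a diagonal are zero")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    point = (c / d) / (a / b)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return OddsRatioResult(
        or_point=float(point),
        ci_low=float(point * math.exp(-z * se)),
        ci_high=float(point * math.exp(z * se)),
        level=level,
        continuity_corrected=corrected,
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U test (two-sided); U is the statistic of the first sample.

    Exact enumeration when both samples have at most
    :data:`MANN_WHITNEY_EXACT_THRESHOLD` observations and no ties; otherwise
    the tie-corrected normal approximation (no continuity correction, so
    identical samples give p = 1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled_unique = np.unique(np.concatenate([x, y])).size
    if pooled_unique == 1:
        # every observation tied: no evidence either way
        return TestResult(
            statistic=float(x.size * y.size / 2),
            p_value=1.0,
            method="Mann-Whitney U (degenerate: all observations tied)",
        )
    small = x.size <= MANN_WHITNEY_EXACT_THRESHOLD and y.size <= MANN_WHITNEY_EXACT_THRESHOLD
    tie_free = pooled_unique == x.size + y.size
    if small and tie_free:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "Mann-Whitney U (exact)"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        method = "Mann-Whitney U (normal approximation, tie-corrected)"
    return TestResult(
        statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)), method=method
    )


def two_sample_t(
    x: Sequence[float], y: Sequence[float], variant: str = "pooled"
) -> TestResult:
    """Two-sample t test; ``variant`` is ``"pooled"`` (Student) or ``"welch"``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        # degenerate: both samples constant and equal
        return TestResult(statistic=0.0, p_value=1.0, method=f"t test ({variant})")
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=None,
        method=f"t test ({variant})",
    )


def two_sample_t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> TestResult:
    """Two-sample t test from printed summary statistics (mean, sd, n)."""
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"t test ({variant}, summary)",
    )


def equivalence_sample_size(design: EquivalenceDesign) -> int:
    """Per-arm n for an equivalence trial on two proportions.

    Smallest n such that, with a true difference of zero, the two-sided
    (1 - alpha) Wald confidence interval for the difference falls entirely
    inside (-delta, delta) with probability >= power, by the normal
    approximation

        n = (z_{1-alpha/2} + z_{(1+power)/2})^2 (p1 q1 + p2 q2) / delta^2.

    :func:`equivalence_coverage_simulation` verifies the returned n by direct
    simulation.
    """
    za = stats.norm.ppf(1 - design.alpha / 2)
    zb = stats.norm.ppf((1 + design.power) / 2)
    variance = design.p1 * (1 - design.p1) + design.p2 * (1 - design.p2)
    n = (za + zb) ** 2 * variance / design.delta**2
    return int(math.ceil(n))


def variance_matching_proportion(design: EquivalenceDesign) -> float:
    """Common proportion p* with 2 p*(1-p*) = p1(1-p1) + p2(1-p2).

    A zero-true-difference simulation needs a single proportion for both arms;
    this choice reproduces the variance the sample-size formula assumes, so the
    simulation checks the formula under its own assumptions.
    """
    v = design.p1 * (1 - design.p1) + design.p2 * (1 - design.p2)
    disc = max(0.0, 1.0 - 2.0 * v)
    return 0.5 * (1.0 + math.sqrt(disc))


def equivalence_coverage_simulation(
    n: int,
    design: EquivalenceDesign,
    n_trials: int = 10_000,
    seed: int = 0,
    common_p: Optional[float] = None,
) -> float:
    """Fraction of simulated zero-difference trials whose Wald CI lies in (-delta, delta).

    Both arms draw Binomial(n, p) with ``p = common_p`` (default: the
    variance-matching proportion of the design).
    """
    if n < 1 or n_trials < 1:
        raise ValueError("n and n_trials must be >= 1")
    p = variance_matching_proportion(design) if common_p is None else common_p
    rng = np.random.default_rng(seed)
    p1_hat = rng.binomial(n, p, size=n_trials) / n
    p2_hat = rng.binomial(n, p, size=n_trials) / n
    diff = p1_hat - p2_hat
    se = np.sqrt(p1_hat * (1 - p1_hat) / n + p2_hat * (1 - p2_hat) / n)
    za = stats.norm.ppf(1 - design.alpha / 2)
    contained = (diff - za * se > -design.delta) & (diff + za * se < design.delta)
    return float(np.mean(contained))
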