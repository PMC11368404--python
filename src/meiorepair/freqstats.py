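"""Frequency statistics for recombinant and SCE counts.

Point estimates are binomial proportions with Wilson score intervals (the
DescTools default, which reproduces the published intervals), and group
comparisons are two-sided Fisher exact tests on pooled 2x2 tables using the
point-probability criterion (the R ``fisher.test`` convention): the p-value is
the sum of hypergeometric probabilities of all tables with the observed
margins whose probability does not exceed that of the observed table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "BinomialEstimate",
    "GroupComparison",
    "wilson_ci",
    "fisher_exact_two_sided",
    "fold_change",
    "crossover_proportion",
    "compare_groups",
]


@dataclasses.dataclass(frozen=True)
class BinomialEstimate:
    """A binomial proportion k/n with a confidence interval."""

    successes: int
    trials: int
    point: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95

    def __str__(self) -> str:  # the paper's reporting convention: 1 decimal in %
        return (f"{self.successes}/{self.trials} = {100 * self.point:.1f}% "
                f"({100 * self.conf_level:g}% CI {100 * self.ci_low:.1f}-"
                f"{100 * self.ci_high:.1f}%)")


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    table: tuple[tuple[int, int], tuple[int, int]]
    p: float
    estimate1: BinomialEstimate
    estimate0: BinomialEstimate


def wilson_ci(k: int, n: int, conf: float = 0.95,
              method: str = "wilson") -> BinomialEstimate:
    """Binomial proportion with a Wilson score interval.

    ``method="beta"`` gives the Clopper-Pearson exact interval instead.
    Bounds are clipped to [0, 1]; k = 0 pins the Wilson lower bound to 0 and
    k = n pins the upper bound to 1.
    """
    k, n = int(k), int(n)
    if n < 1:
        raise ValueError("undefined estimate: n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < conf < 1.0):
        raise ValueError("conf must be in (0, 1)")
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method=method)
    # the analytic Wilson bounds are exactly 0 at k=0 and 1 at k=n; pin them
    # so floating-point round-off cannot push them past the point estimate
    lo = 0.0 if k == 0 else float(np.clip(lo, 0.0, 1.0))
    hi = 1.0 if k == n else float(np.clip(hi, 0.0, 1.0))
    return BinomialEstimate(successes=k, trials=n, point=k / n,
                            ci_low=lo, ci_high=hi, conf_level=conf)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Degenerate margins (a zero row or column total) make the conditional
    distribution a point mass; p = 1 in that case.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    return min(p, 1.0)


def fold_change(k1: int, n1: int, k0: int, n0: int) -> float:
    """Ratio of proportions (k1/n1)/(k0/n0), rounded to one decimal as
    reported in text."""
    if n1 < 1 or n0 < 1:
        raise ValueError("denominator trial counts must be >= 1")
    if k0 == 0:
        raise ValueError("undefined ratio: baseline count k0 is zero")
    return round((k1 / n1) / (k0 / n0), 1)


def crossover_proportion(co: int, nco: int, conf: float = 0.95) -> BinomialEstimate:
    """Crossovers as a proportion of all sequenced recombinants, CO/(CO+NCO).

    Undetermined and mutant progeny are excluded from numerator and
    denominator: the figure denominator is "all recombinant progeny scored"
    of known class.
    """
    if co + nco < 1:
        raise ValueError("undefined estimate: no recombinants of known class")
    return wilson_ci(co, co + nco, conf)


def compare_groups(k1: int, n1: int, k0: int, n0: int,
                   conf: float = 0.95) -> GroupComparison:
    """Fisher-test two pooled binomial groups and report both Wilson estimates.

    The 2x2 table is [[k1, n1-k1], [k0, n0-k0]] (rows = groups, columns =
    outcome yes/no).  Replicates are pooled before testing, matching the
    published convention that displayed frequencies are combined sums of
    replicates.
    """
    table = ((int(k1), int(n1 - k1)), (int(k0), int(n0 - k0)))
    if min(table[0] + table[1]) < 0:
        raise ValueError("need k <= n and non-negative counts in both groups")
    return GroupComparison(
        table=table,
        p=fisher_exact_two_sided(table),
        estimate1=wilson_ci(k1, n1, conf),
        estimate0=wilson_ci(k0, n0, conf),
    )
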