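"""Paired significance testing for per-label model comparison.

The McNemar test compares two classifiers on the same instances through
their discordant counts: n01 (first correct, second wrong) and n10 (second
correct, first wrong). For n01 + n10 ≥ 20 the usual chi-square statistic
|n01 − n10|² / (n01 + n10) is well approximated by a chi-square(1)
distribution; below 20 discordant pairs an exact binomial mid-P test is
used instead, which halves the probability weight of the observed outcome
and is less conservative than the plain exact test.

Holm's step-down procedure controls the family-wise error rate when one
label's selection involves several simultaneous comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .matrices import LabelMatrix

__all__ = [
    "PairedOutcome",
    "TestResult",
    "ProportionComparison",
    "CHI_SQUARE_MIN_DISCORDANT",
    "paired_outcome",
    "mcnemar_chi2",
    "mcnemar_midp",
    "mcnemar",
    "holm_adjust",
    "proportion_compare",
]

#: Below this many discordant pairs the chi-square approximation is poor and
#: the exact mid-P branch is used.
CHI_SQUARE_MIN_DISCORDANT = 20

# the true tail probabilities are strictly positive; extreme statistics can
# underflow to 0.0 in double precision, so p-values are floored at the
# smallest normal float (keeps the alpha -> 0+ limit exact: nothing rejects)
_P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class PairedOutcome:
    """Paired correctness counts of two classifiers on one label.

    n00: correct by both; n01: first correct only; n10: second correct only;
    n11: wrong by both. The four counts partition the instances.
    """

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        if min(self.n00, self.n01, self.n10, self.n11) < 0:
            raise ValueError("paired counts must be non-negative")

    @property
    def n_discordant(self) -> int:
        return self.n01 + self.n10

    @property
    def n_total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11


@dataclass(frozen=True)
class TestResult:
    """Outcome of a McNemar test.

    ``branch`` records which approximation produced the p-value
    ("chi-square" or "mid-p"); ``statistic`` is set on the chi-square branch
    only. ``no_discordance`` flags the degenerate zero-discordant case, which
    yields p = 1 (no evidence either way).
    """

    p_value: float
    branch: str
    statistic: float | None = None
    no_discordance: bool = False


def paired_outcome(
    pred_a: LabelMatrix, pred_b: LabelMatrix, gold: LabelMatrix, label: int
) -> PairedOutcome:
    """Tally paired per-instance correctness of two models on one label.

    "Correct" means the binary decision for this label matches gold.
    """
    if pred_a.shape != gold.shape or pred_b.shape != gold.shape:
        raise ValueError("prediction/gold shape mismatch")
    if not 0 <= label < gold.n_labels:
        raise IndexError(f"label index {label} out of range")
    g = gold.column(label)
    ca = pred_a.column(label) == g
    cb = pred_b.column(label) == g
    n00 = int(np.sum(ca & cb))
    n01 = int(np.sum(ca & ~cb))
    n10 = int(np.sum(~ca & cb))
    n11 = int(np.sum(~ca & ~cb))
    return PairedOutcome(n00=n00, n01=n01, n10=n10, n11=n11)


def mcnemar_chi2(outcome: PairedOutcome) -> TestResult:
    """Chi-square McNemar test; requires ≥ 20 discordant pairs."""
    n01, n10 = outcome.n01, outcome.n10
    nd = n01 + n10
    if nd < CHI_SQUARE_MIN_DISCORDANT:
        raise ValueError(
            f"chi-square branch needs n01+n10 >= {CHI_SQUARE_MIN_DISCORDANT}; "
            f"got {nd} (use the mid-P branch)"
        )
    statistic = abs(n01 - n10) ** 2 / nd
    p = max(float(stats.chi2.sf(statistic, df=1)), _P_FLOOR)
    return TestResult(p_value=p, branch="chi-square", statistic=float(statistic))


def mcnemar_midp(outcome: PairedOutcome) -> TestResult:
    """Exact binomial mid-P McNemar test for small discordant counts.

    With n = n01 + n10 discordant pairs and k = min(n01, n10), under the null
    the discordant split is Binomial(n, 1/2) and

        p = 2·P(X ≤ k) − P(X = k),

    clamped to [0, 1]. Zero discordant pairs yield p = 1 with the
    ``no_discordance`` flag set: no disagreement is no evidence for switching.
    """
    n = outcome.n_discordant
    if n == 0:
        return TestResult(p_value=1.0, branch="mid-p", no_discordance=True)
    k = min(outcome.n01, outcome.n10)
    p = 2.0 * stats.binom.cdf(k, n, 0.5) - stats.binom.pmf(k, n, 0.5)
    return TestResult(p_value=float(min(max(p, _P_FLOOR), 1.0)), branch="mid-p")


def mcnemar(outcome: PairedOutcome) -> TestResult:
    """McNemar test with automatic branch routing on the discordant count."""
    if outcome.n_discordant < CHI_SQUARE_MIN_DISCORDANT:
        return mcnemar_midp(outcome)
    return mcnemar_chi2(outcome)


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjusted p-values.

    Sorted ascending, the i-th smallest p is multiplied by (m − i), a running
    maximum enforces monotonicity, and values are clamped at 1. Rejection at
    level α corresponds to adjusted p ≤ α.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = ps.size
    order = np.argsort(ps, kind="stable")
    adjusted = np.empty(m, dtype=float)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


@dataclass(frozen=True)
class ProportionComparison:
    """Result of the precision/recall proportion-test comparison rule.

    Each relation is one of ``significantly-better``,
    ``not-significantly-worse``, ``significantly-worse`` (of B relative to A),
    or ``undefined`` when the measure's denominator is zero for either model.
    ``switch`` applies the decision rule: prefer B iff one measure is strictly
    significantly better and the other is not significantly worse; any
    undefined measure abstains (no switch).
    """

    precision: str
    recall: str
    switch: bool


def _one_measure_relation(
    successes_a: int, n_a: int, successes_b: int, n_b: int, alpha: float
) -> str:
    if n_a == 0 or n_b == 0:
        return "undefined"
    counts = np.array([successes_b, successes_a])
    nobs = np.array([n_b, n_a])
    pooled = (successes_a + successes_b) / (n_a + n_b)
    if pooled in (0.0, 1.0) or (successes_a == successes_b and n_a == n_b):
        # degenerate pooled variance or exact equality: no detectable difference
        return "not-significantly-worse"
    # pooled one-sided two-proportion z-tests, each direction in turn
    _, p_better = proportions_ztest(counts, nobs, alternative="larger")
    if p_better < alpha:
        return "significantly-better"
    _, p_worse = proportions_ztest(counts, nobs, alternative="smaller")
    if p_worse < alpha:
        return "significantly-worse"
    return "not-significantly-worse"


def proportion_compare(
    counts_a: tuple[int, int, int],
    counts_b: tuple[int, int, int],
    confidence: float,
) -> ProportionComparison:
    """Compare model B against model A on precision and recall for one label.

    ``counts_*`` are the label's (tp, fp, fn). Precision is tested on the
    predicted-positive denominators, recall on the gold-positive ones, each
    with a one-sided pooled two-proportion z-test at significance
    1 − confidence.
    """
    if not 0.5 < confidence < 1.0:
        raise ValueError("confidence must lie in (0.5, 1)")
    alpha = 1.0 - confidence
    tp_a, fp_a, fn_a = counts_a
    tp_b, fp_b, fn_b = counts_b
    precision = _one_measure_relation(tp_a, tp_a + fp_a, tp_b, tp_b + fp_b, alpha)
    recall = _one_measure_relation(tp_a, tp_a + fn_a, tp_b, tp_b + fn_b, alpha)
    better, ok = "significantly-better", ("significantly-better", "not-significantly-worse")
    switch = (precision == better and recall in ok) or (recall == better and precision in ok)
    return ProportionComparison(precision=precision, recall=recall, switch=switch)
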