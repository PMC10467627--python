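"""Concordance, precision, and correlation statistics for assay validation.

The validation design compares test calls against a reference method's
positive calls only: there is no true-negative universe, so the summary
statistics are positive percent agreement (PPA = TP/(TP+FN)), positive
predictive value (PPV = TP/(TP+FP)), and overall accuracy for binary
status calls.  Precision across replicate runs is summarised as the mean
pairwise agreement (Jaccard index over positive call sets), and numeric
biomarkers (tumor mutational burden) as a coefficient of variation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConcordanceTable",
    "PrecisionReport",
    "ppa",
    "ppv",
    "overall_accuracy",
    "binomial_ci",
    "pairwise_concordance",
    "precision_over_samples",
    "coefficient_of_variation",
    "af_reproducibility",
    "percent",
    "load_printed_tables",
]


@dataclass(frozen=True)
class ConcordanceTable:
    """TP/FP/FN counts of test-vs-reference positive calls.

    There is deliberately no TN cell: the comparison universe is the set
    of positive calls made by either method.
    """

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("concordance counts must be non-negative")


@dataclass
class PrecisionReport:
    """Mean pairwise agreement across replicate runs."""

    pairwise_agreements: list[float]
    mode: str = "REPEATABILITY"  # or REPRODUCIBILITY
    overall: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.pairwise_agreements:
            raise ValueError("need at least one pairwise comparison")
        self.overall = float(np.mean(self.pairwise_agreements))


def ppa(t: ConcordanceTable) -> float:
    """Positive percent agreement TP/(TP+FN), as a fraction in [0, 1]."""
    if t.tp + t.fn == 0:
        raise ValueError("PPA undefined: no reference-positive calls")
    return t.tp / (t.tp + t.fn)


def ppv(t: ConcordanceTable) -> float:
    """Positive predictive value TP/(TP+FP), as a fraction in [0, 1]."""
    if t.tp + t.fp == 0:
        raise ValueError("PPV undefined: no test-positive calls")
    return t.tp / (t.tp + t.fp)


def overall_accuracy(n_concordant: int, n_total: int) -> float:
    """Fraction of samples on which two methods agree on a binary status."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_concordant <= n_total:
        raise ValueError("n_concordant must be in [0, n_total]")
    return n_concordant / n_total


def binomial_ci(
    successes: int,
    n: int,
    confidence: float = 0.95,
    method: str = "clopper-pearson",
) -> tuple[float, float]:
    """Two-sided binomial confidence interval for a proportion.

    Default is the exact Clopper-Pearson (beta-quantile) interval;
    ``method="wilson"`` selects the Wilson score interval.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(successes, n, alpha=1 - confidence, method=sm_method)
    # statsmodels reports nan at the degenerate edges of the beta interval
    lo = 0.0 if np.isnan(lo) else float(lo)
    hi = 1.0 if np.isnan(hi) else float(hi)
    return lo, hi


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def pairwise_concordance(
    replicates: Sequence[Iterable], mode: str = "REPEATABILITY"
) -> PrecisionReport:
    """Agreement among replicate positive-call sets of one sample.

    Each replicate is a collection of hashable call identifiers; every
    unordered pair of replicates contributes one Jaccard agreement and
    the overall value is their mean.
    """
    sets = [frozenset(r) for r in replicates]
    if len(sets) < 2:
        raise ValueError("need at least two replicates")
    agreements = [_jaccard(a, b) for a, b in combinations(sets, 2)]
    return PrecisionReport(pairwise_agreements=agreements, mode=mode)


def precision_over_samples(
    per_sample_replicates: Sequence[Sequence[Iterable]], mode: str = "REPEATABILITY"
) -> PrecisionReport:
    """Pool pairwise agreements over many samples run in replicate."""
    agreements: list[float] = []
    for reps in per_sample_replicates:
        agreements.extend(pairwise_concordance(reps, mode=mode).pairwise_agreements)
    return PrecisionReport(pairwise_agreements=agreements, mode=mode)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation divided by the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined at zero mean")
    return float(arr.std(ddof=1) / mean)


def af_reproducibility(
    af_x: Sequence[float], af_y: Sequence[float]
) -> tuple[float, float, float]:
    """Through-origin regression of paired allele-frequency measurements.

    Returns ``(slope, r_squared, pearson)`` for the zero-intercept model
    y = slope * x; r² is the through-origin (uncentered) coefficient of
    determination, the Pearson r the ordinary correlation.
    """
    x = np.asarray(af_x, dtype=float)
    y = np.asarray(af_y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >=2 paired measurements")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("degenerate input: all x measurements are zero")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    syy = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        pearson = float("nan")
    else:
        pearson = float(stats.pearsonr(x, y)[0])
    return slope, r2, pearson


def percent(fraction: float, ndigits: int = 1) -> float:
    """Render a fraction as a percentage rounded half-up to `ndigits`."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))


def load_printed_tables() -> dict:
    """Bundled 2x2 concordance counts from the validation study report."""
    text = resources.files("cgpval.data").joinpath("validation_tables.json").read_text()
    return json.loads(text)
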