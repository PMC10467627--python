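"""Microsatellite-instability calling from repeat-length distributions.

Mismatch-repair-deficient tumors accumulate insertions and deletions in
homopolymer runs, so the distribution of repeat lengths read out at a
microsatellite locus drifts away from the germline distribution seen in
the matched normal.  The caller tests each of the assay's 117
homopolymer loci for a tumor-vs-normal difference in length
distribution; a locus is unstable when the test rejects at level alpha,
and the sample is MSI-H when strictly more than 10% of evaluable loci
are unstable, MSS otherwise.

The per-locus test is a chi-squared homogeneity test on pooled length
bins (sparse tail bins merged so expected counts stay honest), falling
back to a permutation test when counts are too small for the asymptotic
null.  Loci with fewer than 30 reads in either sample are non-evaluable
and excluded from both numerator and denominator.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MicrosatelliteLocus",
    "MsiResult",
    "NoEvaluableLociError",
    "locus_instability_test",
    "call_msi",
    "MIN_EVALUABLE_DEPTH",
    "MSI_H_THRESHOLD",
    "DEFAULT_N_LOCI",
]

MIN_EVALUABLE_DEPTH = 30
MSI_H_THRESHOLD = 0.10
DEFAULT_N_LOCI = 117
# below this expected count per pooled bin the chi-squared null is unreliable
_MIN_EXPECTED = 5.0
_N_PERMUTATIONS = 2000


class NoEvaluableLociError(ValueError):
    """Raised when MSI status cannot be determined (no evaluable loci)."""


@dataclass
class MicrosatelliteLocus:
    """Tumor and normal repeat-length read histograms at one locus."""

    locus_id: str
    tumor_hist: dict[int, int]
    normal_hist: dict[int, int]
    true_unstable: bool | None = None  # ground truth when simulated

    def __post_init__(self) -> None:
        for hist in (self.tumor_hist, self.normal_hist):
            if any(c < 0 for c in hist.values()):
                raise ValueError("histogram counts must be non-negative")

    @property
    def tumor_depth(self) -> int:
        return sum(self.tumor_hist.values())

    @property
    def normal_depth(self) -> int:
        return sum(self.normal_hist.values())

    @property
    def evaluable(self) -> bool:
        return (
            self.tumor_depth >= MIN_EVALUABLE_DEPTH
            and self.normal_depth >= MIN_EVALUABLE_DEPTH
        )


@dataclass
class MsiResult:
    n_evaluable: int
    n_unstable: int
    status: str  # MSI-H | MSS
    per_locus: list[tuple[str, float, bool]] = field(default_factory=list)

    @property
    def unstable_fraction(self) -> float:
        return self.n_unstable / self.n_evaluable


def _paired_table(locus: MicrosatelliteLocus) -> np.ndarray:
    lengths = sorted(set(locus.tumor_hist) | set(locus.normal_hist))
    table = np.array(
        [
            [locus.tumor_hist.get(l, 0) for l in lengths],
            [locus.normal_hist.get(l, 0) for l in lengths],
        ],
        dtype=float,
    )
    return table[:, table.sum(axis=0) > 0]


def _merge_sparse_bins(table: np.ndarray) -> np.ndarray:
    """Merge adjacent length bins until every column total supports the
    chi-squared expected-count guard, preserving ordering of lengths.

    With unequal tumor/normal depths the binding constraint is the
    smaller row: expected count = column_total * row_sum / total.
    """
    cols = [table[:, j].copy() for j in range(table.shape[1])]
    row_sums = table.sum(axis=1)
    target = _MIN_EXPECTED * row_sums.sum() / row_sums.min()
    j = 0
    while j < len(cols) and len(cols) > 2:
        if cols[j].sum() < target:
            k = j + 1 if j + 1 < len(cols) else j - 1
            cols[k] = cols[k] + cols[j]
            del cols[j]
        else:
            j += 1
    return np.column_stack(cols)


def _chi2_stat(table: np.ndarray) -> float:
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def _permutation_p(table: np.ndarray) -> float:
    """Monte-Carlo permutation p-value for the homogeneity statistic.

    The RNG seed is derived from the table contents so the result is a
    deterministic function of the histograms.
    """
    seed = zlib.crc32(np.ascontiguousarray(table, dtype=np.int64).tobytes())
    rng = np.random.default_rng(seed)
    observed = _chi2_stat(table)
    n_tumor = int(table[0].sum())
    col_totals = table.sum(axis=0).astype(int)
    # draw tumor-row counts for all permutations at once, conditional on margins
    t_counts = rng.multivariate_hypergeometric(
        col_totals, n_tumor, size=_N_PERMUTATIONS
    ).astype(float)
    n_counts = col_totals[None, :] - t_counts
    row_sums = np.array([n_tumor, col_totals.sum() - n_tumor], dtype=float)
    expected_t = col_totals * row_sums[0] / col_totals.sum()
    expected_n = col_totals * row_sums[1] / col_totals.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        stats_perm = np.where(
            expected_t > 0, (t_counts - expected_t) ** 2 / expected_t, 0.0
        ).sum(axis=1) + np.where(
            expected_n > 0, (n_counts - expected_n) ** 2 / expected_n, 0.0
        ).sum(axis=1)
    count = int((stats_perm >= observed - 1e-12).sum())
    return (1 + count) / (1 + _N_PERMUTATIONS)


def locus_instability_test(
    locus: MicrosatelliteLocus, alpha: float = 0.01
) -> tuple[bool, float]:
    """Test tumor-vs-normal repeat-length distributions at one locus.

    Returns ``(unstable, p_value)``; unstable iff p < alpha.  Raises on a
    non-evaluable locus — callers must exclude those first.
    """
    if not locus.evaluable:
        raise ValueError(f"locus {locus.locus_id} is not evaluable")
    table = _paired_table(locus)
    if table.shape[1] < 2:
        return False, 1.0  # all reads at a single length in both samples
    merged = _merge_sparse_bins(table)
    expected = (
        np.outer(merged.sum(axis=1), merged.sum(axis=0)) / merged.sum()
    )
    if merged.shape[1] >= 2 and (expected >= _MIN_EXPECTED).all():
        p = float(stats.chi2_contingency(merged, correction=False)[1])
    else:
        p = _permutation_p(table)
    return p < alpha, p


def call_msi(
    loci: list[MicrosatelliteLocus],
    alpha: float = 0.01,
    threshold: float = MSI_H_THRESHOLD,
) -> MsiResult:
    """Call MSI-H iff strictly more than `threshold` of evaluable loci
    are unstable.

    The denominator is the number of evaluable loci (equal to the full
    117-locus panel at nominal coverage); non-evaluable loci are never
    counted unstable.
    """
    evaluable = [l for l in loci if l.evaluable]
    if not evaluable:
        raise NoEvaluableLociError("MSI status unavailable: no evaluable loci")
    per_locus = []
    n_unstable = 0
    for locus in evaluable:
        unstable, p = locus_instability_test(locus, alpha=alpha)
        per_locus.append((locus.locus_id, p, unstable))
        n_unstable += unstable
    fraction = n_unstable / len(evaluable)
    status = "MSI-H" if fraction > threshold else "MSS"
    return MsiResult(
        n_evaluable=len(evaluable),
        n_unstable=n_unstable,
        status=status,
        per_locus=per_locus,
    )
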