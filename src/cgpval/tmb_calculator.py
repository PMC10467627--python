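"""Tumor mutational burden in mutations per megabase.

TMB is the rate of nonsynonymous somatic mutations over the assessed
footprint (default 35 Mb of exome).  In tumor-normal mode the somatic
calls have had germline variants subtracted via the matched normal; in
tumor-only mode germline removal relies on a population database, so
rare germline variants leak through and TMB is systematically inflated
— the tumor-only value is never below the tumor-normal value for the
same sample.  Indels and multi-nucleotide variants count toward TMB by
default.

A >=10 mut/Mb high/low split is provided only to stratify precision
summaries; the assay reports the numeric value.
"""

from __future__ import annotations

from dataclasses import dataclass

from .somatic_small_variants import SOMATIC, ClassifiedCall

__all__ = ["TmbResult", "compute_tmb", "classify_tmb", "DEFAULT_FOOTPRINT_MB",
           "TMB_HIGH_CUTOFF"]

DEFAULT_FOOTPRINT_MB = 35.0
TMB_HIGH_CUTOFF = 10.0


@dataclass(frozen=True)
class TmbResult:
    n_nonsynonymous: int
    footprint_mb: float
    tmb: float
    mode: str  # TUMOR_NORMAL | TUMOR_ONLY


def compute_tmb(
    calls: list[ClassifiedCall],
    footprint_mb: float = DEFAULT_FOOTPRINT_MB,
    mode: str = "TUMOR_NORMAL",
) -> TmbResult:
    """Count nonsynonymous somatic calls and divide by the footprint."""
    if footprint_mb <= 0:
        raise ValueError("footprint_mb must be positive")
    n = sum(
        1
        for c in calls
        if c.call == SOMATIC and c.variant.is_nonsynonymous
    )
    return TmbResult(
        n_nonsynonymous=n, footprint_mb=footprint_mb, tmb=n / footprint_mb, mode=mode
    )


def classify_tmb(tmb: float, cutoff: float = TMB_HIGH_CUTOFF) -> str:
    """High iff tmb >= cutoff (stratification aid, not a reported state)."""
    if tmb < 0:
        raise ValueError("tmb must be non-negative")
    return "high" if tmb >= cutoff else "low"
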