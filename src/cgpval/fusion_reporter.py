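"""Fusion-event reporting against the 284-gene reportable footprint.

Fusions are reportable when either partner belongs to the assay's fusion
gene list (284 symbols, shipped as package data).  The list includes
tumor-suppressor genes such as APC and NF2 because truncating fusions in
those genes inactivate them much as a nonsense variant would.  Presence
is decided by a supporting-read threshold on the (simulated) RNA
evidence; real split-read detection is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

__all__ = ["FusionCall", "load_fusion_gene_list", "filter_reportable", "call_fusion",
           "DEFAULT_MIN_READS"]

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 5


@dataclass
class FusionCall:
    gene5: str
    gene3: str
    supporting_reads: int
    reportable: bool | None = None
    call: str | None = None  # present | absent

    def __post_init__(self) -> None:
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be non-negative")


@lru_cache(maxsize=1)
def load_fusion_gene_list() -> frozenset[str]:
    """The 284 reportable fusion gene symbols (upper-cased)."""
    text = resources.files("cgpval.data").joinpath("fusion_genes.txt").read_text()
    genes = {
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }
    return frozenset(genes)


def filter_reportable(
    fusion: FusionCall, gene_list: frozenset[str] | None = None
) -> bool:
    """True iff either fusion partner is in the reportable gene list.

    Symbols are case-normalized; unknown symbols simply do not match and
    are logged at debug level.
    """
    genes = gene_list if gene_list is not None else load_fusion_gene_list()
    g5, g3 = fusion.gene5.strip().upper(), fusion.gene3.strip().upper()
    reportable = g5 in genes or g3 in genes
    if not reportable:
        logger.debug("fusion %s::%s outside reportable footprint", g5, g3)
    fusion.reportable = reportable
    return reportable


def call_fusion(supporting_reads: int, min_reads: int = DEFAULT_MIN_READS) -> str:
    """Present iff the supporting-read count reaches the threshold."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if supporting_reads < 0:
        raise ValueError("supporting_reads must be non-negative")
    return "present" if supporting_reads >= min_reads else "absent"
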