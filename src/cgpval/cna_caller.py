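"""Gene-level copy-number calling from purity-mixed coverage ratios.

The observed tumor/normal coverage ratio at a gene is a mixture of the
tumor cell copy number CN and the normal contamination at diploid
ploidy:

    ratio = (purity * CN + (1 - purity) * ploidy) / ploidy

Inverting the mixture gives the purity-corrected estimate.  Only
amplifications at >=8 estimated copies are called (the assay's
predefined cutoff; validated amplifications spanned 8-57 copies);
whole-gene deletions are called at <=0.5 copies, homozygous-loss
territory.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CnaCall", "estimate_copy_number", "call_cna", "AMP_CUTOFF", "DEL_CUTOFF"]

AMP_CUTOFF = 8.0
DEL_CUTOFF = 0.5


@dataclass(frozen=True)
class CnaCall:
    gene: str
    estimated_copy_number: float
    call: str  # AMPLIFICATION | DELETION | NEUTRAL


def estimate_copy_number(
    observed_ratio: float, purity: float, ploidy: float = 2.0
) -> float:
    """Invert the purity mixture of tumor CN and diploid normal coverage."""
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if observed_ratio < 0:
        raise ValueError("coverage ratio must be non-negative")
    cn = (observed_ratio * ploidy - (1.0 - purity) * ploidy) / purity
    return max(cn, 0.0)


def call_cna(
    gene: str,
    estimated_cn: float,
    amp_cutoff: float = AMP_CUTOFF,
    del_cutoff: float = DEL_CUTOFF,
) -> CnaCall:
    """Threshold an estimated copy number into AMPLIFICATION/DELETION/NEUTRAL."""
    if estimated_cn < 0:
        raise ValueError("copy number must be non-negative")
    if estimated_cn >= amp_cutoff:
        call = "AMPLIFICATION"
    elif estimated_cn <= del_cutoff:
        call = "DELETION"
    else:
        call = "NEUTRAL"
    return CnaCall(gene=gene, estimated_copy_number=estimated_cn, call=call)
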