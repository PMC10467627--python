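"""Pre-analytical QC acceptance gates on sample metadata.

The assay only accepts specimens meeting fixed quality ranges: tumor
content >=20% by pathologist estimate, RNA input 50-200 ng at DV200
>=30%, DNA input 150-750 ng with A260/230 between 1.7 and 2.9, onboard
Q30 >=75%, and >200 million total RNA reads when a transcriptome library
is run.  All printed ranges are treated as inclusive.  The verdict is a
pure function of the metrics and enumerates every violated gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["QcMetrics", "QcVerdict", "evaluate_qc", "MIN_TUMOR_CONTENT"]

MIN_TUMOR_CONTENT = 0.20
RNA_READS_FLOOR = 200_000_000


@dataclass
class QcMetrics:
    """Per-sample quality metrics; RNA fields are None for DNA-only runs."""

    tumor_content: float | None = None
    dna_input_ng: float | None = None
    a260_230: float | None = None
    q30: float | None = None
    dv200: float | None = None
    rna_input_ng: float | None = None
    total_rna_reads: int | None = None
    median_depth: float | None = None
    library_fragment_bp: float | None = None
    phix_fraction: float | None = None


@dataclass
class QcVerdict:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


_DNA_REQUIRED = ("tumor_content", "dna_input_ng", "a260_230", "q30")


def evaluate_qc(m: QcMetrics) -> QcVerdict:
    """Evaluate every acceptance gate; failures list all violated gates."""
    reasons: list[str] = []
    warnings: list[str] = []

    for name in _DNA_REQUIRED:
        if getattr(m, name) is None:
            reasons.append(f"missing:{name}")

    if m.tumor_content is not None and m.tumor_content < MIN_TUMOR_CONTENT:
        reasons.append("tumor_content")
    if m.dna_input_ng is not None and not 150 <= m.dna_input_ng <= 750:
        reasons.append("dna_input")
    if m.a260_230 is not None and not 1.7 <= m.a260_230 <= 2.9:
        reasons.append("a260_230")
    if m.q30 is not None and m.q30 < 0.75:
        reasons.append("q30")

    rna_present = any(
        v is not None for v in (m.rna_input_ng, m.dv200, m.total_rna_reads)
    )
    if rna_present:
        if m.rna_input_ng is None:
            reasons.append("missing:rna_input_ng")
        elif not 50 <= m.rna_input_ng <= 200:
            reasons.append("rna_input")
        if m.dv200 is None:
            reasons.append("missing:dv200")
        elif m.dv200 < 0.30:
            reasons.append("dv200")
        if m.total_rna_reads is None:
            reasons.append("missing:total_rna_reads")
        elif m.total_rna_reads <= RNA_READS_FLOOR:
            reasons.append("total_rna_reads")

    # library fragment range enforced only when measured
    if m.library_fragment_bp is not None and not 195 <= m.library_fragment_bp <= 350:
        reasons.append("library_fragment_bp")

    # PhiX spike-in outside ~0.2-1% is flagged but does not fail the sample
    if m.phix_fraction is not None and not 0.002 <= m.phix_fraction <= 0.01:
        warnings.append("phix_fraction")

    return QcVerdict(passed=not reasons, reasons=reasons, warnings=warnings)
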