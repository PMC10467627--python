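"""Somatic-vs-germline classification of candidate small variants.

Tumor-normal mode classifies each candidate against its matched-normal
read counts: a variant is somatic when its tumor allele frequency
clears the reportable threshold (>5% AF with a minimum alternate-read
floor) and the matched normal shows no significant evidence for the
allele.  "Significant evidence in the normal" is a one-sided exact
binomial test of the normal alternate count against the sequencing
error rate (alpha 0.01), or a normal AF above 2% with at least three
alternate reads; variants with normal evidence consistent with diploid
expectations (AF near 0.5 or above 0.9) are labelled germline, the rest
are rejected outright.

Tumor-only mode has no matched normal and instead removes candidates
found in a population database at or above a frequency cutoff.  Rare
germline variants (below the cutoff, or private) deliberately survive
this filter — the mode exists to demonstrate the tumor-only vs
tumor-normal contrast in false somatic calls and TMB inflation.

The truth-set builder applies the validation study's inclusion
criteria to reference-method call records: reference-reported AF >5%
and not rejected as germline by the tumor-normal analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .synthetic_cohort import VariantObservation

__all__ = [
    "ClassificationThresholds",
    "ClassifiedCall",
    "NonEvaluableSiteError",
    "classify_variant",
    "classify_sample",
    "classify_tumor_only",
    "tumor_only_filter",
    "build_truth_set",
]

SOMATIC = "SOMATIC"
GERMLINE = "GERMLINE"
REJECTED_LOW_AF = "REJECTED_LOW_AF"
REJECTED_NORMAL_EVIDENCE = "REJECTED_NORMAL_EVIDENCE"


class NonEvaluableSiteError(ValueError):
    """Zero tumor depth: the site cannot enter any denominator."""


@dataclass(frozen=True)
class ClassificationThresholds:
    """Decision thresholds; defaults mirror the assay's reporting rules."""

    af_min_reportable: float = 0.05
    normal_evidence_alpha: float = 0.01
    normal_af_max: float = 0.02
    min_normal_alt_reads: int = 3
    min_tumor_alt_reads: int = 4
    normal_error_rate: float = 1e-3
    population_af_cutoff: float = 0.01  # tumor-only mode
    germline_het_band: tuple[float, float] = (0.3, 0.7)
    germline_hom_min: float = 0.9

    def __post_init__(self) -> None:
        for frac in (self.af_min_reportable, self.normal_af_max,
                     self.population_af_cutoff):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if not 0 < self.normal_evidence_alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ClassifiedCall:
    variant: VariantObservation
    call: str
    tumor_af: float
    normal_af: float
    evidence_p: float


def _normal_evidence(
    obs: VariantObservation, t: ClassificationThresholds
) -> tuple[bool, float]:
    """Does the matched normal carry significant evidence for the allele?"""
    if obs.normal_depth == 0:
        return False, 1.0
    p = stats.binomtest(
        obs.normal_alt, obs.normal_depth, t.normal_error_rate, alternative="greater"
    ).pvalue
    # the alt-read floor applies to both branches: one or two stray
    # error reads in the normal must not veto a true somatic call
    if obs.normal_alt < t.min_normal_alt_reads:
        return False, float(p)
    significant = p < t.normal_evidence_alpha or obs.normal_af > t.normal_af_max
    return significant, float(p)


def classify_variant(
    obs: VariantObservation, t: ClassificationThresholds | None = None
) -> ClassifiedCall:
    """Tumor-normal classification of one candidate variant."""
    t = t or ClassificationThresholds()
    if obs.tumor_depth == 0:
        raise NonEvaluableSiteError("zero tumor depth")
    tumor_af = obs.tumor_af
    normal_af = obs.normal_af if obs.normal_depth > 0 else 0.0
    evidence, p = _normal_evidence(obs, t)
    if evidence:
        lo, hi = t.germline_het_band
        if lo <= normal_af <= hi or normal_af >= t.germline_hom_min:
            call = GERMLINE
        else:
            call = REJECTED_NORMAL_EVIDENCE
    elif tumor_af <= t.af_min_reportable or obs.tumor_alt < t.min_tumor_alt_reads:
        call = REJECTED_LOW_AF
    else:
        call = SOMATIC
    return ClassifiedCall(
        variant=obs, call=call, tumor_af=tumor_af, normal_af=normal_af, evidence_p=p
    )


def classify_sample(
    variants: list[VariantObservation], t: ClassificationThresholds | None = None
) -> list[ClassifiedCall]:
    """Classify every evaluable variant of a sample (zero-depth sites are
    dropped, never counted in any denominator)."""
    t = t or ClassificationThresholds()
    calls = []
    for obs in variants:
        try:
            calls.append(classify_variant(obs, t))
        except NonEvaluableSiteError:
            continue
    return calls


def tumor_only_filter(
    obs: VariantObservation, population_af_cutoff: float = 0.01
) -> str:
    """Population-database germline filter for tumor-only mode.

    Returns "filtered" iff the variant's population AF is at or above
    the cutoff; a missing population AF is treated as 0 (private).
    """
    pop_af = obs.population_af if obs.population_af is not None else 0.0
    return "filtered" if pop_af >= population_af_cutoff else "kept"


def classify_tumor_only(
    variants: list[VariantObservation], t: ClassificationThresholds | None = None
) -> list[ClassifiedCall]:
    """Tumor-only somatic calling: reportable-AF rule plus the population
    filter; the matched normal is never consulted."""
    t = t or ClassificationThresholds()
    calls = []
    for obs in variants:
        if obs.tumor_depth == 0:
            continue
        tumor_af = obs.tumor_af
        if tumor_only_filter(obs, t.population_af_cutoff) == "filtered":
            call = GERMLINE
        elif tumor_af <= t.af_min_reportable or obs.tumor_alt < t.min_tumor_alt_reads:
            call = REJECTED_LOW_AF
        else:
            call = SOMATIC
        calls.append(
            ClassifiedCall(
                variant=obs, call=call, tumor_af=tumor_af,
                normal_af=0.0, evidence_p=1.0,
            )
        )
    return calls


@dataclass
class ReferenceRecord:
    """A reference-method call: its reported AF plus this assay's
    tumor-normal verdict on the same site."""

    record_id: str
    reference_af: float
    tumor_normal_call: str  # one of the four ClassifiedCall states


def build_truth_set(
    reference_calls: list[ReferenceRecord],
    t: ClassificationThresholds | None = None,
) -> tuple[list[ReferenceRecord], dict[str, int]]:
    """Apply the validation truth-set criteria to reference-method calls.

    Keeps records whose reference-reported AF is >5% (strictly) and that
    the tumor-normal analysis did not reject as germline; returns the
    truth set and the counts of removed records by reason.
    """
    t = t or ClassificationThresholds()
    truth, removed = [], {"removed_germline": 0, "removed_low_af": 0}
    for rec in reference_calls:
        if rec.reference_af <= t.af_min_reportable:
            removed["removed_low_af"] += 1
        elif rec.tumor_normal_call in (GERMLINE, REJECTED_NORMAL_EVIDENCE):
            removed["removed_germline"] += 1
        else:
            truth.append(rec)
    return truth, removed
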