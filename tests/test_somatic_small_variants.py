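"""Tumor-normal and tumor-only somatic classification."""

import pytest

from cgpval import (
    ClassificationThresholds,
    ReferenceRecord,
    SimulationConfig,
    VariantObservation,
    build_truth_set,
    classify_sample,
    classify_tumor_only,
    classify_variant,
    simulate_sample_pair,
    tumor_only_filter,
)
from cgpval.somatic_small_variants import (
    GERMLINE,
    NonEvaluableSiteError,
    REJECTED_LOW_AF,
    SOMATIC,
)


def _obs(t_alt, t_ref, n_alt, n_ref, origin="SOMATIC", pop_af=0.0):
    return VariantObservation(
        locus=("chr1", 1000, "A", "T"),
        tumor_alt=t_alt,
        tumor_ref=t_ref,
        normal_alt=n_alt,
        normal_ref=n_ref,
        true_origin=origin,
        population_af=pop_af,
    )


class TestClassifyVariant:
    def test_clean_somatic(self):
        call = classify_variant(_obs(60, 440, 0, 150))
        assert call.call == SOMATIC
        assert call.tumor_af == pytest.approx(0.12)

    def test_het_in_both_is_germline(self):
        call = classify_variant(_obs(250, 250, 75, 75))
        assert call.call == GERMLINE
        assert call.normal_af == pytest.approx(0.5)

    def test_hom_in_both_is_germline(self):
        assert classify_variant(_obs(500, 0, 150, 0)).call == GERMLINE

    def test_low_af_rejected_at_default_threshold(self):
        call = classify_variant(_obs(20, 480, 0, 150))
        assert call.call == REJECTED_LOW_AF

    def test_af_exactly_five_percent_not_reportable(self):
        # the reportable criterion is strict: AF must exceed 5%
        assert classify_variant(_obs(25, 475, 0, 150)).call == REJECTED_LOW_AF

    def test_alt_read_floor(self):
        # 3 alt reads in a shallow site: above 5% AF but below the floor
        assert classify_variant(_obs(3, 30, 0, 150)).call == REJECTED_LOW_AF

    def test_zero_tumor_depth_non_evaluable(self):
        with pytest.raises(NonEvaluableSiteError):
            classify_variant(_obs(0, 0, 0, 150))

    def test_deterministic(self):
        obs = _obs(60, 440, 1, 149)
        assert classify_variant(obs) == classify_variant(obs)

    def test_stray_normal_error_reads_do_not_veto(self):
        # 2 error reads in the normal must not reject a clear somatic call
        assert classify_variant(_obs(60, 440, 2, 130)).call == SOMATIC


class TestTumorOnlyFilter:
    def test_common_variant_filtered(self):
        assert tumor_only_filter(_obs(100, 100, 0, 1, pop_af=0.30), 0.01) == "filtered"

    def test_rare_germline_leaks_through(self):
        assert tumor_only_filter(_obs(100, 100, 0, 1, pop_af=0.0001), 0.01) == "kept"

    def test_missing_population_af_treated_private(self):
        obs = _obs(100, 100, 0, 1)
        obs.population_af = None
        assert tumor_only_filter(obs, 0.01) == "kept"


def test_tumor_only_somatic_superset_of_tumor_normal():
    """Every tumor-normal somatic call with population AF below the
    cutoff must also be called somatic in tumor-only mode."""
    cfg = SimulationConfig(n_somatic_snv=150, n_germline=80, n_msi_loci=0, seed=3)
    pair = simulate_sample_pair(cfg, seed=3)
    tn = {c.variant.key for c in classify_sample(pair.variants) if c.call == SOMATIC}
    to = {
        c.variant.key for c in classify_tumor_only(pair.variants) if c.call == SOMATIC
    }
    assert tn <= to


def test_doubling_rare_germline_inflates_only_tumor_only_calls():
    base = SimulationConfig(
        n_somatic_snv=200, n_germline=150, n_msi_loci=0,
        rare_germline_fraction=0.1, seed=5,
    )
    doubled = SimulationConfig(
        n_somatic_snv=200, n_germline=150, n_msi_loci=0,
        rare_germline_fraction=0.2, seed=5,
    )

    def counts(cfg):
        fp_to = fp_tn = 0
        for s in range(5):
            pair = simulate_sample_pair(cfg, seed=s)
            for c in classify_tumor_only(pair.variants):
                fp_to += c.call == SOMATIC and c.variant.true_origin != "SOMATIC"
            for c in classify_sample(pair.variants):
                fp_tn += c.call == SOMATIC and c.variant.true_origin != "SOMATIC"
        return fp_to, fp_tn

    fp_to_base, fp_tn_base = counts(base)
    fp_to_doubled, fp_tn_doubled = counts(doubled)
    assert fp_to_doubled > fp_to_base
    assert fp_tn_doubled == fp_tn_base == 0


def test_germline_leakage_zero_at_deep_normal():
    cfg = SimulationConfig(
        n_somatic_snv=200, n_germline=200, n_msi_loci=0,
        normal_depth=10_000, seed=9,
    )
    pair = simulate_sample_pair(cfg, seed=9)
    leaked = [
        c
        for c in classify_sample(pair.variants)
        if c.call == SOMATIC and c.variant.true_origin.startswith("GERMLINE")
    ]
    assert leaked == []


class TestBuildTruthSet:
    def test_germline_fraction_removed(self):
        records = [
            ReferenceRecord(f"v{i}", 0.30, "GERMLINE" if i < 25 else "SOMATIC")
            for i in range(100)
        ]
        truth, removed = build_truth_set(records)
        assert len(truth) == 75
        assert removed["removed_germline"] == 25

    def test_empty_input(self):
        truth, removed = build_truth_set([])
        assert truth == [] and removed["removed_germline"] == 0

    def test_all_low_af_flagged(self):
        records = [ReferenceRecord(f"v{i}", 0.05, "SOMATIC") for i in range(10)]
        truth, removed = build_truth_set(records)
        assert truth == [] and removed["removed_low_af"] == 10


def test_threshold_validation():
    with pytest.raises(ValueError):
        ClassificationThresholds(af_min_reportable=1.5)
    with pytest.raises(ValueError):
        ClassificationThresholds(normal_evidence_alpha=0.0)
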