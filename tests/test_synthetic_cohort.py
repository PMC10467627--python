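"""Simulator contracts: determinism, AF expectations, dilution, truth labels."""

import numpy as np
import pytest

from cgpval import (
    QcGateError,
    SimulationConfig,
    dilute_sample,
    simulate_cohort,
    simulate_microsatellite_loci,
    simulate_sample_pair,
)
from cgpval.synthetic_cohort import (
    read_microsatellite_tsv,
    read_vcf,
    write_microsatellite_tsv,
    write_vcf,
)


def test_expected_nonsynonymous_count_is_rate_times_footprint():
    cfg = SimulationConfig(tmb_target=10, footprint_mb=35)
    assert cfg.expected_nonsynonymous_count == 350


def test_low_purity_rejected_unless_overridden():
    with pytest.raises(QcGateError):
        SimulationConfig(purity=0.1)
    cfg = SimulationConfig(purity=0.1, allow_low_purity=True)
    assert cfg.purity == 0.1


def test_identical_seed_gives_identical_sample():
    cfg = SimulationConfig(n_somatic_snv=50, n_germline=20, n_msi_loci=10, seed=4)
    a = simulate_sample_pair(cfg, seed=4)
    b = simulate_sample_pair(cfg, seed=4)
    assert a == b


def test_cohort_subsets_reproducible_from_master_seed():
    cfg = SimulationConfig(
        n_samples=4, n_somatic_snv=30, n_germline=10, n_msi_loci=5, seed=8
    )
    cohort_a = simulate_cohort(cfg)
    cohort_b = simulate_cohort(cfg)
    assert cohort_a == cohort_b
    assert len({p.sample_id for p in cohort_a}) == 4


def test_somatic_af_matches_purity_ccf_closed_form():
    """purity 0.5, ccf 1, diploid het: expected AF 0.25; the Monte-Carlo
    mean over 1,000 variants must sit within +-0.01 of the closed form."""
    cfg = SimulationConfig(
        n_somatic_snv=1000, n_germline=0, n_artifact=0, n_msi_loci=0,
        purity=0.5, seed=2,
    )
    pair = simulate_sample_pair(cfg, seed=2)
    afs = [v.tumor_af for v in pair.variants if v.true_origin == "SOMATIC"]
    assert len(afs) == 1000
    assert np.mean(afs) == pytest.approx(0.25, abs=0.01)


def test_af_law_of_large_numbers():
    """Mean simulated AF converges to the purity-scaled expectation
    (three-standard-error envelope at n=10,000)."""
    cfg = SimulationConfig(
        n_somatic_snv=10_000, n_germline=0, n_artifact=0, n_msi_loci=0,
        purity=0.6, seed=3,
    )
    pair = simulate_sample_pair(cfg, seed=3)
    afs = np.array([v.tumor_af for v in pair.variants])
    se = afs.std(ddof=1) / np.sqrt(afs.size)
    assert abs(afs.mean() - 0.3) <= 3 * se


def test_truth_labels_cover_every_variant():
    cfg = SimulationConfig(n_msi_loci=0, seed=5)
    pair = simulate_sample_pair(cfg, seed=5)
    counts = pair.truth_counts()
    assert sum(counts.values()) == len(pair.variants)
    assert set(counts) <= {"SOMATIC", "GERMLINE_HET", "GERMLINE_HOM", "ARTIFACT"}


def test_germline_roughly_quarter_of_reportable_calls():
    """Under defaults the germline:somatic mix leaves ~25% of a
    tumor-only caller's candidate calls germline."""
    cfg = SimulationConfig(tmb_target=10, n_msi_loci=0, n_artifact=0, seed=6)
    pair = simulate_sample_pair(cfg, seed=6)
    counts = pair.truth_counts()
    n_germ = counts.get("GERMLINE_HET", 0) + counts.get("GERMLINE_HOM", 0)
    frac = n_germ / len(pair.variants)
    assert frac == pytest.approx(0.25, abs=0.03)


class TestMicrosatelliteSimulation:
    def test_mss_has_zero_truth_unstable(self):
        loci = simulate_microsatellite_loci(msi_status="MSS", seed=1)
        assert sum(l.true_unstable for l in loci) == 0

    def test_msi_h_unstable_count(self):
        loci = simulate_microsatellite_loci(
            n_loci=117, msi_status="MSI-H", unstable_fraction=0.20, seed=1
        )
        assert sum(l.true_unstable for l in loci) == 23  # round(0.20 * 117)

    def test_locus_count_and_depths(self):
        loci = simulate_microsatellite_loci(
            n_loci=117, depth=500, normal_depth=150, seed=2
        )
        assert len(loci) == 117
        assert all(l.tumor_depth == 500 and l.normal_depth == 150 for l in loci)

    def test_unstable_locus_power(self):
        """A +2-repeat-unit shift at depth 500 must be flagged in >=99%
        of replicates."""
        from cgpval import locus_instability_test
        from cgpval.msi_caller import MicrosatelliteLocus
        from cgpval.synthetic_cohort import simulate_locus_reads

        rng = np.random.default_rng(11)
        n_reject = 0
        n_rep = 300
        for _ in range(n_rep):
            normal = simulate_locus_reads(rng, 12, 150)
            tumor = simulate_locus_reads(rng, 12, 500, shift=2, shift_weight=0.5)
            unstable, _ = locus_instability_test(
                MicrosatelliteLocus("L", tumor, normal)
            )
            n_reject += unstable
        assert n_reject / n_rep >= 0.99


class TestDilution:
    @pytest.fixture
    def pair(self):
        cfg = SimulationConfig(
            n_somatic_snv=200, n_germline=50, n_artifact=0, n_msi_loci=0,
            purity=0.8, seed=10,
        )
        return simulate_sample_pair(cfg, seed=10)

    def test_somatic_expected_af_scales_by_fraction(self, pair):
        diluted = dilute_sample(pair, 0.25, seed=1)
        for orig, new in zip(pair.variants, diluted.variants):
            if orig.true_origin == "SOMATIC":
                assert new.true_af == pytest.approx(orig.true_af * 0.25)

    def test_identity_at_fraction_one(self, pair):
        diluted = dilute_sample(pair, 1.0, seed=1)
        for orig, new in zip(pair.variants, diluted.variants):
            assert new.true_af == pytest.approx(orig.true_af)

    def test_germline_af_unchanged(self, pair):
        diluted = dilute_sample(pair, 0.05, seed=1)
        for orig, new in zip(pair.variants, diluted.variants):
            if orig.true_origin == "GERMLINE_HET":
                assert new.true_af == 0.5

    def test_expected_af_monotone_in_fraction(self, pair):
        previous = None
        for fraction in (0.025, 0.05, 0.10, 0.30, 0.80):
            diluted = dilute_sample(pair, fraction, seed=1)
            afs = np.array(
                [v.true_af for v in diluted.variants if v.true_origin == "SOMATIC"]
            )
            if previous is not None:
                assert (afs >= previous).all()
            previous = afs

    def test_fraction_out_of_range(self, pair):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                dilute_sample(pair, bad)

    def test_input_label_scales_depth(self, pair):
        d150 = dilute_sample(pair, 0.5, dna_input_label="150ng", seed=1)
        d200 = dilute_sample(pair, 0.5, dna_input_label="200ng", seed=1)
        mean150 = np.mean([v.tumor_depth for v in d150.variants])
        mean200 = np.mean([v.tumor_depth for v in d200.variants])
        assert mean150 == pytest.approx(0.75 * mean200, rel=0.01)


def test_vcf_round_trip(tmp_path, small_pair):
    path = str(tmp_path / "sample.vcf")
    write_vcf(small_pair, path)
    back = read_vcf(path)
    assert len(back) == len(small_pair.variants)
    by_key = {v.key: v for v in small_pair.variants}
    for v in back:
        orig = by_key[v.key]
        assert (v.tumor_alt, v.tumor_ref) == (orig.tumor_alt, orig.tumor_ref)
        assert (v.normal_alt, v.normal_ref) == (orig.normal_alt, orig.normal_ref)
        assert v.true_origin == orig.true_origin
        assert v.variant_type == orig.variant_type
        assert v.true_af == pytest.approx(orig.true_af, abs=1e-5)


def test_microsatellite_tsv_round_trip(tmp_path, small_pair):
    path = str(tmp_path / "loci.tsv")
    write_microsatellite_tsv(small_pair.loci, path)
    back = read_microsatellite_tsv(path)
    assert len(back) == len(small_pair.loci)
    orig = {l.locus_id: l for l in small_pair.loci}
    for locus in back:
        assert locus.tumor_hist == orig[locus.locus_id].tumor_hist
        assert locus.normal_hist == orig[locus.locus_id].normal_hist


def test_config_yaml_round_trip(tmp_path):
    cfg = SimulationConfig(
        n_samples=3, tmb_target=7.5, cna_spec=[("ERBB2", 12.0)],
        fusion_spec=[("EML4", "ALK", 20)], ccf_range=(0.5, 1.0), seed=13,
    )
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    assert SimulationConfig.from_yaml(path) == cfg
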