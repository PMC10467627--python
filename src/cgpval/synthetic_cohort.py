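"""Synthetic matched tumor/normal cohorts with full ground truth.

Every downstream stage of the validation pipeline (somatic
classification, MSI, TMB, CNA, fusion reporting, limit-of-detection)
is exercised on cohorts produced here, so each simulated entity carries
its truth label.

The statistical structure mirrors the assay's study conditions: tumor
exomes at a median depth of 500x with a boosted gene subset at 1500x,
matched normals at 150x, tumor purity at or above the 20% inclusion
gate, binomial sampling of alternate-allele reads, a germline:somatic
mix in which roughly a quarter of reference-method-style calls are
germline, microsatellite repeat-length histograms with a stutter
kernel, gene-level copy-number ratios mixed by purity, and fusion
supporting-read evidence.

A somatic variant at cancer-cell fraction ``ccf`` in a tumor of purity
``p`` on a diploid background has expected allele frequency
``p * ccf / ploidy``; germline heterozygotes sit at AF 0.5 in both
samples regardless of purity.  Normal-sample alternate reads at somatic
sites follow a Binomial(depth, 1e-3) sequencing-error model.

Seeding: one master seed; per-sample child streams are derived with
numpy's SeedSequence spawning, so any subset of a cohort is reproducible
from the master seed alone.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import yaml

from .msi_caller import DEFAULT_N_LOCI, MicrosatelliteLocus

__all__ = [
    "QcGateError",
    "SimulationConfig",
    "VariantObservation",
    "CnaEvidence",
    "FusionEvidence",
    "SamplePair",
    "simulate_sample_pair",
    "simulate_cohort",
    "simulate_microsatellite_loci",
    "simulate_locus_reads",
    "dilute_sample",
    "write_vcf",
    "read_vcf",
    "write_truth_tsv",
    "write_microsatellite_tsv",
    "read_microsatellite_tsv",
]

SOMATIC = "SOMATIC"
GERMLINE_HET = "GERMLINE_HET"
GERMLINE_HOM = "GERMLINE_HOM"
ARTIFACT = "ARTIFACT"

_BASES = "ACGT"


class QcGateError(ValueError):
    """A sample violates an assay inclusion rule (e.g. tumor content <20%)."""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Counts of somatic/germline variants default to None and are then
    derived from the TMB target: nonsynonymous somatic count is
    Poisson(tmb_target * footprint_mb), split into SNVs and indels, and
    the germline count is a third of the somatic count so that roughly a
    quarter of a tumor-only caller's reportable calls are germline.
    """

    n_samples: int = 10
    tumor_depth_median: int = 500
    boosted_depth: int = 1500
    normal_depth: int = 150
    purity: float = 0.5
    n_somatic_snv: int | None = None
    n_somatic_indel: int | None = None
    n_germline: int | None = None
    fraction_boosted_targets: float = 0.1
    msi_status: str = "MSS"
    unstable_locus_fraction: float = 0.2
    n_msi_loci: int = DEFAULT_N_LOCI
    tmb_target: float = 10.0
    footprint_mb: float = 35.0
    cna_spec: list = field(default_factory=list)  # (gene, true_copy_number)
    fusion_spec: list = field(default_factory=list)  # (gene5, gene3, mean_reads)
    seed: int = 0
    # secondary knobs
    indel_fraction: float = 0.18
    n_artifact: int = 10
    normal_error_rate: float = 1e-3
    ploidy: float = 2.0
    ccf_range: tuple[float, float] = (1.0, 1.0)
    germline_hom_fraction: float = 0.1
    rare_germline_fraction: float = 0.1
    reportable_fraction: float = 1.0
    cna_noise_sigma: float = 0.05
    allow_low_purity: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.purity < 0.2 and not self.allow_low_purity:
            raise QcGateError(
                "tumor content below the 20% inclusion gate; "
                "set allow_low_purity=True to override"
            )
        if min(self.tumor_depth_median, self.boosted_depth, self.normal_depth) <= 0:
            raise ValueError("all depths must be positive")
        if not 0 <= self.unstable_locus_fraction <= 1:
            raise ValueError("unstable_locus_fraction must be in [0, 1]")
        if self.footprint_mb <= 0:
            raise ValueError("footprint_mb must be positive")
        if self.msi_status not in ("MSI-H", "MSS"):
            raise ValueError("msi_status must be 'MSI-H' or 'MSS'")

    @property
    def expected_nonsynonymous_count(self) -> float:
        """Expected nonsynonymous somatic count before sampling noise."""
        return self.tmb_target * self.footprint_mb

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["ccf_range"] = list(d["ccf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "ccf_range" in d:
            d["ccf_range"] = tuple(d["ccf_range"])
        if "cna_spec" in d:
            d["cna_spec"] = [tuple(x) for x in d["cna_spec"]]
        if "fusion_spec" in d:
            d["fusion_spec"] = [tuple(x) for x in d["fusion_spec"]]
        return cls(**d)


@dataclass
class VariantObservation:
    """One candidate small variant with tumor/normal read counts and truth."""

    locus: tuple[str, int, str, str]  # chrom, 1-based pos, ref, alt
    tumor_alt: int
    tumor_ref: int
    normal_alt: int
    normal_ref: int
    true_origin: str  # SOMATIC | GERMLINE_HET | GERMLINE_HOM | ARTIFACT
    true_ccf: float = 1.0
    true_af: float = 0.0  # expected tumor AF under the generative model
    is_nonsynonymous: bool = True
    in_reportable_401: bool = True
    population_af: float = 0.0
    variant_type: str = "SNV"  # SNV | INDEL

    def __post_init__(self) -> None:
        if min(self.tumor_alt, self.tumor_ref, self.normal_alt, self.normal_ref) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def tumor_depth(self) -> int:
        return self.tumor_alt + self.tumor_ref

    @property
    def normal_depth(self) -> int:
        return self.normal_alt + self.normal_ref

    @property
    def tumor_af(self) -> float:
        if self.tumor_depth == 0:
            raise ZeroDivisionError("tumor AF undefined at zero depth")
        return self.tumor_alt / self.tumor_depth

    @property
    def normal_af(self) -> float:
        if self.normal_depth == 0:
            raise ZeroDivisionError("normal AF undefined at zero depth")
        return self.normal_alt / self.normal_depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.locus

    @property
    def normal_af_truth(self) -> float:
        """Expected normal-sample AF under the generative model."""
        if self.true_origin == GERMLINE_HET:
            return 0.5
        if self.true_origin == GERMLINE_HOM:
            return 1.0
        return 1e-3


@dataclass(frozen=True)
class CnaEvidence:
    gene: str
    true_copy_number: float
    observed_ratio: float


@dataclass(frozen=True)
class FusionEvidence:
    gene5: str
    gene3: str
    supporting_reads: int
    is_true_event: bool


@dataclass
class SamplePair:
    """One matched tumor/normal sample with all simulated evidence."""

    sample_id: str
    purity: float
    variants: list[VariantObservation] = field(default_factory=list)
    loci: list[MicrosatelliteLocus] = field(default_factory=list)
    cnas: list[CnaEvidence] = field(default_factory=list)
    fusions: list[FusionEvidence] = field(default_factory=list)
    msi_status_truth: str = "MSS"
    dilution_fraction: float = 1.0

    def truth_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.variants:
            counts[v.true_origin] = counts.get(v.true_origin, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# small-variant simulation


def _draw_locus(rng: np.random.Generator, used: set, variant_type: str):
    while True:
        chrom = f"chr{rng.integers(1, 23)}"
        pos = int(rng.integers(1_000_000, 200_000_000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        break
    ref = _BASES[rng.integers(4)]
    if variant_type == "SNV":
        alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
    elif rng.random() < 0.5:  # insertion
        alt = ref + "".join(_BASES[i] for i in rng.integers(0, 4, rng.integers(1, 4)))
    else:  # deletion
        ref = ref + "".join(_BASES[i] for i in rng.integers(0, 4, rng.integers(1, 4)))
        alt = ref[0]
    return chrom, pos, ref, alt


def _tumor_depth(rng: np.random.Generator, config: SimulationConfig) -> int:
    boosted = rng.random() < config.fraction_boosted_targets
    mean = config.boosted_depth if boosted else config.tumor_depth_median
    return max(int(rng.poisson(mean)), 1)


def _emit_variant(
    rng: np.random.Generator,
    config: SimulationConfig,
    used: set,
    origin: str,
    variant_type: str,
    tumor_af: float,
    normal_af: float,
    ccf: float = 1.0,
    population_af: float = 0.0,
) -> VariantObservation:
    locus = _draw_locus(rng, used, variant_type)
    t_depth = _tumor_depth(rng, config)
    n_depth = max(int(rng.poisson(config.normal_depth)), 1)
    t_alt = int(rng.binomial(t_depth, min(tumor_af, 1.0)))
    n_alt = int(rng.binomial(n_depth, min(normal_af, 1.0)))
    return VariantObservation(
        locus=locus,
        tumor_alt=t_alt,
        tumor_ref=t_depth - t_alt,
        normal_alt=n_alt,
        normal_ref=n_depth - n_alt,
        true_origin=origin,
        true_ccf=ccf,
        true_af=tumor_af,
        is_nonsynonymous=True,
        in_reportable_401=bool(rng.random() < config.reportable_fraction),
        population_af=population_af,
        variant_type=variant_type,
    )


def simulate_sample_pair(
    config: SimulationConfig, seed: int | None = None, sample_id: str = "S1"
) -> SamplePair:
    """Generate one matched tumor/normal sample under the study conditions.

    Identical (config, seed) always yields a bitwise-identical sample.
    """
    entropy = config.seed if seed is None else seed
    ss = (
        entropy
        if isinstance(entropy, np.random.SeedSequence)
        else np.random.SeedSequence(entropy)
    )
    rng_var, rng_msi, rng_cna, rng_fus = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    # somatic counts: explicit, or drawn around the TMB target
    if config.n_somatic_snv is not None:
        n_snv = config.n_somatic_snv
        n_indel = config.n_somatic_indel or 0
    else:
        n_total = int(rng_var.poisson(config.expected_nonsynonymous_count))
        n_indel = int(rng_var.binomial(n_total, config.indel_fraction))
        n_snv = n_total - n_indel
    n_germline = (
        config.n_germline
        if config.n_germline is not None
        else round((n_snv + n_indel) / 3)
    )

    used: set = set()
    variants: list[VariantObservation] = []
    lo, hi = config.ccf_range
    for variant_type, count in (("SNV", n_snv), ("INDEL", n_indel)):
        for _ in range(count):
            ccf = float(rng_var.uniform(lo, hi)) if hi > lo else float(lo)
            af = config.purity * ccf / config.ploidy
            variants.append(
                _emit_variant(
                    rng_var, config, used, SOMATIC, variant_type,
                    tumor_af=af, normal_af=config.normal_error_rate, ccf=ccf,
                )
            )
    for _ in range(n_germline):
        hom = rng_var.random() < config.germline_hom_fraction
        af = 1.0 if hom else 0.5
        rare = rng_var.random() < config.rare_germline_fraction
        pop_af = (
            float(rng_var.uniform(0, 1e-3))
            if rare
            else float(rng_var.uniform(0.01, 0.5))
        )
        variants.append(
            _emit_variant(
                rng_var, config, used,
                GERMLINE_HOM if hom else GERMLINE_HET, "SNV",
                tumor_af=af, normal_af=af, population_af=pop_af,
            )
        )
    for _ in range(config.n_artifact):
        af = float(rng_var.uniform(0.005, 0.03))
        variants.append(
            _emit_variant(
                rng_var, config, used, ARTIFACT, "SNV",
                tumor_af=af, normal_af=config.normal_error_rate,
            )
        )

    loci = simulate_microsatellite_loci(
        n_loci=config.n_msi_loci,
        msi_status=config.msi_status,
        unstable_fraction=config.unstable_locus_fraction,
        depth=config.tumor_depth_median,
        seed=rng_msi,
        normal_depth=config.normal_depth,
        purity=config.purity,
    )

    cnas = []
    for gene, true_cn in config.cna_spec:
        expected_ratio = (
            config.purity * true_cn + (1 - config.purity) * config.ploidy
        ) / config.ploidy
        ratio = expected_ratio * float(
            np.exp(rng_cna.normal(0.0, config.cna_noise_sigma))
        )
        cnas.append(CnaEvidence(gene=gene, true_copy_number=true_cn, observed_ratio=ratio))

    fusions = [
        FusionEvidence(
            gene5=g5,
            gene3=g3,
            supporting_reads=int(rng_fus.poisson(mean_reads)),
            is_true_event=True,
        )
        for g5, g3, mean_reads in config.fusion_spec
    ]

    return SamplePair(
        sample_id=sample_id,
        purity=config.purity,
        variants=variants,
        loci=loci,
        cnas=cnas,
        fusions=fusions,
        msi_status_truth=config.msi_status,
    )


def simulate_cohort(config: SimulationConfig) -> list[SamplePair]:
    """Simulate n_samples pairs with per-sample child seeds spawned from
    the master seed."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_samples)
    return [
        simulate_sample_pair(config, seed=child, sample_id=f"S{i + 1:03d}")
        for i, child in enumerate(children)
    ]


# ---------------------------------------------------------------------------
# microsatellite simulation


def _stutter_weights(decay: float, max_offset: int = 3) -> np.ndarray:
    offsets = np.arange(-max_offset, max_offset + 1)
    w = decay ** np.abs(offsets)
    return w / w.sum()


def simulate_locus_reads(
    rng: np.random.Generator,
    germline_length: int,
    depth: int,
    decay: float = 0.15,
    shift: int = 0,
    shift_weight: float = 0.0,
    shifted_decay: float = 0.35,
) -> dict[int, int]:
    """Draw a repeat-length read histogram from a geometric stutter kernel.

    ``shift_weight`` mixes in a second allele at ``germline_length +
    shift`` with a wider kernel, modelling the unstable-tumor read
    population (tumor purity times the unstable-allele fraction).
    """
    offsets = np.arange(-3, 4)
    probs = (1.0 - shift_weight) * _stutter_weights(decay)
    lengths = germline_length + offsets
    hist: dict[int, int] = {}
    if shift_weight > 0:
        shifted = shift_weight * _stutter_weights(shifted_decay)
        all_lengths = np.concatenate([lengths, germline_length + shift + offsets])
        all_probs = np.concatenate([probs, shifted])
    else:
        all_lengths, all_probs = lengths, probs
    counts = rng.multinomial(depth, all_probs / all_probs.sum())
    for length, c in zip(all_lengths, counts):
        if c > 0:
            length = max(int(length), 1)
            hist[length] = hist.get(length, 0) + int(c)
    return hist


def simulate_microsatellite_loci(
    n_loci: int = DEFAULT_N_LOCI,
    msi_status: str = "MSS",
    unstable_fraction: float = 0.2,
    depth: int = 500,
    seed=0,
    normal_depth: int | None = None,
    purity: float = 0.5,
    decay: float = 0.15,
) -> list[MicrosatelliteLocus]:
    """Simulate the repeat-length histograms of the homopolymer panel.

    For an MSI-H sample, round(unstable_fraction * n_loci) loci carry a
    tumor length-distribution whose mode is shifted by 2-3 repeat units
    (and whose stutter variance is inflated); stable loci draw tumor and
    normal reads from the same kernel.  An MSS sample has zero unstable
    loci in truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if normal_depth is None:
        normal_depth = depth
    n_unstable = round(unstable_fraction * n_loci) if msi_status == "MSI-H" else 0
    unstable_idx = set(
        rng.choice(n_loci, size=n_unstable, replace=False).tolist()
    )
    loci = []
    for i in range(n_loci):
        germline_length = int(rng.integers(8, 21))
        normal_hist = simulate_locus_reads(rng, germline_length, normal_depth, decay)
        if i in unstable_idx:
            shift = int(rng.choice([-3, -2, 2, 3]))
            tumor_hist = simulate_locus_reads(
                rng, germline_length, depth, decay,
                shift=shift, shift_weight=purity,
            )
            true_unstable = True
        else:
            tumor_hist = simulate_locus_reads(rng, germline_length, depth, decay)
            true_unstable = False
        loci.append(
            MicrosatelliteLocus(
                locus_id=f"MS{i + 1:03d}",
                tumor_hist=tumor_hist,
                normal_hist=normal_hist,
                true_unstable=true_unstable,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# dilution


def dilute_sample(
    pair: SamplePair,
    fraction: float,
    dna_input_label: str = "200ng",
    seed: int = 0,
) -> SamplePair:
    """Mix the tumor with its matched normal at the given tumor fraction.

    Somatic (and tumor-restricted artifact) expected AFs scale by the
    fraction; germline variants are present in the diluent too, so their
    expected AFs are unchanged.  Counts are re-drawn at each variant's
    original total depth, scaled by DNA input (linear, 200 ng -> the
    undiluted depth).
    """
    if not 0 < fraction <= 1:
        raise ValueError("dilution fraction must be in (0, 1]")
    depth_factor = _input_depth_factor(dna_input_label)
    rng = np.random.default_rng(seed)
    new_variants = []
    for v in pair.variants:
        if v.true_origin == SOMATIC:
            af = v.true_af * fraction
        else:  # germline in both components; artifact rate process-level
            af = v.true_af
        t_depth = max(int(round(v.tumor_depth * depth_factor)), 1)
        n_depth = v.normal_depth
        t_alt = int(rng.binomial(t_depth, min(af, 1.0)))
        n_alt = int(rng.binomial(n_depth, min(v.normal_af_truth, 1.0)))
        new_variants.append(
            dataclasses.replace(
                v,
                tumor_alt=t_alt,
                tumor_ref=t_depth - t_alt,
                normal_alt=n_alt,
                normal_ref=n_depth - n_alt,
                true_af=af,
            )
        )
    return SamplePair(
        sample_id=f"{pair.sample_id}_d{fraction:g}_{dna_input_label}",
        purity=pair.purity * fraction,
        variants=new_variants,
        loci=pair.loci,
        cnas=pair.cnas,
        fusions=pair.fusions,
        msi_status_truth=pair.msi_status_truth,
        dilution_fraction=pair.dilution_fraction * fraction,
    )


def _input_depth_factor(dna_input_label: str) -> float:
    """Linear ng-to-depth mapping anchored at 200 ng -> full depth."""
    m = re.fullmatch(r"\s*(\d+(?:\.\d+)?)\s*ng\s*", dna_input_label)
    if not m:
        return 1.0
    return float(m.group(1)) / 200.0


# ---------------------------------------------------------------------------
# serialization: VCF 4.2 + TSV sidecars


_INFO_FIELDS = [
    ("TRUE_ORIGIN", "1", "String", "Ground-truth variant origin"),
    ("TRUE_AF", "1", "Float", "Expected tumor AF under the generative model"),
    ("TRUE_CCF", "1", "Float", "Ground-truth cancer cell fraction"),
    ("POP_AF", "1", "Float", "Population allele frequency"),
    ("VTYPE", "1", "String", "SNV or INDEL"),
    ("NONSYN", "0", "Flag", "Nonsynonymous consequence"),
    ("REPORTABLE", "0", "Flag", "In the 401-gene reportable set"),
]


def write_vcf(pair: SamplePair, path: str) -> None:
    """Write tumor/normal observations as uncompressed VCF 4.2 with
    AD/DP per-sample fields and truth labels in INFO."""
    header = pysam.VariantHeader()
    for i in range(1, 23):
        header.contigs.add(f"chr{i}", length=250_000_000)
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", "1", "Integer", "Total depth")
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")
    vcf = pysam.VariantFile(path, "w", header=header)
    for v in sorted(pair.variants, key=lambda x: (int(x.locus[0][3:]), x.locus[1])):
        chrom, pos, ref, alt = v.locus
        rec = vcf.new_record(
            contig=chrom, start=pos - 1, stop=pos - 1 + len(ref), alleles=(ref, alt)
        )
        rec.info["TRUE_ORIGIN"] = v.true_origin
        rec.info["TRUE_AF"] = v.true_af
        rec.info["TRUE_CCF"] = v.true_ccf
        rec.info["POP_AF"] = v.population_af
        rec.info["VTYPE"] = v.variant_type
        rec.info["NONSYN"] = v.is_nonsynonymous
        rec.info["REPORTABLE"] = v.in_reportable_401
        rec.samples["TUMOR"]["AD"] = (v.tumor_ref, v.tumor_alt)
        rec.samples["TUMOR"]["DP"] = v.tumor_depth
        rec.samples["NORMAL"]["AD"] = (v.normal_ref, v.normal_alt)
        rec.samples["NORMAL"]["DP"] = v.normal_depth
        vcf.write(rec)
    vcf.close()


def read_vcf(path: str) -> list[VariantObservation]:
    vcf = pysam.VariantFile(path)
    variants = []
    for rec in vcf:
        t_ref, t_alt = rec.samples["TUMOR"]["AD"]
        n_ref, n_alt = rec.samples["NORMAL"]["AD"]
        variants.append(
            VariantObservation(
                locus=(rec.chrom, rec.pos, rec.ref, rec.alts[0]),
                tumor_alt=t_alt,
                tumor_ref=t_ref,
                normal_alt=n_alt,
                normal_ref=n_ref,
                true_origin=rec.info["TRUE_ORIGIN"],
                true_ccf=float(rec.info["TRUE_CCF"]),
                true_af=float(rec.info["TRUE_AF"]),
                is_nonsynonymous="NONSYN" in rec.info,
                in_reportable_401="REPORTABLE" in rec.info,
                population_af=float(rec.info["POP_AF"]),
                variant_type=rec.info["VTYPE"],
            )
        )
    vcf.close()
    return variants


def write_truth_tsv(pair: SamplePair, path: str) -> None:
    rows = [
        {
            "sample_id": pair.sample_id,
            "chrom": v.locus[0],
            "pos": v.locus[1],
            "ref": v.locus[2],
            "alt": v.locus[3],
            "true_origin": v.true_origin,
            "true_af": v.true_af,
            "true_ccf": v.true_ccf,
            "variant_type": v.variant_type,
            "population_af": v.population_af,
        }
        for v in pair.variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_microsatellite_tsv(loci: list[MicrosatelliteLocus], path: str) -> None:
    rows = []
    for locus in loci:
        for sample, hist in (("tumor", locus.tumor_hist), ("normal", locus.normal_hist)):
            for length, count in sorted(hist.items()):
                rows.append(
                    {
                        "locus_id": locus.locus_id,
                        "sample": sample,
                        "repeat_length": length,
                        "read_count": count,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_microsatellite_tsv(path: str) -> list[MicrosatelliteLocus]:
    df = pd.read_csv(path, sep="\t")
    loci = []
    for locus_id, group in df.groupby("locus_id", sort=True):
        hists: dict[str, dict[int, int]] = {"tumor": {}, "normal": {}}
        for _, row in group.iterrows():
            hists[row["sample"]][int(row["repeat_length"])] = int(row["read_count"])
        loci.append(
            MicrosatelliteLocus(
                locus_id=str(locus_id),
                tumor_hist=hists["tumor"],
                normal_hist=hists["normal"],
            )
        )
    return loci
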