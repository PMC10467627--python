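"""Limit-of-detection analysis from a tumor-into-normal dilution series.

Tumor samples are mixed with the matched normal at fractions 80%, 50%,
30%, 20%, 10%, 5%, and 2.5%, at two DNA inputs (200 ng and 150 ng,
mapped linearly to sequencing depth).  The somatic variants detected in
the undiluted sample form the truth set; each truth variant's expected
AF in a dilution is its measured undiluted AF times the dilution
fraction.  Detection in a dilution requires at least 4 alternate reads
under binomial sampling at depth, times a logistic caller-sensitivity
term in the expected AF (midpoint 4% AF) emulating the real caller's
roll-off at low allele fractions.

The LOD interval is the lowest expected-AF bin whose positive percent
agreement is at or above 95% with every higher bin also at or above
95%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_cohort import SamplePair, dilute_sample

__all__ = [
    "DEFAULT_FRACTIONS",
    "DEFAULT_BIN_EDGES",
    "LodResult",
    "expected_af",
    "detection_probability",
    "detect_variants",
    "run_dilution_series",
    "ppa_by_af_bin",
    "plot_ppa_vs_af",
]

DEFAULT_FRACTIONS = (0.80, 0.50, 0.30, 0.20, 0.10, 0.05, 0.025)
DEFAULT_INPUTS_NG = (200, 150)
DEFAULT_BIN_EDGES = (0.0, 0.025, 0.05, 0.10, 0.20, 0.50, 1.0)
PPA_THRESHOLD = 0.95
MIN_ALT_READS = 4
LOGISTIC_MIDPOINT = 0.04
LOGISTIC_SCALE = 0.004


def expected_af(undiluted_af: float, fraction: float) -> float:
    """Expected AF of a somatic variant after dilution: the product of
    the measured undiluted AF and the tumor fraction."""
    if not 0 <= undiluted_af <= 1 or not 0 <= fraction <= 1:
        raise ValueError("AF and fraction must be in [0, 1]")
    return undiluted_af * fraction


def detection_probability(
    af: float,
    midpoint: float = LOGISTIC_MIDPOINT,
    scale: float = LOGISTIC_SCALE,
) -> float:
    """Logistic caller-sensitivity curve in expected AF."""
    return float(1.0 / (1.0 + np.exp(-(af - midpoint) / scale)))


def detect_variants(
    pair: SamplePair,
    seed: int = 0,
    min_alt_reads: int = MIN_ALT_READS,
    midpoint: float = LOGISTIC_MIDPOINT,
    scale: float = LOGISTIC_SCALE,
    reportable_only: bool = True,
) -> set:
    """Somatic variants detected in one (possibly diluted) sample.

    A variant is detected when its alternate-read count meets the floor
    and a Bernoulli draw under the logistic sensitivity at its expected
    AF succeeds.
    """
    rng = np.random.default_rng(seed)
    detected = set()
    for v in pair.variants:
        if v.true_origin != "SOMATIC":
            continue
        if reportable_only and not v.in_reportable_401:
            continue
        if v.tumor_alt < min_alt_reads:
            continue
        if rng.random() < detection_probability(v.true_af, midpoint, scale):
            detected.add(v.key)
    return detected


@dataclass
class LodResult:
    """Per-bin PPA over expected-AF intervals and the derived LOD."""

    bins: list[tuple[float, float]]
    ppa_per_bin: list[float | None]
    n_per_bin: list[int]
    threshold: float = PPA_THRESHOLD
    empty_bins: list[tuple[float, float]] = field(default_factory=list)

    @property
    def lod_interval(self) -> tuple[float, float] | None:
        """Lowest bin meeting the PPA threshold with all higher
        (non-empty) bins also meeting it."""
        lod = None
        for b, p in zip(reversed(self.bins), reversed(self.ppa_per_bin)):
            if p is None:
                continue
            if p >= self.threshold:
                lod = b
            else:
                break
        return lod


def ppa_by_af_bin(
    records: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
    threshold: float = PPA_THRESHOLD,
) -> LodResult:
    """Bin truth-variant instances by expected AF and compute per-bin PPA.

    `records` needs columns ``expected_af`` (fraction) and ``detected``
    (bool); each row is one truth variant in one dilution sample.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    bins = list(zip(edges[:-1], edges[1:]))
    ppas: list[float | None] = []
    ns: list[int] = []
    empty = []
    for lo, hi in bins:
        mask = (records["expected_af"] >= lo) & (records["expected_af"] < hi)
        n = int(mask.sum())
        ns.append(n)
        if n == 0:
            ppas.append(None)
            empty.append((lo, hi))
        else:
            ppas.append(float(records.loc[mask, "detected"].mean()))
    return LodResult(
        bins=bins, ppa_per_bin=ppas, n_per_bin=ns, threshold=threshold,
        empty_bins=empty,
    )


def run_dilution_series(
    base_pair: SamplePair,
    fractions=DEFAULT_FRACTIONS,
    inputs_ng=DEFAULT_INPUTS_NG,
    seed: int = 0,
    min_alt_reads: int = MIN_ALT_READS,
    midpoint: float = LOGISTIC_MIDPOINT,
    scale: float = LOGISTIC_SCALE,
) -> pd.DataFrame:
    """Dilute, re-call, and tabulate detection for every truth variant.

    Returns one row per (DNA input, dilution fraction, truth variant)
    with the variant type, its expected AF in that dilution, and whether
    it was detected.  The truth set is the set of somatic variants
    detected in the undiluted sample, with their measured undiluted AFs.
    """
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(2 + 2 * len(fractions) * len(inputs_ng)).tolist())
    truth_keys = detect_variants(
        base_pair, seed=next(seeds), min_alt_reads=min_alt_reads,
        midpoint=midpoint, scale=scale,
    )
    by_key = {v.key: v for v in base_pair.variants}
    undiluted_af = {k: by_key[k].tumor_af for k in truth_keys}
    rows = []
    for input_ng in inputs_ng:
        label = f"{input_ng}ng"
        for fraction in fractions:
            diluted = dilute_sample(
                base_pair, fraction, dna_input_label=label, seed=next(seeds) % (2**31)
            )
            detected = detect_variants(
                diluted, seed=next(seeds), min_alt_reads=min_alt_reads,
                midpoint=midpoint, scale=scale,
            )
            for key in truth_keys:
                rows.append(
                    {
                        "input_ng": input_ng,
                        "fraction": fraction,
                        "key": key,
                        "variant_type": by_key[key].variant_type,
                        "expected_af": expected_af(undiluted_af[key], fraction),
                        "detected": key in detected,
                    }
                )
    return pd.DataFrame(rows)


def plot_ppa_vs_af(results: dict[str, LodResult], path: str) -> None:
    """PPA versus expected-AF interval, one line per series, with the
    95% threshold dashed."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, res in results.items():
        xs, ys = [], []
        for (lo, hi), p in zip(res.bins, res.ppa_per_bin):
            if p is not None:
                xs.append(f"{lo * 100:g}-{hi * 100:g}%")
                ys.append(p * 100)
        ax.plot(xs, ys, marker="o", label=label)
    ax.axhline(95, linestyle="--", color="grey", label="95% PPA")
    ax.set_xlabel("expected AF interval")
    ax.set_ylabel("PPA (%)")
    ax.set_ylim(0, 105)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
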