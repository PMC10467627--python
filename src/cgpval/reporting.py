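"""End-to-end pipeline runs and the summary validation report.

``run_end_to_end`` executes simulate -> qc -> call (small variants,
MSI, TMB, CNA, fusions) -> validate (-> optionally LOD) on a synthetic
cohort and writes a report whose layout mirrors the validation study's
summary and 2x2 concordance tables.  Reports are deterministic for a
fixed config and seed; output filenames carry the config hash and seed
for provenance.  ``printed_tables_report`` renders the same layout from
the bundled printed counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (
    cna_caller,
    fusion_reporter,
    lod_analyzer,
    msi_caller,
    qc_gates,
    somatic_small_variants as ssv,
    synthetic_cohort as syn,
    tmb_calculator,
    validation_stats as vstats,
)

__all__ = ["RunConfig", "run_end_to_end", "printed_tables_report", "render_markdown"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable configuration of one end-to-end run."""

    simulation: syn.SimulationConfig = field(default_factory=syn.SimulationConfig)
    thresholds: ssv.ClassificationThresholds = field(
        default_factory=ssv.ClassificationThresholds
    )
    out_dir: str = "cgpval_run"
    seed: int = 0
    run_lod: bool = False
    lod_n_somatic: int = 400

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["ccf_range"] = list(d["simulation"]["ccf_range"])
        d["thresholds"]["germline_het_band"] = list(
            d["thresholds"]["germline_het_band"]
        )
        return d

    @property
    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:8]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = d.pop("simulation", {})
        if "ccf_range" in sim:
            sim["ccf_range"] = tuple(sim["ccf_range"])
        thr = d.pop("thresholds", {})
        if "germline_het_band" in thr:
            thr["germline_het_band"] = tuple(thr["germline_het_band"])
        return cls(
            simulation=syn.SimulationConfig(**sim),
            thresholds=ssv.ClassificationThresholds(**thr),
            **d,
        )


def _concordance_vs_truth(
    calls: list[ssv.ClassifiedCall], af_min: float, variant_type: str | None = None
) -> vstats.ConcordanceTable:
    """Compare somatic calls against simulation truth.

    Truth positives are true somatic variants whose expected AF clears
    the reportable threshold (the same >5% criterion the validation
    study applied to its reference calls).
    """
    tp = fp = fn = 0
    for c in calls:
        if variant_type and c.variant.variant_type != variant_type:
            continue
        truth_pos = c.variant.true_origin == "SOMATIC" and c.variant.true_af > af_min
        called_pos = c.call == ssv.SOMATIC
        if called_pos and truth_pos:
            tp += 1
        elif called_pos and not truth_pos:
            fp += 1
        elif truth_pos:
            fn += 1
    return vstats.ConcordanceTable(tp=tp, fp=fp, fn=fn)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                logger.error("stage %s: FAILED after %.2fs (%s)", name, dt, exc)
                return False
            logger.info("stage %s: done in %.2fs", name, dt)
            return None

    return _Timer()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full synthetic validation pipeline and write the report.

    Returns the report dict; writes ``report_<hash>_s<seed>.json`` and a
    Markdown rendering into ``config.out_dir``.
    """
    if config.simulation.n_samples <= 0:
        raise StageError("simulate: config requests zero samples")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    t = config.thresholds

    try:
        with _stage("simulate"):
            cohort = syn.simulate_cohort(sim_cfg)
        with _stage("qc"):
            qc_verdicts = {
                p.sample_id: qc_gates.evaluate_qc(
                    qc_gates.QcMetrics(
                        tumor_content=p.purity,
                        dna_input_ng=200.0,
                        a260_230=2.0,
                        q30=0.9,
                    )
                )
                for p in cohort
            }
        with _stage("call"):
            per_sample = {}
            agg = {"SNV": [0, 0, 0], "INDEL": [0, 0, 0],
                   "CNA": [0, 0, 0], "FUSION": [0, 0, 0]}
            msi_concordant = 0
            for p in cohort:
                calls_tn = ssv.classify_sample(p.variants, t)
                calls_to = ssv.classify_tumor_only(p.variants, t)
                msi = msi_caller.call_msi(p.loci)
                tmb_tn = tmb_calculator.compute_tmb(
                    calls_tn, sim_cfg.footprint_mb, mode="TUMOR_NORMAL"
                )
                tmb_to = tmb_calculator.compute_tmb(
                    calls_to, sim_cfg.footprint_mb, mode="TUMOR_ONLY"
                )
                cna_calls = [
                    cna_caller.call_cna(
                        e.gene,
                        cna_caller.estimate_copy_number(e.observed_ratio, p.purity),
                    )
                    for e in p.cnas
                ]
                fusion_calls = []
                for f in p.fusions:
                    fc = fusion_reporter.FusionCall(
                        f.gene5, f.gene3, f.supporting_reads
                    )
                    fusion_reporter.filter_reportable(fc)
                    fc.call = fusion_reporter.call_fusion(f.supporting_reads)
                    fusion_calls.append(fc)
                for vt in ("SNV", "INDEL"):
                    ct = _concordance_vs_truth(calls_tn, t.af_min_reportable, vt)
                    for i, x in enumerate((ct.tp, ct.fp, ct.fn)):
                        agg[vt][i] += x
                for ev, cc in zip(p.cnas, cna_calls):
                    truth_pos = (
                        ev.true_copy_number >= cna_caller.AMP_CUTOFF
                        or ev.true_copy_number <= cna_caller.DEL_CUTOFF
                    )
                    called_pos = cc.call != "NEUTRAL"
                    agg["CNA"][0] += called_pos and truth_pos
                    agg["CNA"][1] += called_pos and not truth_pos
                    agg["CNA"][2] += truth_pos and not called_pos
                for ev, fc in zip(p.fusions, fusion_calls):
                    truth_pos = ev.is_true_event and fc.reportable
                    called_pos = fc.call == "present" and fc.reportable
                    agg["FUSION"][0] += called_pos and truth_pos
                    agg["FUSION"][1] += called_pos and not truth_pos
                    agg["FUSION"][2] += truth_pos and not called_pos
                msi_concordant += msi.status == p.msi_status_truth
                per_sample[p.sample_id] = {
                    "qc_pass": qc_verdicts[p.sample_id].passed,
                    "msi_status": msi.status,
                    "msi_unstable_fraction": round(msi.unstable_fraction, 4),
                    "tmb_tumor_normal": round(tmb_tn.tmb, 3),
                    "tmb_tumor_only": round(tmb_to.tmb, 3),
                    "cna_calls": [
                        (c.gene, round(c.estimated_copy_number, 2), c.call)
                        for c in cna_calls
                    ],
                    "fusion_calls": [
                        (fc.gene5, fc.gene3, fc.reportable, fc.call)
                        for fc in fusion_calls
                    ],
                }
        with _stage("validate"):
            concordance = {}
            for vt, (tp, fp, fn) in agg.items():
                table = vstats.ConcordanceTable(tp=tp, fp=fp, fn=fn)
                entry = {"tp": tp, "fp": fp, "fn": fn}
                if tp + fn > 0:
                    lo, hi = vstats.binomial_ci(tp, tp + fn)
                    entry.update(
                        ppa_pct=vstats.percent(vstats.ppa(table)),
                        ppa_ci_pct=[vstats.percent(lo), vstats.percent(hi)],
                    )
                if tp + fp > 0:
                    entry["ppv_pct"] = vstats.percent(vstats.ppv(table))
                concordance[vt.lower()] = entry
            concordance["msi"] = {
                "n_concordant": msi_concordant,
                "n_total": len(cohort),
                "accuracy_pct": vstats.percent(
                    vstats.overall_accuracy(msi_concordant, len(cohort))
                ),
            }
        report = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "n_samples": len(cohort),
            "concordance": concordance,
            "per_sample": per_sample,
        }
        if config.run_lod:
            with _stage("lod"):
                lod_cfg = dataclasses.replace(
                    sim_cfg,
                    n_somatic_snv=config.lod_n_somatic,
                    n_somatic_indel=round(config.lod_n_somatic * 0.2),
                    purity=0.8,
                    ccf_range=(0.3, 1.0),
                )
                base = syn.simulate_sample_pair(lod_cfg, seed=config.seed)
                records = lod_analyzer.run_dilution_series(base, seed=config.seed)
                lod = lod_analyzer.ppa_by_af_bin(records)
                report["lod"] = {
                    "bins": lod.bins,
                    "ppa_per_bin": [
                        None if p is None else round(p, 4) for p in lod.ppa_per_bin
                    ],
                    "lod_interval": lod.lod_interval,
                }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
        raise StageError(f"pipeline failed: {exc}") from exc

    stem = f"report_{config.config_hash}_s{config.seed}"
    (out_dir / f"{stem}.json").write_text(json.dumps(report, indent=2) + "\n")
    (out_dir / f"{stem}.md").write_text(render_markdown(report))
    return report


def printed_tables_report() -> dict:
    """Recompute the eight concordance percentages from the bundled
    printed 2x2 counts."""
    tables = vstats.load_printed_tables()
    out = {}
    for name in ("snv", "indel", "cna", "fusion"):
        t = vstats.ConcordanceTable(**tables[name])
        lo, hi = vstats.binomial_ci(t.tp, t.tp + t.fn)
        out[name] = {
            "tp": t.tp,
            "fp": t.fp,
            "fn": t.fn,
            "ppa_pct": vstats.percent(vstats.ppa(t)),
            "ppv_pct": vstats.percent(vstats.ppv(t)),
            "ppa_ci_pct": [vstats.percent(lo), vstats.percent(hi)],
        }
    msi = tables["msi"]
    out["msi"] = {
        "n_concordant": msi["n_concordant"],
        "n_total": msi["n_total"],
        "accuracy_pct": vstats.percent(
            vstats.overall_accuracy(msi["n_concordant"], msi["n_total"])
        ),
    }
    return out


def render_markdown(report: dict) -> str:
    """Markdown tables mirroring the summary/2x2 layout of the study."""
    lines = ["# Validation summary", ""]
    conc = report.get("concordance", report)
    lines += ["| Variant class | TP | FP | FN | PPA (%) | PPV (%) | PPA 95% CI |",
              "|---|---|---|---|---|---|---|"]
    for name, entry in conc.items():
        if name == "msi":
            continue
        ci = entry.get("ppa_ci_pct")
        lines.append(
            "| {} | {} | {} | {} | {} | {} | {} |".format(
                name.upper(),
                entry.get("tp", ""),
                entry.get("fp", ""),
                entry.get("fn", ""),
                entry.get("ppa_pct", "n/a"),
                entry.get("ppv_pct", "n/a"),
                f"{ci[0]}-{ci[1]}" if ci else "n/a",
            )
        )
    if "msi" in conc:
        m = conc["msi"]
        lines += [
            "",
            f"MSI status concordance: {m['n_concordant']}/{m['n_total']}"
            f" = {m['accuracy_pct']}%",
        ]
    if "lod" in report:
        lines += ["", "## Limit of detection", ""]
        for (lo, hi), p in zip(report["lod"]["bins"], report["lod"]["ppa_per_bin"]):
            shown = "n/a" if p is None else f"{p * 100:.1f}%"
            lines.append(f"- expected AF {lo * 100:g}-{hi * 100:g}%: PPA {shown}")
        lines.append(f"- LOD interval: {report['lod']['lod_interval']}")
    return "\n".join(lines) + "\n"
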