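"""End-to-end reporting pipeline: filter -> triage -> LOH -> benchmark.

Ties the stages together under one resolved, hashable configuration so a
run is reproducible bit-for-bit from its inputs: per-sample variant
filtering and triage, clinical-significance partition, 1p/19q calling,
optional benchmarking against a truth table, coverage QC, and a
deterministic output tree (per-sample TSV/JSON, cohort summaries,
oncoplot matrix, attrition table).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as gio
from .diagnostics import ConfusionCounts, metrics
from .errors import ValidationError
from .loh import CodeletionCall, LohConfig, benchmark_codeletion, call_sample
from .panel import CoverageReport, PanelDesign, coverage_qc, default_panel, load_panel
from .variants import (
    FilterConfig,
    FilterTrace,
    VariantRecord,
    apply_filter_chain,
    category_counts,
    classify_clinical,
    oncoplot_matrix,
    prioritize,
)

log = logging.getLogger(__name__)


@dataclass
class SampleInput:
    """Paths for one sample; variants come from a VCF+sidecar or one TSV."""

    sample_id: str
    vcf: str | None = None
    sidecar: str | None = None
    variants_tsv: str | None = None
    snp_table: str | None = None
    depth_table: str | None = None


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; YAML round-trips losslessly."""

    samples: list[SampleInput] = field(default_factory=list)
    panel_bed: str | None = None
    panel_manifest: str | None = None
    panel_markers: str | None = None
    truth: str | None = None
    out_dir: str = "gliopanel_out"
    seed: int = 0
    force: bool = False
    log_level: str = "INFO"
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    loh_config: LohConfig = field(default_factory=LohConfig)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter_config"]["allowed_locations"] = sorted(
            self.filter_config.allowed_locations
        )
        d["filter_config"]["allowed_effects"] = sorted(self.filter_config.allowed_effects)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        fc = dict(d.pop("filter_config", {}))
        if "allowed_locations" in fc:
            fc["allowed_locations"] = frozenset(fc["allowed_locations"])
        if "allowed_effects" in fc:
            fc["allowed_effects"] = frozenset(fc["allowed_effects"])
        lc = dict(d.pop("loh_config", {}))
        samples = [SampleInput(**s) for s in d.pop("samples", [])]
        return cls(
            samples=samples,
            filter_config=FilterConfig(**fc),
            loh_config=LohConfig(**lc),
            **d,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable digest of every resolved threshold and path."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SampleReport:
    """Everything reported for one sample."""

    sample_id: str
    n_raw: int
    kept: list[VariantRecord]
    prioritized: list[VariantRecord]
    clinical: dict[str, list[VariantRecord]]
    trace: FilterTrace
    codeletion: CodeletionCall | None = None
    coverage: CoverageReport | None = None

    def summary(self, config_hash: str) -> dict:
        out = {
            "sample_id": self.sample_id,
            "config_hash": config_hash,
            "n_raw_variants": self.n_raw,
            "n_kept": len(self.kept),
            "n_prioritized": len(self.prioritized),
            "categories": category_counts(self.prioritized),
            "clinical": {k: len(v) for k, v in self.clinical.items()},
            "attrition": dict(self.trace.attrition),
        }
        if self.codeletion is not None:
            out["codeletion"] = {
                "call": self.codeletion.codeleted,
                "qc_tier": self.codeletion.qc_tier.value,
                "arm_1p": self.codeletion.arm_1p.status.value,
                "arm_19q": self.codeletion.arm_19q.status.value,
            }
        if self.coverage is not None:
            out["coverage"] = {
                "n_amplicons": self.coverage.n_amplicons,
                "mean_depth": self.coverage.mean_depth,
                "pct_at": {str(k): v for k, v in self.coverage.pct_at.items()},
                "n_low_coverage": len(self.coverage.low_coverage_amplicons),
            }
        return out


@dataclass
class CohortResult:
    reports: list[SampleReport]
    oncoplot: pd.DataFrame
    config_hash: str
    benchmark: dict[str, dict] | None = None  # marker class -> counts + metrics


def _load_sample_variants(s: SampleInput) -> list[VariantRecord]:
    if s.variants_tsv:
        return gio.read_variants_tsv(s.variants_tsv)
    if s.vcf:
        return gio.read_vcf_with_sidecar(s.vcf, s.sidecar, sample_id=s.sample_id)
    return []


def process_sample(
    sample_id: str,
    raw_variants: Sequence[VariantRecord],
    snp_observations: Sequence | None,
    cfg: RunConfig,
    panel: PanelDesign | None = None,
    depths: Mapping[str, float] | None = None,
) -> SampleReport:
    """Run all analytic stages for one sample's in-memory tables."""
    kept, trace = apply_filter_chain(list(raw_variants), cfg.filter_config)
    prioritized = prioritize(kept)
    clinical = classify_clinical(prioritized)
    codeletion = None
    if snp_observations:
        codeletion = call_sample(list(snp_observations), cfg.loh_config, sample_id=sample_id)
    coverage = None
    if depths is not None and panel is not None:
        coverage = coverage_qc(panel, depths)
    log.info(
        "sample %s: %d raw -> %d kept -> %d prioritized (thresholds: cov>=%d, "
        "alt in [%d, %d], vaf>=%.3f, maf<=%.2f)",
        sample_id, len(raw_variants), len(kept), len(prioritized),
        cfg.filter_config.min_coverage, cfg.filter_config.min_allele_reads,
        cfg.filter_config.max_allele_reads, cfg.filter_config.min_vaf,
        cfg.filter_config.max_maf,
    )
    return SampleReport(
        sample_id=sample_id,
        n_raw=len(raw_variants),
        kept=kept,
        prioritized=prioritized,
        clinical=clinical,
        trace=trace,
        codeletion=codeletion,
        coverage=coverage,
    )


def _benchmark(reports: Sequence[SampleReport], truth: pd.DataFrame) -> dict[str, dict]:
    """Benchmark codeletion and IDH1 hotspot detection against truth columns."""
    truth = truth.set_index("sample_id")
    out: dict[str, dict] = {}
    # 1p/19q codeletion
    calls = {
        r.sample_id: r.codeletion
        for r in reports
        if r.codeletion is not None and r.sample_id in truth.index
    }
    if calls and "loh_1p19q" in truth.columns:
        counts = benchmark_codeletion(
            calls, {s: truth.loc[s, "loh_1p19q"] for s in calls}
        )
        out["codeletion"] = _metric_block(counts)
    # IDH1 p.R132H presence among chain-passing variants
    if "idh1_2" in truth.columns:
        tp = tn = fp = fn = 0
        for r in reports:
            if r.sample_id not in truth.index:
                raise ValidationError(f"sample {r.sample_id} has no truth label")
            called = any(
                v.gene == "IDH1" and v.pos == 209_113_112 and v.alt == "T"
                for v in r.kept
            )
            positive = str(truth.loc[r.sample_id, "idh1_2"]).strip() != "wt"
            if called and positive:
                tp += 1
            elif called:
                fp += 1
            elif positive:
                fn += 1
            else:
                tn += 1
        out["idh1"] = _metric_block(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    return out


def _metric_block(counts: ConfusionCounts) -> dict:
    m = metrics(counts)
    return {
        "tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn,
        **m.as_dict(),
    }


def run_pipeline(cfg: RunConfig, panel: PanelDesign | None = None) -> CohortResult:
    """Execute the pipeline for every configured sample and write reports."""
    if panel is None:
        if cfg.panel_bed and cfg.panel_manifest and cfg.panel_markers:
            panel = load_panel(cfg.panel_bed, cfg.panel_manifest, cfg.panel_markers)
        else:
            panel = default_panel()
    reports: list[SampleReport] = []
    for s in cfg.samples:
        try:
            raw = _load_sample_variants(s)
            snps = None
            if s.snp_table:
                per_sample = gio.read_snp_tsv(s.snp_table)
                snps = per_sample.get(s.sample_id) or next(iter(per_sample.values()), None)
            depths = gio.read_depth_tsv(s.depth_table) if s.depth_table else None
            reports.append(
                process_sample(s.sample_id, raw, snps, cfg, panel=panel, depths=depths)
            )
        except ValidationError as exc:
            raise ValidationError(f"sample {s.sample_id}: {exc}") from exc
    oncoplot = oncoplot_matrix(
        {r.sample_id: r.clinical["pathogenic_like"] for r in reports}
    )
    benchmark = None
    if cfg.truth:
        benchmark = _benchmark(reports, gio.read_truth_tsv(cfg.truth))
    result = CohortResult(
        reports=reports,
        oncoplot=oncoplot,
        config_hash=cfg.config_hash(),
        benchmark=benchmark,
    )
    write_reports(result, cfg)
    return result


def write_reports(result: CohortResult, cfg: RunConfig) -> None:
    """Write the deterministic output tree (stable column order)."""
    out_dir = Path(cfg.out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not cfg.force:
        existing = {p.name for p in out_dir.iterdir()}
        ours = {"cohort_summary.json", "oncoplot.tsv", "attrition.tsv", "codeletion_calls.tsv"}
        if existing & ours:
            raise ValidationError(
                f"output directory {out_dir} already holds reports; pass force=True/--force"
            )
    out_dir.mkdir(parents=True, exist_ok=True)

    attr_rows = []
    codel_rows = []
    for r in result.reports:
        gio.write_variants_tsv(r.prioritized, out_dir / f"{r.sample_id}.variants.tsv")
        with open(out_dir / f"{r.sample_id}.summary.json", "w") as fh:
            json.dump(r.summary(result.config_hash), fh, indent=2, sort_keys=True)
            fh.write("\n")
        for rule, n in r.trace.attrition.items():
            attr_rows.append({"sample_id": r.sample_id, "rule": rule, "removed": n})
        if r.codeletion is not None:
            codel_rows.append(
                {
                    "sample_id": r.sample_id,
                    "codeleted": r.codeletion.codeleted,
                    "qc_tier": r.codeletion.qc_tier.value,
                    "arm_1p": r.codeletion.arm_1p.status.value,
                    "arm_19q": r.codeletion.arm_19q.status.value,
                    "n_het_1p": r.codeletion.arm_1p.n_het,
                    "n_het_19q": r.codeletion.arm_19q.n_het,
                    "n_imbalance_1p": r.codeletion.arm_1p.n_imbalance,
                    "n_imbalance_19q": r.codeletion.arm_19q.n_imbalance,
                }
            )
    pd.DataFrame(
        attr_rows, columns=["sample_id", "rule", "removed"]
    ).to_csv(out_dir / "attrition.tsv", sep="\t", index=False)
    pd.DataFrame(
        codel_rows,
        columns=[
            "sample_id", "codeleted", "qc_tier", "arm_1p", "arm_19q",
            "n_het_1p", "n_het_19q", "n_imbalance_1p", "n_imbalance_19q",
        ],
    ).to_csv(out_dir / "codeletion_calls.tsv", sep="\t", index=False)
    result.oncoplot.to_csv(out_dir / "oncoplot.tsv", sep="\t")
    cohort = {
        "config_hash": result.config_hash,
        "n_samples": len(result.reports),
        "samples": [r.summary(result.config_hash) for r in result.reports],
    }
    if result.benchmark is not None:
        cohort["benchmark"] = result.benchmark
    with open(out_dir / "cohort_summary.json", "w") as fh:
        json.dump(cohort, fh, indent=2, sort_keys=True)
        fh.write("\n")
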