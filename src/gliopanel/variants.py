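"""Somatic variant filter chain, triage, clinical classification, oncoplot.

Tumor-only targeted sequencing of FFPE glioma tissue yields thousands of
raw caller records per run; only a handful are clinically reportable.
Reduction happens in three explicit stages:

1. :func:`apply_filter_chain` — the caller-level chain of seven conjunctive
   rules (coverage, allele read-count, location, VAF, effect class,
   population MAF, in-silico deleteriousness).  The chain intentionally
   still admits intronic/upstream records, mirroring caller-side settings.
2. :func:`prioritize` — the triage step that removes intronic and upstream
   records and buckets the remainder into exonic / splice-site / UTR
   categories (somatic synonymous and UTR variants are retained as
   functionally cancer-associated).
3. :func:`classify_clinical` — a label-driven partition on the annotated
   clinical-significance string (pathogenic-like vs benign/conflicting).

All rules are pure predicates on a single record, so the chain is
order-independent and idempotent; :class:`FilterTrace` records every rule
outcome and attributes each removal to the first failing rule in the
canonical a–g order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

LOCATIONS = {
    "exonic",
    "intronic",
    "upstream",
    "splicesite_5",
    "splicesite_3",
    "utr_5",
    "utr_3",
}

EFFECTS = {
    "refAllele",
    "unknown",
    "missense",
    "synonymous",
    "nonframeshiftInsertion",
    "nonframeshiftDeletion",
    "nonframeshiftBlockSubstitution",
    "nonsense",
    "stoploss",
    "frameshiftInsertion",
    "frameshiftDeletion",
    "frameshiftBlockSubstitution",
}

#: rule identifiers in canonical chain order (a-g)
RULE_IDS = (
    "coverage",
    "allele_reads",
    "location",
    "vaf",
    "effect",
    "maf",
    "sift_polyphen",
)


@dataclass(frozen=True)
class VariantRecord:
    """One annotated candidate variant from the caller output."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    filtered_coverage: int
    allele_read_count: int
    vaf: float
    location: str | None = None
    effect: str | None = None
    maf: float | None = None
    sift: float | None = None
    polyphen: float | None = None
    clin_sig: str | None = None
    #: triage bucket set by :func:`prioritize` (exonic / splicesite / utr)
    category: str | None = None
    sample_id: str | None = None

    def validate(self) -> None:
        if self.location is not None and self.location not in LOCATIONS:
            raise ValidationError(
                f"{self.key()}: unknown location label {self.location!r} "
                f"(expected one of {sorted(LOCATIONS)})"
            )
        if self.effect is not None and self.effect not in EFFECTS:
            raise ValidationError(
                f"{self.key()}: unknown effect label {self.effect!r} "
                f"(expected one of {sorted(EFFECTS)})"
            )
        if self.filtered_coverage < 0 or self.allele_read_count < 0:
            raise ValidationError(f"{self.key()}: negative read counts")
        if self.allele_read_count > self.filtered_coverage:
            raise ValidationError(
                f"{self.key()}: allele reads ({self.allele_read_count}) exceed "
                f"coverage ({self.filtered_coverage})"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"{self.key()}: VAF {self.vaf} outside [0, 1]")
        if self.filtered_coverage > 0:
            implied = self.allele_read_count / self.filtered_coverage
            if abs(self.vaf - implied) > 0.01:
                raise ValidationError(
                    f"{self.key()}: VAF {self.vaf:.4f} inconsistent with "
                    f"{self.allele_read_count}/{self.filtered_coverage} = {implied:.4f}"
                )
        for name in ("maf", "sift", "polyphen"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.key()}: {name} {v} outside [0, 1]")

    def key(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class FilterConfig:
    """Thresholds of the seven-rule chain, defaults as run clinically.

    Comparisons follow the printed conventions: coverage and allele-read
    bounds and the minimum VAF are closed (>= / <=); the SIFT/PolyPhen
    gates are strict (< 0.05, > 0.85).
    """

    min_coverage: int = 100
    min_allele_reads: int = 50
    max_allele_reads: int = 100_000
    allowed_locations: frozenset[str] = frozenset(
        {"exonic", "intronic", "upstream", "splicesite_5", "splicesite_3"}
    )
    min_vaf: float = 0.05
    # the caller-side effect list plus synonymous: the downstream triage
    # explicitly keeps somatic synonymous variants as cancer-associated,
    # so the chain default must admit them
    allowed_effects: frozenset[str] = frozenset(EFFECTS)
    max_maf: float = 0.5
    sift_cutoff: float = 0.05
    polyphen_cutoff: float = 0.85

    def validate(self) -> None:
        if min(self.min_coverage, self.min_allele_reads, self.min_vaf, self.max_maf) < 0:
            raise ValidationError("filter thresholds must be non-negative")
        if self.min_allele_reads > self.max_allele_reads:
            raise ValidationError(
                f"min_allele_reads ({self.min_allele_reads}) exceeds "
                f"max_allele_reads ({self.max_allele_reads})"
            )
        unknown = (self.allowed_locations - LOCATIONS) | (self.allowed_effects - EFFECTS)
        if unknown:
            raise ValidationError(f"unknown labels in filter config: {sorted(unknown)}")


@dataclass
class FilterTrace:
    """Per-variant rule outcomes and per-rule attrition (first failure)."""

    outcomes: list[dict[str, bool]] = field(default_factory=list)
    attrition: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULE_IDS})
    n_input: int = 0
    n_kept: int = 0

    def attrition_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": self.attrition[r]} for r in RULE_IDS]
        rows.append({"rule": "kept", "removed": self.n_kept})
        return pd.DataFrame(rows)


# -- rule predicates (pure, one record each) --------------------------------

def _rule_coverage(v: VariantRecord, cfg: FilterConfig) -> bool:
    return v.filtered_coverage >= cfg.min_coverage


def _rule_allele_reads(v: VariantRecord, cfg: FilterConfig) -> bool:
    return cfg.min_allele_reads <= v.allele_read_count <= cfg.max_allele_reads


def _rule_location(v: VariantRecord, cfg: FilterConfig) -> bool:
    return v.location in cfg.allowed_locations


def _rule_vaf(v: VariantRecord, cfg: FilterConfig) -> bool:
    return v.vaf >= cfg.min_vaf


def _rule_effect(v: VariantRecord, cfg: FilterConfig) -> bool:
    return v.effect in cfg.allowed_effects


def _rule_maf(v: VariantRecord, cfg: FilterConfig) -> bool:
    # absent from population databases = novel; must not remove somatic candidates
    maf = 0.0 if v.maf is None else v.maf
    return maf <= cfg.max_maf


def _rule_sift_polyphen(v: VariantRecord, cfg: FilterConfig) -> bool:
    # deleteriousness scores are only defined for missense changes; records
    # without any score pass unpenalized
    if v.effect != "missense":
        return True
    if v.sift is None and v.polyphen is None:
        return True
    sift_hit = v.sift is not None and v.sift < cfg.sift_cutoff
    poly_hit = v.polyphen is not None and v.polyphen > cfg.polyphen_cutoff
    return sift_hit or poly_hit


_RULES = {
    "coverage": _rule_coverage,
    "allele_reads": _rule_allele_reads,
    "location": _rule_location,
    "vaf": _rule_vaf,
    "effect": _rule_effect,
    "maf": _rule_maf,
    "sift_polyphen": _rule_sift_polyphen,
}


def apply_filter_chain(
    variants: Sequence[VariantRecord], cfg: FilterConfig | None = None
) -> tuple[list[VariantRecord], FilterTrace]:
    """Apply the seven-rule chain; return kept records and a full trace.

    A record is kept iff it passes every rule (pure conjunction, so rule
    order cannot change the kept set).  The trace records the outcome of
    every rule for every record; attrition counts attribute each removal
    to the first failing rule in a-g order.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    trace = FilterTrace(n_input=len(variants))
    kept: list[VariantRecord] = []
    for v in variants:
        v.validate()
        outcome = {rid: _RULES[rid](v, cfg) for rid in RULE_IDS}
        trace.outcomes.append(outcome)
        if all(outcome.values()):
            kept.append(v)
        else:
            first_fail = next(rid for rid in RULE_IDS if not outcome[rid])
            trace.attrition[first_fail] += 1
    trace.n_kept = len(kept)
    return kept, trace


# -- triage -----------------------------------------------------------------

_CATEGORY_BY_LOCATION = {
    "exonic": "exonic",
    "splicesite_5": "splicesite",
    "splicesite_3": "splicesite",
    "utr_5": "utr",
    "utr_3": "utr",
}


def prioritize(kept: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Remove intronic and upstream records; tag the rest with a category.

    Exonic records (including synonymous changes), splice-site records and
    5'/3' UTR records are retained and tagged ``exonic`` / ``splicesite``
    / ``utr`` respectively.
    """
    out: list[VariantRecord] = []
    for v in kept:
        cat = _CATEGORY_BY_LOCATION.get(v.location or "")
        if cat is not None:
            out.append(dataclasses.replace(v, category=cat))
    return out


def category_counts(prioritized: Sequence[VariantRecord]) -> dict[str, int]:
    counts = {"exonic": 0, "splicesite": 0, "utr": 0}
    for v in prioritized:
        counts[v.category] = counts.get(v.category, 0) + 1
    return counts


# -- clinical-significance partition ----------------------------------------

def classify_clinical(
    variants: Sequence[VariantRecord],
) -> dict[str, list[VariantRecord]]:
    """Partition records by annotated clinical significance.

    Labels mentioning "conflicting" or "benign" go to
    ``benign_or_conflicting`` (checked first, so "conflicting
    interpretations of pathogenicity" is not mistaken for pathogenic);
    labels mentioning "pathogenic" go to ``pathogenic_like``; everything
    else, including missing labels, is ``unclassified``.
    """
    parts: dict[str, list[VariantRecord]] = {
        "pathogenic_like": [],
        "benign_or_conflicting": [],
        "unclassified": [],
    }
    for v in variants:
        label = (v.clin_sig or "").strip().lower()
        if not label:
            parts["unclassified"].append(v)
        elif "conflicting" in label or "benign" in label:
            parts["benign_or_conflicting"].append(v)
        elif "pathogenic" in label:
            parts["pathogenic_like"].append(v)
        else:
            parts["unclassified"].append(v)
    return parts


# -- oncoplot ---------------------------------------------------------------

def oncoplot_matrix(
    samples: Mapping[str, Sequence[VariantRecord]],
) -> pd.DataFrame:
    """Gene x sample mutation-type matrix for oncoplot rendering.

    Each cell holds the record's effect label, ``multi_hit`` when a sample
    carries more than one variant in the gene, and ``none`` otherwise.
    Marginal counts are exposed via :func:`oncoplot_margins`.
    """
    cells: dict[tuple[str, str], list[str]] = {}
    for sample_id, variants in samples.items():
        for v in variants:
            cells.setdefault((v.gene, sample_id), []).append(v.effect or "unknown")
    genes = sorted({g for g, _ in cells})
    sample_ids = list(samples)
    matrix = pd.DataFrame("none", index=genes, columns=sample_ids, dtype=object)
    for (gene, sample_id), effects in cells.items():
        matrix.loc[gene, sample_id] = effects[0] if len(effects) == 1 else "multi_hit"
    return matrix


def oncoplot_margins(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """(per-gene mutated-sample counts, per-sample mutated-gene counts)."""
    mutated = matrix != "none"
    return mutated.sum(axis=1), mutated.sum(axis=0)
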