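"""Synthetic, seed-reproducible glioma samples with known ground truth.

Generates everything the downstream stages consume — annotated variant
tables, SNP allelic-frequency profiles, per-amplicon depths, and dilution
series — from an explicit :class:`TruthModel`, so the whole pipeline is
testable without sequencing data.

Read model: per-amplicon depths are Poisson around the target depth
(optionally scaled by a log-normal amplicon efficiency to emulate the
handful of chronically under-performing amplicons of real panels).  A
clonal heterozygous somatic variant in a tumor of purity f has expected
observed VAF f * v (copy-neutral assumption), and its alternate reads are
binomial at that expectation.  Germline-heterozygous SNPs read AF 0.5
without deletion and 1/(2 - f) (or its mirror, depending on which allele
is lost) under hemizygous arm deletion; homozygous SNPs read near 0 or 1
up to a small base-error rate.  Regenerating with the same seed and truth
is bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .loh import SNPObservation
from .panel import PanelDesign, default_panel
from .variants import VariantRecord


@dataclass(frozen=True)
class SomaticVariantSpec:
    """One ground-truth somatic variant (VAF is in-cancer-cell fraction)."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float = 0.5  # VAF within pure tumor; a clonal het variant is 0.5
    location: str = "exonic"
    effect: str = "missense"
    clin_sig: str | None = None
    sift: float | None = None
    polyphen: float | None = None
    maf: float = 0.0
    label: str | None = None


#: canonical hotspot variants used throughout the examples and tests
IDH1_R132H = SomaticVariantSpec(
    gene="IDH1", chrom="chr2", pos=209_113_112, ref="C", alt="T",
    vaf=0.5, effect="missense", clin_sig="Pathogenic",
    sift=0.0, polyphen=0.998, label="IDH1 p.R132H",
)
TERT_C124T = SomaticVariantSpec(
    gene="TERT-Promoter", chrom="chr5", pos=1_295_228, ref="G", alt="A",
    vaf=0.5, location="upstream", effect="unknown", label="TERT c.-124C>T",
)
TERT_C146T = SomaticVariantSpec(
    gene="TERT-Promoter", chrom="chr5", pos=1_295_250, ref="G", alt="A",
    vaf=0.5, location="upstream", effect="unknown", label="TERT c.-146C>T",
)
PTEN_R335X = SomaticVariantSpec(
    gene="PTEN", chrom="chr10", pos=89_717_672, ref="C", alt="T",
    vaf=0.5, effect="nonsense", clin_sig="Pathogenic", label="PTEN p.R335*",
)
TP53_R282W = SomaticVariantSpec(
    gene="TP53", chrom="chr17", pos=7_577_094, ref="G", alt="A",
    vaf=0.5, effect="missense", clin_sig="Pathogenic",
    sift=0.0, polyphen=1.0, label="TP53 p.R282W",
)


@dataclass
class TruthModel:
    """Ground truth for one synthetic sample."""

    sample_id: str
    purity: float  # tumor fraction f in [0, 1]
    somatic_variants: list[SomaticVariantSpec] = field(default_factory=list)
    del_1p: bool = False
    del_19q: bool = False
    target_depth: int = 1000
    overdispersion: float | None = None  # log-normal sigma for amplicon efficiency

    def validate(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValidationError(f"{self.sample_id}: purity {self.purity} outside [0, 1]")
        if self.target_depth <= 0:
            raise ValidationError(f"{self.sample_id}: target depth must be positive")

    @property
    def codeleted(self) -> bool:
        return self.del_1p and self.del_19q


@dataclass
class SimulatedSample:
    """One generated sample: tables in the dialects the pipeline consumes."""

    truth: TruthModel
    seed: int
    variants: list[VariantRecord]
    snps: list[SNPObservation]
    depths: dict[str, float]  # amplicon_id -> mean depth


def _expected_ref_af(is_het: bool, arm_deleted: bool, purity: float,
                     ref_retained: bool, base_error: float) -> float:
    if not is_het:
        return (1.0 - base_error) if ref_retained else base_error
    if not arm_deleted:
        return 0.5
    af = 1.0 / (2.0 - purity)
    return af if ref_retained else 1.0 - af


def simulate_sample(
    truth: TruthModel,
    panel: PanelDesign | None = None,
    seed: int = 0,
    het_rate: float = 0.4,
    base_error: float = 0.002,
) -> SimulatedSample:
    """Generate one sample's variant, SNP, and depth tables from truth.

    Each panel marker is germline-heterozygous with probability
    ``het_rate``; marker depths are Poisson around the target depth and
    AFs binomial at the mixture expectation.  Somatic variants must target
    genes present in the panel design.
    """
    truth.validate()
    panel = panel or default_panel()
    gene_names = panel.gene_names
    for v in truth.somatic_variants:
        if v.gene not in gene_names:
            raise ValidationError(
                f"{truth.sample_id}: variant gene {v.gene!r} is not a panel target"
            )
    rng = np.random.default_rng(seed)

    # per-amplicon depths
    depths: dict[str, float] = {}
    for a in panel.amplicons:
        lam = truth.target_depth
        if truth.overdispersion:
            lam = lam * rng.lognormal(mean=0.0, sigma=truth.overdispersion)
        depths[a.amplicon_id] = float(rng.poisson(lam))

    # somatic variants
    variants: list[VariantRecord] = []
    for v in truth.somatic_variants:
        depth = int(rng.poisson(truth.target_depth))
        expected = min(1.0, truth.purity * v.vaf)
        alt = int(rng.binomial(depth, expected)) if depth > 0 else 0
        variants.append(
            VariantRecord(
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                gene=v.gene,
                filtered_coverage=depth,
                allele_read_count=alt,
                vaf=alt / depth if depth > 0 else 0.0,
                location=v.location,
                effect=v.effect,
                maf=v.maf,
                sift=v.sift,
                polyphen=v.polyphen,
                clin_sig=v.clin_sig,
                sample_id=truth.sample_id,
            )
        )

    # SNP marker observations
    deleted = {"1p": truth.del_1p, "19q": truth.del_19q}
    snps: list[SNPObservation] = []
    for m in panel.snp_markers:
        is_het = bool(rng.random() < het_rate)
        ref_retained = bool(rng.random() < 0.5)
        p = _expected_ref_af(is_het, deleted[m.arm], truth.purity, ref_retained, base_error)
        depth = int(rng.poisson(truth.target_depth))
        ref_reads = int(rng.binomial(depth, p)) if depth > 0 else 0
        snps.append(
            SNPObservation(
                marker_id=m.marker_id,
                arm=m.arm,
                depth=depth,
                af=ref_reads / depth if depth > 0 else 0.0,
            )
        )
    return SimulatedSample(truth=truth, seed=seed, variants=variants, snps=snps, depths=depths)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSettings:
    """Composition of a synthetic cohort, mirroring the validation cohort:

    34 samples of which 7 carry a full 1p/19q codeletion, 6 of those also
    the IDH1 p.R132H hotspot, 4 carry a single-arm (partial) deletion
    counted as codeletion-negative, and 2 carry a TERT promoter hotspot.
    """

    n_samples: int = 34
    n_idh1: int = 6
    n_codeleted: int = 7
    n_partial_1p: int = 2
    n_partial_19q: int = 2
    n_tert: int = 2
    purity_range: tuple[float, float] = (0.6, 0.85)
    target_depth: int = 1000
    het_rate: float = 0.4
    n_background_variants: int = 0

    def validate(self) -> None:
        if self.n_idh1 > self.n_samples or self.n_codeleted > self.n_samples:
            raise ValidationError("subgroup counts exceed cohort size")
        if self.n_codeleted + self.n_partial_1p + self.n_partial_19q > self.n_samples:
            raise ValidationError("deletion subgroups exceed cohort size")


#: background-noise templates: raw caller chatter the chain must remove
_BACKGROUND_TEMPLATES = (
    {"location": "intronic", "effect": "unknown", "maf": 0.0},
    {"location": "intronic", "effect": "refAllele", "maf": 0.2},
    {"location": "upstream", "effect": "unknown", "maf": 0.1},
    {"location": "exonic", "effect": "synonymous", "maf": 0.3},
    {"location": "exonic", "effect": "missense", "maf": 0.8},  # common poly, rule f
    {"location": "utr_3", "effect": "unknown", "maf": 0.4},
)


def _background_variants(rng: np.random.Generator, n: int, genes: Sequence[str],
                         depth: int) -> list[SomaticVariantSpec]:
    out = []
    for i in range(n):
        t = _BACKGROUND_TEMPLATES[int(rng.integers(len(_BACKGROUND_TEMPLATES)))]
        gene = genes[int(rng.integers(len(genes)))]
        out.append(
            SomaticVariantSpec(
                gene=gene,
                chrom="chr1",
                pos=1_000_000 + i,
                ref="A",
                alt="G",
                vaf=float(rng.uniform(0.3, 0.6)),
                location=t["location"],
                effect=t["effect"],
                maf=t["maf"],
            )
        )
    return out


def generate_cohort_truth(settings: CohortSettings, seed: int) -> list[TruthModel]:
    """Assign subgroup memberships and purities for a synthetic cohort.

    The IDH1-mutant samples are placed among the codeleted ones (as in
    the real cohort, where six of the seven codeleted tumors carried the
    hotspot); single-arm deletions alternate between 1p-only and
    19q-only; TERT hotspots go to codeletion-negative samples.
    """
    settings.validate()
    rng = np.random.default_rng(seed)
    lo, hi = settings.purity_range
    truths: list[TruthModel] = []
    tert_assigned = 0
    for i in range(settings.n_samples):
        sample_id = f"SYN{i + 1:03d}"
        purity = float(rng.uniform(lo, hi))
        del_1p = del_19q = False
        variants: list[SomaticVariantSpec] = []
        if i < settings.n_codeleted:
            del_1p = del_19q = True
        elif i < settings.n_codeleted + settings.n_partial_1p:
            del_1p = True
        elif i < settings.n_codeleted + settings.n_partial_1p + settings.n_partial_19q:
            del_19q = True
        elif tert_assigned < settings.n_tert:
            variants.append(TERT_C124T if tert_assigned % 2 == 0 else TERT_C146T)
            tert_assigned += 1
        if i < settings.n_idh1:
            variants.append(IDH1_R132H)
        truths.append(
            TruthModel(
                sample_id=sample_id,
                purity=purity,
                somatic_variants=variants,
                del_1p=del_1p,
                del_19q=del_19q,
                target_depth=settings.target_depth,
            )
        )
    return truths


def simulate_cohort(
    settings: CohortSettings,
    panel: PanelDesign | None = None,
    seed: int = 0,
) -> tuple[list[SimulatedSample], pd.DataFrame]:
    """Generate a full cohort plus its truth table.

    The truth table mirrors the clinical reference layout: sample id,
    IDH1/2 status, 1p/19q status, TERT status.
    """
    settings.validate()
    panel = panel or default_panel()
    truths = generate_cohort_truth(settings, seed)
    rng = np.random.default_rng(seed + 1)
    samples = []
    gene_names = sorted(panel.gene_names)
    for k, truth in enumerate(truths):
        if settings.n_background_variants:
            truth = replace(
                truth,
                somatic_variants=list(truth.somatic_variants)
                + _background_variants(
                    rng, settings.n_background_variants, gene_names, settings.target_depth
                ),
            )
        samples.append(
            simulate_sample(truth, panel, seed=seed + 1000 + k, het_rate=settings.het_rate)
        )
    return samples, truth_table([s.truth for s in samples])


def truth_table(truths: Sequence[TruthModel]) -> pd.DataFrame:
    """Truth TSV layout: sample_id, idh1_2, loh_1p19q, tert."""
    rows = []
    for t in truths:
        labels = {v.label for v in t.somatic_variants if v.label}
        idh = "p.R132H" if "IDH1 p.R132H" in labels else "wt"
        if t.codeleted:
            loh = "LOH"
        elif t.del_1p:
            loh = "1p"
        elif t.del_19q:
            loh = "19q"
        else:
            loh = "wt"
        tert = next((l.split()[-1] for l in labels if l and l.startswith("TERT")), "wt")
        rows.append({"sample_id": t.sample_id, "idh1_2": idh, "loh_1p19q": loh, "tert": tert})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort from a clinical truth table
# ---------------------------------------------------------------------------

def load_cohort_truth(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged (or a user-supplied) cohort truth table."""
    if path is None:
        path = Path(__file__).parent / "data" / "cohort_truth.tsv"
    return pd.read_csv(path, sep="\t", dtype=str)


def truth_models_from_table(
    table: pd.DataFrame,
    purity: float = 0.7,
    purity_overrides: Mapping[str, float] | None = None,
    target_depth: int = 1000,
) -> list[TruthModel]:
    """Build per-sample truth models from a clinical-style truth table.

    Maps the reference-method columns onto simulator truth: an IDH1
    ``p.R132H`` entry adds the hotspot variant, ``LOH`` marks both arms
    deleted, ``1p``/``19q`` a single arm, and a TERT promoter entry adds
    the corresponding hotspot.  ``purity_overrides`` lets individual
    samples be generated at a different tumor fraction.
    """
    overrides = dict(purity_overrides or {})
    models: list[TruthModel] = []
    for _, row in table.iterrows():
        sample_id = str(row["sample_id"])
        variants: list[SomaticVariantSpec] = []
        if str(row.get("idh1_2", "wt")).strip() == "p.R132H":
            variants.append(IDH1_R132H)
        tert = str(row.get("tert", "wt")).strip()
        if "124" in tert:
            variants.append(TERT_C124T)
        elif "146" in tert:
            variants.append(TERT_C146T)
        loh = str(row.get("loh_1p19q", "wt")).strip()
        models.append(
            TruthModel(
                sample_id=sample_id,
                purity=float(overrides.get(sample_id, purity)),
                somatic_variants=variants,
                del_1p=loh in {"LOH", "1p"},
                del_19q=loh in {"LOH", "19q"},
                target_depth=target_depth,
            )
        )
    return models


# ---------------------------------------------------------------------------
# dilution series inputs
# ---------------------------------------------------------------------------

def make_dilution_inputs(
    mutant: TruthModel,
    fractions: Sequence[float],
    panel: PanelDesign | None = None,
    seed: int = 0,
) -> list[SimulatedSample]:
    """One sample per mutant-DNA fraction, tumor fraction scaled accordingly.

    Mixing mutant DNA at fraction f scales the effective tumor fraction to
    ``f * purity``, which scales both somatic VAFs and the arm-deletion
    allelic shift consistently; fraction 0 is a pure wild-type sample.
    """
    if not mutant.somatic_variants:
        raise ValidationError("dilution input requires at least one somatic variant")
    panel = panel or default_panel()
    out = []
    for i, f in enumerate(fractions):
        if not 0.0 <= f <= 1.0:
            raise ValidationError(f"dilution fraction {f} outside [0, 1]")
        diluted = replace(
            mutant,
            sample_id=f"{mutant.sample_id}_dil{f:g}",
            purity=mutant.purity * f,
        )
        out.append(simulate_sample(diluted, panel, seed=seed + i))
    return out
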