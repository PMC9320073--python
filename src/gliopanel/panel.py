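"""Targeted-panel model: amplicons, gene targets, SNP markers, coverage QC.

The panel targets the coding regions of 13 glioma genes, a short stretch of
the TERT promoter, and a set of SNP markers spread along chromosome arms 1p
and 19q used for allelic-imbalance (LOH) calling.  This module represents
that design, loads it from a BED file plus a tab-separated manifest, and
computes amplicon-level coverage statistics against depth exports.

Coordinate conventions: BED records are 0-based half-open; marker and
variant positions surfaced to users are 1-based.  Conversions happen only
at the I/O boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

#: chromosome each arm's markers must live on
ARM_CHROM = {"1p": "chr1", "19q": "chr19"}

#: manifest rows whose Target matches this are SNP marker groups, not genes
_SNP_GROUP_RE = re.compile(r"^(\d+)\s+SNPs$", re.IGNORECASE)

MANIFEST_COLUMNS = [
    "Target",
    "Chromosome",
    "Number of Amplicons",
    "Covered Bases",
    "% Overall Coverage",
    "Number of Exons",
]


@dataclass(frozen=True)
class SNPMarker:
    """One allelic-imbalance marker (a common SNP) on arm 1p or 19q."""

    marker_id: str
    arm: str  # "1p" or "19q"
    chrom: str
    pos: int  # 1-based

    def validate(self) -> None:
        if self.arm not in ARM_CHROM:
            raise ValidationError(f"marker {self.marker_id}: unknown arm {self.arm!r}")
        if self.chrom != ARM_CHROM[self.arm]:
            raise ValidationError(
                f"marker {self.marker_id}: arm {self.arm} is inconsistent with "
                f"chromosome {self.chrom} (expected {ARM_CHROM[self.arm]})"
            )
        if self.pos < 1:
            raise ValidationError(f"marker {self.marker_id}: position must be 1-based positive")


@dataclass(frozen=True)
class GeneTarget:
    """One manifest row for a gene (or the TERT promoter region)."""

    name: str
    chrom: str
    n_amplicons: int
    covered_bases: int
    pct_coverage: float
    n_exons: int | None  # None for non-exonic targets (promoter)


@dataclass(frozen=True)
class AmpliconRecord:
    """One PCR amplicon of the panel (BED convention: 0-based half-open)."""

    amplicon_id: str
    chrom: str
    start: int
    end: int
    pool: int  # primer pool, 1 or 2
    target: str  # gene symbol or SNP marker id
    mean_depth: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self, length_band: tuple[int, int] = (50, 500)) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"amplicon {self.amplicon_id}: end ({self.end}) must exceed start ({self.start})"
            )
        lo, hi = length_band
        if not lo <= self.length <= hi:
            raise ValidationError(
                f"amplicon {self.amplicon_id}: length {self.length} bp outside "
                f"sanity band [{lo}, {hi}]"
            )
        if self.pool not in (1, 2):
            raise ValidationError(f"amplicon {self.amplicon_id}: pool must be 1 or 2, got {self.pool}")
        if self.mean_depth < 0:
            raise ValidationError(f"amplicon {self.amplicon_id}: negative mean depth")


@dataclass
class PanelDesign:
    """The full panel: amplicons plus the manifest they must agree with."""

    amplicons: list[AmpliconRecord]
    gene_targets: list[GeneTarget]
    snp_markers: list[SNPMarker]
    #: expected amplicon count per SNP arm group, straight from the manifest
    snp_group_expected: dict[str, int] = field(default_factory=dict)
    amplicon_length_band: tuple[int, int] = (50, 500)

    # -- lookups ---------------------------------------------------------
    @property
    def gene_names(self) -> set[str]:
        return {g.name for g in self.gene_targets}

    @property
    def marker_ids(self) -> set[str]:
        return {m.marker_id for m in self.snp_markers}

    def markers_by_arm(self) -> dict[str, list[SNPMarker]]:
        out: dict[str, list[SNPMarker]] = {"1p": [], "19q": []}
        for m in self.snp_markers:
            out[m.arm].append(m)
        return out

    def amplicons_for_target(self, target: str) -> list[AmpliconRecord]:
        return [a for a in self.amplicons if a.target == target]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check every structural invariant; raise ValidationError on the first hard failure.

        Known manifest-internal discrepancies for the SNP marker groups
        (amplicon counts that do not equal marker counts) are logged as
        warnings rather than raised, since the marker-to-amplicon mapping
        is not part of the published design.
        """
        for m in self.snp_markers:
            m.validate()
        genes = self.gene_names
        markers = self.marker_ids
        for a in self.amplicons:
            a.validate(self.amplicon_length_band)
            if a.target not in genes and a.target not in markers:
                raise ValidationError(
                    f"amplicon {a.amplicon_id} targets unknown gene/marker {a.target!r}"
                )
            if a.target in markers:
                marker = next(m for m in self.snp_markers if m.marker_id == a.target)
                if a.chrom != marker.chrom:
                    raise ValidationError(
                        f"amplicon {a.amplicon_id} on {a.chrom} is labelled as "
                        f"{marker.arm} marker {marker.marker_id} (expected {marker.chrom})"
                    )
        # per-gene amplicon counts must equal the manifest
        for g in self.gene_targets:
            n = len(self.amplicons_for_target(g.name))
            if n != g.n_amplicons:
                raise ValidationError(
                    f"gene {g.name}: {n} amplicons in BED but manifest expects {g.n_amplicons}"
                )
        # SNP group counts: warn only (fixture maps one amplicon per marker)
        by_arm = self.markers_by_arm()
        for arm, expected in self.snp_group_expected.items():
            n_ampl = sum(1 for a in self.amplicons if a.target in {m.marker_id for m in by_arm[arm]})
            if n_ampl != expected:
                log.info(
                    "SNP group %s: %d amplicons present vs %d in manifest "
                    "(marker/amplicon mapping is unpublished; counts kept as data)",
                    arm,
                    n_ampl,
                    expected,
                )

    def __post_init__(self) -> None:
        if not self.amplicons:
            log.warning("panel design has zero amplicons")


@dataclass
class CoverageReport:
    """Amplicon-level coverage QC for one sample (or a pooled run)."""

    n_amplicons: int
    mean_depth: float
    pct_at: dict[int, float]  # cutoff (reads) -> % amplicons at or above it
    low_coverage_amplicons: list[str]  # below the lowest cutoff

    @property
    def pct_ge_100x(self) -> float | None:
        return self.pct_at.get(100)

    @property
    def pct_ge_500x(self) -> float | None:
        return self.pct_at.get(500)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Read the tab-separated panel manifest (Target, Chromosome, ...)."""
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"manifest {manifest_path}: missing columns {missing}")
    return df


def read_markers(markers_path: str | Path) -> list[SNPMarker]:
    """Read the SNP-marker table (marker_id, arm, chrom, pos)."""
    df = pd.read_csv(markers_path, sep="\t", comment="#", dtype={"marker_id": str, "arm": str, "chrom": str})
    markers = [
        SNPMarker(row.marker_id, row.arm, row.chrom, int(row.pos))
        for row in df.itertuples(index=False)
    ]
    for m in markers:
        m.validate()
    return markers


def read_bed(bed_path: str | Path) -> list[AmpliconRecord]:
    """Parse an amplicon BED (chrom, start, end, amplicon_id, pool, target)."""
    records: list[AmpliconRecord] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{bed_path}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom, start, end, ampl_id, pool, target = fields[:6]
            try:
                records.append(
                    AmpliconRecord(ampl_id, chrom, int(start), int(end), int(pool), target)
                )
            except ValueError as exc:
                raise ParseError(f"{bed_path}:{lineno}: {exc}") from exc
    if not records:
        log.warning("BED %s contained no amplicon records", bed_path)
    return records


def _parse_manifest(df: pd.DataFrame) -> tuple[list[GeneTarget], dict[str, int]]:
    genes: list[GeneTarget] = []
    snp_expected: dict[str, int] = {}
    chrom_to_arm = {v: k for k, v in ARM_CHROM.items()}
    for _, row in df.iterrows():
        target = str(row["Target"]).strip().strip("*")
        chrom = str(row["Chromosome"]).strip()
        n_ampl = int(row["Number of Amplicons"])
        m = _SNP_GROUP_RE.match(target)
        if m:
            arm = chrom_to_arm.get(chrom)
            if arm is None:
                raise ValidationError(f"SNP group {target!r} on unexpected chromosome {chrom}")
            snp_expected[arm] = n_ampl
        else:
            exons_raw = str(row["Number of Exons"]).strip()
            n_exons = None if exons_raw.lower() in {"n/a", "na", "nan", ""} else int(exons_raw)
            genes.append(
                GeneTarget(
                    name=target,
                    chrom=chrom,
                    n_amplicons=n_ampl,
                    covered_bases=int(row["Covered Bases"]),
                    pct_coverage=float(row["% Overall Coverage"]),
                    n_exons=n_exons,
                )
            )
    return genes, snp_expected


def load_panel(
    bed_path: str | Path,
    manifest_path: str | Path,
    markers_path: str | Path,
) -> PanelDesign:
    """Load and validate the panel from BED + manifest + marker table.

    Count mismatches between the BED and the manifest's per-gene amplicon
    counts raise :class:`ValidationError`; SNP-group mismatches are logged
    (the published marker/amplicon mapping is ambiguous).
    """
    genes, snp_expected = _parse_manifest(read_manifest(manifest_path))
    markers = read_markers(markers_path)
    amplicons = read_bed(bed_path)
    design = PanelDesign(
        amplicons=amplicons,
        gene_targets=genes,
        snp_markers=markers,
        snp_group_expected=snp_expected,
    )
    design.validate()
    return design


# ---------------------------------------------------------------------------
# packaged default design
# ---------------------------------------------------------------------------

#: Approximate hg19 locus anchors used to synthesize amplicon coordinates.
#: Only counts and target labels matter to the downstream analytics; the
#: per-amplicon coordinates of the real design are not published, so the
#: packaged BED is synthetic.
_GENE_LOCI = {
    "ACVR1": ("chr2", 158_592_958),
    "ATRX": ("chrX", 76_760_356),
    "BRAF": ("chr7", 140_419_127),
    "CDKN2A": ("chr9", 21_967_751),
    "EGFR": ("chr7", 55_086_714),
    "H3F3A": ("chr1", 226_249_463),
    "HIST1H3B": ("chr6", 26_031_817),
    "HIST1H3C": ("chr6", 26_045_639),
    "IDH1": ("chr2", 209_100_951),
    "IDH2": ("chr15", 90_627_212),
    "TP53": ("chr17", 7_571_720),
    "PDGFRA": ("chr4", 55_095_264),
    "PTEN": ("chr10", 89_623_195),
    "TERT-Promoter": ("chr5", 1_295_150),
}

_AMPLICON_LEN = 150
_AMPLICON_STEP = 160


def synthesize_bed_records(
    genes: Sequence[GeneTarget], markers: Sequence[SNPMarker]
) -> list[AmpliconRecord]:
    """Deterministically tile synthetic amplicons for a manifest.

    Gene amplicons are tiled non-overlapping from a fixed locus anchor;
    SNP amplicons are one per marker, centred on the marker position.
    """
    records: list[AmpliconRecord] = []
    pool = 1
    for g in genes:
        chrom, anchor = _GENE_LOCI.get(g.name, (g.chrom, 1_000_000))
        for i in range(g.n_amplicons):
            start = anchor + i * _AMPLICON_STEP
            records.append(
                AmpliconRecord(
                    amplicon_id=f"AMPL_{g.name}_{i + 1:03d}",
                    chrom=chrom,
                    start=start,
                    end=start + _AMPLICON_LEN,
                    pool=pool,
                    target=g.name,
                )
            )
            pool = 3 - pool
    for m in markers:
        start = max(0, m.pos - 1 - (_AMPLICON_LEN // 2))
        records.append(
            AmpliconRecord(
                amplicon_id=f"AMPL_{m.marker_id}",
                chrom=m.chrom,
                start=start,
                end=start + _AMPLICON_LEN,
                pool=pool,
                target=m.marker_id,
            )
        )
        pool = 3 - pool
    return records


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def default_panel() -> PanelDesign:
    """The packaged panel design.

    The manifest reproduces the published target table verbatim; the SNP
    markers and amplicon coordinates are synthetic stand-ins (one amplicon
    per marker), since neither is published at that resolution.
    """
    genes, snp_expected = _parse_manifest(read_manifest(_data_path("panel_manifest.tsv")))
    markers = read_markers(_data_path("snp_markers_synthetic.tsv"))
    amplicons = synthesize_bed_records(genes, markers)
    design = PanelDesign(
        amplicons=amplicons,
        gene_targets=genes,
        snp_markers=markers,
        snp_group_expected=snp_expected,
    )
    design.validate()
    return design


def write_panel_bed(design: PanelDesign, path: str | Path) -> None:
    """Write the design's amplicons as a 6-column BED."""
    with open(path, "w") as fh:
        for a in design.amplicons:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.amplicon_id}\t{a.pool}\t{a.target}\n")


# ---------------------------------------------------------------------------
# coverage QC
# ---------------------------------------------------------------------------

def coverage_qc(
    panel: PanelDesign,
    depths: Mapping[str, float],
    cutoffs: Iterable[int] = (100, 500),
) -> CoverageReport:
    """Compute per-cutoff coverage percentages over all panel amplicons.

    Amplicons missing from ``depths`` count as zero coverage (with a
    warning); negative depths are rejected.  ``low_coverage_amplicons``
    lists amplicons below the lowest cutoff.
    """
    cutoffs = sorted(set(int(c) for c in cutoffs))
    if not cutoffs:
        raise ValidationError("coverage_qc requires at least one cutoff")
    n = len(panel.amplicons)
    if n == 0:
        return CoverageReport(0, 0.0, {c: 0.0 for c in cutoffs}, [])
    resolved: dict[str, float] = {}
    for a in panel.amplicons:
        d = depths.get(a.amplicon_id)
        if d is None:
            log.warning("amplicon %s has no depth entry; treating as 0", a.amplicon_id)
            d = 0.0
        if d < 0:
            raise ValidationError(f"amplicon {a.amplicon_id}: negative depth {d}")
        resolved[a.amplicon_id] = float(d)
    values = list(resolved.values())
    pct_at = {c: 100.0 * sum(1 for v in values if v >= c) / n for c in cutoffs}
    low = [aid for aid, v in resolved.items() if v < cutoffs[0]]
    return CoverageReport(
        n_amplicons=n,
        mean_depth=sum(values) / n,
        pct_at=pct_at,
        low_coverage_amplicons=low,
    )


def count_snp_markers(panel: PanelDesign) -> dict[str, int]:
    """Per-arm SNP marker counts plus a ``total`` entry."""
    by_arm = panel.markers_by_arm()
    counts = {arm: len(ms) for arm, ms in by_arm.items()}
    counts["total"] = sum(len(ms) for ms in by_arm.values())
    return counts
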