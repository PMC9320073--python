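"""File I/O: VCF + annotation sidecar, SNP/depth/truth TSV dialects.

The variant interchange format is a per-sample VCF (depth, alt reads and
allele frequency read from FORMAT or INFO under the Torrent-style DP/AO/AF
tags) plus a tab-separated annotation sidecar keyed by (chrom, pos, ref,
alt) carrying the fields the filter chain consumes.  A combined one-file
TSV dialect is also accepted.  All TSVs are plain pandas round-trips.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .errors import ParseError, ValidationError
from .loh import SNPObservation
from .variants import VariantRecord

log = logging.getLogger(__name__)

SIDECAR_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "location", "effect",
    "maf", "sift", "polyphen", "clin_sig",
]

VARIANT_TSV_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene",
    "filtered_coverage", "allele_read_count", "vaf",
    "location", "effect", "maf", "sift", "polyphen", "clin_sig", "category",
]

SNP_TSV_COLUMNS = ["sample_id", "marker_id", "arm", "chrom", "pos", "depth", "af"]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return str(value)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _scalar(value, index: int):
    """Pick the per-allele entry out of a Number=A tuple, else the scalar."""
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else value[0]
    return value


def read_vcf_with_sidecar(
    vcf_path: str | Path,
    sidecar_path: str | Path | None = None,
    sample_id: str | None = None,
) -> list[VariantRecord]:
    """Read a one-sample VCF, splitting multi-allelic lines, and annotate.

    DP/AO/AF are taken from the single sample's FORMAT fields when
    present, else from INFO; a missing AF is computed as AO/DP.  Sidecar
    rows are joined on (chrom, pos, ref, alt); records without a sidecar
    row are kept with missing annotations and a warning.
    """
    annotations: dict[tuple[str, int, str, str], dict] = {}
    if sidecar_path is not None:
        df = pd.read_csv(sidecar_path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        for _, row in df.iterrows():
            key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
            annotations[key] = row.to_dict()

    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        if len(samples) > 1:
            raise ValidationError(
                f"{vcf_path}: multi-sample VCFs are not supported "
                f"(found samples {samples}); export one VCF per barcode"
            )
        inferred_sample = sample_id or (samples[0] if samples else Path(vcf_path).stem)
        for rec in vcf:
            if not rec.alts:
                continue
            source = rec.samples[samples[0]] if samples else rec.info
            for i, alt in enumerate(rec.alts):
                def _get(tag):
                    if samples and tag in source:
                        return source[tag]
                    return rec.info.get(tag)

                dp = _scalar(_get("DP"), i)
                ao = _scalar(_get("AO"), i)
                af = _scalar(_get("AF"), i)
                if dp is None:
                    raise ParseError(f"{vcf_path}: record {rec.chrom}:{rec.pos} lacks DP")
                dp = int(dp)
                ao = int(ao) if ao is not None else 0
                vaf = float(af) if af is not None else (ao / dp if dp > 0 else 0.0)
                ann = annotations.get((rec.chrom, rec.pos, rec.ref, alt))
                if sidecar_path is not None and ann is None:
                    log.warning(
                        "no sidecar annotation for %s:%d %s>%s; keeping with defaults",
                        rec.chrom, rec.pos, rec.ref, alt,
                    )
                    ann = {}
                ann = ann or {}
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=_opt_str(ann.get("gene")) or "unknown",
                        filtered_coverage=dp,
                        allele_read_count=ao,
                        vaf=vaf,
                        location=_opt_str(ann.get("location")),
                        effect=_opt_str(ann.get("effect")),
                        maf=_opt_float(ann.get("maf")),
                        sift=_opt_float(ann.get("sift")),
                        polyphen=_opt_float(ann.get("polyphen")),
                        clin_sig=_opt_str(ann.get("clin_sig")),
                        sample_id=inferred_sample,
                    )
                )
    return records


def write_vcf(records: Sequence[VariantRecord], path: str | Path,
              sample_id: str | None = None) -> None:
    """Write records as a minimal VCF 4.2 with INFO DP/AO/AF tags."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered read depth">')
    header.add_line('##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele reads">')
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">')
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.contigs.add(chrom)
    if sample_id is None and records and records[0].sample_id:
        sample_id = records[0].sample_id
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
            )
            rec.info["DP"] = r.filtered_coverage
            rec.info["AO"] = (r.allele_read_count,)
            rec.info["AF"] = (r.vaf,)
            out.write(rec)


def write_sidecar(records: Sequence[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "gene": r.gene, "location": r.location, "effect": r.effect,
            "maf": r.maf, "sift": r.sift, "polyphen": r.polyphen,
            "clin_sig": r.clin_sig,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# combined variant TSV dialect
# ---------------------------------------------------------------------------

def variants_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = [
        {col: getattr(r, col) for col in VARIANT_TSV_COLUMNS}
        for r in records
    ]
    return pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS)


def write_variants_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    variants_to_frame(records).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    records = []
    for _, row in df.iterrows():
        records.append(
            VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=str(row["gene"]),
                filtered_coverage=int(row["filtered_coverage"]),
                allele_read_count=int(row["allele_read_count"]),
                vaf=float(row["vaf"]),
                location=_opt_str(row.get("location")),
                effect=_opt_str(row.get("effect")),
                maf=_opt_float(row.get("maf")),
                sift=_opt_float(row.get("sift")),
                polyphen=_opt_float(row.get("polyphen")),
                clin_sig=_opt_str(row.get("clin_sig")),
                category=_opt_str(row.get("category")),
                sample_id=_opt_str(row.get("sample_id")),
            )
        )
    return records


# ---------------------------------------------------------------------------
# SNP / depth / truth tables
# ---------------------------------------------------------------------------

def write_snp_tsv(
    observations: Mapping[str, Sequence[SNPObservation]] | Sequence[SNPObservation],
    path: str | Path,
    marker_positions: Mapping[str, tuple[str, int]] | None = None,
) -> None:
    """Write SNP observations; accepts one sample's list or a sample->list map."""
    if not isinstance(observations, Mapping):
        observations = {"sample": list(observations)}
    rows = []
    for sample_id, obs in observations.items():
        for o in obs:
            chrom, pos = (marker_positions or {}).get(o.marker_id, ("", 0))
            rows.append(
                {
                    "sample_id": sample_id, "marker_id": o.marker_id, "arm": o.arm,
                    "chrom": chrom, "pos": pos, "depth": o.depth, "af": o.af,
                }
            )
    # %.17g keeps the AF round-trip bit-exact
    pd.DataFrame(rows, columns=SNP_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_snp_tsv(path: str | Path) -> dict[str, list[SNPObservation]]:
    """Read a SNP table TSV into per-sample observation lists."""
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "marker_id": str, "arm": str},
        float_precision="round_trip",
    )
    out: dict[str, list[SNPObservation]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample_id"]), []).append(
            SNPObservation(
                marker_id=str(row["marker_id"]),
                arm=str(row["arm"]),
                depth=int(row["depth"]),
                af=float(row["af"]),
            )
        )
    return out


def write_depth_tsv(depths: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(depths.items()), columns=["amplicon_id", "mean_depth"]
    ).to_csv(path, sep="\t", index=False)


def read_depth_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"amplicon_id": str})
    return {str(r["amplicon_id"]): float(r["mean_depth"]) for _, r in df.iterrows()}


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"truth table {path} lacks a sample_id column")
    return df
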