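"""Diagnostic performance metrics and in-silico limit-of-detection assays.

Accuracy, sensitivity, and specificity are computed exactly on rationals
from TP/TN/FP/FN tallies against an orthogonal reference method, and
displayed as integer percentages by truncation toward zero (so 6/7 prints
as 85 and 33/34 as 97); the exact values stay available.

The limit of detection (LOD) for point mutations is estimated by an
in-silico dilution series: a mutant sample of known VAF is mixed with
wild-type DNA at decreasing fractions, alternate-allele reads are drawn
binomially at the expected VAF over a fixed depth, and a dilution is
"detected" when a replicate clears both the minimum alt-read count and
the minimum VAF.  The copy-number (arm-deletion) detection limit follows
from the allelic-frequency mixture curve AF(f) = 1/(2 - f) of a retained
allele at a germline-heterozygous SNP under hemizygous deletion at tumor
fraction f: deletion is visible once AF(f) leaves the heterozygous band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .loh import LohConfig


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies against a reference genotype."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Exact rational metrics plus the truncated integer-percent display."""

    accuracy_exact: Fraction
    sensitivity_exact: Fraction | None  # None when TP + FN == 0
    specificity_exact: Fraction | None  # None when TN + FP == 0

    @staticmethod
    def _display(value: Fraction | None) -> int | None:
        # truncation toward zero: 6/7 -> 85, 33/34 -> 97
        return None if value is None else int(100 * value)

    @property
    def accuracy(self) -> int:
        return self._display(self.accuracy_exact)

    @property
    def sensitivity(self) -> int | None:
        return self._display(self.sensitivity_exact)

    @property
    def specificity(self) -> int | None:
        return self._display(self.specificity_exact)

    def as_dict(self) -> dict[str, int | None]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def metrics(c: ConfusionCounts) -> DiagnosticMetrics:
    """accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

    Metrics with a zero denominator are reported as undefined (``None``),
    never silently as zero; an all-zero tally is an error.
    """
    if c.total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = Fraction(c.tp + c.tn, c.total)
    sensitivity = Fraction(c.tp, c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = Fraction(c.tn, c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return DiagnosticMetrics(accuracy, sensitivity, specificity)


# ---------------------------------------------------------------------------
# VAF limit of detection
# ---------------------------------------------------------------------------

@dataclass
class DilutionConfig:
    """Settings of the in-silico dilution series.

    ``dilution_fractions`` are mutant-DNA fractions; the expected VAF at
    fraction f is ``f * base_vaf``.  Detection thresholds are separate
    from the clinical reporting chain: the floor observed in validation
    is a 2% VAF, with a configurable minimum alternate-read count.
    ``overdispersion`` switches the read model from binomial to
    beta-binomial with that concentration parameter (reads of real
    amplicon chemistry are noisier than binomial).
    """

    base_vaf: float = 0.5
    dilution_fractions: Sequence[float] = (1.0, 0.5, 0.2, 0.1, 0.08, 0.06, 0.04, 0.02)
    depth: int = 2000
    n_replicates: int = 500
    seed: int | None = None
    lod_min_vaf: float = 0.02
    lod_min_alt_reads: int = 50
    noise: bool = True
    overdispersion: float | None = None
    detection_threshold: float = 0.95

    def validate(self) -> None:
        if not 0 < self.base_vaf <= 1:
            raise ValidationError(f"base_vaf {self.base_vaf} outside (0, 1]")
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        for f in self.dilution_fractions:
            if not 0 <= f <= 1:
                raise ValidationError(f"dilution fraction {f} outside [0, 1]")
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")


@dataclass
class LodResult:
    """Per-dilution detection table and the resulting LOD."""

    table: pd.DataFrame  # columns: fraction, expected_vaf, mean_observed_vaf, detection_rate
    lod: float | None  # lowest expected VAF with detection rate >= threshold
    analytic_lod: float  # max(lod_min_vaf, lod_min_alt_reads / depth)


def analytic_lod(cfg: DilutionConfig) -> float:
    """The no-noise detection floor: max(min VAF, min alt reads / depth)."""
    return max(cfg.lod_min_vaf, cfg.lod_min_alt_reads / cfg.depth)


def simulate_dilution_series(
    cfg: DilutionConfig, rng: np.random.Generator | None = None
) -> LodResult:
    """Run the dilution series and estimate the LOD.

    With ``noise=True`` alternate reads are drawn per replicate
    (binomially, or beta-binomially under overdispersion) and a replicate
    detects when it clears both thresholds; the LOD is the lowest
    expected VAF whose detection rate reaches ``detection_threshold``.
    With ``noise=False`` the series is evaluated at its expectation and
    the LOD equals the analytic floor.
    """
    cfg.validate()
    if cfg.noise and rng is None:
        if cfg.seed is None:
            raise ValidationError("stochastic dilution series requires a seed or rng")
        rng = np.random.default_rng(cfg.seed)
    fractions = sorted(cfg.dilution_fractions, reverse=True)
    rows = []
    floor = analytic_lod(cfg)
    for f in fractions:
        expected = f * cfg.base_vaf
        if not cfg.noise:
            detected = expected >= floor
            rows.append(
                {
                    "fraction": f,
                    "expected_vaf": expected,
                    "mean_observed_vaf": expected,
                    "detection_rate": 1.0 if detected else 0.0,
                }
            )
            continue
        if cfg.overdispersion is not None and expected > 0:
            # beta-binomial: mean preserved, concentration = overdispersion
            a = expected * cfg.overdispersion
            b = (1 - expected) * cfg.overdispersion
            p = rng.beta(a, b, size=cfg.n_replicates)
            alt = rng.binomial(cfg.depth, p)
        else:
            alt = rng.binomial(cfg.depth, expected, size=cfg.n_replicates)
        obs_vaf = alt / cfg.depth
        detected = (alt >= cfg.lod_min_alt_reads) & (obs_vaf >= cfg.lod_min_vaf)
        rows.append(
            {
                "fraction": f,
                "expected_vaf": expected,
                "mean_observed_vaf": float(obs_vaf.mean()),
                "detection_rate": float(detected.mean()),
            }
        )
    table = pd.DataFrame(rows)
    hits = table[table["detection_rate"] >= cfg.detection_threshold]
    lod = float(hits["expected_vaf"].min()) if len(hits) else None
    return LodResult(table=table, lod=lod, analytic_lod=floor)


def expected_detection_rate(expected_vaf: float, cfg: DilutionConfig) -> float:
    """Closed-form binomial detection probability at one expected VAF."""
    k = max(cfg.lod_min_alt_reads, math.ceil(cfg.lod_min_vaf * cfg.depth))
    return float(stats.binom.sf(k - 1, cfg.depth, expected_vaf))


# ---------------------------------------------------------------------------
# CNA (arm deletion) detection limit
# ---------------------------------------------------------------------------

def deletion_af(f: float) -> float:
    """AF of the retained allele at a het SNP under hemizygous deletion.

    Tumor fraction f mixes one-copy tumor DNA with two-copy normal DNA:
    the retained allele contributes (1 - f) + f = 1 dose out of a total
    site dose of 2 - f, hence AF(f) = 1 / (2 - f); the lost allele reads
    1 - 1/(2 - f).
    """
    if not 0 <= f <= 1:
        raise ValidationError(f"tumor fraction {f} outside [0, 1]")
    return 1.0 / (2.0 - f)


@dataclass
class CnaBoundary:
    """Detectability window of an arm deletion over tumor fraction f."""

    f_lower: float  # AF(f) leaves the heterozygous band above this f
    f_upper: float  # AF(f) enters the homozygous band at/above this f
    evaluations: pd.DataFrame | None = None

    def detected(self, f: float) -> bool:
        """True when AF(f) falls in the allelic-imbalance band."""
        return self.f_lower < f < self.f_upper


def cna_detection_boundary(
    cfg: "LohConfig | None" = None,
    fractions: Iterable[float] | None = None,
) -> CnaBoundary:
    """Analytic detection window of a hemizygous arm deletion.

    Inverts AF(f) = 1/(2 - f) at the band edges: the deletion becomes
    visible (imbalance) once AF exceeds the upper heterozygous edge,
    at f* = 2 - 1/het_high, and saturates into the homozygous band at
    f = 2 - 1/hom_high, where markers stop being informative.  With the
    default bands f* = 2 - 1/0.6 = 1/3.
    """
    from .loh import LohConfig  # local import to avoid a cycle

    cfg = cfg or LohConfig()
    cfg.validate()
    if cfg.het_high >= 1.0 or (cfg.het_low <= 0.0 and cfg.het_high >= 1.0):
        raise ValidationError("undetectable configuration: heterozygous band spans [0, 1]")
    f_lower = 2.0 - 1.0 / cfg.het_high
    f_upper = 2.0 - 1.0 / cfg.hom_high
    boundary = CnaBoundary(f_lower=f_lower, f_upper=f_upper)
    if fractions is not None:
        rows = [
            {
                "fraction": f,
                "af": deletion_af(f),
                "detected": boundary.detected(f),
            }
            for f in fractions
        ]
        boundary.evaluations = pd.DataFrame(rows)
    return boundary


# ---------------------------------------------------------------------------
# depth summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthSummary:
    n: int
    mean: float
    sd: float
    cv: float


def depth_summary(depths: Sequence[float]) -> DepthSummary:
    """Mean, sample standard deviation, and coefficient of variation."""
    arr = np.asarray(list(depths), dtype=float)
    if arr.size == 0:
        raise ValidationError("depth_summary requires at least one value")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    cv = sd / mean if mean > 0 else float("nan")
    return DepthSummary(n=int(arr.size), mean=mean, sd=sd, cv=cv)
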