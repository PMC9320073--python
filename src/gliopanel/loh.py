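"""1p/19q LOH and codeletion calling from SNP allelic frequencies.

Combined loss of chromosome arms 1p and 19q is the defining lesion of
oligodendroglioma.  On a targeted panel it is read out from common SNPs
along both arms: a germline-heterozygous SNP sits near 50% allelic
frequency (AF, the fraction of reads matching the reference-genome base);
hemizygous loss of one arm in the tumor shifts every heterozygous marker
on that arm away from 50%, toward 1/(2 - f) for tumor fraction f.

Calling proceeds in fixed AF bands:

* homozygous:      AF in [0, 0.10] or [0.90, 1.00]   (uninformative)
* heterozygous:    AF in [0.40, 0.60]                (allele retained)
* allelic imbalance: the open remainder (0.10, 0.40) or (0.60, 0.90)

Markers under a minimum read depth (default 250x) are excluded.  An arm is
called LOH only when it has no heterozygous marker and enough informative
(non-homozygous, adequately covered) markers, all of them imbalanced; a
single heterozygous marker on either arm vetoes codeletion.  The bands are
symmetric in AF vs 1 - AF, so the reference-vs-alternate orientation of
the AF is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .diagnostics import ConfusionCounts
from .errors import ValidationError


class Zygosity(str, Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    IMBALANCE = "imbalance"
    LOW_DEPTH = "low_depth"


class ArmStatus(str, Enum):
    RETAINED = "retained"
    LOH = "loh"
    NON_INFORMATIVE = "non_informative"


class QcTier(str, Enum):
    OPTIMAL = "optimal"
    SUBOPTIMAL = "suboptimal"
    NON_INFORMATIVE = "non_informative"


@dataclass(frozen=True)
class SNPObservation:
    """One panel SNP in one sample."""

    marker_id: str
    arm: str  # "1p" or "19q"
    depth: int
    af: float  # fraction of reads matching the reference-genome base

    def validate(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise ValidationError(f"marker {self.marker_id}: AF {self.af} outside [0, 1]")
        if self.depth < 0:
            raise ValidationError(f"marker {self.marker_id}: negative depth {self.depth}")
        if self.arm not in {"1p", "19q"}:
            raise ValidationError(f"marker {self.marker_id}: unknown arm {self.arm!r}")


@dataclass
class LohConfig:
    """Band edges and evidence thresholds for arm-level calling.

    The homozygous and heterozygous bands are closed at their printed
    edges; allelic imbalance is the open remainder, so the three classes
    partition [0, 1] exactly.
    """

    min_marker_depth: int = 250
    hom_low: float = 0.10   # AF <= hom_low or AF >= hom_high -> homozygous
    het_low: float = 0.40   # het_low <= AF <= het_high -> heterozygous
    het_high: float = 0.60
    hom_high: float = 0.90
    min_informative_per_arm: int = 3
    #: above this fraction of low-depth markers the sample is non-informative
    qc_suboptimal_fraction: float = 0.5
    #: require every informative marker imbalanced for an LOH call (the
    #: strict reading; with the heterozygous veto in place the two
    #: readings coincide, see docs)
    require_all_informative_imbalanced: bool = True

    def validate(self) -> None:
        if not 0 < self.hom_low < self.het_low < self.het_high < self.hom_high < 1:
            raise ValidationError(
                "band edges must satisfy 0 < hom_low < het_low < het_high < hom_high < 1"
            )
        if self.min_marker_depth < 0 or self.min_informative_per_arm < 1:
            raise ValidationError("depth/evidence thresholds out of range")


def classify_zygosity(obs: SNPObservation, cfg: LohConfig | None = None) -> Zygosity:
    """Band membership of one marker (exhaustive and mutually exclusive)."""
    cfg = cfg or LohConfig()
    cfg.validate()
    obs.validate()
    if obs.depth < cfg.min_marker_depth:
        return Zygosity.LOW_DEPTH
    af = obs.af
    if af <= cfg.hom_low or af >= cfg.hom_high:
        return Zygosity.HOMOZYGOUS
    if cfg.het_low <= af <= cfg.het_high:
        return Zygosity.HETEROZYGOUS
    return Zygosity.IMBALANCE


@dataclass
class ArmResult:
    """Verdict and marker tallies for one chromosome arm."""

    arm: str
    status: ArmStatus
    n_markers: int
    n_low_depth: int
    n_hom: int
    n_het: int
    n_imbalance: int

    @property
    def n_informative(self) -> int:
        return self.n_het + self.n_imbalance


@dataclass
class CodeletionCall:
    """Combined 1p/19q verdict for one sample."""

    arm_1p: ArmResult
    arm_19q: ArmResult
    codeleted: str  # "yes" | "no" | "non_informative"
    qc_tier: QcTier = QcTier.OPTIMAL
    sample_id: str | None = None


def qc_sample(observations: Sequence[SNPObservation], cfg: LohConfig | None = None) -> QcTier:
    """Coverage-quality tier of a sample's marker set.

    ``optimal`` when no marker is under the depth floor; ``non_informative``
    when either arm retains fewer adequately covered markers than the
    evidence minimum, or more than ``qc_suboptimal_fraction`` of all
    markers are under-covered; ``suboptimal`` otherwise.
    """
    cfg = cfg or LohConfig()
    cfg.validate()
    if not observations:
        return QcTier.NON_INFORMATIVE
    for o in observations:
        o.validate()
    n_low = sum(1 for o in observations if o.depth < cfg.min_marker_depth)
    if n_low == 0:
        return QcTier.OPTIMAL
    adequate_by_arm = {"1p": 0, "19q": 0}
    for o in observations:
        if o.depth >= cfg.min_marker_depth:
            adequate_by_arm[o.arm] += 1
    if min(adequate_by_arm.values()) < cfg.min_informative_per_arm:
        return QcTier.NON_INFORMATIVE
    if n_low / len(observations) > cfg.qc_suboptimal_fraction:
        return QcTier.NON_INFORMATIVE
    return QcTier.SUBOPTIMAL


def call_arm(
    observations: Sequence[SNPObservation],
    cfg: LohConfig | None = None,
    arm: str | None = None,
) -> ArmResult:
    """Arm-level verdict from that arm's marker observations.

    Low-depth markers are excluded; informative markers are those neither
    low-depth nor homozygous.  One heterozygous marker suffices for
    ``retained``; ``loh`` needs zero heterozygous markers and at least
    ``min_informative_per_arm`` informative markers, all imbalanced;
    anything weaker is ``non_informative``.
    """
    cfg = cfg or LohConfig()
    cfg.validate()
    arms = {o.arm for o in observations}
    if arm is None:
        if len(arms) > 1:
            raise ValidationError(f"observations span multiple arms: {sorted(arms)}")
        arm = next(iter(arms)) if arms else "1p"
    elif arms - {arm}:
        raise ValidationError(
            f"observations for arms {sorted(arms)} passed to call_arm({arm!r})"
        )
    counts = {z: 0 for z in Zygosity}
    for o in observations:
        counts[classify_zygosity(o, cfg)] += 1
    n_het = counts[Zygosity.HETEROZYGOUS]
    n_imb = counts[Zygosity.IMBALANCE]
    n_informative = n_het + n_imb
    if n_het >= 1:
        status = ArmStatus.RETAINED
    elif (
        n_informative >= cfg.min_informative_per_arm
        and n_imb >= 1
        and (not cfg.require_all_informative_imbalanced or n_imb == n_informative)
    ):
        status = ArmStatus.LOH
    else:
        status = ArmStatus.NON_INFORMATIVE
    return ArmResult(
        arm=arm,
        status=status,
        n_markers=len(observations),
        n_low_depth=counts[Zygosity.LOW_DEPTH],
        n_hom=counts[Zygosity.HOMOZYGOUS],
        n_het=n_het,
        n_imbalance=n_imb,
    )


def call_codeletion(r1p: ArmResult, r19q: ArmResult) -> CodeletionCall:
    """Combine the two arm verdicts into a codeletion decision.

    ``yes`` only when both arms are LOH; ``no`` as soon as either arm is
    retained (a heterozygous marker anywhere vetoes codeletion);
    ``non_informative`` otherwise.
    """
    statuses = (r1p.status, r19q.status)
    if all(s == ArmStatus.LOH for s in statuses):
        codeleted = "yes"
    elif ArmStatus.RETAINED in statuses:
        codeleted = "no"
    else:
        codeleted = "non_informative"
    return CodeletionCall(arm_1p=r1p, arm_19q=r19q, codeleted=codeleted)


def call_sample(
    observations: Sequence[SNPObservation],
    cfg: LohConfig | None = None,
    sample_id: str | None = None,
) -> CodeletionCall:
    """QC + per-arm calls + codeletion for one sample's full marker set."""
    cfg = cfg or LohConfig()
    by_arm: dict[str, list[SNPObservation]] = {"1p": [], "19q": []}
    for o in observations:
        o.validate()
        by_arm[o.arm].append(o)
    call = call_codeletion(
        call_arm(by_arm["1p"], cfg, arm="1p"),
        call_arm(by_arm["19q"], cfg, arm="19q"),
    )
    call.qc_tier = qc_sample(observations, cfg)
    call.sample_id = sample_id
    return call


# ---------------------------------------------------------------------------
# benchmarking against an orthogonal reference method
# ---------------------------------------------------------------------------

POSITIVE_TRUTH_LABELS = {"codeleted", "loh", "yes", "1p19q"}
NEGATIVE_TRUTH_LABELS = {"wt", "none", "no", "1p", "19q", "1p_only", "19q_only"}


def _truth_is_positive(label: str) -> bool:
    norm = label.strip().lower().replace(" ", "").replace("-", "_")
    if norm in POSITIVE_TRUTH_LABELS:
        return True
    if norm in NEGATIVE_TRUTH_LABELS:
        # partial single-arm deletions count as negative for codeletion
        return False
    raise ValidationError(f"unrecognized codeletion truth label {label!r}")


def benchmark_codeletion(
    calls: Mapping[str, CodeletionCall | str],
    truth: Mapping[str, str],
    non_informative_policy: str = "conservative",
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN of codeletion calls against reference labels.

    Truth labels naming a single-arm deletion ("1p", "19q") count as
    negative.  Under the default ``conservative`` policy a
    non-informative call scores as FN when the truth is positive and TN
    when negative; the ``exclude`` policy drops such samples from the
    tally.
    """
    if non_informative_policy not in {"conservative", "exclude"}:
        raise ValidationError(f"unknown policy {non_informative_policy!r}")
    tp = tn = fp = fn = 0
    for sample_id, call in calls.items():
        if sample_id not in truth:
            raise ValidationError(f"sample {sample_id} has no truth label")
        verdict = call.codeleted if isinstance(call, CodeletionCall) else str(call)
        positive_truth = _truth_is_positive(truth[sample_id])
        if verdict == "non_informative":
            if non_informative_policy == "exclude":
                continue
            if positive_truth:
                fn += 1
            else:
                tn += 1
        elif verdict == "yes":
            if positive_truth:
                tp += 1
            else:
                fp += 1
        elif verdict == "no":
            if positive_truth:
                fn += 1
            else:
                tn += 1
        else:
            raise ValidationError(f"sample {sample_id}: unknown call verdict {verdict!r}")
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
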