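"""LOH caller: band semantics, arm/codeletion rules, benchmark tallies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliopanel import (
    ArmStatus,
    LohConfig,
    QcTier,
    SNPObservation,
    Zygosity,
    benchmark_codeletion,
    call_arm,
    call_codeletion,
    call_sample,
    classify_zygosity,
    qc_sample,
)
from gliopanel.errors import ValidationError
from gliopanel.loh import ArmResult


def obs(af, depth=1000, arm="1p", marker_id="m"):
    return SNPObservation(marker_id=marker_id, arm=arm, depth=depth, af=af)


def obs_list(afs, depth=1000, arm="1p"):
    return [obs(af, depth=depth, arm=arm, marker_id=f"m{i}") for i, af in enumerate(afs)]


def zygosity_oracle(af, depth, cfg: LohConfig) -> Zygosity:
    """Independent truth-table restatement of the band rules."""
    if depth < cfg.min_marker_depth:
        return Zygosity.LOW_DEPTH
    in_hom = (0.0 <= af <= cfg.hom_low) or (cfg.hom_high <= af <= 1.0)
    in_het = cfg.het_low <= af <= cfg.het_high
    if in_hom:
        return Zygosity.HOMOZYGOUS
    if in_het:
        return Zygosity.HETEROZYGOUS
    return Zygosity.IMBALANCE


def arm_oracle(afs, depths, cfg: LohConfig) -> ArmStatus:
    """Independent restatement of the arm decision."""
    classes = [zygosity_oracle(a, d, cfg) for a, d in zip(afs, depths)]
    n_het = classes.count(Zygosity.HETEROZYGOUS)
    n_imb = classes.count(Zygosity.IMBALANCE)
    if n_het > 0:
        return ArmStatus.RETAINED
    if n_imb >= cfg.min_informative_per_arm:
        return ArmStatus.LOH
    return ArmStatus.NON_INFORMATIVE


def codeletion_oracle(s1, s2) -> str:
    if s1 == ArmStatus.LOH and s2 == ArmStatus.LOH:
        return "yes"
    if ArmStatus.RETAINED in (s1, s2):
        return "no"
    return "non_informative"


class TestZygosity:
    @pytest.mark.parametrize(
        "af,depth,expected",
        [
            (0.50, 1000, Zygosity.HETEROZYGOUS),
            (1.00, 1000, Zygosity.HOMOZYGOUS),
            (0.00, 1000, Zygosity.HOMOZYGOUS),
            (0.75, 1000, Zygosity.IMBALANCE),
            (0.25, 1000, Zygosity.IMBALANCE),
            (0.50, 200, Zygosity.LOW_DEPTH),
            # closed band edges
            (0.10, 1000, Zygosity.HOMOZYGOUS),
            (0.90, 1000, Zygosity.HOMOZYGOUS),
            (0.40, 1000, Zygosity.HETEROZYGOUS),
            (0.60, 1000, Zygosity.HETEROZYGOUS),
            # adequate-depth edge: 250 reads itself is adequate
            (0.50, 250, Zygosity.HETEROZYGOUS),
        ],
    )
    def test_band_membership(self, af, depth, expected):
        assert classify_zygosity(obs(af, depth=depth)) == expected

    def test_af_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError, match="AF"):
            classify_zygosity(obs(1.5))

    def test_band_partition_exhaustive_on_grid(self):
        # every AF on a 1e-3 grid falls in exactly one of the three AF bands
        cfg = LohConfig()
        for af in np.round(np.arange(0, 1.0001, 0.001), 3):
            z = classify_zygosity(obs(float(af)), cfg)
            assert z in {Zygosity.HOMOZYGOUS, Zygosity.HETEROZYGOUS, Zygosity.IMBALANCE}
            assert z == zygosity_oracle(float(af), 1000, cfg)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=300, derandomize=True)
    def test_symmetry_under_af_reflection(self, i):
        # the default bands are symmetric, so AF orientation is immaterial
        af, mirror = i / 10_000, (10_000 - i) / 10_000
        assert classify_zygosity(obs(af)) == classify_zygosity(obs(mirror))


class TestQcSample:
    def test_all_adequate_is_optimal(self):
        observations = obs_list([0.5] * 29) + obs_list([0.5] * 25, arm="19q")
        assert qc_sample(observations) == QcTier.OPTIMAL

    def test_underpowered_arm_is_non_informative(self):
        one_p = obs_list([0.5] * 2) + obs_list([0.5] * 5, depth=100)
        nine_q = obs_list([0.5] * 20, arm="19q")
        assert qc_sample(one_p + nine_q) == QcTier.NON_INFORMATIVE

    def test_some_low_depth_is_suboptimal(self):
        observations = (
            obs_list([0.5] * 19) + obs_list([0.5] * 10, depth=100)
            + obs_list([0.5] * 25, arm="19q")
        )
        assert qc_sample(observations) == QcTier.SUBOPTIMAL


class TestCallArm:
    def test_imbalanced_arm_called_loh(self):
        result = call_arm(obs_list([0.98, 0.02, 0.80, 0.25, 0.70]))
        assert result.status == ArmStatus.LOH
        assert (result.n_hom, result.n_het, result.n_imbalance) == (2, 0, 3)

    def test_single_het_marker_retains_arm(self):
        result = call_arm(obs_list([0.98, 0.52, 0.80]))
        assert result.status == ArmStatus.RETAINED

    def test_all_homozygous_is_non_informative(self):
        result = call_arm(obs_list([1.0, 0.0, 0.99]))
        assert result.status == ArmStatus.NON_INFORMATIVE
        assert result.n_informative == 0

    def test_too_few_imbalanced_markers_non_informative(self):
        result = call_arm(obs_list([0.8, 0.75, 1.0, 0.0]))
        assert result.status == ArmStatus.NON_INFORMATIVE

    def test_counts_sum_to_marker_count(self):
        afs = [0.5, 0.8, 1.0, 0.3, 0.0, 0.55]
        result = call_arm(obs_list(afs, depth=1000) + obs_list([0.5], depth=10))
        assert (
            result.n_low_depth + result.n_hom + result.n_het + result.n_imbalance
            == result.n_markers
            == len(afs) + 1
        )

    def test_mixed_arm_input_rejected(self):
        with pytest.raises(ValidationError, match="arms"):
            call_arm(obs_list([0.5]) + obs_list([0.5], arm="19q"))

    def test_low_depth_markers_excluded_from_evidence(self):
        # three imbalanced markers, all under-covered: no call possible
        result = call_arm(obs_list([0.8, 0.8, 0.8], depth=100))
        assert result.status == ArmStatus.NON_INFORMATIVE


class TestCallCodeletion:
    def make(self, status, arm="1p"):
        return ArmResult(arm, status, 5, 0, 2, int(status == ArmStatus.RETAINED),
                         3 if status == ArmStatus.LOH else 0)

    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            (ArmStatus.LOH, ArmStatus.LOH, "yes"),
            (ArmStatus.LOH, ArmStatus.RETAINED, "no"),
            (ArmStatus.RETAINED, ArmStatus.RETAINED, "no"),
            (ArmStatus.NON_INFORMATIVE, ArmStatus.LOH, "non_informative"),
            (ArmStatus.NON_INFORMATIVE, ArmStatus.RETAINED, "no"),
            (ArmStatus.NON_INFORMATIVE, ArmStatus.NON_INFORMATIVE, "non_informative"),
        ],
    )
    def test_verdict_table(self, s1, s2, expected):
        call = call_codeletion(self.make(s1), self.make(s2, arm="19q"))
        assert call.codeleted == expected

    def test_oracle_equivalence_on_random_marker_vectors(self):
        # independent truth-table evaluator vs the caller on 10^4 instances
        rng = np.random.default_rng(42)
        cfg = LohConfig()
        for _ in range(10_000):
            n1 = int(rng.integers(0, 30))
            n2 = int(rng.integers(0, 30))
            afs1 = rng.random(n1)
            afs2 = rng.random(n2)
            d1 = rng.choice([100, 1000], size=n1, p=[0.1, 0.9])
            d2 = rng.choice([100, 1000], size=n2, p=[0.1, 0.9])
            o1 = [obs(float(a), depth=int(d), marker_id=f"p{i}")
                  for i, (a, d) in enumerate(zip(afs1, d1))]
            o2 = [obs(float(a), depth=int(d), arm="19q", marker_id=f"q{i}")
                  for i, (a, d) in enumerate(zip(afs2, d2))]
            r1, r2 = call_arm(o1, cfg, arm="1p"), call_arm(o2, cfg, arm="19q")
            assert r1.status == arm_oracle(afs1, d1, cfg)
            assert r2.status == arm_oracle(afs2, d2, cfg)
            assert call_codeletion(r1, r2).codeleted == codeletion_oracle(r1.status, r2.status)

    def test_het_marker_veto_is_monotone(self):
        # adding a heterozygous marker never creates or preserves an LOH call
        base = obs_list([0.8, 0.75, 0.7, 0.98])
        assert call_arm(base).status == ArmStatus.LOH
        with_het = base + [obs(0.5, marker_id="het")]
        assert call_arm(with_het).status == ArmStatus.RETAINED


class TestSimulationRecovery:
    def test_deleted_arms_called_loh_at_adequate_purity(self, panel):
        from gliopanel import TruthModel, simulate_sample

        rng = np.random.default_rng(0)
        n_loh = 0
        n = 200
        for k in range(n):
            purity = float(rng.uniform(0.5, 0.85))
            t = TruthModel(sample_id=f"S{k}", purity=purity, del_1p=True, del_19q=True,
                           target_depth=1000)
            s = simulate_sample(t, panel, seed=10_000 + k)
            call = call_sample(s.snps)
            n_loh += call.codeleted == "yes"
        assert n_loh / n >= 0.99

    def test_pure_normal_never_called_loh(self, panel):
        from gliopanel import TruthModel, simulate_sample

        for k in range(200):
            t = TruthModel(sample_id=f"N{k}", purity=1.0, target_depth=1000)
            s = simulate_sample(t, panel, seed=20_000 + k)
            call = call_sample(s.snps)
            assert call.codeleted == "no"


class TestBenchmark:
    def test_published_style_confusion_tally(self):
        calls = {f"pos{i}": "yes" for i in range(6)}
        calls.update({f"neg{i}": "no" for i in range(27)})
        calls["miss"] = "no"
        truth = {f"pos{i}": "codeleted" for i in range(6)}
        truth.update({f"neg{i}": "wt" for i in range(27)})
        truth["miss"] = "codeleted"
        counts = benchmark_codeletion(calls, truth)
        assert (counts.tp, counts.tn, counts.fn, counts.fp) == (6, 27, 1, 0)

    def test_empty_inputs_give_zero_tally(self):
        counts = benchmark_codeletion({}, {})
        assert counts.total == 0

    def test_single_arm_deletion_truth_counts_negative(self):
        counts = benchmark_codeletion({"s": "no"}, {"s": "1p"})
        assert counts.tn == 1 and counts.total == 1

    def test_non_informative_policy(self):
        calls = {"a": "non_informative", "b": "non_informative"}
        truth = {"a": "codeleted", "b": "wt"}
        counts = benchmark_codeletion(calls, truth)
        assert (counts.fn, counts.tn) == (1, 1)
        excluded = benchmark_codeletion(calls, truth, non_informative_policy="exclude")
        assert excluded.total == 0

    def test_missing_truth_label_rejected(self):
        with pytest.raises(ValidationError, match="truth"):
            benchmark_codeletion({"s": "yes"}, {})
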