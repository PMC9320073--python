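"""Filter chain: rule semantics, oracle equivalence, triage, clinical labels."""

import dataclasses
import itertools

import numpy as np
import pytest

from gliopanel import (
    FilterConfig,
    VariantRecord,
    apply_filter_chain,
    classify_clinical,
    oncoplot_matrix,
    prioritize,
)
from gliopanel.errors import ValidationError
from gliopanel.variants import EFFECTS, LOCATIONS, RULE_IDS, oncoplot_margins


def make_variant(**kwargs) -> VariantRecord:
    base = dict(
        chrom="chr2",
        pos=209_113_112,
        ref="C",
        alt="T",
        gene="IDH1",
        filtered_coverage=1500,
        allele_read_count=300,
        vaf=0.20,
        location="exonic",
        effect="missense",
        maf=0.0,
        sift=0.01,
        polyphen=0.2,
    )
    base.update(kwargs)
    return VariantRecord(**base)


def chain_oracle(v: VariantRecord, cfg: FilterConfig) -> bool:
    """Independent one-predicate recheck of the whole chain."""
    ok = v.filtered_coverage >= cfg.min_coverage
    ok = ok and cfg.min_allele_reads <= v.allele_read_count <= cfg.max_allele_reads
    ok = ok and v.location in cfg.allowed_locations
    ok = ok and v.vaf >= cfg.min_vaf
    ok = ok and v.effect in cfg.allowed_effects
    ok = ok and (v.maf if v.maf is not None else 0.0) <= cfg.max_maf
    if v.effect == "missense" and (v.sift is not None or v.polyphen is not None):
        ok = ok and (
            (v.sift is not None and v.sift < cfg.sift_cutoff)
            or (v.polyphen is not None and v.polyphen > cfg.polyphen_cutoff)
        )
    return ok


def random_variants(n: int, seed: int) -> list[VariantRecord]:
    rng = np.random.default_rng(seed)
    locations = sorted(LOCATIONS)
    effects = sorted(EFFECTS)
    out = []
    for i in range(n):
        depth = int(rng.integers(0, 3000))
        alt = int(rng.integers(0, depth + 1))
        out.append(
            VariantRecord(
                chrom="chr1",
                pos=1000 + i,
                ref="A",
                alt="G",
                gene="TP53",
                filtered_coverage=depth,
                allele_read_count=alt,
                vaf=alt / depth if depth else 0.0,
                location=str(rng.choice(locations)),
                effect=str(rng.choice(effects)),
                maf=None if rng.random() < 0.2 else float(rng.random()),
                sift=None if rng.random() < 0.3 else float(rng.random()),
                polyphen=None if rng.random() < 0.3 else float(rng.random()),
            )
        )
    return out


class TestFilterChain:
    def test_fully_passing_missense_kept(self):
        kept, trace = apply_filter_chain([make_variant()])
        assert len(kept) == 1 and trace.n_kept == 1

    @pytest.mark.parametrize(
        "override,failing_rule",
        [
            (dict(filtered_coverage=99, allele_read_count=50, vaf=50 / 99), "coverage"),
            (dict(allele_read_count=49, vaf=49 / 1500), "allele_reads"),
            (dict(location="utr_3"), "location"),
            (dict(allele_read_count=60, vaf=0.04), "vaf"),
            (dict(effect=None), "effect"),
            (dict(maf=0.51), "maf"),
            (dict(sift=0.5, polyphen=0.2), "sift_polyphen"),
        ],
    )
    def test_single_rule_failures_attributed(self, override, failing_rule):
        v = make_variant(**override)
        kept, trace = apply_filter_chain([v])
        assert kept == []
        assert trace.attrition[failing_rule] == 1
        assert trace.outcomes[0][failing_rule] is False

    def test_sift_polyphen_or_gate(self):
        # deleterious by PolyPhen alone passes despite a tolerated SIFT score
        v = make_variant(sift=0.50, polyphen=0.90)
        kept, _ = apply_filter_chain([v])
        assert len(kept) == 1

    def test_scores_only_gate_missense(self):
        nonsense = make_variant(effect="nonsense", sift=0.9, polyphen=0.1)
        kept, _ = apply_filter_chain([nonsense])
        assert len(kept) == 1

    def test_score_missing_missense_passes_unpenalized(self):
        v = make_variant(sift=None, polyphen=None)
        kept, _ = apply_filter_chain([v])
        assert len(kept) == 1

    def test_missing_maf_treated_as_novel(self):
        kept, _ = apply_filter_chain([make_variant(maf=None)])
        assert len(kept) == 1

    def test_unknown_location_label_rejected(self):
        v = make_variant(location="exonic")
        v = dataclasses.replace(v, location="weird_location")
        with pytest.raises(ValidationError, match="weird_location"):
            apply_filter_chain([v])

    def test_boundary_conventions(self):
        # closed bounds at 100 reads coverage and 0.05 VAF; closed at 50 alt reads
        v = make_variant(filtered_coverage=100, allele_read_count=50, vaf=0.5)
        assert len(apply_filter_chain([v])[0]) == 1
        v = make_variant(filtered_coverage=1000, allele_read_count=50, vaf=0.05)
        assert len(apply_filter_chain([v])[0]) == 1

    def test_oracle_equivalence_on_random_tables(self):
        cfg = FilterConfig()
        variants = random_variants(1000, seed=7)
        kept, _ = apply_filter_chain(variants, cfg)
        expected = [v for v in variants if chain_oracle(v, cfg)]
        assert kept == expected

    def test_idempotence(self):
        variants = random_variants(500, seed=11)
        kept, _ = apply_filter_chain(variants)
        kept_again, trace = apply_filter_chain(kept)
        assert kept_again == kept
        assert trace.n_kept == trace.n_input

    def test_attrition_accounts_for_every_removal(self):
        variants = random_variants(800, seed=13)
        kept, trace = apply_filter_chain(variants)
        assert len(variants) == len(kept) + sum(trace.attrition.values())

    def test_order_independence_of_kept_set(self):
        # conjunction: the kept set equals the intersection of per-rule passes
        cfg = FilterConfig()
        variants = random_variants(300, seed=17)
        kept, trace = apply_filter_chain(variants, cfg)
        for perm in itertools.islice(itertools.permutations(RULE_IDS), 5):
            ids = [
                i
                for i, outcome in enumerate(trace.outcomes)
                if all(outcome[r] for r in perm)
            ]
            assert [variants[i] for i in ids] == kept


class TestPrioritize:
    def test_category_tagging(self):
        records = [
            make_variant(location="exonic"),
            make_variant(location="intronic"),
            make_variant(location="utr_3", effect="synonymous"),
            make_variant(location="splicesite_5"),
        ]
        out = prioritize(records)
        assert [v.category for v in out] == ["exonic", "utr", "splicesite"]

    def test_all_intronic_removed(self):
        assert prioritize([make_variant(location="intronic")] * 5) == []

    def test_upstream_removed(self):
        assert prioritize([make_variant(location="upstream")]) == []

    def test_synonymous_exonic_retained(self):
        out = prioritize([make_variant(effect="synonymous")])
        assert len(out) == 1 and out[0].category == "exonic"


class TestClassifyClinical:
    @pytest.mark.parametrize(
        "label,bucket",
        [
            ("Pathogenic/Likely pathogenic", "pathogenic_like"),
            ("Pathogenic", "pathogenic_like"),
            ("Likely pathogenic", "pathogenic_like"),
            ("Likely benign", "benign_or_conflicting"),
            ("Conflicting interpretations of pathogenicity", "benign_or_conflicting"),
            (None, "unclassified"),
            ("drug response", "unclassified"),
        ],
    )
    def test_label_partition(self, label, bucket):
        parts = classify_clinical([make_variant(clin_sig=label)])
        assert len(parts[bucket]) == 1
        assert sum(len(v) for v in parts.values()) == 1


class TestOncoplot:
    def test_single_hit_and_absent_cells(self):
        m = oncoplot_matrix(
            {"A": [make_variant(gene="TP53")], "B": []}
        )
        assert m.loc["TP53", "A"] == "missense"
        assert m.loc["TP53", "B"] == "none"

    def test_multi_hit_collapse(self):
        m = oncoplot_matrix(
            {"A": [make_variant(gene="PTEN"), make_variant(gene="PTEN", pos=2, effect="nonsense")]}
        )
        assert m.loc["PTEN", "A"] == "multi_hit"

    def test_empty_input(self):
        m = oncoplot_matrix({})
        assert m.empty

    def test_margins(self):
        m = oncoplot_matrix(
            {"A": [make_variant(gene="TP53"), make_variant(gene="PTEN")], "B": [make_variant(gene="TP53")]}
        )
        gene_counts, sample_counts = oncoplot_margins(m)
        assert gene_counts["TP53"] == 2
        assert sample_counts["A"] == 2 and sample_counts["B"] == 1
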