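"""Normalization, bracket-semantics aggregation, comparisons, FDR."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from histoquant.aggregation_stats import (
    StatThresholds,
    bh_adjust,
    bulk_metrics,
    compare,
    discrete_ptm,
    fdr_two_stage,
    normalize,
    validate_abundance_table,
)
from histoquant.proteoform_space import parse_notation, realize_exact

from conftest import make_abundance_table


def manifest_frame(samples):
    return pd.DataFrame(
        [
            {"sample": s, "tissue": "BAT", "condition": "TN", "replicate": r}
            for s in samples
            for r in (1, 2)
        ]
    )


class TestNormalize:
    def test_single_class_single_proteoform(self, h4_schema):
        p = realize_exact(parse_notation("H4<K16ac>"), h4_schema)
        quants = {("s1", 1): [(1234.5, {p: 1.0})]}
        t = normalize(quants, manifest_frame(["s1"]), "H4")
        assert t["abundance_percent"].tolist() == [100.0]

    def test_two_classes_proportional(self, h4_schema):
        a = realize_exact(parse_notation("H4<>"), h4_schema)
        b = realize_exact(parse_notation("H4<K16ac>"), h4_schema)
        quants = {("s1", 1): [(300.0, {a: 1.0}), (100.0, {b: 1.0})]}
        t = normalize(quants, manifest_frame(["s1"]), "H4").set_index("proteoform")
        assert t.loc["H4<>", "abundance_percent"] == pytest.approx(75.0)
        assert t.loc["H4<K16ac>", "abundance_percent"] == pytest.approx(25.0)

    def test_technical_replicates_averaged(self, h4_schema):
        a = realize_exact(parse_notation("H4<>"), h4_schema)
        b = realize_exact(parse_notation("H4<K16ac>"), h4_schema)
        quants = {
            ("s1", 1): [(40.0, {a: 1.0}), (60.0, {b: 1.0})],
            ("s1", 2): [(60.0, {a: 1.0}), (40.0, {b: 1.0})],
        }
        t = normalize(quants, manifest_frame(["s1"]), "H4").set_index("proteoform")
        assert t.loc["H4<>", "abundance_percent"] == pytest.approx(50.0)
        assert t.loc["H4<K16ac>", "abundance_percent"] == pytest.approx(50.0)

    def test_all_samples_keep_manifest_metadata(self, h4_schema):
        a = realize_exact(parse_notation("H4<>"), h4_schema)
        quants = {(s, r): [(10.0, {a: 1.0})] for s in ("s1", "s2", "s3") for r in (1, 2)}
        t = normalize(quants, manifest_frame(["s1", "s2", "s3"]), "H4")
        assert t["tissue"].notna().all() and t["condition"].notna().all()
        assert set(t["sample"]) == {"s1", "s2", "s3"}

    def test_zero_intensity_replicate_excluded(self, h4_schema):
        a = realize_exact(parse_notation("H4<>"), h4_schema)
        quants = {("s1", 1): [(10.0, {a: 1.0})], ("s1", 2): [(0.0, {a: 1.0})]}
        t = normalize(quants, manifest_frame(["s1"]), "H4")
        validate_abundance_table(t)


class TestDiscretePtm:
    def test_summation_semantics(self, h3_schema):
        t = make_abundance_table(
            {"s1": {"H3.2<K9me2K27me1>": 6.0, "H3.2<K9me3>": 1.0, "H3.2<>": 93.0}},
            family="H3.2",
        )
        got = discrete_ptm(t, "{K9me2/3}", h3_schema)
        assert got["s1"] == pytest.approx(7.0)

    def test_empty_query_sums_to_100(self, h3_schema):
        t = make_abundance_table(
            {"s1": {"H3.2<K9me2>": 40.0, "H3.2<>": 60.0}}, family="H3.2"
        )
        assert discrete_ptm(t, "{}", h3_schema)["s1"] == pytest.approx(100.0)

    def test_binary_query_equals_brute_force(self, h3_schema):
        rng = np.random.default_rng(17)
        from histoquant.proteoform_space import enumerate_proteoforms

        space = enumerate_proteoforms(h3_schema)
        picks = rng.choice(len(space), size=30, replace=False)
        vals = rng.dirichlet(np.ones(30)) * 100
        t = make_abundance_table(
            {"s1": {space[i].notation(): v for i, v in zip(picks, vals)}}, family="H3.2"
        )
        got = discrete_ptm(t, "{K27me3K36un}", h3_schema)["s1"]
        expected = sum(
            v
            for i, v in zip(picks, vals)
            if space[i].state_at(27) == "me3" and space[i].state_at(36) == "un"
        )
        assert got == pytest.approx(expected)

    def test_k9_partition_conservation(self, h3_schema):
        rng = np.random.default_rng(23)
        from histoquant.proteoform_space import enumerate_proteoforms

        space = enumerate_proteoforms(h3_schema)
        picks = rng.choice(len(space), size=25, replace=False)
        vals = rng.dirichlet(np.ones(25)) * 100
        t = make_abundance_table(
            {"s1": {space[i].notation(): v for i, v in zip(picks, vals)}}, family="H3.2"
        )
        total = sum(
            discrete_ptm(t, "{K9%s}" % st, h3_schema)["s1"]
            for st in ("un", "ac", "me1", "me2", "me3")
        )
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_extra_constraint_never_increases(self, h3_schema):
        t = make_abundance_table(
            {"s1": {"H3.2<K9me2K27me1>": 30.0, "H3.2<K9me2>": 20.0, "H3.2<>": 50.0}},
            family="H3.2",
        )
        base = discrete_ptm(t, "{K9me2}", h3_schema)["s1"]
        narrowed = discrete_ptm(t, "{K9me2K27me1}", h3_schema)["s1"]
        assert narrowed <= base

    def test_contains_at_least_exact(self, h3_schema):
        t = make_abundance_table(
            {"s1": {"H3.2<K9me2K27me1>": 10.0, "H3.2<K9me2>": 25.0, "H3.2<>": 65.0}},
            family="H3.2",
        )
        assert (
            discrete_ptm(t, "{K9me2}", h3_schema)["s1"]
            >= discrete_ptm(t, "<K9me2>", h3_schema)["s1"]
        )

    def test_wrong_family_rejected(self, h4_schema):
        t = make_abundance_table({"s1": {"H4<>": 100.0}})
        with pytest.raises(ValueError, match="family"):
            discrete_ptm(t, "H3.2{K9me2}", h4_schema)


class TestBulkMetrics:
    def test_acetyl_arithmetic(self, h4_schema):
        t = make_abundance_table(
            {"s1": {"H4<>": 50.0, "H4<K16ac>": 30.0, "H4<K8acK16ac>": 20.0}}
        )
        m = bulk_metrics(t, h4_schema).loc["s1"]
        assert m["percent_acetylated"] == pytest.approx(50.0)
        assert m["acetyls_per_molecule"] == pytest.approx(0.7)

    def test_methyl_counts_per_group(self, h4_schema):
        t = make_abundance_table({"s1": {"H4<K20me2>": 100.0}})
        m = bulk_metrics(t, h4_schema).loc["s1"]
        assert m["percent_methylated"] == pytest.approx(100.0)
        assert m["methyls_per_molecule"] == pytest.approx(2.0)  # me2 = 2 methyls

    def test_all_unmodified_zero(self, h4_schema):
        t = make_abundance_table({"s1": {"H4<>": 100.0}})
        m = bulk_metrics(t, h4_schema).loc["s1"]
        assert (m == 0).all()

    def test_nterm_ac_excluded_from_bulk(self, h4_schema):
        # the fixed N-terminal acetyl never counts toward "acetylated"
        t = make_abundance_table({"s1": {"H4<K20me1>": 100.0}})
        m = bulk_metrics(t, h4_schema).loc["s1"]
        assert m["percent_acetylated"] == 0.0

    def test_acetylated_complement_identity(self, h4_schema):
        t = make_abundance_table(
            {"s1": {"H4<>": 40.0, "H4<K20me2>": 25.0, "H4<K16ac>": 35.0}}
        )
        m = bulk_metrics(t, h4_schema).loc["s1"]
        zero_ac = 40.0 + 25.0
        assert m["percent_acetylated"] == pytest.approx(100.0 - zero_ac)


class TestCompare:
    def test_pp_from_printed_means(self):
        res = compare({"BAT": [6.0, 6.0], "liver": [1.7, 1.7]})
        assert res.pp_change == pytest.approx(4.3)

    def test_fold_from_printed_means(self):
        res = compare({"BAT": [36.0, 36.0], "liver": [39.4, 39.4]})
        assert round(res.fold_change, 2) == 0.91

    def test_identical_groups(self):
        res = compare({"a": [5.0, 6.0, 7.0], "b": [5.0, 6.0, 7.0]})
        assert res.pp_change == 0.0
        assert res.fold_change == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_constant_equal_groups_p_one(self):
        res = compare({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert res.p == 1.0

    def test_small_groups_descriptives_only(self):
        res = compare({"a": [5.0], "b": [7.0, 8.0]})
        assert res.p is None
        assert res.pp_change == pytest.approx(-2.5)

    def test_three_groups_anova_tukey(self):
        rng = np.random.default_rng(3)
        groups = {
            "TN": rng.normal(10, 1, 5),
            "RT": rng.normal(10, 1, 5),
            "SC": rng.normal(18, 1, 5),
        }
        res = compare(groups)
        assert res.anova_p is not None and res.anova_p < 0.01
        pair = {(p.group_a, p.group_b): p for p in res.pairwise}
        assert pair[("TN", "SC")].p < 0.05
        assert pair[("TN", "RT")].p > 0.05

    def test_significance_needs_both_p_and_fold(self):
        strong_p_small_fold = compare({"a": [10.0, 10.1, 9.9], "b": [11.0, 11.1, 10.9]})
        assert strong_p_small_fold.pairwise[0].p < 0.05
        assert not strong_p_small_fold.pairwise[0].significant
        big = compare({"a": [10.0, 10.1, 9.9], "b": [20.0, 20.1, 19.9]})
        assert big.pairwise[0].significant


class TestFdr:
    def test_bh_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_bh_hand_computed_stepup(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_dominates_p(self):
        rng = np.random.default_rng(31)
        p = rng.random(50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_bh_matches_reference(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_two_stage_all_null(self):
        flags, _ = fdr_two_stage(np.ones(8))
        assert not flags.any()

    def test_two_stage_uniform_strong_signal(self):
        flags, q = fdr_two_stage([0.001] * 10, alpha=0.05)
        assert flags.sum() == 10

    def test_two_stage_flags_match_reference(self):
        rng = np.random.default_rng(41)
        for _ in range(200):
            m = int(rng.integers(1, 50))
            p = np.where(rng.random(m) < 0.3, rng.random(m) * 1e-3, rng.random(m))
            ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            assert np.array_equal(fdr_two_stage(p, 0.05)[0], ref)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            fdr_two_stage([-0.1])
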