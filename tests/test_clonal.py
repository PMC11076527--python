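"""Clonal dynamics: somatic filter clauses, CCF algebra, intervals,
extinction rule, and the co-evolution contingency tests."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from imd.clonal import (
    ccf_interval,
    classify_clonal_evolution,
    compute_ccf,
    contingency_tests,
    coevolution_contingency,
    filter_somatic_calls,
    subclone_fraction,
)
from imd.io import MutationTable


def _records():
    """Hand-evaluated toy records covering every filter clause."""
    cols = ["chrom", "pos", "ref", "alt", "variant_class", "alt_count",
            "depth", "vaf", "caller_flags", "normal_vaf", "normal_alt_count",
            "population_freq", "cn_t", "cn_n", "purity", "sample_id",
            "patient_id", "timepoint", "keep"]
    rows = [
        # both callers, vaf 3% > 2%: kept
        ("c1", 1, "A", "T", "SNV", 2, 67, 0.03, "callerA,callerB", 0.005, 1, 0.0, 2, 2, 0.5, "s1", "p1", "pre", True),
        # single caller at 3%, single timepoint: rejected (needs > 5%)
        ("c1", 2, "A", "T", "SNV", 2, 67, 0.03, "callerA", 0.0, 0, 0.0, 2, 2, 0.5, "s1", "p1", "pre", False),
        # single caller at 6% > 5%: kept
        ("c1", 3, "A", "T", "SNV", 4, 67, 0.06, "callerB", 0.0, 0, 0.0, 2, 2, 0.5, "s1", "p1", "pre", True),
        # single caller at 3% but recurrent at two timepoints: kept (both rows)
        ("c1", 4, "A", "T", "SNV", 2, 67, 0.03, "callerA", 0.0, 0, 0.0, 2, 2, 0.5, "s1", "p1", "pre", True),
        ("c1", 4, "A", "T", "SNV", 2, 67, 0.03, "callerA", 0.0, 0, 0.0, 2, 2, 0.4, "s2", "p1", "post", True),
        # depth 30 is not > 30: rejected
        ("c1", 5, "A", "T", "SNV", 3, 30, 0.10, "callerA,callerB", 0.0, 0, 0.0, 2, 2, 0.5, "s1", "p1", "pre", False),
        # normal VAF 1.5% >= 1%: rejected
        ("c1", 6, "A", "T", "SNV", 7, 70, 0.10, "callerA,callerB", 0.015, 2, 0.0, 2, 2, 0.5, "s1", "p1", "pre", False),
        # normal alt reads 5 (not < 5): rejected
        ("c1", 7, "A", "T", "SNV", 7, 70, 0.10, "callerA,callerB", 0.005, 5, 0.0, 2, 2, 0.5, "s1", "p1", "pre", False),
        # population frequency 2% > 1%: rejected
        ("c1", 8, "A", "T", "SNV", 7, 70, 0.10, "callerA,callerB", 0.0, 0, 0.02, 2, 2, 0.5, "s1", "p1", "pre", False),
        # population frequency exactly 1%: kept (rule rejects only > 1%)
        ("c1", 9, "A", "T", "SNV", 7, 70, 0.10, "callerA,callerB", 0.0, 0, 0.01, 2, 2, 0.5, "s1", "p1", "pre", True),
        # indel at depth 45 (> 30 but not > 50): rejected
        ("c1", 10, "A", "AT", "indel", 5, 45, 0.111, "callerA,callerB", 0.0, 0, 0.0, 2, 2, 0.5, "s1", "p1", "pre", False),
        # indel at depth 60: kept
        ("c1", 11, "A", "AT", "indel", 6, 60, 0.10, "callerA,callerB", 0.0, 0, 0.0, 2, 2, 0.5, "s1", "p1", "pre", True),
        # both callers but vaf exactly 2%: rejected (strict >)
        ("c1", 12, "A", "T", "SNV", 2, 100, 0.02, "callerA,callerB", 0.0, 0, 0.0, 2, 2, 0.5, "s1", "p1", "pre", False),
        # all clauses pass at once
        ("c1", 13, "A", "T", "SNV", 20, 100, 0.20, "callerA,callerB", 0.0, 0, 0.005, 2, 2, 0.5, "s1", "p1", "pre", True),
    ]
    df = pd.DataFrame(rows, columns=cols)
    want = df.pop("keep")
    return MutationTable(df), want


class TestSomaticFilter:
    def test_hand_evaluated_records(self):
        table, want = _records()
        kept, counts = filter_somatic_calls(table)
        got = table.table.index.isin(kept.table.index)
        assert list(got) == list(want)

    def test_kept_set_is_intersection_of_per_rule_sets(self):
        table, _ = _records()
        df = table.table
        kept, _ = filter_somatic_calls(table)
        # recompute each clause independently and intersect
        n_callers = df["caller_flags"].map(lambda s: len(s.split(",")))
        key = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
        n_tp = key.map(df.assign(k=key).groupby("k")["timepoint"].nunique())
        masks = [
            ((n_callers >= 2) & (df.vaf > 0.02)) | ((n_callers >= 1) & (df.vaf > 0.05))
            | ((df.vaf > 0.02) & (n_tp >= 2)),
            df.depth > 30,
            df.normal_vaf < 0.01,
            df.normal_alt_count < 5,
            df.population_freq <= 0.01,
            (df.variant_class != "indel") | (df.depth > 50),
        ]
        expected = np.logical_and.reduce(masks)
        assert (df.index.isin(kept.table.index) == expected).all()

    def test_missing_column_named_in_error(self):
        table, _ = _records()
        broken = table.table.drop(columns=["population_freq"])
        broken = MutationTable.__new__(MutationTable)
        broken.table = table.table.drop(columns=["population_freq"])
        with pytest.raises(ValueError, match="population_freq"):
            filter_somatic_calls(broken)


class TestCCF:
    @pytest.mark.parametrize("vaf,p,cnt,cnn,want", [
        (0.5, 1.0, 2, 2, 1.0),
        (0.0, 0.3, 2, 2, 0.0),
        (0.2, 0.5, 3, 2, 1.0),
    ])
    def test_closed_form(self, vaf, p, cnt, cnn, want):
        assert compute_ccf(vaf, p, cnt, cnn) == pytest.approx(want, abs=1e-12)

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError, match="purity"):
            compute_ccf(0.1, 0.0, 2)

    def test_clonal_interval_straddles_one(self):
        est = ccf_interval(50, 100, 1.0, 2)
        assert est.ccf == pytest.approx(1.0)
        assert est.clonality == "clonal"

    def test_low_vaf_interval_is_subclonal(self):
        est = ccf_interval(5, 100, 1.0, 2)
        assert est.ccf == pytest.approx(0.1)
        assert est.ci_high < 1.0
        assert est.clonality == "subclonal"

    def test_zero_alt_reads_subclonal_at_zero(self):
        est = ccf_interval(0, 100, 1.0, 2)
        assert est.ccf == 0.0
        assert est.clonality == "subclonal"

    def test_interval_coverage_near_nominal(self):
        # 1,000 simulated diploid mutations at depth 100
        rng = np.random.default_rng(12)
        p, cnt = 0.6, 2
        hits = 0
        n = 1000
        for _ in range(n):
            ccf_true = rng.uniform(0.1, 1.0)
            ev = ccf_true * p / (p * cnt + 2 * (1 - p))
            alt = rng.binomial(100, ev)
            est = ccf_interval(alt, 100, p, cnt)
            hits += est.ci_low <= ccf_true <= est.ci_high
        assert abs(hits / n - 0.95) <= 0.02

    def test_normal_approximation_available(self):
        a = ccf_interval(30, 100, 0.5, 2, method="normal")
        b = ccf_interval(30, 100, 0.5, 2, method="clopper-pearson")
        assert a.ci_low == pytest.approx(b.ci_low, abs=0.15)

    def test_bad_conf_rejected(self):
        with pytest.raises(ValueError, match="conf"):
            ccf_interval(5, 10, 0.5, 2, conf=1.5)


class TestClonalEvolution:
    def test_massive_loss_is_extinction(self):
        base = {f"m{i}" for i in range(20)}
        post = {"m0"} | {f"new{i}" for i in range(15)}
        assert classify_clonal_evolution(base, post).status == "extinction"

    def test_small_post_burden_is_extinction(self):
        base = {f"m{i}" for i in range(20)}
        post = {f"m{i}" for i in range(9)}
        assert classify_clonal_evolution(base, post).status == "extinction"

    def test_retention_is_persistence(self):
        base = {f"m{i}" for i in range(20)}
        post = {f"m{i}" for i in range(15)} | {f"new{i}" for i in range(25)}
        assert classify_clonal_evolution(base, post).status == "persistence"

    def test_boundary_exactly_ninety_percent_is_persistence(self):
        # 18 of 20 disappeared = exactly 90%, rule requires > 90%
        base = {f"m{i}" for i in range(20)}
        post = {"m0", "m1"} | {f"new{i}" for i in range(10)}
        call = classify_clonal_evolution(base, post)
        assert call.fraction_disappeared == pytest.approx(0.9)
        assert call.status == "persistence"

    def test_boundary_exactly_ten_post_mutations_is_persistence(self):
        base = {f"m{i}" for i in range(10)}
        post = {f"m{i}" for i in range(10)}
        assert classify_clonal_evolution(base, post).status == "persistence"

    def test_duplicates_and_order_do_not_matter(self):
        base = ["m1", "m2", "m3", "m1"]
        post = ["m3", "m2", "m1", "m2"] + [f"n{i}" for i in range(10)]
        a = classify_clonal_evolution(set(base), set(post))
        b = classify_clonal_evolution(base[::-1], post[::-1])
        assert a == b

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="empty baseline"):
            classify_clonal_evolution(set(), {"m1"})


class TestSubcloneFraction:
    def test_fractions(self):
        clonal = ccf_interval(50, 100, 1.0, 2)
        sub = ccf_interval(5, 100, 1.0, 2)
        assert subclone_fraction([clonal, clonal]) == 0.0
        assert subclone_fraction([sub, sub]) == 100.0
        assert subclone_fraction([sub, sub, sub] + [clonal] * 7) == 30.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            subclone_fraction([])


def fisher_oracle(table):
    """Two-sided Fisher p by exhaustive enumeration of tables with the same
    margins, summing hypergeometric probabilities <= the observed one."""
    a, b, c, d = np.asarray(table).ravel()
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestContingency:
    def test_printed_coevolution_table_reproduces_p(self):
        res = contingency_tests([[7, 2], [0, 11]])
        assert round(res["p_yates"], 3) == 0.002

    def test_balanced_table_shows_no_association(self):
        res = contingency_tests([[5, 5], [5, 5]])
        assert res["p_yates"] == pytest.approx(1.0)
        assert res["fisher_p"] == pytest.approx(1.0)

    def test_fisher_matches_enumeration_oracle_exhaustively(self):
        rng = np.random.default_rng(5)
        tables = [[[7, 2], [0, 11]]]
        for _ in range(200):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0 or t.sum() > 30:
                continue
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            tables.append(t.tolist())
        for t in tables:
            res = contingency_tests(t)
            assert res["fisher_p"] == pytest.approx(fisher_oracle(t), abs=1e-9)

    def test_series_interface_builds_expected_table(self):
        ic = pd.Series(["positive"] * 9 + ["negative"] * 11,
                       index=[f"p{i}" for i in range(20)])
        st = pd.Series(["extinction"] * 7 + ["persistence"] * 2
                       + ["persistence"] * 11,
                       index=[f"p{i}" for i in range(20)])
        res = coevolution_contingency(ic, st)
        assert res["table"].tolist() == [[7, 2], [0, 11]]
        assert res["odds_ratio"] > 1

    def test_unknown_labels_rejected(self):
        ic = pd.Series(["positive"], index=["p"])
        st = pd.Series(["vanished"], index=["p"])
        with pytest.raises(ValueError, match="vanished"):
            coevolution_contingency(ic, st)

    def test_zero_margin_table_handled(self):
        res = contingency_tests([[0, 0], [3, 4]])
        assert res["p_yates"] == 1.0
        assert 0 <= res["fisher_p"] <= 1
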