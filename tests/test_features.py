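"""EGFR subtyping, TMB, HLA LOH rules, and the rank-based statistics
against a hand-coded Kruskal-Wallis oracle."""

import numpy as np
import pandas as pd
import pytest

from neoshare.errors import DomainError
from neoshare.features import (
    b2m_flag,
    classify_egfr,
    hla_loh_patient,
    kruskal_subtypes,
    patient_feature_table,
    subgroup_rates,
    tmb_count,
)
from neoshare.io import LocusLohCall, PatientRecord

from conftest import make_genotype, make_mutation


class TestClassifyEgfr:
    def test_l858r(self):
        assert classify_egfr([make_mutation("S1")]) == "L858R"

    def test_archetypal_exon19_deletion(self):
        m = make_mutation("S1", hgvs_p="p.E746_A750del", consequence="inframe_indel")
        assert classify_egfr([m]) == "del19"

    def test_other_egfr(self):
        assert classify_egfr([make_mutation("S1", hgvs_p="p.G719A")]) == "other"

    def test_non_egfr_only_is_wt(self):
        m = make_mutation("S1", gene="TP53", hgvs_p="p.R175H")
        assert classify_egfr([m]) == "WT"
        assert classify_egfr([]) == "WT"

    def test_deletion_outside_exon19_span_is_other(self):
        m = make_mutation("S1", hgvs_p="p.S768_D770del", consequence="inframe_indel")
        assert classify_egfr([m]) == "other"

    def test_precedence_and_order_invariance(self):
        muts = [
            make_mutation("S1", hgvs_p="p.E746_A750del", consequence="inframe_indel"),
            make_mutation("S1"),  # p.L858R
            make_mutation("S1", hgvs_p="p.G719A"),
        ]
        assert classify_egfr(muts) == "L858R"
        assert classify_egfr(list(reversed(muts))) == "L858R"

    def test_synonymous_egfr_does_not_count(self):
        m = make_mutation("S1", hgvs_p="p.L100=", consequence="other")
        assert classify_egfr([m]) == "WT"


class TestTmb:
    def test_empty(self):
        assert tmb_count([]) == 0

    def test_counts_protein_altering_only(self):
        muts = [
            make_mutation("S1", gene="TP53", hgvs_p="p.R175H"),
            make_mutation("S1", gene="TP53", hgvs_p="p.R280K"),
            make_mutation("S1", gene="KRAS", hgvs_p="p.G12C"),
            make_mutation("S1", gene="G", hgvs_p="p.K5fs", consequence="frameshift"),
            make_mutation("S1", gene="G", hgvs_p="p.L10=", consequence="other"),
        ]
        assert tmb_count(muts) == 4

    def test_stop_gain_counts(self):
        m = make_mutation("S1", gene="TP53", hgvs_p="p.R196*", consequence="other")
        assert tmb_count([m]) == 1


class TestB2m:
    def test_truncating_lesion_flags(self):
        m = make_mutation("S1", gene="B2M", hgvs_p="p.L15Ffs*41",
                          consequence="frameshift")
        assert b2m_flag([m]) is True

    def test_synonymous_b2m_does_not_flag(self):
        m = make_mutation("S1", gene="B2M", hgvs_p="p.L15=", consequence="other")
        assert b2m_flag([m]) is False

    def test_no_b2m_rows(self):
        assert b2m_flag([make_mutation("S1", gene="TP53", hgvs_p="p.R175H")]) is False


class TestHlaLoh:
    def test_one_significant_het_locus_affects(self):
        calls = [
            LocusLohCall("S1", "A", True, 0.005),
            LocusLohCall("S1", "B", True, 0.5),
            LocusLohCall("S1", "C", False, None),
        ]
        assert hla_loh_patient(calls) == "affected"

    def test_all_homozygous_is_unaffected(self):
        calls = [LocusLohCall("S1", l, False, None) for l in "ABC"]
        assert hla_loh_patient(calls) == "unaffected"

    def test_boundary_pvalue_is_strict(self):
        calls = [LocusLohCall("S1", "A", True, 0.01)]
        assert hla_loh_patient(calls) == "unaffected"

    def test_no_calls_not_evaluable(self):
        assert hla_loh_patient(None) == "not_evaluable"
        assert hla_loh_patient([]) == "not_evaluable"

    def test_duplicate_locus_rejected(self):
        calls = [LocusLohCall("S1", "A", True, 0.5)] * 2
        with pytest.raises(DomainError):
            hla_loh_patient(calls)

    def test_adding_subthreshold_locus_never_flips_to_affected(self):
        base = [LocusLohCall("S1", "A", True, 0.5)]
        extra = base + [LocusLohCall("S1", "B", True, 0.2)]
        assert hla_loh_patient(base) == hla_loh_patient(extra) == "unaffected"


def oracle_kruskal_h(groups):
    """Textbook Kruskal-Wallis H with midranks and tie correction."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    order = np.argsort(all_vals, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = all_vals[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 12.0 / (n * (n + 1))
    offset = 0
    s = 0.0
    for g in groups:
        r = ranks[offset : offset + len(g)].sum()
        s += r * r / len(g)
        offset += len(g)
    h = h * s - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestKruskal:
    def test_matches_hand_rank_computation(self):
        groups = {
            "a": [1.0, 2.0, 3.0],
            "b": [101.0, 102.0, 103.0],
            "c": [201.0, 202.0, 203.0],
        }
        res = kruskal_subtypes(groups)
        h = oracle_kruskal_h([np.array(v) for v in groups.values()])
        assert res.h_statistic == pytest.approx(h, abs=1e-10)

    def test_matches_oracle_with_heavy_ties(self):
        rng = np.random.default_rng(17)
        groups = {
            k: rng.integers(0, 6, size=25).astype(float).tolist()
            for k in ("w", "x", "y", "z")
        }
        res = kruskal_subtypes(groups)
        h = oracle_kruskal_h([np.array(groups[k]) for k in res.groups])
        assert res.h_statistic == pytest.approx(h, abs=1e-10)

    def test_constant_data_statistic_zero(self):
        res = kruskal_subtypes({"a": [2, 2, 2], "b": [2, 2, 2]})
        assert res.h_statistic == 0.0 and res.p_value == 1.0

    def test_small_group_excluded_with_warning(self, caplog):
        res = kruskal_subtypes({"a": [1, 2, 3], "b": [4, 5, 6], "tiny": [1]})
        assert "tiny" not in res.groups

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(DomainError):
            kruskal_subtypes({"a": [1, 2, 3], "tiny": [1]})

    def test_pairwise_bh_adjustment_monotone(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": rng.normal(0, 1, 30).tolist(),
            "b": rng.normal(1, 1, 30).tolist(),
            "c": rng.normal(2, 1, 30).tolist(),
        }
        res = kruskal_subtypes(groups, pairwise=True)
        pw = res.pairwise
        assert len(pw) == 3
        assert (pw["p_adjusted"] >= pw["p_value"] - 1e-15).all()

    def test_power_against_planted_median_shift(self):
        """>=1-unit median shifts at n=200/group are detected reliably."""
        rng = np.random.default_rng(100)
        rejections = 0
        reps = 60
        for _ in range(reps):
            a = rng.negative_binomial(3, 3 / 5.2, 200).astype(float)  # median 3
            b = rng.negative_binomial(3, 3 / 8.4, 200).astype(float)  # median 5
            res = kruskal_subtypes({"a": a.tolist(), "b": b.tolist()})
            rejections += res.p_value < 0.05
        assert rejections / reps > 0.9


class TestSubgroupRates:
    def _features(self, rates, n_per_group, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for gi, (group, rate) in enumerate(rates.items()):
            for i in range(n_per_group):
                affected = rng.random() < rate
                rows.append((f"S{gi}_{i}", group, 3,
                             "affected" if affected else "unaffected", False))
        return pd.DataFrame(
            rows, columns=["sample_id", "subtype", "tmb_count", "hla_loh",
                           "b2m_aberrant"]
        )

    def test_identical_planted_rates_not_significant(self):
        feats = self._features({"WT": 0.6, "L858R": 0.6}, 400, seed=21)
        comp = subgroup_rates(feats)["hla_loh"]
        assert comp.defined and comp.p_value > 0.05

    def test_distinct_planted_rates_significant(self):
        feats = self._features({"WT": 0.3, "L858R": 0.8}, 200, seed=22)
        comp = subgroup_rates(feats)["hla_loh"]
        assert comp.defined and comp.p_value < 0.05

    def test_not_evaluable_excluded_from_denominator(self):
        feats = pd.DataFrame({
            "sample_id": ["S1", "S2", "S3", "S4"],
            "subtype": ["WT", "WT", "L858R", "L858R"],
            "tmb_count": [1, 2, 3, 4],
            "hla_loh": ["affected", "not_evaluable", "unaffected", "affected"],
            "b2m_aberrant": [False, False, False, True],
        })
        comp = subgroup_rates(feats)["hla_loh"]
        assert comp.rates.set_index("group").loc["WT", "n_evaluable"] == 1


def test_patient_feature_table_integrates_all_features():
    g = make_genotype("S1")
    patient = PatientRecord(
        sample_id="S1", genotype=g,
        mutations=[make_mutation("S1"),
                   make_mutation("S1", gene="TP53", hgvs_p="p.R175H")],
        loh_calls=[LocusLohCall("S1", "A", True, 0.001)],
    )
    table = patient_feature_table([patient])
    row = table.iloc[0]
    assert (row["subtype"], row["tmb_count"], row["hla_loh"],
            row["b2m_aberrant"]) == ("L858R", 2, "affected", False)
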