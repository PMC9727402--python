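"""Cohort aggregation: prevalence, uniqueness, frequencies, shared ranking,
and the chi-square engine against a hand-coded textbook oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoshare.binding import CANDIDATE_COLUMNS
from neoshare.errors import DomainError
from neoshare.prioritize import (
    binder_breakdown_by_prevalence,
    chi_square_2x2,
    neoantigen_frequency,
    per_mutation_counts,
    prevalence_tables,
    round_percent,
    shared_candidate_table,
    shared_frequency,
    unique_neoantigens,
)

from conftest import make_mutation


def cand_row(sample, gene, hgvs, pep, allele, mt, wt):
    cls = "strong" if mt < 50 else "weak"
    return (sample, gene, hgvs, pep, "WT" + pep[2:], allele, mt, wt, cls)


def frame(rows):
    return pd.DataFrame(rows, columns=list(CANDIDATE_COLUMNS))


class TestPrevalence:
    def test_half_the_cohort(self):
        muts = [make_mutation(f"S{i}", gene="G", hgvs_p="p.A10V") for i in (1, 2)]
        gene, variant = prevalence_tables(muts, n_patients=4)
        assert gene.set_index("gene").loc["G", "prevalence"] == 0.5
        assert variant.iloc[0]["prevalence"] == 0.5

    def test_patient_with_two_variants_counts_once(self):
        muts = [
            make_mutation("S1", gene="G", hgvs_p="p.A10V"),
            make_mutation("S1", gene="G", hgvs_p="p.A20V"),
        ]
        gene, variant = prevalence_tables(muts, n_patients=4)
        assert gene.set_index("gene").loc["G", "n_patients_mut"] == 1
        assert len(variant) == 2

    def test_duplicate_rows_deduplicated(self):
        muts = [make_mutation("S1", gene="G", hgvs_p="p.A10V")] * 3
        gene, variant = prevalence_tables(muts, n_patients=2)
        assert variant.iloc[0]["n_patients_mut"] == 1

    def test_frameshift_flag(self):
        muts = [
            make_mutation("S1", gene="G", hgvs_p="p.A10V"),
            make_mutation("S2", gene="G", hgvs_p="p.K5fs", consequence="frameshift"),
        ]
        gene_off, _ = prevalence_tables(muts, n_patients=4, include_frameshift=False)
        gene_on, _ = prevalence_tables(muts, n_patients=4, include_frameshift=True)
        assert gene_off.set_index("gene").loc["G", "prevalence"] == 0.25
        assert gene_on.set_index("gene").loc["G", "prevalence"] == 0.50


class TestUniqueNeoantigens:
    def test_published_driver_rows_collapse_to_two(self, table1_candidates):
        l858r = table1_candidates[table1_candidates["hgvs_p"] == "p.L858R"]
        uniq = unique_neoantigens(l858r)
        assert len(uniq) == 2
        hv = uniq[uniq["mt_peptide"] == "HVKITDFGR"].iloc[0]
        assert hv["n_alleles"] == 3 and hv["class_summary"] == "strong"

    def test_mixed_classes_are_ambiguous(self):
        df = frame([
            cand_row("S1", "G", "p.A10V", "PEPTIDEK", "A*01:01", 20.0, 900.0),
            cand_row("S2", "G", "p.A10V", "PEPTIDEK", "A*02:01", 200.0, 900.0),
        ])
        uniq = unique_neoantigens(df)
        assert uniq.iloc[0]["class_summary"] == "ambiguous"
        assert uniq.iloc[0]["n_samples"] == 2

    def test_empty_and_idempotent(self, table1_candidates):
        assert unique_neoantigens(frame([])).empty
        u1 = unique_neoantigens(table1_candidates)
        # grouping keys already unique: collapsing again changes nothing
        assert u1.groupby(["gene", "hgvs_p", "mt_peptide"]).size().max() == 1


class TestPerMutationCounts:
    def test_published_driver_counts(self, table1_candidates):
        counts = per_mutation_counts(table1_candidates).set_index("hgvs_p")
        l858r = counts.loc["p.L858R"]
        assert (l858r["n_pairs"], l858r["n_unique_peptides"],
                l858r["n_strong_peptides"]) == (4, 2, 2)
        ex19 = counts.loc["p.E746_A750del"]
        assert ex19["n_unique_peptides"] == 2 and ex19["n_strong_peptides"] == 0

    def test_variant_without_candidates_absent(self, table1_candidates):
        counts = per_mutation_counts(table1_candidates)
        assert "p.G719A" not in set(counts["hgvs_p"])


class TestNeoantigenFrequency:
    def _fixture(self):
        muts = []
        for i in range(10):  # 10 distinct occurrences of gene G in 10 patients
            muts.append(make_mutation(f"S{i}", gene="G", hgvs_p=f"p.A{10 + i}V"))
        rows = [
            cand_row(f"S{i}", "G", f"p.A{10 + i}V", f"PEPTID{i}K", "A*01:01",
                     100.0, 900.0)
            for i in range(6)
        ]
        return muts, frame(rows)

    def test_hand_counted_frequency(self):
        muts, cands = self._fixture()
        uniq = unique_neoantigens(cands)
        total, per_allele = neoantigen_frequency(uniq, muts, n_patients=100)
        row = total.set_index("gene").loc["G"]
        assert row["frequency"] == pytest.approx(0.6)
        # single-allele gene: allele-specific equals total
        arow = per_allele.set_index(["gene", "allele"]).loc[("G", "A*01:01")]
        assert arow["frequency"] == pytest.approx(0.6)

    def test_low_prevalence_gene_dropped(self):
        muts, cands = self._fixture()
        uniq = unique_neoantigens(cands)
        total, _ = neoantigen_frequency(uniq, muts, n_patients=2001)
        assert "G" not in set(total["gene"])

    def test_multi_allele_neoantigen_counted_once_in_total(self):
        muts = [make_mutation(f"S{i}", gene="G", hgvs_p=f"p.A{10 + i}V")
                for i in range(10)]
        rows = [
            cand_row("S0", "G", "p.A10V", "PEPTIDEK", "A*01:01", 20.0, 900.0),
            cand_row("S0", "G", "p.A10V", "PEPTIDEK", "A*02:01", 200.0, 900.0),
        ]
        uniq = unique_neoantigens(frame(rows))
        total, per_allele = neoantigen_frequency(uniq, muts, n_patients=100)
        assert total.set_index("gene").loc["G", "n_neoantigens"] == 1
        # allele-specific sums can exceed the total
        assert per_allele["n_neoantigens"].sum() == 2


class TestSharedFrequency:
    @pytest.mark.parametrize(
        "prev,carrier,pct",
        [(0.2261, 0.1294, 2.93), (0.2261, 0.0526, 1.19), (0.2261, 0.0124, 0.28),
         (0.5, 0.0, 0.0)],
    )
    def test_published_products(self, prev, carrier, pct):
        assert round_percent(shared_frequency(prev, carrier)) == pct

    @pytest.mark.parametrize("bad", [(-0.1, 0.5), (0.5, 1.2)])
    def test_domain(self, bad):
        with pytest.raises(DomainError):
            shared_frequency(*bad)

    @settings(deadline=None)
    @given(
        st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1)
    )
    def test_commutative_and_bounded(self, a, b):
        assert shared_frequency(a, b) == shared_frequency(b, a)
        assert shared_frequency(a, b) <= min(a, b) + 1e-15

    def test_half_up_reporting(self):
        assert round_percent(0.029250) == 2.93  # 2.925% rounds up, not to even


class TestSharedTable:
    def test_ranking_and_tiebreak(self):
        df = frame([
            cand_row("S1", "EGFR", "p.L858R", "HVKITDFGR", "A*33:03", 22.9, 12734.0),
            cand_row("S1", "EGFR", "p.L858R", "HVKITDFGR", "A*31:01", 18.9, 11653.7),
            cand_row("S2", "EGFR", "p.E746_A750del", "IPVAIKTSPK", "A*11:01",
                     158.2, 31132.7),
        ])
        variant_prev = pd.DataFrame({
            "gene": ["EGFR", "EGFR"],
            "hgvs_p": ["p.L858R", "p.E746_A750del"],
            "n_patients_mut": [421, 242],
            "prevalence": [0.2261, 0.13],
        })
        carrier = {"A*33:03": 0.1294, "A*31:01": 0.0526, "A*11:01": 0.4259}
        tab = shared_candidate_table(df, variant_prev, carrier)
        assert list(tab["shared_frequency_pct"]) == [5.54, 2.93, 1.19]
        assert tab.iloc[0]["allele"] == "A*11:01"

    def test_equal_shared_frequencies_sort_lexicographically(self):
        df = frame([
            cand_row("S1", "B", "p.A10V", "PEPTIDEK", "A*01:01", 100.0, 900.0),
            cand_row("S1", "A", "p.A10V", "PEPTIDEK", "A*01:01", 100.0, 900.0),
        ])
        variant_prev = pd.DataFrame({
            "gene": ["A", "B"], "hgvs_p": ["p.A10V", "p.A10V"],
            "n_patients_mut": [1, 1], "prevalence": [0.1, 0.1],
        })
        tab = shared_candidate_table(df, variant_prev, {"A*01:01": 0.5})
        assert list(tab["gene"]) == ["A", "B"]


def oracle_chi2_2x2(table, yates):
    """Textbook 2x2 chi-square with optional continuity correction."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / n
            d = abs(table[i, j] - e)
            if yates:
                d = max(0.0, d - 0.5)
            stat += d * d / e
    from scipy.stats import chi2 as chi2_dist  # survival fn only, not the test

    return stat, float(chi2_dist.sf(stat, 1))


class TestChiSquare:
    @pytest.mark.parametrize("yates", [True, False])
    @pytest.mark.parametrize(
        "table", [[[98, 406], [169, 765]], [[12, 30], [45, 9]], [[5, 95], [20, 80]]]
    )
    def test_matches_textbook_oracle(self, table, yates):
        res = chi_square_2x2(np.array(table), yates=yates)
        stat, p = oracle_chi2_2x2(table, yates)
        assert res.chi2 == pytest.approx(stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_symmetric_table_statistic_zero(self):
        res = chi_square_2x2(np.array([[10, 10], [10, 10]]), yates=True)
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_zero_margin_undefined(self):
        res = chi_square_2x2(np.array([[0, 10], [0, 20]]))
        assert not res.defined and np.isnan(res.chi2)


class TestBinderBreakdown:
    def test_published_proportions(self):
        """The published strata: 98/504 (19%) vs 169/934 (18%) strong."""
        table = np.array([[98, 406], [169, 765]])
        assert table[0].sum() == 504 and table[1].sum() == 934
        assert round(table[0, 0] / table[0].sum() * 100) == 19
        assert round(table[1, 0] / table[1].sum() * 100) == 18
        res = chi_square_2x2(table, yates=True)
        assert res.defined and res.p_value > 0.05  # not significant

    def test_stratification_and_ambiguous_count_as_strong(self):
        uniq = pd.DataFrame({
            "gene": ["G1", "G1", "G2"],
            "hgvs_p": ["p.A10V", "p.A20V", "p.A10V"],
            "mt_peptide": ["PEPA", "PEPB", "PEPC"],
            "class_summary": ["strong", "ambiguous", "weak"],
        })
        gene_prev = pd.DataFrame({"gene": ["G1", "G2"], "prevalence": [0.05, 0.005]})
        res = binder_breakdown_by_prevalence(uniq, gene_prev, cut=0.01)
        # rows: [low prevalence, high prevalence] x [strong, weak]
        assert res.table.tolist() == [[0, 1], [2, 0]]
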