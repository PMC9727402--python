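"""Cohort-level neoantigen aggregation and shared-frequency ranking.

A "unique" neoantigen is a (gene, protein change, mutant peptide)
combination, collapsing over patients and HLA alleles; its binding-class
summary is ``strong`` when every supporting allele binds strongly,
``weak`` when all are weak, and ``ambiguous`` when mixed. The shared
frequency of a (mutation, HLA allele) pair is the product of the
mutation's population prevalence and the allele's carrier frequency —
the expected fraction of patients eligible for an off-the-shelf vaccine
targeting that pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binding import NeoantigenCandidate, candidates_to_frame
from .errors import DomainError
from .io import SomaticMutation

ENUMERABLE_CONSEQUENCES = ("missense", "inframe_indel")


def round_percent(fraction: float, ndigits: int = 2) -> float:
    """Express a fraction as a percentage rounded half-up to ``ndigits``.

    Reporting-layer rounding only; internal math stays at full
    precision. Half-up (not banker's) so 0.0292573 -> 2.93.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


def shared_frequency(mutation_prevalence: float, allele_carrier: float) -> float:
    """Population shared frequency of a (mutation, HLA allele) pair."""
    for name, v in (("mutation_prevalence", mutation_prevalence),
                    ("allele_carrier", allele_carrier)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} {v} outside [0, 1]")
    return mutation_prevalence * allele_carrier


# ---------------------------------------------------------------------------
# Prevalence


def _mutations_frame(mutations) -> pd.DataFrame:
    if isinstance(mutations, pd.DataFrame):
        return mutations
    rows = [
        (m.sample_id, m.gene, m.hgvs_p, m.consequence) for m in mutations
    ]
    return pd.DataFrame(rows, columns=["sample_id", "gene", "hgvs_p", "consequence"])


def prevalence_tables(
    mutations: Iterable[SomaticMutation] | pd.DataFrame,
    n_patients: int,
    include_frameshift: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level and variant-level prevalence tables.

    Prevalence is the fraction of the cohort carrying >=1 qualifying
    mutation; a patient with several distinct variants of a gene counts
    once at gene level. The main analysis counts missense and in-frame
    indels only; ``include_frameshift=True`` adds frameshift rows (the
    sensitivity recalculation for genes whose lesions are often
    truncating).
    """
    if n_patients < 1:
        raise DomainError("n_patients must be >= 1")
    df = _mutations_frame(mutations)
    keep = list(ENUMERABLE_CONSEQUENCES) + (
        ["frameshift"] if include_frameshift else []
    )
    q = df[df["consequence"].isin(keep)]
    gene = (
        q.drop_duplicates(["sample_id", "gene"])
        .groupby("gene")
        .size()
        .rename("n_patients_mut")
        .reset_index()
    )
    gene["prevalence"] = gene["n_patients_mut"] / n_patients
    gene = gene.sort_values(
        ["prevalence", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    variant = (
        q.drop_duplicates(["sample_id", "gene", "hgvs_p"])
        .groupby(["gene", "hgvs_p"])
        .size()
        .rename("n_patients_mut")
        .reset_index()
    )
    variant["prevalence"] = variant["n_patients_mut"] / n_patients
    variant = variant.sort_values(
        ["prevalence", "gene", "hgvs_p"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return gene, variant


# ---------------------------------------------------------------------------
# Unique neoantigens


def _candidates_frame(candidates) -> pd.DataFrame:
    if isinstance(candidates, pd.DataFrame):
        return candidates
    return candidates_to_frame(candidates)


def unique_neoantigens(
    candidates: Iterable[NeoantigenCandidate] | pd.DataFrame,
) -> pd.DataFrame:
    """Collapse candidate rows to unique (gene, hgvs_p, mt_peptide) entries.

    Columns: gene, hgvs_p, mt_peptide, alleles (comma-joined sorted),
    allele_classes (allele=class pairs), class_summary
    (strong/weak/ambiguous), n_alleles, n_samples.
    """
    df = _candidates_frame(candidates)
    if df.empty:
        return pd.DataFrame(
            columns=["gene", "hgvs_p", "mt_peptide", "alleles", "allele_classes",
                     "class_summary", "n_alleles", "n_samples"]
        )
    rows = []
    for (gene, hgvs_p, pep), grp in df.groupby(
        ["gene", "hgvs_p", "mt_peptide"], sort=True
    ):
        # per-allele class: a deterministic predictor gives one class per
        # allele; if rows disagree, the strongest observed binding wins
        per_allele = (
            grp.sort_values("ic50_mt").drop_duplicates("allele")
            .set_index("allele")["binding_class"]
            .sort_index()
        )
        classes = set(per_allele)
        summary = per_allele.iloc[0] if len(classes) == 1 else "ambiguous"
        rows.append(
            (
                gene, hgvs_p, pep,
                ",".join(per_allele.index),
                ",".join(f"{a}={c}" for a, c in per_allele.items()),
                summary,
                len(per_allele),
                grp["sample_id"].nunique(),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "hgvs_p", "mt_peptide", "alleles", "allele_classes",
                 "class_summary", "n_alleles", "n_samples"],
    )


def per_mutation_counts(
    candidates: Iterable[NeoantigenCandidate] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-variant neoantigen counts.

    ``n_pairs`` counts distinct (peptide, allele) candidate pairs,
    ``n_unique_peptides`` distinct mutant peptides, and
    ``n_strong_peptides`` distinct peptides with >=1 strong allele.
    """
    df = _candidates_frame(candidates)
    if df.empty:
        return pd.DataFrame(
            columns=["gene", "hgvs_p", "n_pairs", "n_unique_peptides",
                     "n_strong_peptides"]
        )
    rows = []
    for (gene, hgvs_p), grp in df.groupby(["gene", "hgvs_p"], sort=True):
        pairs = grp.drop_duplicates(["mt_peptide", "allele"])
        strong_peps = pairs.loc[pairs["binding_class"] == "strong", "mt_peptide"]
        rows.append(
            (gene, hgvs_p, len(pairs), pairs["mt_peptide"].nunique(),
             strong_peps.nunique())
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "hgvs_p", "n_pairs", "n_unique_peptides",
                 "n_strong_peptides"],
    )


# ---------------------------------------------------------------------------
# Neoantigen frequency


def neoantigen_frequency(
    uniques: pd.DataFrame,
    mutations: Iterable[SomaticMutation] | pd.DataFrame,
    n_patients: int,
    min_gene_prevalence: float = 0.01,
    min_gene_mutations: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene total and per-(gene, allele) neoantigen frequency.

    Frequency = number of unique neoantigens of the gene divided by the
    number of qualifying mutation occurrences targeting the gene
    cohort-wide (rows after per-patient variant dedup). The total counts
    a multi-allele neoantigen once; the allele-specific figure counts it
    for each allele and may exceed the total. Genes below the prevalence
    or occurrence filters are dropped.
    """
    mdf = _mutations_frame(mutations)
    q = mdf[mdf["consequence"].isin(ENUMERABLE_CONSEQUENCES)]
    occ = (
        q.drop_duplicates(["sample_id", "gene", "hgvs_p"])
        .groupby("gene")
        .size()
        .rename("n_mutations")
    )
    prev = (
        q.drop_duplicates(["sample_id", "gene"]).groupby("gene").size() / n_patients
    ).rename("prevalence")
    genes = pd.concat([occ, prev], axis=1)
    genes = genes[
        (genes["prevalence"] >= min_gene_prevalence)
        & (genes["n_mutations"] >= min_gene_mutations)
    ]

    total_rows = []
    allele_rows = []
    for gene, info in genes.iterrows():
        sub = uniques[uniques["gene"] == gene]
        denom = int(info["n_mutations"])
        total_rows.append((gene, len(sub), denom, len(sub) / denom))
        counts: dict[str, int] = {}
        for alleles in sub["alleles"]:
            for a in alleles.split(","):
                if a:
                    counts[a] = counts.get(a, 0) + 1
        for a in sorted(counts):
            allele_rows.append((gene, a, counts[a], denom, counts[a] / denom))
    total = pd.DataFrame(
        total_rows, columns=["gene", "n_neoantigens", "n_mutations", "frequency"]
    ).sort_values(["frequency", "gene"], ascending=[False, True]).reset_index(drop=True)
    per_allele = pd.DataFrame(
        allele_rows,
        columns=["gene", "allele", "n_neoantigens", "n_mutations", "frequency"],
    ).sort_values(
        ["gene", "frequency", "allele"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return total, per_allele


# ---------------------------------------------------------------------------
# Shared-candidate ranking


def shared_candidate_table(
    candidates: Iterable[NeoantigenCandidate] | pd.DataFrame,
    variant_prevalence: pd.DataFrame,
    allele_carrier: Mapping[str, float],
) -> pd.DataFrame:
    """Rank candidate (mutation, peptide, allele) triples by shared frequency.

    ``variant_prevalence`` is the variant-level table from
    :func:`prevalence_tables`; ``allele_carrier`` maps allele name to
    carrier frequency (observed cohort rate by default, or the
    Hardy-Weinberg formula value if computed from an AF table — the
    caller chooses which to supply). Ranking is by descending shared
    frequency with a stable (gene, hgvs_p, allele) lexicographic
    tie-break. The reported percentage is rounded half-up to 2 decimals.
    """
    df = _candidates_frame(candidates)
    prev_map = {
        (r.gene, r.hgvs_p): r.prevalence
        for r in variant_prevalence.itertuples()
    }
    pairs = df.drop_duplicates(["gene", "hgvs_p", "mt_peptide", "allele"])
    rows = []
    for r in pairs.itertuples():
        mp = prev_map.get((r.gene, r.hgvs_p))
        ac = allele_carrier.get(r.allele)
        if mp is None or ac is None:
            continue
        sf = shared_frequency(mp, ac)
        rows.append(
            (r.gene, r.hgvs_p, r.mt_peptide, r.allele, r.ic50_mt, r.ic50_wt,
             r.binding_class, mp, ac, sf, round_percent(sf))
        )
    out = pd.DataFrame(
        rows,
        columns=["gene", "hgvs_p", "mt_peptide", "allele", "ic50_mt", "ic50_wt",
                 "binding_class", "mutation_prevalence", "allele_carrier",
                 "shared_frequency", "shared_frequency_pct"],
    )
    out = out.sort_values(
        ["shared_frequency", "gene", "hgvs_p", "allele"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Binder-proportion comparison


@dataclass(frozen=True)
class BinderBreakdown:
    """2x2 strong/weak counts split by gene prevalence, with chi-square."""

    table: np.ndarray  # rows: low-prevalence, high-prevalence; cols: strong, weak
    chi2: float
    p_value: float
    chi2_uncorrected: float
    p_value_uncorrected: float
    defined: bool


def binder_breakdown_by_prevalence(
    uniques: pd.DataFrame,
    gene_prevalence: pd.DataFrame,
    cut: float = 0.01,
    yates: bool = True,
) -> BinderBreakdown:
    """Compare strong-binder proportions between rarely and frequently
    mutated genes.

    Each unique neoantigen is assigned to the "high" stratum when its
    gene's prevalence exceeds ``cut``. Ambiguous neoantigens count as
    strong (they bind >=1 allele strongly). Returns the contingency
    table with chi-square statistics both with and without Yates
    continuity correction; a zero margin leaves the statistic undefined
    (``defined=False``).
    """
    prev_map = dict(zip(gene_prevalence["gene"], gene_prevalence["prevalence"]))
    counts = np.zeros((2, 2), dtype=int)
    for r in uniques.itertuples():
        high = prev_map.get(r.gene, 0.0) > cut
        strong = r.class_summary in ("strong", "ambiguous")
        counts[1 if high else 0, 0 if strong else 1] += 1
    return chi_square_2x2(counts, yates=yates)


def chi_square_2x2(counts: np.ndarray, yates: bool = True) -> BinderBreakdown:
    counts = np.asarray(counts, dtype=int)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return BinderBreakdown(counts, float("nan"), float("nan"),
                               float("nan"), float("nan"), defined=False)
    chi2_c, p_c, _, _ = stats.chi2_contingency(counts, correction=yates)
    chi2_u, p_u, _, _ = stats.chi2_contingency(counts, correction=False)
    if yates:
        return BinderBreakdown(counts, chi2_c, p_c, chi2_u, p_u, defined=True)
    return BinderBreakdown(counts, chi2_u, p_u, chi2_u, p_u, defined=True)
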