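"""Immunogenomic feature summaries per patient and per subgroup.

Covers: EGFR driver subtype classification (L858R / exon-19 deletion /
other EGFR / wild-type), panel tumor mutational burden (raw count of
non-synonymous mutations), patient-level HLA loss-of-heterozygosity from
locus-level allele-imbalance calls, B2M aberration flagging, and the
subgroup comparisons (proportion tests, Kruskal-Wallis with pairwise
rank-sum post hocs under Benjamini-Hochberg adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, HgvsParseError
from .io import PatientRecord, SomaticMutation
from .peptides import is_stop_gain, parse_hgvs_p
from .prioritize import chi_square_2x2

log = logging.getLogger(__name__)

EGFR_SUBTYPES = ("L858R", "del19", "other", "WT")

# Protein-residue span of EGFR exon 19 (config value; the archetypal
# E746_A750del lies inside it).
EXON19_SPAN = (729, 761)

PROTEIN_ALTERING = ("missense", "inframe_indel", "frameshift")


def _is_protein_altering(mut: SomaticMutation) -> bool:
    if mut.consequence in PROTEIN_ALTERING:
        return True
    # stop-gains are filed under 'other' but do alter the protein
    return mut.consequence == "other" and is_stop_gain(mut.hgvs_p)


def classify_egfr(
    mutations: Iterable[SomaticMutation],
    exon19_span: tuple[int, int] = EXON19_SPAN,
) -> str:
    """Assign one EGFR driver subtype to a patient.

    Precedence L858R > del19 > other, so a (rare) co-mutated patient is
    labelled by the headline driver; precedence firing on a co-mutated
    patient is logged. del19 = any EGFR in-frame deletion overlapping
    the exon-19 protein span.
    """
    has_l858r = has_del19 = has_other = False
    for mut in mutations:
        if mut.gene != "EGFR" or not _is_protein_altering(mut):
            continue
        try:
            change = parse_hgvs_p(mut.hgvs_p)
        except HgvsParseError:
            has_other = True
            continue
        if (
            change.kind == "missense"
            and change.start == 858
            and change.ref_start == "L"
            and change.alt == "R"
        ):
            has_l858r = True
        elif (
            change.kind in ("inframe_del", "inframe_delins")
            and change.start <= exon19_span[1]
            and change.end >= exon19_span[0]
        ):
            has_del19 = True
        else:
            has_other = True
    if has_l858r:
        if has_del19 or has_other:
            log.info("EGFR co-mutated patient labelled L858R by precedence")
        return "L858R"
    if has_del19:
        if has_other:
            log.info("EGFR co-mutated patient labelled del19 by precedence")
        return "del19"
    if has_other:
        return "other"
    return "WT"


def tmb_count(mutations: Iterable[SomaticMutation]) -> int:
    """Panel TMB: raw count of non-synonymous (protein-altering) rows.

    Counts missense, in-frame indel, frameshift and stop-gain rows; no
    VAF filter beyond whatever was applied at ingest.
    """
    return sum(1 for m in mutations if _is_protein_altering(m))


def tmb_per_mb(count: int, panel_mb: float) -> float:
    """Optional per-megabase conversion (unused by the default report)."""
    if panel_mb <= 0:
        raise DomainError("panel size must be positive")
    return count / panel_mb


def b2m_flag(mutations: Iterable[SomaticMutation]) -> bool:
    """True iff the patient carries any protein-altering B2M mutation
    (frameshifts included: truncating lesions abolish class I assembly)."""
    return any(m.gene == "B2M" and _is_protein_altering(m) for m in mutations)


def hla_loh_patient(calls, alpha: float = 0.01) -> str:
    """Patient-level HLA LOH status from locus-level calls.

    ``affected`` when any heterozygous locus shows allele imbalance at
    ``pval_unique < alpha`` (strict); ``unaffected`` otherwise,
    including patients homozygous at every locus; ``not_evaluable`` only
    when the caller produced no output for the patient.
    """
    if calls is None:
        return "not_evaluable"
    calls = list(calls)
    if not calls:
        return "not_evaluable"
    loci = [c.locus for c in calls]
    if len(set(loci)) != len(loci):
        raise DomainError(f"duplicate locus in LOH calls: {sorted(loci)}")
    for c in calls:
        if c.heterozygous and c.pval_unique is not None and c.pval_unique < alpha:
            return "affected"
    return "unaffected"


# ---------------------------------------------------------------------------
# Feature table


FEATURE_COLUMNS = ("sample_id", "subtype", "tmb_count", "hla_loh", "b2m_aberrant")


def patient_feature_table(
    patients: Iterable[PatientRecord],
    loh_alpha: float = 0.01,
    exon19_span: tuple[int, int] = EXON19_SPAN,
) -> pd.DataFrame:
    rows = [
        (
            p.sample_id,
            classify_egfr(p.mutations, exon19_span),
            tmb_count(p.mutations),
            hla_loh_patient(p.loh_calls, loh_alpha),
            b2m_flag(p.mutations),
        )
        for p in patients
    ]
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


# ---------------------------------------------------------------------------
# Subgroup statistics


@dataclass(frozen=True)
class SubgroupComparison:
    """Per-group rates for one binary feature plus a chi-square comparison."""

    rates: pd.DataFrame  # group, n_evaluable, n_affected, rate
    chi2: float
    p_value: float
    defined: bool


def subgroup_rates(
    features: pd.DataFrame,
    group_col: str = "subtype",
) -> dict[str, SubgroupComparison]:
    """LOH and B2M rates per group with an overall chi-square comparison.

    LOH denominators exclude ``not_evaluable`` patients. Groups with no
    evaluable patients are excluded with a warning. When only one group
    survives, the comparison is undefined.
    """
    out: dict[str, SubgroupComparison] = {}

    loh = features[features["hla_loh"] != "not_evaluable"]
    out["hla_loh"] = _binary_comparison(
        loh, group_col, loh["hla_loh"] == "affected"
    )
    out["b2m"] = _binary_comparison(
        features, group_col, features["b2m_aberrant"].astype(bool)
    )
    return out


def _binary_comparison(df, group_col, affected: pd.Series) -> SubgroupComparison:
    work = pd.DataFrame({"group": df[group_col], "affected": affected.values if len(df) else []})
    rows = []
    for group, grp in work.groupby("group", sort=True):
        n = len(grp)
        if n == 0:
            log.warning("empty group %r excluded from comparison", group)
            continue
        k = int(grp["affected"].sum())
        rows.append((group, n, k, k / n))
    rates = pd.DataFrame(rows, columns=["group", "n_evaluable", "n_affected", "rate"])
    if len(rates) < 2:
        return SubgroupComparison(rates, float("nan"), float("nan"), defined=False)
    table = np.column_stack(
        [rates["n_affected"], rates["n_evaluable"] - rates["n_affected"]]
    )
    if (table.sum(axis=0) == 0).any():
        return SubgroupComparison(rates, float("nan"), float("nan"), defined=False)
    if table.shape[0] == 2:
        res = chi_square_2x2(table, yates=True)
        return SubgroupComparison(rates, res.chi2, res.p_value, res.defined)
    chi2, p, _, _ = stats.chi2_contingency(table)
    return SubgroupComparison(rates, chi2, p, defined=True)


@dataclass(frozen=True)
class KruskalResult:
    h_statistic: float
    p_value: float
    groups: tuple[str, ...]
    group_sizes: tuple[int, ...]
    medians: tuple[float, ...]
    pairwise: pd.DataFrame | None = field(default=None)


def kruskal_subtypes(
    values_by_group: Mapping[str, Sequence[float]],
    pairwise: bool = False,
) -> KruskalResult:
    """Kruskal-Wallis test across groups (midranks, tie correction).

    Groups with fewer than 2 observations are excluded with a warning.
    With ``pairwise=True``, all group pairs are compared by the
    two-sided Wilcoxon rank-sum test and adjusted by
    Benjamini-Hochberg.
    """
    kept: dict[str, np.ndarray] = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            log.warning("group %r has <2 observations; excluded", name)
            continue
        kept[name] = arr
    if len(kept) < 2:
        raise DomainError("kruskal_subtypes needs >=2 groups with >=2 observations")
    names = tuple(kept)
    samples = [kept[n] for n in names]
    if np.ptp(np.concatenate(samples)) == 0:
        # a single shared value everywhere: H is 0 by definition
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    pw = None
    if pairwise:
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                stat, pval = stats.ranksums(samples[i], samples[j])
                rows.append((names[i], names[j], stat, pval))
        pw = pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p_value"])
        pw["p_adjusted"] = stats.false_discovery_control(pw["p_value"], method="bh")
    return KruskalResult(
        h_statistic=float(h),
        p_value=float(p),
        groups=names,
        group_sizes=tuple(len(s) for s in samples),
        medians=tuple(float(np.median(s)) for s in samples),
        pairwise=pw,
    )
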