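"""Shared fixtures: tiny literature-derived tables and synthetic helpers."""

import pandas as pd
import pytest

from neoshare import worked_example as wx
from neoshare.binding import CANDIDATE_COLUMNS
from neoshare.io import HLAGenotype, SomaticMutation


@pytest.fixture(scope="session")
def published_table():
    """Published EGFR shared-neoantigen rows (mutation, peptide, allele, IC50s)."""
    return wx.PUBLISHED_SHARED_TABLE


@pytest.fixture()
def table1_candidates():
    """The published EGFR rows recast as candidate rows of one nominal sample.

    Binding classes follow the IC50 thresholds (<50 strong, <500 weak).
    """
    rows = []
    for r in wx.PUBLISHED_SHARED_TABLE:
        hgvs = f"p.{r.mutation}"
        cls = "strong" if r.ic50_mt < 50 else "weak"
        rows.append(("S1", "EGFR", hgvs, r.peptide, "WTPEPTIDE", r.allele,
                     r.ic50_mt, r.ic50_wt, cls))
    return pd.DataFrame(rows, columns=list(CANDIDATE_COLUMNS))


def make_genotype(sample_id, a=("A*11:01", "A*11:01"), b=("B*46:01", "B*40:01"),
                  c=("C*01:02", "C*07:02")):
    return HLAGenotype(sample_id=sample_id, alleles={"A": a, "B": b, "C": c})


def make_mutation(sample_id, gene="EGFR", hgvs_p="p.L858R", vaf=0.3,
                  consequence="missense", protein_id=None):
    return SomaticMutation(
        sample_id=sample_id, gene=gene,
        protein_id=protein_id or f"PROT_{gene}",
        hgvs_p=hgvs_p, vaf=vaf, consequence=consequence,
    )


@pytest.fixture()
def genotype_factory():
    return make_genotype


@pytest.fixture()
def mutation_factory():
    return make_mutation
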