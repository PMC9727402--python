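"""Literature worked example: EGFR driver neoepitopes in Chinese NSCLC.

Published values for the two dominant EGFR drivers — the exon-21
substitution L858R and the archetypal exon-19 deletion E746_A750del —
as reported for a 1862-patient Chinese NSCLC panel-sequencing cohort:
local protein context around each lesion, the candidate neoepitopes
with their netMHCpan-style mutant/wild-type IC50 predictions, and the
population prevalence / HLA carrier percentages that feed the
shared-frequency ranking. These are *inputs* for validation and for the
README example; nothing in the pipeline depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass

# Wild-type EGFR protein context around L858 (residues 850-867): the
# kinase-domain DFG motif region. L858 is position 9 of this fragment.
L858R_CONTEXT = "HVKITDFGLAKLLGAEEK"
L858R_CONTEXT_OFFSET = 850  # residue number of the fragment's first position

# Wild-type EGFR context around the exon-19 deletion (residues 740-758);
# E746..A750 = ELREA occupy fragment positions 7-11.
EX19DEL_CONTEXT = "IPVAIKELREATSPKANKE"
EX19DEL_CONTEXT_OFFSET = 740

# HGVS.p of the two drivers, in fragment-local coordinates.
L858R_LOCAL_HGVS = "p.L9R"
EX19DEL_LOCAL_HGVS = "p.E7_A11del"

# Expected mutant neoepitopes reported for these drivers.
L858R_PEPTIDES = ("HVKITDFGR", "RAKLLGAEEK")
EX19DEL_PEPTIDES = ("IPVAIKTSPK", "AIKTSPKANK")


@dataclass(frozen=True)
class PublishedSharedRow:
    """One row of the published shared-neoantigen table."""

    mutation: str
    peptide: str
    allele: str
    ic50_mt: float
    ic50_wt: float
    shared_pct: float


PUBLISHED_SHARED_TABLE = (
    PublishedSharedRow("L858R", "HVKITDFGR", "A*31:01", 18.9, 11653.7, 1.19),
    PublishedSharedRow("L858R", "HVKITDFGR", "A*33:03", 22.9, 12734.0, 2.93),
    PublishedSharedRow("L858R", "HVKITDFGR", "A*68:01", 19.6, 8625.5, 0.28),
    PublishedSharedRow("L858R", "RAKLLGAEEK", "A*30:01", 47.5, 881.9, 1.71),
    PublishedSharedRow("E746_A750del", "IPVAIKTSPK", "A*11:01", 158.2, 31132.7, 5.60),
    PublishedSharedRow("E746_A750del", "IPVAIKTSPK", "A*03:01", 70.7, 30763.0, 0.63),
    PublishedSharedRow("E746_A750del", "IPVAIKTSPK", "A*03:02", 376.4, 29825.9, 0.05),
    PublishedSharedRow("E746_A750del", "IPVAIKTSPK", "A*11:02", 158.2, 31132.7, 0.48),
    PublishedSharedRow("E746_A750del", "IPVAIKTSPK", "A*11:20", 65.1, 26653.4, 0.03),
    PublishedSharedRow("E746_A750del", "IPVAIKTSPK", "A*68:01", 429.6, 11669.5, 0.16),
    PublishedSharedRow("E746_A750del", "AIKTSPKANK", "A*30:01", 355.0, 5721.5, 1.00),
)

# Population prevalence of L858R and carrier frequencies of its
# restricting alleles, as percentages (the published shared-frequency
# worked example multiplies these).
L858R_PREVALENCE_PCT = 22.61
CARRIER_PCT = {"A*33:03": 12.94, "A*31:01": 5.26, "A*68:01": 1.24}
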