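"""Peptide-MHC binding prediction contract and threshold classification.

A predictor is any callable ``(peptide, allele) -> IC50 in nM``; a real
affinity model can be adapted behind that contract. The package ships a
deterministic toy predictor driven by planted allele-specific anchor
motifs, so every downstream stage is testable without external binaries
or network access.

Candidate calling follows the standard mutant-specific IC50 rule: a
mutant peptide is a candidate neoantigen when IC50(mutant) < 500 nM
while IC50(wild-type) >= 500 nM, and a strong binder when
IC50(mutant) < 50 nM. The mutant-side thresholds are strict (<), the
wild-type side inclusive (>=).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

import yaml

from .errors import DomainError, HgvsParseError
from .io import PatientRecord
from .peptides import (
    DEFAULT_LENGTHS,
    PeptidePair,
    enumerate_peptides,
    parse_hgvs_p,
)

IC50_CANDIDATE = 500.0  # nM, mutant must be strictly below
IC50_STRONG = 50.0  # nM, strong-binder cut on the mutant side

Predictor = Callable[[str, str], float]


def classify_pair(ic50_mt: float, ic50_wt: float) -> str:
    """Classify a mutant/wild-type IC50 pair: ``none`` | ``weak`` | ``strong``.

    ``none`` if the mutant is not a binder (>=500 nM) or the wild-type
    also binds (<500 nM); otherwise ``strong`` below 50 nM, else ``weak``.
    """
    if ic50_mt <= 0 or ic50_wt <= 0:
        raise DomainError("IC50 values must be positive")
    if ic50_mt >= IC50_CANDIDATE or ic50_wt < IC50_CANDIDATE:
        return "none"
    return "strong" if ic50_mt < IC50_STRONG else "weak"


# ---------------------------------------------------------------------------
# Toy predictor


@dataclass(frozen=True)
class AnchorMotif:
    """A planted anchor rule: required residue sets at fixed positions.

    Positions are 1-based; ``-1`` denotes the C-terminal residue. A
    peptide matching every anchor has its baseline IC50 divided by
    ``factor``, pulling it into the binder (or strong-binder) range.
    """

    anchors: tuple[tuple[int, frozenset[str]], ...]
    factor: float

    def matches(self, peptide: str) -> bool:
        for pos, residues in self.anchors:
            idx = pos - 1 if pos > 0 else len(peptide) + pos
            if idx < 0 or idx >= len(peptide):
                return False
            if peptide[idx] not in residues:
                return False
        return True


MotifTable = Mapping[str, tuple[AnchorMotif, ...]]

# Baseline IC50 range for motif-free peptides: log-uniform on [500, 50000) nM,
# i.e. never a binder without a motif hit.
_BASE_LO = 500.0
_BASE_SPAN = 100.0  # hi/lo ratio


class ToyPredictor:
    """Deterministic hash-based IC50 predictor with planted anchor motifs.

    The baseline affinity is a pure function of (peptide, allele, salt):
    a 64-bit blake2b digest mapped log-uniformly into [500, 50000) nM.
    Peptides matching one of the allele's anchor motifs are divided by
    the motif factor (the strongest matching motif wins), so
    motif-matching peptides land below 500 nM — or below 50 nM for
    strong motifs — while motif-free peptides never bind.
    """

    def __init__(self, motif_table: MotifTable | None = None, seed_salt: int = 0):
        self.motif_table = dict(motif_table or {})
        self.seed_salt = int(seed_salt)

    def baseline(self, peptide: str, allele: str) -> float:
        digest = hashlib.blake2b(
            f"{peptide}|{allele}|{self.seed_salt}".encode(), digest_size=8
        ).digest()
        u = int.from_bytes(digest, "big") / 2**64
        return _BASE_LO * _BASE_SPAN**u

    def __call__(self, peptide: str, allele: str) -> float:
        if not min(DEFAULT_LENGTHS) <= len(peptide) <= max(DEFAULT_LENGTHS):
            raise DomainError(
                f"peptide length {len(peptide)} outside "
                f"[{min(DEFAULT_LENGTHS)}, {max(DEFAULT_LENGTHS)}]"
            )
        ic50 = self.baseline(peptide, allele)
        factor = max(
            (m.factor for m in self.motif_table.get(allele, ()) if m.matches(peptide)),
            default=1.0,
        )
        return ic50 / factor


# Division factors: baseline is [500, 50000), so /1100 puts every strong-motif
# hit below 50 nM and /110 puts every weak-motif hit below 500 nM (mostly in
# the weak band, occasionally strong).
STRONG_FACTOR = 1100.0
WEAK_FACTOR = 110.0


def motif_table_to_yaml(table: MotifTable, path: str | Path) -> None:
    doc = {
        allele: [
            {
                "anchors": {int(pos): "".join(sorted(res)) for pos, res in m.anchors},
                "factor": m.factor,
            }
            for m in motifs
        ]
        for allele, motifs in table.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def motif_table_from_yaml(path: str | Path) -> dict[str, tuple[AnchorMotif, ...]]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    table: dict[str, tuple[AnchorMotif, ...]] = {}
    for allele, motifs in doc.items():
        table[allele] = tuple(
            AnchorMotif(
                anchors=tuple(
                    sorted(
                        (int(pos), frozenset(res))
                        for pos, res in m["anchors"].items()
                    )
                ),
                factor=float(m["factor"]),
            )
            for m in motifs
        )
    return table


def default_motif_table() -> dict[str, tuple[AnchorMotif, ...]]:
    """Anchor motifs for the common alleles of the default synthetic cohort.

    Coarse caricatures of real class I preferences: the A3 supertype
    members (A*11:01, A*31:01, A*33:03, A*68:01) favour basic C-termini;
    the arginine-preferring members get a strong C-terminal-R motif so
    an L->R substitution at a peptide terminus creates a strong binder
    whose wild-type counterpart does not bind.
    """
    cterm_R = AnchorMotif(anchors=((-1, frozenset("R")),), factor=STRONG_FACTOR)
    cterm_K_weak = AnchorMotif(anchors=((-1, frozenset("K")),), factor=WEAK_FACTOR)
    p1R_ctermK = AnchorMotif(
        anchors=((1, frozenset("R")), (-1, frozenset("K"))), factor=STRONG_FACTOR
    )
    # A*30:01's weak rule adds a P2 restriction so a C-terminal K alone
    # (common in wild-type windows) is not sufficient to bind
    p2_ctermK_weak = AnchorMotif(
        anchors=((2, frozenset("ITV")), (-1, frozenset("K"))), factor=WEAK_FACTOR
    )
    return {
        "A*33:03": (cterm_R,),
        "A*31:01": (cterm_R,),
        "A*68:01": (cterm_R,),
        "A*30:01": (p1R_ctermK, p2_ctermK_weak),
        "A*11:01": (cterm_K_weak,),
        "A*11:02": (cterm_K_weak,),
        "A*03:01": (cterm_K_weak,),
    }


def toy_predictor(
    peptide: str,
    allele: str,
    motif_table: MotifTable | None = None,
    seed_salt: int = 0,
) -> float:
    """Functional form of :class:`ToyPredictor` (pure in its arguments)."""
    return ToyPredictor(motif_table, seed_salt)(peptide, allele)


# ---------------------------------------------------------------------------
# Patient-level candidate calling


@dataclass(frozen=True)
class NeoantigenCandidate:
    """One (sample, mutation, mutant peptide, HLA allele) candidate row."""

    sample_id: str
    gene: str
    hgvs_p: str
    mt_peptide: str
    wt_peptide: str
    allele: str
    ic50_mt: float
    ic50_wt: float
    binding_class: str  # strong | weak


def call_patient_neoantigens(
    patient: PatientRecord,
    proteins: Mapping[str, str],
    predictor: Predictor,
    lengths: tuple[int, ...] = DEFAULT_LENGTHS,
    errors: list[str] | None = None,
) -> list[NeoantigenCandidate]:
    """Call candidate neoantigens for one patient.

    Each enumerable mutation is expanded to mutant/wild-type peptide
    pairs, predicted against each *distinct* allele of the patient
    (homozygous alleles queried once), and kept when the pair classifies
    weak or strong. Output rows are unique on
    (sample, gene, hgvs_p, mt_peptide, allele). Mutations whose protein
    is missing (or whose change mismatches the sequence) are skipped,
    logged into ``errors`` if given, and processing continues.
    """
    import logging

    log = logging.getLogger(__name__)
    alleles = patient.genotype.distinct_alleles()
    out: list[NeoantigenCandidate] = []
    seen: set[tuple[str, str, str, str]] = set()
    for mut in patient.mutations:
        pairs = _enumerable_pairs(mut, proteins, lengths, errors, log)
        if not pairs:
            continue
        for pair in pairs:
            for allele in alleles:
                key = (mut.gene, mut.hgvs_p, pair.mt_peptide, allele)
                if key in seen:
                    continue
                ic50_mt = predictor(pair.mt_peptide, allele)
                ic50_wt = predictor(pair.wt_peptide, allele)
                cls = classify_pair(ic50_mt, ic50_wt)
                if cls == "none":
                    continue
                seen.add(key)
                out.append(
                    NeoantigenCandidate(
                        sample_id=patient.sample_id,
                        gene=mut.gene,
                        hgvs_p=mut.hgvs_p,
                        mt_peptide=pair.mt_peptide,
                        wt_peptide=pair.wt_peptide,
                        allele=allele,
                        ic50_mt=ic50_mt,
                        ic50_wt=ic50_wt,
                        binding_class=cls,
                    )
                )
    return out


def _enumerable_pairs(mut, proteins, lengths, errors, log) -> list[PeptidePair]:
    from .errors import NonEnumerableError, ReferenceMismatchError

    try:
        change = parse_hgvs_p(mut.hgvs_p)
    except HgvsParseError:
        return []
    if not change.enumerable:
        return []
    seq = proteins.get(mut.protein_id)
    if seq is None:
        msg = f"{mut.sample_id}: protein {mut.protein_id!r} not in FASTA ({mut.hgvs_p})"
        log.warning(msg)
        if errors is not None:
            errors.append(msg)
        return []
    try:
        return enumerate_peptides(seq, change, lengths)
    except (ReferenceMismatchError, NonEnumerableError) as exc:
        msg = f"{mut.sample_id}: {mut.gene} {mut.hgvs_p}: {exc}"
        log.warning(msg)
        if errors is not None:
            errors.append(msg)
        return []


def call_cohort_neoantigens(
    patients: Iterable[PatientRecord],
    proteins: Mapping[str, str],
    predictor: Predictor,
    lengths: tuple[int, ...] = DEFAULT_LENGTHS,
    errors: list[str] | None = None,
) -> list[NeoantigenCandidate]:
    out: list[NeoantigenCandidate] = []
    for patient in patients:
        out.extend(
            call_patient_neoantigens(patient, proteins, predictor, lengths, errors)
        )
    return out


CANDIDATE_COLUMNS = (
    "sample_id", "gene", "hgvs_p", "mt_peptide", "wt_peptide",
    "allele", "ic50_mt", "ic50_wt", "binding_class",
)


def candidates_to_frame(candidates: Iterable[NeoantigenCandidate]):
    import pandas as pd

    rows = [
        (c.sample_id, c.gene, c.hgvs_p, c.mt_peptide, c.wt_peptide,
         c.allele, c.ic50_mt, c.ic50_wt, c.binding_class)
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=list(CANDIDATE_COLUMNS))
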