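"""Cohort data model and readers/writers for the pipeline's tabular inputs.

All tables are tab-separated UTF-8 with a header row; ``.`` or an empty
field means missing. Protein sequences travel as FASTA (first
whitespace-delimited header token = protein id). Output tables are
written with a deterministic column order and row sort (sample_id, then
gene, then hgvs_p) so runs are byte-reproducible.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, RowError
from .peptides import infer_consequence

LOCI = ("A", "B", "C")
CONSEQUENCES = ("missense", "inframe_indel", "frameshift", "other")

_ALLELE_RE = re.compile(r"^([ABCabc])\s*\*\s*(\d+):(\d+)(?::\S+)?$")


def normalize_allele(name: str) -> str:
    """Canonicalize an HLA class I allele name to four-digit ``X*nn:nn``.

    Uppercases the locus, zero-pads both fields to two digits, and
    discards resolution beyond two fields (``A*33:03:01`` → ``A*33:03``).
    """
    m = _ALLELE_RE.match(name.strip())
    if not m:
        raise ValueError(f"malformed HLA allele name: {name!r}")
    locus, f1, f2 = m.groups()
    return f"{locus.upper()}*{int(f1):02d}:{int(f2):02d}"


@dataclass(frozen=True)
class HLAGenotype:
    """Four-digit HLA class I genotype of one patient (two slots per locus)."""

    sample_id: str
    alleles: Mapping[str, tuple[str, str]]  # locus -> ordered allele pair

    def __post_init__(self):
        for locus in LOCI:
            if locus not in self.alleles or len(self.alleles[locus]) != 2:
                raise ValueError(
                    f"{self.sample_id}: genotype needs exactly two alleles at locus {locus}"
                )

    def is_homozygous(self, locus: str) -> bool:
        a1, a2 = self.alleles[locus]
        return a1 == a2

    def distinct_alleles(self) -> tuple[str, ...]:
        """Distinct alleles over all loci, in first-seen order."""
        seen: dict[str, None] = {}
        for locus in LOCI:
            for a in self.alleles[locus]:
                seen.setdefault(a)
        return tuple(seen)


@dataclass(frozen=True)
class SomaticMutation:
    sample_id: str
    gene: str
    protein_id: str
    hgvs_p: str
    vaf: float
    consequence: str

    def __post_init__(self):
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


@dataclass(frozen=True)
class LocusLohCall:
    """One locus-level allele-imbalance call (allele-specific CN caller output)."""

    sample_id: str
    locus: str
    heterozygous: bool
    pval_unique: float | None

    def __post_init__(self):
        if self.locus not in LOCI:
            raise ValueError(f"unknown HLA locus {self.locus!r}")
        if self.heterozygous and self.pval_unique is None:
            raise ValueError("heterozygous locus call is missing pval_unique")
        if not self.heterozygous and self.pval_unique is not None:
            raise ValueError("homozygous locus call must not carry pval_unique")
        if self.pval_unique is not None and not 0.0 <= self.pval_unique <= 1.0:
            raise ValueError(f"pval_unique {self.pval_unique} outside [0, 1]")


@dataclass
class PatientRecord:
    sample_id: str
    genotype: HLAGenotype
    mutations: list[SomaticMutation] = field(default_factory=list)
    loh_calls: list[LocusLohCall] | None = None


# ---------------------------------------------------------------------------
# TSV helpers


def _open_rows(path: str | Path, required: tuple[str, ...]):
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames
        if header is None:
            raise FormatError(f"{path}: empty file, header row required")
        lower = {h.lower(): h for h in header}
        for col in required:
            if col.lower() not in lower:
                raise FormatError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            yield lineno, {k.lower(): v for k, v in row.items() if k is not None}


def _missing(value: str | None) -> bool:
    return value is None or value.strip() in ("", ".")


def _parse_float(value: str, name: str, lineno: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(f"unparseable {name} {value!r}", lineno) from None


def _parse_bool(value: str, lineno: int) -> bool:
    v = value.strip().lower()
    if v in ("true", "t", "1", "yes"):
        return True
    if v in ("false", "f", "0", "no"):
        return False
    raise RowError(f"unparseable boolean {value!r}", lineno)


# ---------------------------------------------------------------------------
# Mutations

MUTATION_COLUMNS = ("sample_id", "gene", "protein_id", "hgvs_p", "vaf", "consequence")


def read_mutations(path: str | Path, min_vaf: float = 0.05) -> list[SomaticMutation]:
    """Read a somatic-mutation TSV, dropping rows with VAF below ``min_vaf``.

    The VAF boundary is inclusive: a row at exactly ``min_vaf`` is
    retained. The ``consequence`` column is optional; when absent or
    missing it is inferred from ``hgvs_p``. File order is preserved.
    """
    out: list[SomaticMutation] = []
    for lineno, row in _open_rows(path, MUTATION_COLUMNS[:5]):
        vaf = _parse_float(row["vaf"], "vaf", lineno)
        if not 0.0 <= vaf <= 1.0:
            raise RowError(f"vaf {vaf} outside [0, 1]", lineno)
        if vaf < min_vaf:
            continue
        hgvs_p = row["hgvs_p"].strip()
        cons = row.get("consequence")
        if _missing(cons):
            cons = infer_consequence(hgvs_p)
        else:
            cons = cons.strip().lower()
            if cons not in CONSEQUENCES:
                raise RowError(f"unknown consequence {cons!r}", lineno)
            inferred = infer_consequence(hgvs_p)
            # the hgvs-derived class must agree when both are informative
            if inferred != "other" and cons != "other" and inferred != cons:
                raise RowError(
                    f"consequence {cons!r} inconsistent with hgvs_p "
                    f"{hgvs_p!r} (parsed as {inferred})",
                    lineno,
                )
        try:
            out.append(
                SomaticMutation(
                    sample_id=row["sample_id"].strip(),
                    gene=row["gene"].strip(),
                    protein_id=row["protein_id"].strip(),
                    hgvs_p=hgvs_p,
                    vaf=vaf,
                    consequence=cons,
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), lineno) from None
    return out


def write_mutations(mutations: Iterable[SomaticMutation], path: str | Path) -> None:
    rows = sorted(mutations, key=lambda m: (m.sample_id, m.gene, m.hgvs_p))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MUTATION_COLUMNS)
        for m in rows:
            w.writerow([m.sample_id, m.gene, m.protein_id, m.hgvs_p,
                        f"{m.vaf:.4f}", m.consequence])


# ---------------------------------------------------------------------------
# HLA genotypes

HLA_COLUMNS = ("sample_id", "a1", "a2", "b1", "b2", "c1", "c2")


def read_hla(path: str | Path) -> list[HLAGenotype]:
    """Read a genotype TSV (six allele columns A1..C2), normalizing names."""
    out: list[HLAGenotype] = []
    for lineno, row in _open_rows(path, HLA_COLUMNS):
        alleles = {}
        for locus in LOCI:
            pair = []
            for slot in (1, 2):
                raw = row[f"{locus.lower()}{slot}"]
                try:
                    pair.append(normalize_allele(raw))
                except ValueError as exc:
                    raise RowError(str(exc), lineno) from None
            a1, a2 = pair
            if not a1.startswith(locus) or not a2.startswith(locus):
                raise RowError(
                    f"allele from wrong locus in column {locus}1/{locus}2", lineno
                )
            alleles[locus] = (a1, a2)
        out.append(HLAGenotype(sample_id=row["sample_id"].strip(), alleles=alleles))
    return out


def write_hla(genotypes: Iterable[HLAGenotype], path: str | Path) -> None:
    rows = sorted(genotypes, key=lambda g: g.sample_id)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "A1", "A2", "B1", "B2", "C1", "C2"])
        for g in rows:
            w.writerow([g.sample_id] + [a for locus in LOCI for a in g.alleles[locus]])


# ---------------------------------------------------------------------------
# FASTA

_SEQ_OK_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXU\*]+$")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into an id → uppercased sequence mapping.

    Non-standard residues (U, X) are permitted but flagged with a
    warning; duplicate ids are a format error.
    """
    import logging

    log = logging.getLogger(__name__)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in out:
            raise FormatError(f"{path}: duplicate FASTA id {pid!r}")
        seq = str(rec.seq).upper()
        if not _SEQ_OK_RE.match(seq):
            raise FormatError(f"{path}: {pid}: non-amino-acid characters in sequence")
        if "U" in seq or "X" in seq:
            log.warning("%s: sequence contains ambiguous residues (U/X)", pid)
        out[pid] = seq
    return out


def write_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in sorted(proteins.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# HLA LOH calls

LOH_COLUMNS = ("sample_id", "locus", "heterozygous", "pval_unique")


def read_loh_calls(path: str | Path) -> list[LocusLohCall]:
    """Read locus-level LOH calls (column contract mirrors the upstream
    allele-specific HLA copy-number caller: sample, locus, heterozygous
    flag, ``PVal_unique``)."""
    out: list[LocusLohCall] = []
    for lineno, row in _open_rows(path, LOH_COLUMNS):
        het = _parse_bool(row["heterozygous"], lineno)
        pval_raw = row["pval_unique"]
        pval = None if _missing(pval_raw) else _parse_float(pval_raw, "pval_unique", lineno)
        try:
            out.append(
                LocusLohCall(
                    sample_id=row["sample_id"].strip(),
                    locus=row["locus"].strip().upper(),
                    heterozygous=het,
                    pval_unique=pval,
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), lineno) from None
    return out


def write_loh_calls(calls: Iterable[LocusLohCall], path: str | Path) -> None:
    rows = sorted(calls, key=lambda c: (c.sample_id, c.locus))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "locus", "heterozygous", "PVal_unique"])
        for c in rows:
            w.writerow([
                c.sample_id, c.locus, str(c.heterozygous),
                "." if c.pval_unique is None else f"{c.pval_unique:.6g}",
            ])


# ---------------------------------------------------------------------------
# Assembly


def assemble_patients(
    genotypes: Iterable[HLAGenotype],
    mutations: Iterable[SomaticMutation] = (),
    loh_calls: Iterable[LocusLohCall] | None = None,
) -> list[PatientRecord]:
    """Join genotypes, mutations and LOH calls into per-patient records.

    A patient with no LOH rows gets ``loh_calls=None`` (not evaluable),
    distinct from an empty list. Mutations for unknown samples raise.
    """
    by_sample: dict[str, PatientRecord] = {}
    for g in genotypes:
        if g.sample_id in by_sample:
            raise FormatError(f"duplicate genotype for sample {g.sample_id}")
        by_sample[g.sample_id] = PatientRecord(sample_id=g.sample_id, genotype=g)
    for m in mutations:
        if m.sample_id not in by_sample:
            raise FormatError(f"mutation for unknown sample {m.sample_id}")
        by_sample[m.sample_id].mutations.append(m)
    if loh_calls is not None:
        for c in loh_calls:
            rec = by_sample.get(c.sample_id)
            if rec is None:
                raise FormatError(f"LOH call for unknown sample {c.sample_id}")
            if rec.loh_calls is None:
                rec.loh_calls = []
            rec.loh_calls.append(c)
    return list(by_sample.values())
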