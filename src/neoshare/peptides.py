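"""Protein-level variant interpretation and neoepitope window enumeration.

Parses a practical subset of HGVS.p nomenclature (missense, in-frame
deletion / delins / insertion / duplication, frameshift, stop-gain,
synonymous), applies enumerable changes to a wild-type protein sequence,
and enumerates every 8-11-mer mutant/wild-type peptide pair whose window
spans the change — the peptide substrate for MHC class I binding
prediction.

Coordinates are 1-based residue indices with closed intervals, following
HGVS convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .errors import HgvsParseError, NonEnumerableError, ReferenceMismatchError

log = logging.getLogger(__name__)

DEFAULT_LENGTHS = (8, 9, 10, 11)

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Sec": "U", "Ter": "*",
}

# Residues that invalidate a peptide window (unknown / non-standard).
AMBIGUOUS_RESIDUES = frozenset("XU*")

ENUMERABLE_KINDS = frozenset(
    {"missense", "inframe_del", "inframe_delins", "inframe_ins"}
)


@dataclass(frozen=True)
class ProteinChange:
    """A parsed protein-level sequence change.

    ``start``/``end`` delimit the affected wild-type residues (for pure
    insertions they are the two flanking residues). ``ref_start`` and
    ``ref_end`` are the asserted wild-type residues at those positions;
    the full reference stretch of a multi-residue deletion is only
    validated against the sequence when the change is applied. ``alt``
    is the replacement stretch ('' for a pure deletion; the inserted
    stretch for insertions).
    """

    kind: str  # missense | inframe_del | inframe_delins | inframe_ins | frameshift | other
    start: int
    end: int
    ref_start: str = ""
    ref_end: str = ""
    alt: str = ""
    raw: str = ""

    @property
    def enumerable(self) -> bool:
        return self.kind in ENUMERABLE_KINDS

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise HgvsParseError(self.raw or str(self), "invalid residue interval")


def _aa(token: str, raw: str) -> str:
    """Normalize a 1- or 3-letter residue token to 1-letter code."""
    if len(token) == 1:
        if token.upper() in "ACDEFGHIKLMNPQRSTVWYXU*":
            return token.upper()
        raise HgvsParseError(raw, f"unknown residue {token!r}")
    one = AA3_TO_1.get(token.capitalize())
    if one is None:
        raise HgvsParseError(raw, f"unknown residue {token!r}")
    return one


_RES = r"(?:[A-Z\*]|[A-Za-z]{3})"
_FS_RE = re.compile(
    rf"^({_RES})(\d+)({_RES})?fs(?:\*|Ter)?\d*$", re.IGNORECASE
)
_MISSENSE_RE = re.compile(rf"^({_RES})(\d+)({_RES}|=)$")
_DEL_RE = re.compile(rf"^({_RES})(\d+)(?:_({_RES})(\d+))?del$")
_DELINS_RE = re.compile(rf"^({_RES})(\d+)(?:_({_RES})(\d+))?delins((?:{_RES})+)$")
_INS_RE = re.compile(rf"^({_RES})(\d+)_({_RES})(\d+)ins((?:{_RES})+)$")
_DUP_RE = re.compile(rf"^({_RES})(\d+)(?:_({_RES})(\d+))?dup$")
_ALT_SPLIT_RE = re.compile(r"[A-Z\*]|[A-Za-z]{3}")


def _split_residues(stretch: str, raw: str) -> str:
    """Convert a residue stretch (1- or 3-letter run) to 1-letter codes."""
    if stretch.isupper() and all(c in "ACDEFGHIKLMNPQRSTVWYXU*" for c in stretch):
        return stretch
    tokens = _ALT_SPLIT_RE.findall(stretch)
    if "".join(tokens) != stretch:
        raise HgvsParseError(raw, f"unparseable residue stretch {stretch!r}")
    return "".join(_aa(t, raw) for t in tokens)


def parse_hgvs_p(text: str) -> ProteinChange:
    """Parse an HGVS.p description into a :class:`ProteinChange`.

    Accepts 1-letter or 3-letter residue codes, with or without the
    ``p.`` prefix and surrounding parentheses. Frameshift, stop-gain and
    synonymous changes parse but are flagged non-enumerable
    (``kind='frameshift'`` / ``'other'``).
    """
    raw = text
    body = text.strip()
    if body.lower().startswith("p."):
        body = body[2:]
    body = body.strip("()")
    if not body:
        raise HgvsParseError(raw, "empty")
    if body == "=":
        raise HgvsParseError(raw, "synonymous change carries no position")

    m = _FS_RE.match(body)
    # 'fs' suffix is case-insensitive but a 3-letter residue like 'Phefs'
    # must split correctly; the regex handles this by greedy residue match.
    if m:
        ref = _aa(m.group(1), raw)
        pos = int(m.group(2))
        return ProteinChange(
            kind="frameshift", start=pos, end=pos, ref_start=ref, ref_end=ref, raw=raw
        )

    m = _DELINS_RE.match(body)
    if m:
        r1, p1, r2, p2, alt = m.groups()
        start, end = int(p1), int(p2 or p1)
        return ProteinChange(
            kind="inframe_delins",
            start=start,
            end=end,
            ref_start=_aa(r1, raw),
            ref_end=_aa(r2, raw) if r2 else _aa(r1, raw),
            alt=_split_residues(alt, raw),
            raw=raw,
        )

    m = _DEL_RE.match(body)
    if m:
        r1, p1, r2, p2 = m.groups()
        start, end = int(p1), int(p2 or p1)
        return ProteinChange(
            kind="inframe_del",
            start=start,
            end=end,
            ref_start=_aa(r1, raw),
            ref_end=_aa(r2, raw) if r2 else _aa(r1, raw),
            alt="",
            raw=raw,
        )

    m = _INS_RE.match(body)
    if m:
        r1, p1, r2, p2, alt = m.groups()
        start, end = int(p1), int(p2)
        if end != start + 1:
            raise HgvsParseError(raw, "insertion flanks must be adjacent")
        return ProteinChange(
            kind="inframe_ins",
            start=start,
            end=end,
            ref_start=_aa(r1, raw),
            ref_end=_aa(r2, raw),
            alt=_split_residues(alt, raw),
            raw=raw,
        )

    m = _DUP_RE.match(body)
    if m:
        r1, p1, r2, p2 = m.groups()
        start, end = int(p1), int(p2 or p1)
        # Duplication = insertion of the [start,end] stretch after end;
        # alt is resolved from the sequence at apply time.
        return ProteinChange(
            kind="inframe_delins",
            start=start,
            end=end,
            ref_start=_aa(r1, raw),
            ref_end=_aa(r2, raw) if r2 else _aa(r1, raw),
            alt="<dup>",
            raw=raw,
        )

    m = _MISSENSE_RE.match(body)
    if m:
        ref = _aa(m.group(1), raw)
        pos = int(m.group(2))
        alt_tok = m.group(3)
        if alt_tok == "=":
            return ProteinChange(
                kind="other", start=pos, end=pos, ref_start=ref, ref_end=ref,
                alt=ref, raw=raw,
            )
        alt = _aa(alt_tok, raw)
        if alt == "*":
            # stop-gain: parseable, excluded from enumeration
            return ProteinChange(
                kind="other", start=pos, end=pos, ref_start=ref, ref_end=ref,
                alt="*", raw=raw,
            )
        if alt == ref:
            return ProteinChange(
                kind="other", start=pos, end=pos, ref_start=ref, ref_end=ref,
                alt=alt, raw=raw,
            )
        return ProteinChange(
            kind="missense", start=pos, end=pos, ref_start=ref, ref_end=ref,
            alt=alt, raw=raw,
        )

    raise HgvsParseError(raw)


def infer_consequence(hgvs_p: str) -> str:
    """Map an HGVS.p string to a coarse consequence class.

    Returns one of ``missense``, ``inframe_indel``, ``frameshift``,
    ``other`` (stop-gain, synonymous and anything unparseable fall into
    ``other``).
    """
    try:
        change = parse_hgvs_p(hgvs_p)
    except HgvsParseError:
        return "other"
    if change.kind == "missense":
        return "missense"
    if change.kind in ("inframe_del", "inframe_delins", "inframe_ins"):
        return "inframe_indel"
    if change.kind == "frameshift":
        return "frameshift"
    return "other"


def is_stop_gain(hgvs_p: str) -> bool:
    try:
        change = parse_hgvs_p(hgvs_p)
    except HgvsParseError:
        return False
    return change.kind == "other" and change.alt == "*"


def _check_ref(seq: str, pos: int, expected: str) -> None:
    if pos > len(seq):
        raise ReferenceMismatchError(pos, expected, "<beyond sequence end>")
    observed = seq[pos - 1]
    if expected and observed != expected:
        raise ReferenceMismatchError(pos, expected, observed)


def apply_change(wt_seq: str, change: ProteinChange) -> str:
    """Apply an enumerable change to a wild-type sequence.

    Validates the asserted reference residues at both ends of the
    affected interval before editing and raises
    :class:`ReferenceMismatchError` on disagreement.
    """
    if not change.enumerable:
        raise NonEnumerableError(
            f"{change.raw or change.kind}: {change.kind} changes cannot be applied "
            "to the protein sequence"
        )
    if change.end > len(wt_seq):
        raise ReferenceMismatchError(change.end, change.ref_end, "<beyond sequence end>")
    _check_ref(wt_seq, change.start, change.ref_start)
    _check_ref(wt_seq, change.end, change.ref_end)

    if change.kind == "inframe_ins":
        return wt_seq[: change.start] + change.alt + wt_seq[change.start:]
    alt = change.alt
    if alt == "<dup>":  # duplication resolved against the sequence
        dup = wt_seq[change.start - 1 : change.end]
        return wt_seq[: change.end] + dup + wt_seq[change.end :]
    return wt_seq[: change.start - 1] + alt + wt_seq[change.end :]


@dataclass(frozen=True)
class PeptidePair:
    """An aligned mutant/wild-type k-mer spanning the change.

    ``mt_start`` is the 1-based start of the mutant window in the mutant
    protein; the wild-type window is the coordinate-matched same-length
    window of the wild-type protein.
    """

    mt_peptide: str
    wt_peptide: str
    length: int
    mt_start: int
    spans_change: bool = field(default=True)


def _mutant_change_interval(change: ProteinChange, mt_len: int) -> tuple[int, int, bool]:
    """Return (c1, c2, require_containment) in mutant coordinates.

    For substitutions and replacements the window must overlap
    [c1, c2] (the altered residues). For pure deletions the interval is
    the two residues juxtaposed at the junction and the window must
    contain both.
    """
    if change.kind == "missense":
        return change.start, change.start, False
    if change.kind == "inframe_ins":
        c1 = change.start + 1
        return c1, c1 + len(change.alt) - 1, False
    if change.kind == "inframe_delins":
        if change.alt == "<dup>":
            c1 = change.end + 1
            return c1, c1 + (change.end - change.start), False
        if change.alt:
            return change.start, change.start + len(change.alt) - 1, False
        # delins to nothing degenerates to a deletion
    # pure deletion: junction between start-1 and start (mutant coords)
    c1 = max(1, change.start - 1)
    c2 = min(mt_len, change.start)
    return c1, c2, True


def _wt_start_for(change: ProteinChange, mt_start: int) -> int:
    """Map a mutant window start to the coordinate-matched wild-type start."""
    if mt_start < change.start:
        return mt_start
    if change.kind == "inframe_ins":
        shift = -len(change.alt)
    elif change.alt == "<dup>":
        shift = -(change.end - change.start + 1)
    else:
        shift = (change.end - change.start + 1) - len(change.alt)
    return mt_start + shift


def enumerate_peptides(
    wt_seq: str,
    change: ProteinChange,
    lengths: tuple[int, ...] = DEFAULT_LENGTHS,
) -> list[PeptidePair]:
    """Enumerate all mutant/wild-type peptide pairs spanning a change.

    Missense: every window of each requested length containing the
    substituted residue. In-frame indels: every window overlapping the
    altered stretch (deletions: containing both junction-flank
    residues). Windows are truncated at the protein termini — short
    windows are not emitted — and pairs whose mutant and wild-type
    peptides coincide are dropped. Windows containing ambiguous
    residues (X, U, *) are skipped with a warning.

    Raises :class:`NonEnumerableError` for frameshift/stop-gain input
    ("frameshift mutations excluded").
    """
    if not change.enumerable:
        raise NonEnumerableError(
            f"{change.raw or change.kind}: frameshift and stop-gain mutations "
            "are excluded from neoepitope enumeration"
        )
    mt_seq = apply_change(wt_seq, change)
    c1, c2, contain = _mutant_change_interval(change, len(mt_seq))

    pairs: list[PeptidePair] = []
    for k in lengths:
        if contain:
            lo, hi = c2 - k + 1, c1
        else:
            lo, hi = c1 - k + 1, c2
        lo = max(1, lo)
        hi = min(hi, len(mt_seq) - k + 1)
        for s in range(lo, hi + 1):
            mt_pep = mt_seq[s - 1 : s - 1 + k]
            ws = _wt_start_for(change, s)
            if ws < 1:
                continue
            wt_pep = wt_seq[ws - 1 : ws - 1 + k]
            if len(wt_pep) < k:
                continue
            if mt_pep == wt_pep:
                continue
            bad = AMBIGUOUS_RESIDUES.intersection(mt_pep) or AMBIGUOUS_RESIDUES.intersection(wt_pep)
            if bad:
                log.warning(
                    "skipping window at %d (length %d): ambiguous residue(s) %s",
                    s, k, ",".join(sorted(bad)),
                )
                continue
            pairs.append(PeptidePair(mt_pep, wt_pep, k, s))
    return pairs
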