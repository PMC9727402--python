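"""Synthetic NSCLC panel cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a large Chinese NSCLC
targeted-sequencing cohort so every pipeline stage can be exercised and
validated without patient data:

* HLA class I genotypes drawn per locus under Hardy-Weinberg from an
  allele-frequency spectrum with a few common alleles (top A-locus
  allele AF 0.2423, carrier ~43%) and a long uniform tail;
* two dominant EGFR driver hotspots (an L858R-like substitution at
  prevalence 0.2261 and an exon-19-deletion-like indel at 0.13) over a
  long tail of rare background variants;
* subtype-specific non-synonymous mutation counts (negative binomial)
  tuned so the theoretical per-subtype medians are 3 / 3 / 4 / 5 for
  L858R / del19 / other-EGFR / wild-type;
* locus-level HLA LOH p-values from a two-component mixture giving a
  tunable patient-level LOH rate (default 0.631) with a small
  not-evaluable fraction;
* rare B2M truncating lesions (default 7/1862).

The EGFR-like protein carries the published local contexts around both
driver lesions, so the planted hotspots reproduce the literature
neoepitopes verbatim. All randomness flows from the single config seed;
identical configs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import worked_example as wx
from .binding import (
    AnchorMotif,
    MotifTable,
    ToyPredictor,
    call_cohort_neoantigens,
    candidates_to_frame,
    default_motif_table,
)
from .errors import DomainError
from .features import patient_feature_table
from .hla import allele_frequencies
from .io import (
    LOCI,
    HLAGenotype,
    LocusLohCall,
    PatientRecord,
    SomaticMutation,
    assemble_patients,
    write_fasta,
    write_hla,
    write_loh_calls,
    write_mutations,
)
from .prioritize import prevalence_tables, shared_candidate_table

# Internal seed for the fixed synthetic protein panel (independent of the
# cohort seed so the FASTA is identical across cohorts).
_PANEL_SEED = 7021862

_AA20 = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class Hotspot:
    """A planted recurrent driver variant."""

    gene: str
    hgvs_p: str
    prevalence: float
    subtype: str  # EGFR subtype the hotspot defines
    consequence: str


def _default_allele_af() -> dict[str, dict[str, float]]:
    """Per-locus allele -> AF tables (a few common alleles + uniform tail).

    The A-locus head is back-solved from published carrier percentages
    via AF = 1 - sqrt(1 - carrier): A*11:01 0.2423 (carrier 42.59%),
    A*33:03 0.0670 (12.94%), A*31:01 0.0267 (5.26%), A*68:01 0.0062
    (1.24%), A*30:01 0.0386 (7.56%).
    """
    a_head = {
        "A*11:01": 0.2423, "A*24:02": 0.16, "A*02:01": 0.10, "A*02:07": 0.06,
        "A*33:03": 0.0670, "A*02:06": 0.05, "A*30:01": 0.0386,
        "A*31:01": 0.0267, "A*26:01": 0.02, "A*68:01": 0.0062,
    }
    a_tail = ["A*01:01", "A*03:01", "A*11:02", "A*29:01", "A*32:01", "A*33:01",
              "A*34:01", "A*36:01", "A*43:01", "A*66:01", "A*69:01", "A*74:01"]
    b_head = {
        "B*46:01": 0.13, "B*40:01": 0.13, "B*58:01": 0.08, "B*13:01": 0.07,
        "B*15:01": 0.05, "B*51:01": 0.05, "B*38:02": 0.04, "B*54:01": 0.03,
    }
    b_tail = ["B*07:02", "B*08:01", "B*15:02", "B*18:01", "B*27:04", "B*35:01",
              "B*37:01", "B*39:01", "B*40:02", "B*44:03", "B*48:01", "B*55:02",
              "B*56:01", "B*67:01"]
    c_head = {
        "C*01:02": 0.17, "C*07:02": 0.14, "C*03:04": 0.10, "C*06:02": 0.07,
        "C*08:01": 0.06, "C*03:02": 0.05,
    }
    c_tail = ["C*01:03", "C*03:03", "C*04:01", "C*04:03", "C*05:01", "C*07:01",
              "C*07:04", "C*08:03", "C*12:02", "C*12:03", "C*14:02", "C*15:02",
              "C*15:05", "C*16:02"]
    out = {}
    for locus, head, tail in (("A", a_head, a_tail), ("B", b_head, b_tail),
                              ("C", c_head, c_tail)):
        table = dict(head)
        rem = 1.0 - sum(head.values())
        for allele in tail:
            table[allele] = rem / len(tail)
        out[locus] = table
    return out


def _default_hotspots() -> tuple[Hotspot, ...]:
    return (
        Hotspot("EGFR", "p.L858R", 0.2261, "L858R", "missense"),
        Hotspot("EGFR", "p.E746_A750del", 0.13, "del19", "inframe_indel"),
        Hotspot("EGFR", "p.G719A", 0.078, "other", "missense"),
    )


# Background negative-binomial means per subtype (size r below), solved so
# the target median of driver-row + background (or of the zero-truncated
# background for WT) is centred in its probability band, i.e.
# F(median-1) + F(median) = 1, which maximises the stability of the
# sample median at realistic group sizes.
_DEFAULT_BG_MEAN = {"L858R": 2.2268, "del19": 2.2268, "other": 3.2649,
                    "WT": 5.2839}
_DEFAULT_TMB_MEDIANS = {"L858R": 3, "del19": 3, "other": 4, "WT": 5}


def _default_gene_weights() -> dict[str, float]:
    weights = {"TP53": 0.18, "LRP1B": 0.08, "KRAS": 0.05}
    n_tail = 36
    rem = 1.0 - sum(weights.values())
    for i in range(1, n_tail + 1):
        weights[f"GENE{i:03d}"] = rem / n_tail
    return weights


@dataclass
class CohortConfig:
    """Everything that determines a synthetic cohort, plus the seed."""

    seed: int
    n_patients: int = 2000
    allele_af: dict[str, dict[str, float]] = field(default_factory=_default_allele_af)
    hotspots: tuple[Hotspot, ...] = field(default_factory=_default_hotspots)
    bg_mean: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BG_MEAN))
    bg_size: float = 10.0
    target_tmb_medians: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_TMB_MEDIANS)
    )
    gene_weights: dict[str, float] = field(default_factory=_default_gene_weights)
    frameshift_fraction: float = 0.10
    synonymous_mean: float = 0.3
    loh_affected_rate: float = 0.631
    loh_not_evaluable_rate: float = 131 / 1862
    b2m_rate: float = 7 / 1862
    motif_table: MotifTable = field(default_factory=default_motif_table)

    def validate(self) -> None:
        if self.seed is None:
            raise DomainError("config seed is mandatory")
        if self.n_patients < 1:
            raise DomainError("n_patients must be >= 1")
        for locus in LOCI:
            table = self.allele_af.get(locus)
            if not table:
                raise DomainError(f"allele_af missing locus {locus}")
            total = sum(table.values())
            if abs(total - 1.0) > 1e-6:
                raise DomainError(f"locus {locus} AFs sum to {total}, expected 1")
        total_hot = sum(h.prevalence for h in self.hotspots)
        if total_hot > 1.0 + 1e-9:
            raise DomainError("hotspot prevalences exceed 1")
        for h in self.hotspots:
            if not 0.0 <= h.prevalence <= 1.0:
                raise DomainError(f"hotspot {h.hgvs_p}: prevalence outside [0,1]")
        for rate in (self.loh_affected_rate, self.loh_not_evaluable_rate,
                     self.b2m_rate, self.frameshift_fraction):
            if not 0.0 <= rate <= 1.0:
                raise DomainError("rates must lie in [0, 1]")

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "n_patients": int(self.n_patients),
            "allele_af": {loc: dict(tab) for loc, tab in self.allele_af.items()},
            "hotspots": [
                {"gene": h.gene, "hgvs_p": h.hgvs_p, "prevalence": h.prevalence,
                 "subtype": h.subtype, "consequence": h.consequence}
                for h in self.hotspots
            ],
            "bg_mean": dict(self.bg_mean),
            "bg_size": self.bg_size,
            "target_tmb_medians": dict(self.target_tmb_medians),
            "gene_weights": dict(self.gene_weights),
            "frameshift_fraction": self.frameshift_fraction,
            "synonymous_mean": self.synonymous_mean,
            "loh_affected_rate": self.loh_affected_rate,
            "loh_not_evaluable_rate": self.loh_not_evaluable_rate,
            "b2m_rate": self.b2m_rate,
            "motif_table": {
                allele: [
                    {"anchors": {int(p): "".join(sorted(r)) for p, r in m.anchors},
                     "factor": m.factor}
                    for m in motifs
                ]
                for allele, motifs in self.motif_table.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "CohortConfig":
        kwargs = dict(doc)
        if "hotspots" in kwargs:
            kwargs["hotspots"] = tuple(Hotspot(**h) for h in kwargs["hotspots"])
        if "motif_table" in kwargs:
            kwargs["motif_table"] = {
                allele: tuple(
                    AnchorMotif(
                        anchors=tuple(sorted(
                            (int(p), frozenset(r))
                            for p, r in m["anchors"].items()
                        )),
                        factor=float(m["factor"]),
                    )
                    for m in motifs
                )
                for allele, motifs in kwargs["motif_table"].items()
            }
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Synthetic protein panel


@lru_cache(maxsize=1)
def build_panel() -> tuple[dict[str, str], dict[str, list[tuple[int, str, str]]]]:
    """Fixed synthetic protein panel and background variant catalog.

    Returns (protein_id -> sequence, gene -> [(pos, ref, alt), ...]).
    The EGFR-like protein embeds the published local contexts around the
    two driver lesions (and a G at 719 for the other-EGFR hotspot); the
    B2M-like protein has L at residue 15 so the canonical truncating
    lesion applies. Everything else is a random scaffold from a fixed
    internal seed.
    """
    rng = np.random.default_rng(_PANEL_SEED)

    def scaffold(length: int) -> list[str]:
        return [_AA20[i] for i in rng.integers(0, 20, size=length)]

    proteins: dict[str, str] = {}

    egfr = scaffold(1210)
    egfr[wx.EX19DEL_CONTEXT_OFFSET - 1:
         wx.EX19DEL_CONTEXT_OFFSET - 1 + len(wx.EX19DEL_CONTEXT)] = list(wx.EX19DEL_CONTEXT)
    egfr[wx.L858R_CONTEXT_OFFSET - 1:
         wx.L858R_CONTEXT_OFFSET - 1 + len(wx.L858R_CONTEXT)] = list(wx.L858R_CONTEXT)
    egfr[719 - 1] = "G"
    proteins["PROT_EGFR"] = "".join(egfr)

    b2m = scaffold(119)
    b2m[15 - 1] = "L"
    proteins["PROT_B2M"] = "".join(b2m)

    lengths = {"TP53": 393, "KRAS": 189, "LRP1B": 360}
    for i in range(1, 37):
        lengths[f"GENE{i:03d}"] = 300
    catalog: dict[str, list[tuple[int, str, str]]] = {}
    for gene in lengths:
        seq = scaffold(lengths[gene])
        proteins[f"PROT_{gene}"] = "".join(seq)
        positions = sorted(
            rng.choice(np.arange(16, lengths[gene] - 15), size=12, replace=False)
        )
        sites = []
        for pos in positions:
            ref = seq[pos - 1]
            alt = _AA20[(_AA20.index(ref) + 5) % 20]
            sites.append((int(pos), ref, alt))
        catalog[gene] = sites
    return proteins, catalog


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class SyntheticCohort:
    config: CohortConfig
    genotypes: list[HLAGenotype]
    mutations: list[SomaticMutation]
    loh_calls: list[LocusLohCall]
    proteins: dict[str, str]
    subtypes: dict[str, str]  # sample_id -> planted subtype

    def patients(self) -> list[PatientRecord]:
        return assemble_patients(self.genotypes, self.mutations, self.loh_calls)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "hla": outdir / "hla.tsv",
            "mutations": outdir / "mutations.tsv",
            "loh": outdir / "loh_calls.tsv",
            "proteins": outdir / "proteins.fasta",
            "config": outdir / "cohort_config.yaml",
        }
        write_hla(self.genotypes, paths["hla"])
        write_mutations(self.mutations, paths["mutations"])
        write_loh_calls(self.loh_calls, paths["loh"])
        write_fasta(self.proteins, paths["proteins"])
        self.config.to_yaml(paths["config"])
        manifest = {
            "config_hash": self.config.config_hash(),
            "files": {
                name: hashlib.sha256(p.read_bytes()).hexdigest()
                for name, p in paths.items()
            },
        }
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        paths["manifest"] = mpath
        return paths


def _draw_genotype(rng, sample_id: str, allele_af) -> HLAGenotype:
    alleles = {}
    for locus in LOCI:
        names = sorted(allele_af[locus])
        probs = np.array([allele_af[locus][a] for a in names], dtype=float)
        probs = probs / probs.sum()
        idx = rng.choice(len(names), size=2, p=probs)
        alleles[locus] = (names[idx[0]], names[idx[1]])
    return HLAGenotype(sample_id=sample_id, alleles=alleles)


def _draw_background_count(rng, cfg: CohortConfig, subtype: str) -> int:
    mean = cfg.bg_mean[subtype]
    p = cfg.bg_size / (cfg.bg_size + mean)
    if subtype == "WT":
        # zero-truncated: every tumor on the panel shows >=1 mutation
        for _ in range(1000):
            k = int(rng.negative_binomial(cfg.bg_size, p))
            if k >= 1:
                return k
        return 1
    return int(rng.negative_binomial(cfg.bg_size, p))


def generate_cohort(config: CohortConfig, outdir: str | Path | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort (genotypes, mutations, LOH calls, FASTA).

    Deterministic: config (including seed) fully determines every output
    byte. With ``outdir`` the standard TSV/FASTA file set plus a
    manifest (config hash and file hashes) is written.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    proteins, catalog = build_panel()
    genes = sorted(config.gene_weights)
    gene_probs = np.array([config.gene_weights[g] for g in genes], dtype=float)
    gene_probs = gene_probs / gene_probs.sum()

    subtype_edges = np.cumsum([h.prevalence for h in config.hotspots])

    genotypes: list[HLAGenotype] = []
    mutations: list[SomaticMutation] = []
    loh_calls: list[LocusLohCall] = []
    subtypes: dict[str, str] = {}

    for i in range(config.n_patients):
        sid = f"P{i:05d}"
        genotype = _draw_genotype(rng, sid, config.allele_af)
        genotypes.append(genotype)

        # subtype + driver
        u = rng.random()
        hotspot = None
        for edge, h in zip(subtype_edges, config.hotspots):
            if u < edge:
                hotspot = h
                break
        subtype = hotspot.subtype if hotspot else "WT"
        subtypes[sid] = subtype
        if hotspot is not None:
            mutations.append(
                SomaticMutation(
                    sample_id=sid, gene=hotspot.gene,
                    protein_id=f"PROT_{hotspot.gene}", hgvs_p=hotspot.hgvs_p,
                    vaf=float(rng.uniform(0.10, 0.60)),
                    consequence=hotspot.consequence,
                )
            )

        # background non-synonymous rows
        n_bg = _draw_background_count(rng, config, subtype)
        used: set[tuple[str, int, str]] = set()
        for _ in range(n_bg):
            for _attempt in range(100):
                gene = genes[int(rng.choice(len(genes), p=gene_probs))]
                pos, ref, alt = catalog[gene][int(rng.integers(0, len(catalog[gene])))]
                kind = "frameshift" if rng.random() < config.frameshift_fraction else "missense"
                key = (gene, pos, kind)
                if key not in used:
                    used.add(key)
                    break
            else:  # pragma: no cover - panel big enough in practice
                continue
            hgvs = f"p.{ref}{pos}fs" if kind == "frameshift" else f"p.{ref}{pos}{alt}"
            mutations.append(
                SomaticMutation(
                    sample_id=sid, gene=gene, protein_id=f"PROT_{gene}",
                    hgvs_p=hgvs, vaf=float(rng.uniform(0.05, 0.50)),
                    consequence=kind,
                )
            )

        # synonymous passengers (not counted toward TMB)
        for _ in range(rng.poisson(config.synonymous_mean)):
            gene = genes[int(rng.choice(len(genes), p=gene_probs))]
            pos, ref, _alt = catalog[gene][int(rng.integers(0, len(catalog[gene])))]
            if ("SYN", pos, gene) in used:
                continue
            used.add(("SYN", pos, gene))
            mutations.append(
                SomaticMutation(
                    sample_id=sid, gene=gene, protein_id=f"PROT_{gene}",
                    hgvs_p=f"p.{ref}{pos}=", vaf=float(rng.uniform(0.05, 0.50)),
                    consequence="other",
                )
            )

        # B2M truncating lesion
        if rng.random() < config.b2m_rate:
            mutations.append(
                SomaticMutation(
                    sample_id=sid, gene="B2M", protein_id="PROT_B2M",
                    hgvs_p="p.L15Ffs*41", vaf=float(rng.uniform(0.05, 0.50)),
                    consequence="frameshift",
                )
            )

        # locus-level LOH calls
        if rng.random() >= config.loh_not_evaluable_rate:
            het_loci = [loc for loc in LOCI if not genotype.is_homozygous(loc)]
            affected = bool(het_loci) and rng.random() < config.loh_affected_rate
            target = het_loci[int(rng.integers(0, len(het_loci)))] if affected else None
            for locus in LOCI:
                if locus not in het_loci:
                    loh_calls.append(LocusLohCall(sid, locus, False, None))
                elif locus == target:
                    loh_calls.append(
                        LocusLohCall(sid, locus, True, float(rng.uniform(0.0, 0.01)))
                    )
                else:
                    loh_calls.append(
                        LocusLohCall(sid, locus, True, float(rng.uniform(0.01, 1.0)))
                    )

    cohort = SyntheticCohort(
        config=config, genotypes=genotypes, mutations=mutations,
        loh_calls=loh_calls, proteins=dict(proteins), subtypes=subtypes,
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort


# ---------------------------------------------------------------------------
# End-to-end recovery


@dataclass
class RecoveryReport:
    checks: dict[str, dict]
    ok: bool

    def failures(self) -> dict[str, dict]:
        return {k: v for k, v in self.checks.items() if not v["passed"]}


def _ci_check(value: float, expected: float, n: int, z: float = 2.576) -> tuple[bool, float]:
    """Binomial normal-approximation CI of half-width z*sqrt(p(1-p)/n)."""
    half = z * np.sqrt(expected * (1.0 - expected) / n)
    return abs(value - expected) <= half, half


def end_to_end_recovery(config: CohortConfig) -> RecoveryReport:
    """Run the full pipeline on a generated cohort and verify the planted
    structure is recovered.

    Checks: top-allele carrier rate (within 5 points of the planted
    Hardy-Weinberg value), hotspot prevalence and patient-level LOH rate
    (within 99% binomial CIs), exact per-subtype TMB medians, presence
    of the planted strong neoepitope, and that the top-ranked shared
    candidate is the planted (hotspot, common-allele) pair.
    """
    cohort = generate_cohort(config)
    patients = cohort.patients()
    n = config.n_patients
    checks: dict[str, dict] = {}

    # top-allele carrier rate
    af = allele_frequencies(cohort.genotypes)
    a_locus = af[af["locus"] == "A"]
    top = a_locus.loc[a_locus["carrier_rate"].idxmax()]
    top_af = max(config.allele_af["A"].items(), key=lambda kv: kv[1])
    expected_carrier = top_af[1] * (2 - top_af[1])
    checks["top_allele_carrier"] = {
        "passed": bool(
            top["allele"] == top_af[0]
            and abs(top["carrier_rate"] - expected_carrier) <= 0.05
        ),
        "allele": str(top["allele"]),
        "value": float(top["carrier_rate"]),
        "expected": expected_carrier,
        "tol": 0.05,
    }

    # hotspot prevalence
    gene_prev, variant_prev = prevalence_tables(cohort.mutations, n)
    main = config.hotspots[0] if config.hotspots else None
    if main is not None:
        row = variant_prev[
            (variant_prev["gene"] == main.gene)
            & (variant_prev["hgvs_p"] == main.hgvs_p)
        ]
        est = float(row["prevalence"].iloc[0]) if len(row) else 0.0
        ok, half = _ci_check(est, main.prevalence, n)
        checks["hotspot_prevalence"] = {
            "passed": bool(ok), "value": est, "expected": main.prevalence,
            "tol": float(half),
        }

    # per-subtype TMB medians (planted subtype labels, which the observed
    # EGFR-based classification must reproduce)
    features = patient_feature_table(patients)
    features["planted"] = features["sample_id"].map(cohort.subtypes)
    label_match = float((features["planted"] == features["subtype"]).mean())
    checks["subtype_labels"] = {
        "passed": label_match == 1.0, "value": label_match, "expected": 1.0,
        "tol": 0.0,
    }
    medians = features.groupby("subtype")["tmb_count"].median().to_dict()
    med_ok = all(
        medians.get(st) == target
        for st, target in config.target_tmb_medians.items()
    )
    checks["tmb_medians"] = {
        "passed": bool(med_ok),
        "value": {k: float(v) for k, v in medians.items()},
        "expected": dict(config.target_tmb_medians),
        "tol": 0.0,
    }

    # patient-level LOH rate
    evaluable = features[features["hla_loh"] != "not_evaluable"]
    loh_rate = float((evaluable["hla_loh"] == "affected").mean())
    ok, half = _ci_check(loh_rate, config.loh_affected_rate, len(evaluable))
    checks["loh_rate"] = {
        "passed": bool(ok), "value": loh_rate,
        "expected": config.loh_affected_rate, "tol": float(half),
    }

    # neoantigen calling: planted strong neoepitope + top shared candidate
    predictor = ToyPredictor(config.motif_table, seed_salt=config.seed)
    candidates = call_cohort_neoantigens(patients, cohort.proteins, predictor)
    cdf = candidates_to_frame(candidates)
    if main is not None:
        strong = cdf[
            (cdf["gene"] == main.gene)
            & (cdf["hgvs_p"] == main.hgvs_p)
            & (cdf["mt_peptide"] == wx.L858R_PEPTIDES[0])
            & (cdf["binding_class"] == "strong")
        ]
        checks["planted_strong_neoepitope"] = {
            "passed": len(strong) > 0, "value": int(len(strong)),
            "expected": ">=1", "tol": None,
        }

    carrier = dict(zip(af["allele"], af["carrier_rate"]))
    shared = shared_candidate_table(cdf, variant_prev, carrier)
    if len(config.hotspots) >= 2 and len(shared):
        # the planted top pair: the indel-like hotspot restricted by the
        # cohort's most common allele
        indel_hot = config.hotspots[1]
        expected_pair = (indel_hot.gene, indel_hot.hgvs_p, top_af[0])
        top_row = shared.iloc[0]
        got_pair = (top_row["gene"], top_row["hgvs_p"], top_row["allele"])
        checks["top_shared_candidate"] = {
            "passed": got_pair == expected_pair,
            "value": list(got_pair),
            "expected": list(expected_pair),
            "shared_pct": float(top_row["shared_frequency_pct"]),
            "tol": None,
        }
    elif len(config.hotspots) >= 2:
        checks["top_shared_candidate"] = {
            "passed": False, "value": None, "expected": "nonempty table",
            "tol": None,
        }

    return RecoveryReport(checks=checks, ok=all(c["passed"] for c in checks.values()))
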