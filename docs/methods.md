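# Methods

## Scope and data model

`neoshare` implements a cohort-level shared-neoantigen analysis for
panel-sequenced tumors. Its inputs are four plain-text tables plus a
protein FASTA: somatic mutations (sample, gene, protein id, HGVS.p
change, variant allele fraction, consequence class), HLA class I
genotypes at four-digit resolution (two alleles per locus A/B/C),
locus-level HLA LOH calls mirroring the output contract of an
allele-specific HLA copy-number caller (sample, locus, heterozygous
flag, `PVal_unique`), and an optional per-sample immune-fraction table
for subgroup comparisons. All tables are tab-separated UTF-8 with a
header; `.`/empty means missing; outputs are sorted deterministically
(sample, gene, HGVS.p) so every run is byte-reproducible from its
resolved config.

Protein coordinates are 1-based with closed intervals throughout (HGVS
convention). HLA allele names are normalized to `X*nn:nn`, discarding
resolution beyond two fields. The mutation ingest filter keeps variant
allele fraction ≥ 0.05 (inclusive boundary) and, for neoepitope
enumeration, missense and in-frame indel changes only.

## Variant interpretation and peptide enumeration

`parse_hgvs_p` covers the protein-level subset that a panel pipeline
emits: missense, in-frame deletion / delins / insertion / duplication,
frameshift, stop-gain and synonymous, in 1- or 3-letter residue codes.
Frameshifts and stop-gains parse but are flagged non-enumerable: their
downstream product is unreliable (premature termination codons and
nonsense-mediated decay), so no neoepitopes are derived from them. The
gene-prevalence sensitivity flag (`include_frameshift`) lets frameshift
rows count toward gene-level mutation prevalence without entering the
peptide stage.

`enumerate_peptides` emits every 8–11-mer window of the mutant protein
that covers the change: for missense, all windows containing the
substituted residue (an interior substitution yields 8+9+10+11 = 38
pairs); for in-frame indels, all windows overlapping the altered
stretch, and for pure deletions all windows containing both residues
juxtaposed at the junction. Windows are truncated at the protein
termini (never padded; short windows are not emitted), windows
containing ambiguous residues (X, U, `*`) are skipped with a warning,
and pairs whose mutant and wild-type peptides coincide are dropped.

**Wild-type counterpart convention.** The wild-type peptide of an
indel-derived window is the *coordinate-matched* same-length window of
the wild-type protein (window starts left of the change map 1:1;
starts beyond it shift by the indel length). Published pipelines vary
here; coordinate matching is the simplest reproducible convention that
yields a single canonical WT per mutant peptide, and the function is
isolated so a "best WT over all overlapping windows" rule can be
swapped in.

## Binding prediction and candidate calling

A predictor is any pure function `(peptide, allele) → IC50 [nM]`. The
candidate rule is fixed: a peptide–allele pair is a candidate
neoantigen iff IC50(MT) < 500 nM **and** IC50(WT) ≥ 500 nM (mutant side
strict, wild-type side inclusive), and a strong binder iff
IC50(MT) < 50 nM (strict). Candidates are called per patient against
the patient's *distinct* alleles (homozygous alleles queried once);
rows are unique on (sample, mutation, peptide, allele). Percentile-rank
calling is intentionally out of scope — the analysis is defined on IC50
thresholds.

The shipped **toy predictor** is a deterministic stand-in for a neural
affinity model, built so every pipeline property is testable offline:
the baseline IC50 is a 64-bit hash of (peptide, allele, salt) mapped
log-uniformly onto [500, 50000) nM — i.e. a motif-free peptide never
binds — and peptides matching an allele's planted anchor motif
(required residue sets at fixed positions, C-terminus addressable as
position −1) are divided by the motif factor: 1100 for "strong" motifs
(always < 50 nM), 110 for "weak" ones (always < 500 nM). The default
motif table caricatures A3-supertype preferences: C-terminal arginine
anchors for A\*31:01/A\*33:03/A\*68:01, C-terminal lysine for
A\*11:01-like alleles, and a position-1-R / position-2-{I,T,V} refined
pair of rules for A\*30:01 so that the canonical exon-21 and exon-19
driver neoepitopes reproduce their published binding behaviour by
construction while their wild-type counterparts do not bind.

## Cohort aggregation

* **Prevalence**: fraction of patients carrying ≥ 1 qualifying mutation
  of a gene (or exact variant), after per-patient deduplication.
* **Unique neoantigens**: (gene, change, mutant peptide) groups.
  Binding-class summary is `strong`/`weak` when all supporting alleles
  agree and `ambiguous` when mixed; in the strong-vs-weak breakdown,
  ambiguous neoantigens count as strong (they bind ≥ 1 allele
  strongly).
* **Neoantigen frequency** of a gene: unique neoantigens divided by the
  number of qualifying mutation occurrences targeting the gene
  cohort-wide (rows after per-patient variant dedup) — the reading
  consistent with the companion "≥ 10 mutations per gene" filter. A
  multi-allele neoantigen counts once in the total; allele-specific
  frequencies count it per allele and may exceed the total. Genes under
  1% patient prevalence or under 10 occurrences are dropped.
* **Shared frequency**: exact product, full precision internally;
  percentages are rounded half-up to 2 decimals only at the reporting
  layer (22.61% × 12.94% → 2.93%). Ranking is by descending shared
  frequency with a stable lexicographic (gene, change, allele)
  tie-break.

## Immunogenomic features

* **EGFR subtype**: L858R > del19 > other precedence (the headline
  driver is never masked; precedence firing on a co-mutated patient is
  logged). del19 means any EGFR in-frame deletion overlapping the
  exon-19 protein span, residues 729–761 (a config value).
* **Panel TMB**: raw count of protein-altering rows (missense, in-frame
  indel, frameshift, stop-gain). Counts are compared directly; a
  per-megabase conversion exists but is unused by default.
* **HLA LOH**: a patient is `affected` when any heterozygous locus has
  `PVal_unique` < 0.01 (strict), `unaffected` otherwise — including
  patients homozygous at all three loci — and `not_evaluable` only when
  the upstream caller produced no output for them; not-evaluable
  patients are excluded from rate denominators.
* **B2M**: flagged on any protein-altering B2M row, frameshifts
  included, since truncation abolishes class I assembly.

Group comparisons use chi-square for rates (Yates-corrected for 2×2,
with the uncorrected statistic also reported) and Kruskal–Wallis
(midranks, tie correction) for counts, with optional pairwise two-sided
Wilcoxon rank-sum tests under Benjamini–Hochberg adjustment. The
pairwise post-hoc choice is a package convention — the source analyses
this mirrors do not name theirs. A known calibration note: on the
published strong/weak × prevalence 2×2 counts ([[98, 406], [169, 765]])
the corrected and uncorrected statistics give p ≈ 0.585 and p ≈ 0.532
respectively, while the source reports p = 0.61; the package reports
both statistics and does not tune either.

## Synthetic cohorts

The generator produces full cohorts with the statistical structure the
analysis assumes, so every stage is testable without any download. All
randomness flows from the single config seed; identical configs give
byte-identical files (hash manifest included).

* **Genotypes**: two independent draws per locus (Hardy–Weinberg) from
  per-locus AF tables. The default A-locus head is back-solved from
  published carrier percentages via AF = 1 − √(1 − cf): A\*11:01
  0.2423 (carrier 42.6%), A\*33:03 0.0670 (12.9%), A\*31:01 0.0267,
  A\*68:01 0.0062, A\*30:01 0.0386, plus uniform tails (~60 alleles
  cohort-wide).
* **Drivers**: mutually exclusive hotspot assignment at prevalence
  0.2261 (L858R-like), 0.13 (E746_A750del-like) and 0.078 (other-EGFR,
  G719A-like; 145/1862 from the motivating cohort's subgroup sizes).
  The EGFR-like protein embeds the published wild-type contexts around
  both driver lesions, so the planted hotspots regenerate the published
  neoepitope junction sequences verbatim.
* **Background mutations**: per-subtype negative-binomial counts on a
  fixed synthetic 40-gene panel (12 recurrent sites per gene, 10%
  frameshift, plus Poisson synonymous passengers that do not count
  toward TMB). The NB size defaults to 10 and the subtype means
  (2.2268 / 2.2268 / 3.2649 / 5.2839, the last zero-truncated) are
  solved so each target TMB median (3 / 3 / 4 / 5 for
  L858R / del19 / other / WT) satisfies F(m−1) + F(m) = 1 — centred in
  its probability band, which is what makes *sample* medians of
  realistic subgroup sizes (~80–1200 patients) land on the target
  almost surely. A more dispersed size (e.g. 3) leaves the smallest
  subgroup's median unstable; the size is exposed in config.
* **LOH**: a patient is not evaluable with probability 131/1862;
  otherwise affected with probability 0.631 given ≥ 1 heterozygous
  locus — one heterozygous locus gets `PVal_unique` ~ U[0, 0.01), the
  rest U[0.01, 1); homozygous loci carry no p-value. B2M truncating
  lesions occur at 7/1862.

**What the generator does not emulate**: linkage between HLA loci,
mutational signatures, gene length–dependent mutation rates, VAF–purity
structure, and any correlation between TMB and LOH. Passing recovery
tests therefore demonstrates that the pipeline's estimators are
consistent under the stated sampling model — not that the model captures
every property of real panel data.

## Verification

Each statistical engine is checked to 1e-10 against a hand-coded
textbook oracle (Kruskal–Wallis H with midranks and tie correction;
chi-square with and without continuity correction), and the
Kruskal–Wallis null calibration is simulated (4 groups × 25 normal
observations, 2000 replicates → rejection ≈ 0.05; smaller groups make
the asymptotic χ² reference visibly conservative, which is a property
of the approximation). Peptide enumeration is checked against a
brute-force all-windows oracle, including near-terminus truncation, and
as a property test over random sequences. End-to-end, a planted n=2000
cohort must return: hotspot prevalence and patient-level LOH rate
within 99% binomial CIs, top-allele carrier rate within 5 points, exact
per-subtype TMB medians, the planted strong neoepitope among strong
candidates, and the planted (indel hotspot × most-common-allele) pair
at the top of the shared-frequency ranking. Problem sizes (n = 2000
cohort, 2000 null replicates, 10–20 oracle fixtures) are the package's
verification defaults.

## Known limitations

* The toy predictor is a contract fixture: its IC50 values are
  arbitrary within their bands and carry no biochemical meaning.
* One protein per gene: the caller must supply a single protein id per
  mutation; transcript selection is out of scope.
* Frameshift neoepitopes, splice/fusion peptides, proteasomal
  processing and TAP transport are out of scope by design.
* HLA typing, allele-specific copy-number inference and immune
  deconvolution happen upstream; the package consumes their outputs.
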