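# neoshare

Shared neoantigen discovery and prioritization for panel-sequenced tumor
cohorts: from somatic protein changes and HLA class I genotypes to a
ranked table of (mutation, peptide, HLA allele) off-the-shelf vaccine
candidates, plus the immunogenomic feature summaries that qualify them
(HLA loss of heterozygosity, B2M aberrations, panel TMB, EGFR driver
subtypes).

## The problem

Personalized neoantigen vaccines are expensive; *shared* neoantigens —
recurrent driver mutations presented by common HLA class I alleles — can
serve many patients with one product. Finding them requires joining
three population quantities:

* **Binding.** A mutant 8–11-mer peptide is a candidate neoantigen when
  its predicted affinity is IC50(MT) < 500 nM while the coordinate-matched
  wild-type peptide does not bind, IC50(WT) ≥ 500 nM; it is a *strong
  binder* below 50 nM.
* **Carrier frequency.** For an allele at population frequency AF, the
  fraction of diploid individuals carrying ≥ 1 copy under Hardy–Weinberg
  is `cf = 1 − (1 − AF)²`.
* **Shared frequency.** For a (mutation, allele) pair,
  `shared = mutation prevalence × allele carrier frequency` — the
  expected fraction of patients eligible for a vaccine against that pair.

In the NSCLC setting that motivates the defaults, the two dominant EGFR
drivers are the exon-21 substitution L858R (~23% of patients) and the
archetypal exon-19 deletion E746_A750del (~13%), and the pipeline ranks
their neoepitopes against common East-Asian alleles such as A\*11:01 and
A\*33:03.

Affinity prediction itself is a pluggable contract (`(peptide, allele)
→ IC50 nM`): the package ships a deterministic, motif-driven toy
predictor so the whole pipeline is testable offline, and a real tool
(e.g. a netMHCpan wrapper) can be dropped in behind the same interface.

## Worked example

The published EGFR L858R neoepitope falls out of the enumeration of its
kinase-domain context (wild-type residues 850–867), and the published
IC50 pair for A\*33:03 classifies as a strong binder:

```python
from neoshare import carrier_frequency, classify_pair, round_percent, shared_frequency
from neoshare.peptides import enumerate_peptides, parse_hgvs_p

ctx = "HVKITDFGLAKLLGAEEK"          # EGFR residues 850-867
change = parse_hgvs_p("p.L9R")       # L858R in fragment coordinates
for pair in enumerate_peptides(ctx, change, lengths=(9,)):
    if pair.mt_peptide == "HVKITDFGR":
        print(pair.mt_peptide, pair.wt_peptide, pair.mt_start)

print(classify_pair(22.9, 12734.0))                       # published IC50 MT/WT
print(round(carrier_frequency(0.0670), 4))                # A*33:03-like AF
print(round_percent(shared_frequency(0.2261, 0.1294)))    # prevalence x carrier
```

prints

```
HVKITDFGR HVKITDFGL 1
strong
0.1295
2.93
```

i.e. the mutant 9-mer `HVKITDFGR` (wild-type `HVKITDFGL`) is a strong
binder for its allele, the allele's carrier frequency is ~12.9%, and the
(L858R, A\*33:03) pair would be actionable in 2.93% of the population.

## Pipeline

The `neoshare` command chains the stages on TSV/FASTA inputs (or on a
fully synthetic cohort):

```sh
neoshare simulate --n 2000 --seed 1 --outdir run/cohort
neoshare hla-stats --hla run/cohort/hla.tsv --outdir run/hla \
    --rarefaction-grid 200,500,1000,2000 --reps 100 --seed 1
neoshare neoantigens --mutations run/cohort/mutations.tsv \
    --hla run/cohort/hla.tsv --proteins run/cohort/proteins.fasta \
    --salt 1 --outdir run/neo
neoshare prioritize --candidates run/neo/candidates.tsv \
    --mutations run/cohort/mutations.tsv --hla run/cohort/hla.tsv \
    --outdir run/pri
neoshare features --mutations run/cohort/mutations.tsv \
    --hla run/cohort/hla.tsv --loh run/cohort/loh_calls.tsv \
    --outdir run/feat
neoshare report --rundir run/pri --outdir run/report
```

Every stage logs row counts at each filter step, writes a resolved
config next to its outputs, and is byte-reproducible from that config.
See `docs/methods.md` for the model, the synthetic-cohort generator, and
all numerical conventions.

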