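"""Population statistics over HLA class I genotypes.

Allele frequency (AF) is the fraction of allele slots (2 per patient per
locus) carrying an allele; the carrier rate is the fraction of patients
carrying at least one copy. Under Hardy-Weinberg the two are linked by
the carrier-frequency formula cf = 1 - (1 - AF)^2, which this module
exposes both as a closed form and as the ``carrier_freq_formula`` column
of the observed table. Rarefaction (classical, without-replacement
patient subsampling) measures how thoroughly a cohort samples the
population's allele diversity.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .io import LOCI, HLAGenotype

AF_COLUMNS = ("locus", "allele", "af", "carrier_count", "carrier_rate",
              "carrier_freq_formula")


def carrier_frequency(af: float) -> float:
    """Carrier frequency of an allele with population frequency ``af``.

    Probability that a diploid individual carries >=1 copy under
    Hardy-Weinberg: 1 - (1 - af)^2 = af (2 - af).
    """
    if not 0.0 <= af <= 1.0:
        raise DomainError(f"allele frequency {af} outside [0, 1]")
    return af * (2.0 - af)


def allele_frequencies(genotypes: Sequence[HLAGenotype]) -> pd.DataFrame:
    """Per-allele AF, carrier count/rate, and formula carrier frequency.

    AF normalizes by allele slots (2 x n patients per locus) so per-locus
    AFs sum to 1; the carrier rate counts a homozygous patient once.
    """
    genotypes = list(genotypes)
    if not genotypes:
        raise DomainError("allele_frequencies requires a nonempty cohort")
    n = len(genotypes)
    rows = []
    for locus in LOCI:
        slot_counts: dict[str, int] = {}
        carrier_counts: dict[str, int] = {}
        for g in genotypes:
            a1, a2 = g.alleles[locus]
            slot_counts[a1] = slot_counts.get(a1, 0) + 1
            slot_counts[a2] = slot_counts.get(a2, 0) + 1
            for allele in {a1, a2}:
                carrier_counts[allele] = carrier_counts.get(allele, 0) + 1
        for allele in sorted(slot_counts):
            af = slot_counts[allele] / (2 * n)
            cc = carrier_counts[allele]
            rows.append(
                (locus, allele, af, cc, cc / n, carrier_frequency(af))
            )
    return pd.DataFrame(rows, columns=list(AF_COLUMNS))


def distinct_allele_count(genotypes: Iterable[HLAGenotype]) -> int:
    """Number of distinct alleles over all loci in the cohort."""
    alleles: set[str] = set()
    for g in genotypes:
        for locus in LOCI:
            alleles.update(g.alleles[locus])
    return len(alleles)


def rarefaction(
    genotypes: Sequence[HLAGenotype],
    grid: Sequence[int],
    reps: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rarefaction curve of distinct-allele count vs. cohort size.

    For each size in ``grid``, patients are subsampled without
    replacement ``reps`` times and the mean and (population) standard
    deviation of the distinct-allele count recorded. Deterministic for a
    fixed seed.
    """
    genotypes = list(genotypes)
    n = len(genotypes)
    if reps < 1:
        raise DomainError("reps must be >= 1")
    for size in grid:
        if not 1 <= size <= n:
            raise DomainError(f"subsample size {size} outside [1, {n}]")
    rng = np.random.default_rng(seed)
    allele_sets = [frozenset(g.distinct_alleles()) for g in genotypes]
    rows = []
    for size in grid:
        counts = np.empty(reps)
        for r in range(reps):
            idx = rng.choice(n, size=size, replace=False)
            seen: set[str] = set()
            for i in idx:
                seen |= allele_sets[i]
            counts[r] = len(seen)
        rows.append((int(size), float(counts.mean()), float(counts.std(ddof=0))))
    return pd.DataFrame(rows, columns=["size", "mean", "sd"])
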