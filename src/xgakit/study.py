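"""Accounting arithmetic for combinatorial-knockout study designs.

The reference experiment profiled two mating-type pools of randomly
combinatorial 16-locus knockout strains against a 16-drug panel; the
published pool sizes below let the bookkeeping (observation counts,
genotype-space coverage, group counts) be recomputed exactly.
"""
from __future__ import annotations

#: uniquely barcoded + genotyped strains per mating pool (MATa, MATalpha)
POOL_SIZES = (3231, 3595)

#: strains per pool surviving the count and baseline-growth filters,
#: i.e. those with a resistance estimate in every drug
FILTERED_POOL_SIZES = (2367, 2986)

N_LOCI = 16
N_DRUGS = 16
N_FREQUENT_LOCI = 5  # frequently associated transporters used for grouping


def pool_total(pool_sizes: tuple[int, ...] = POOL_SIZES) -> int:
    """Total uniquely barcoded, genotyped strains across mating pools."""
    return sum(pool_sizes)


def observation_count(
    filtered_pool_sizes: tuple[int, ...] = FILTERED_POOL_SIZES,
    n_drugs: int = N_DRUGS,
) -> int:
    """Genotype-to-resistance observations: filtered strains x drugs."""
    return sum(filtered_pool_sizes) * n_drugs


def genotype_space(n_loci: int = N_LOCI) -> int:
    """Number of possible knockout combinations at n_loci loci."""
    return 2**n_loci


def group_count(n_focal: int = N_FREQUENT_LOCI) -> int:
    """Genotype classes when grouping by n_focal loci."""
    return 2**n_focal
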