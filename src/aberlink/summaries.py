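"""Cohort-level summary fractions over module sets and label tables.

These small operations produce the headline percentages of a module
analysis: what fraction of the gene universe any module explains, how
many chromosomes carry trans-acting CNV modules, how often an effector
modality is used, and conditional rates of a binary flag within labelled
sample groups.
"""

from __future__ import annotations

import pandas as pd

from .modules import AssociationModule, target_universe


def percent(k: int, n: int, ndigits: int = 2) -> float:
    """k/n as a percentage rounded to ``ndigits`` decimals."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, ndigits)


def module_gene_coverage(modules: list[AssociationModule], universe: set[str]):
    """Fraction of the gene universe belonging to at least one module."""
    covered = target_universe(modules) & universe
    return len(covered), len(universe), percent(len(covered), len(universe))


def effector_usage(modules: list[AssociationModule], modality: str,
                   universe_size: int, ndigits: int = 2):
    """How many distinct effectors of one modality appear in any module."""
    used = {e for m in modules for (e, t, _s) in m.effectors if t == modality}
    return len(used), universe_size, percent(len(used), universe_size, ndigits)


def chromosomes_with_type(modules: list[AssociationModule], assoc_type: str,
                          chrom_of: dict[str, str], n_chromosomes: int):
    """How many chromosomes carry at least one module of the given CNV type."""
    chroms = {
        chrom_of[e]
        for m in modules
        for (e, t, _s) in m.effectors
        if t == assoc_type and e in chrom_of
    }
    return len(chroms), n_chromosomes, percent(len(chroms), n_chromosomes)


def group_positive_rate(flags: pd.Series, groups: pd.Series, ndigits: int = 2):
    """Rate of a binary flag within each group label.

    Returns {group: (k, n, percent)} over samples present in both series.
    """
    shared = [s for s in flags.index if s in groups.index]
    f = flags.loc[shared].astype(bool)
    g = groups.loc[shared]
    out = {}
    for label in sorted(g.dropna().unique(), key=str):
        members = g[g == label].index
        k = int(f.loc[members].sum())
        n = len(members)
        out[label] = (k, n, percent(k, n, ndigits))
    return out
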