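"""Phenotype-group cosegregation filter.

The discovery filter for a two-group cohort: collect the sites at which
every member of a group carries the identical genotype call (the
within-group "consensus" sets, one per group), then keep the sites whose
two group consensus calls differ. A homozygous-reference consensus is a
legitimate consensus, so "absent in one group, shared het/hom in the
other" counts as discordant.

Also provides the Hardy-Weinberg null model for how often a neutral,
unlinked biallelic site passes the filter by chance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .variant_io import (
    GT_STR,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    GroupAssignment,
    VariantKey,
)


@dataclass(frozen=True)
class GroupConsensus:
    """A site where every member of one group shares the same non-missing call."""

    variant: VariantKey
    group: str
    genotype: int  # HOM_REF / HET / HOM_ALT, never MISSING
    n_members: int


@dataclass(frozen=True)
class DiscordantVariant:
    """A site with a consensus in both groups whose consensus calls differ."""

    variant: VariantKey
    genotype_a: int
    genotype_b: int

    def __post_init__(self) -> None:
        if self.genotype_a == self.genotype_b:
            raise ValueError(f"{self.variant}: consensus genotypes are identical")
        if MISSING in (self.genotype_a, self.genotype_b):
            raise ValueError(f"{self.variant}: consensus genotype is missing")


def group_consensus(
    matrix: GenotypeMatrix,
    assignment: GroupAssignment,
    group: str,
    max_missing: int = 0,
) -> dict[VariantKey, GroupConsensus]:
    """Sites at which the group's members all carry the same genotype.

    A variant is included iff every member has the same non-missing call;
    the shared call (including 0/0) is recorded. With ``max_missing`` > 0,
    up to that many members may be missing provided all called members
    agree and at least one member is called.
    """
    members = assignment.members(group)
    if not members:
        raise ValueError(f"group {group!r} is empty")
    idx = [matrix.samples.index(s) for s in members]
    sub = matrix.calls[:, idx]

    out: dict[VariantKey, GroupConsensus] = {}
    n_missing = (sub == MISSING).sum(axis=1)
    for i, variant in enumerate(matrix.variants):
        if n_missing[i] > max_missing or n_missing[i] == len(idx):
            continue
        called = sub[i][sub[i] != MISSING]
        if (called == called[0]).all():
            out[variant] = GroupConsensus(
                variant=variant, group=group, genotype=int(called[0]),
                n_members=len(idx),
            )
    return out


def discordant_sites(
    set_a: dict[VariantKey, GroupConsensus],
    set_b: dict[VariantKey, GroupConsensus],
) -> list[DiscordantVariant]:
    """Sites with a consensus in both groups and differing consensus calls.

    Output is sorted by (chrom, pos, ref, alt).
    """
    shared = set(set_a) & set(set_b)
    out = [
        DiscordantVariant(v, set_a[v].genotype, set_b[v].genotype)
        for v in shared
        if set_a[v].genotype != set_b[v].genotype
    ]
    out.sort(key=lambda d: d.variant)
    return out


def hwe_genotype_probs(p_alt: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities [P(0/0), P(0/1), P(1/1)]."""
    if not 0.0 <= p_alt <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {p_alt}")
    q = 1.0 - p_alt
    return np.array([q * q, 2.0 * p_alt * q, p_alt * p_alt])


def chance_cosegregation_probability(p_alt: float, n_a: int, n_b: int) -> float:
    """Probability a neutral HWE site lands in the discordant set by chance.

    Under Hardy-Weinberg equilibrium at alternate-allele frequency
    ``p_alt`` with independent samples, the site is discordant iff all
    ``n_a`` members of group A share one genotype, all ``n_b`` members of
    group B share another, and the two differ:

        sum over ordered pairs g1 != g2 of P(g1)**n_a * P(g2)**n_b
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be >= 1")
    probs = hwe_genotype_probs(p_alt)
    total = 0.0
    for g1 in range(3):
        for g2 in range(3):
            if g1 != g2:
                total += probs[g1] ** n_a * probs[g2] ** n_b
    return float(total)


def enumerate_cosegregation_probability(p_alt: float, n_a: int, n_b: int) -> float:
    """Brute-force check of the null model: sum over all 3**(n_a+n_b)
    genotype configurations, weighting each by its HWE probability and
    testing the discordance predicate directly. Exponential; test use only.
    """
    probs = hwe_genotype_probs(p_alt)
    total = 0.0
    for config in itertools.product(range(3), repeat=n_a + n_b):
        ga, gb = config[:n_a], config[n_a:]
        if len(set(ga)) == 1 and len(set(gb)) == 1 and ga[0] != gb[0]:
            total += float(np.prod(probs[list(config)]))
    return total


def discordant_to_rows(sites: list[DiscordantVariant], label_a: str, label_b: str):
    """Rows for the set-C TSV: one per discordant site with both consensus calls."""
    return [
        {
            "chrom": d.variant.chrom,
            "pos": d.variant.pos,
            "ref": d.variant.ref,
            "alt": d.variant.alt,
            f"genotype_{label_a}": GT_STR[d.genotype_a],
            f"genotype_{label_b}": GT_STR[d.genotype_b],
        }
        for d in sites
    ]
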