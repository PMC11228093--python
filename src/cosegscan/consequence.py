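"""Effect-class filtering of discordant sites and gene mapping.

Keeps only the exonic/splice consequence classes relevant to coding
impact and maps the survivors to gene symbols. Class matching tolerates
both annotator dialects — space-separated ("missense variant") and
snake_case ("missense_variant") — by normalizing before comparison.
Compound classes ("missense variant/splice region variant") match on the
full compound string by default; ``split_compound`` relaxes this to
any-component matching.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .cosegregation import DiscordantVariant
from .variant_io import VariantKey

log = logging.getLogger(__name__)

#: Default whitelist: the six exonic/splice-region consequence classes kept
#: by the discovery filter (5'UTR premature-start-gain, missense, splice
#: region, and the splice-region compounds).
DEFAULT_EFFECT_CLASSES = (
    "5_prime_UTR_premature_start_codon_gain_variant",
    "missense_variant",
    "splice_region_variant",
    "missense_variant/splice_region_variant",
    "splice_region_variant/intron_variant",
    "splice_region_variant/synonymous_variant",
)


def normalize_effect(effect: str) -> str:
    """Canonical form for an effect-class string: trimmed, case-folded,
    whitespace collapsed to underscores, per compound component."""
    parts = [
        "_".join(p.strip().casefold().replace("′", "'").split())
        for p in effect.split("/")
    ]
    return "/".join(parts)


@dataclass
class EffectWhitelist:
    """Ordered set of admissible effect classes; matching is dialect-tolerant."""

    classes: tuple[str, ...] = DEFAULT_EFFECT_CLASSES
    split_compound: bool = False
    _normalized: frozenset = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("whitelist must be non-empty")
        norm = {normalize_effect(c) for c in self.classes}
        if self.split_compound:
            norm |= {p for c in norm for p in c.split("/")}
        self._normalized = frozenset(norm)

    def matches(self, effect: str) -> bool:
        eff = normalize_effect(effect)
        if eff in self._normalized:
            return True
        if self.split_compound:
            return any(p in self._normalized for p in eff.split("/"))
        return False


@dataclass
class CandidateVariant:
    """A discordant site surviving the effect whitelist, mapped to a gene."""

    variant: VariantKey
    genotype_a: int
    genotype_b: int
    effect_class: str
    gene: str
    transcript: str = ""
    aa_change: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError(f"{self.variant}: candidate gene must be non-empty")


def filter_by_effect(
    set_c: list[DiscordantVariant],
    annotations: pd.DataFrame,
    whitelist: EffectWhitelist | None = None,
) -> list[CandidateVariant]:
    """One candidate per (variant, transcript, gene) whose effect class is
    whitelisted. Discordant sites with no annotation are dropped and
    counted in a log summary. Output sorted by (chrom, pos, ref, alt)."""
    whitelist = whitelist or EffectWhitelist()
    ann_by_key: dict[tuple, list] = {}
    for row in annotations.itertuples(index=False):
        ann_by_key.setdefault((str(row.chrom), int(row.pos), row.ref, row.alt), []).append(row)

    out: list[CandidateVariant] = []
    n_unannotated = 0
    for d in sorted(set_c, key=lambda d: d.variant):
        key = (d.variant.chrom, d.variant.pos, d.variant.ref, d.variant.alt)
        rows = ann_by_key.get(key)
        if not rows:
            n_unannotated += 1
            continue
        for row in rows:
            if whitelist.matches(row.effect_class):
                out.append(
                    CandidateVariant(
                        variant=d.variant,
                        genotype_a=d.genotype_a,
                        genotype_b=d.genotype_b,
                        effect_class=row.effect_class,
                        gene=str(row.gene),
                        transcript=str(row.transcript),
                    )
                )
    if n_unannotated:
        log.info("dropped %d discordant site(s) with no annotation", n_unannotated)
    return out


def map_to_genes(candidates: list[CandidateVariant]) -> dict[str, int]:
    """Unique gene symbols with per-gene candidate counts.

    Counts sum to the number of candidate (variant, gene) pairs.
    """
    counts = Counter()
    for c in candidates:
        counts[c.gene] += 1
    return dict(sorted(counts.items()))
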