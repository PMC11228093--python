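"""Codon-level consequences of candidate SNVs.

A variant is projected from genomic coordinates into a transcript's CDS
(strand-aware: on the minus strand the coding alleles are reverse
complements and the coding offset counts from the 3' genomic end), the
substitution is applied to the affected codon, and both codons are
translated under the standard genetic code to classify the change as
synonymous, missense, stop gain/loss or start loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .consequence import CandidateVariant
from .variant_io import GeneModel, VariantKey, reverse_complement

log = logging.getLogger(__name__)

# Standard genetic code (nuclear); stops map to '*'.
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
TRANSLATE = {**_CODON_TABLE.forward_table, **{c: "*" for c in _CODON_TABLE.stop_codons}}
START_CODONS = frozenset({"ATG"})


def three_letter(aa: str) -> str:
    """Three-letter code for a one-letter amino acid; '*' renders as 'Ter'."""
    return seq3(aa)


@dataclass(frozen=True)
class CodonChange:
    cds_pos: int          # 1-based offset of the substituted base in the CDS
    codon_index: int      # 1-based codon number
    codon_pos: int        # 1-3 position within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str           # one-letter
    alt_aa: str
    kind: str             # synonymous | missense | stop_gain | stop_loss | start_loss

    @property
    def aa_change(self) -> str:
        """Formatted amino-acid change, e.g. 'Ala > Gly'."""
        return f"{three_letter(self.ref_aa)} > {three_letter(self.alt_aa)}"


def project_to_cds(variant: VariantKey, model: GeneModel) -> tuple[int, str, str]:
    """Map a genomic SNV into CDS coordinates.

    Returns (cds_pos, coding_ref, coding_alt). For minus-strand models the
    coding alleles are the reverse complements of the genomic alleles.
    Raises ``ValueError`` if the position falls outside every CDS segment
    ("non-coding") or the projected reference base disagrees with the
    stored CDS sequence ("reference mismatch").
    """
    offset = 0
    for chrom, start, end in model.cds_segments:
        if chrom == variant.chrom and start <= variant.pos <= end:
            if model.strand == "+":
                cds_pos = offset + (variant.pos - start + 1)
                coding_ref, coding_alt = variant.ref, variant.alt
            else:
                cds_pos = offset + (end - variant.pos + 1)
                coding_ref = reverse_complement(variant.ref)
                coding_alt = reverse_complement(variant.alt)
            expected = model.cds_sequence[cds_pos - 1]
            if expected != coding_ref:
                raise ValueError(
                    f"reference mismatch: {variant} projects to CDS position "
                    f"{cds_pos} of {model.transcript} which holds {expected!r}, "
                    f"not coding ref {coding_ref!r}"
                )
            return cds_pos, coding_ref, coding_alt
        offset += end - start + 1
    raise ValueError(f"non-coding: {variant} lies outside the CDS of {model.transcript}")


def codon_change(
    cds_pos: int, coding_ref: str, coding_alt: str, model: GeneModel
) -> CodonChange:
    """Apply a coding-strand substitution to its codon and classify it."""
    codon_index = (cds_pos - 1) // 3 + 1
    codon_pos = (cds_pos - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = model.cds_sequence[start : start + 3]
    if ref_codon[codon_pos - 1] != coding_ref:
        raise ValueError(
            f"reference mismatch in codon {codon_index} of {model.transcript}"
        )
    alt_codon = (
        ref_codon[: codon_pos - 1] + coding_alt + ref_codon[codon_pos:]
    )
    ref_aa, alt_aa = TRANSLATE[ref_codon], TRANSLATE[alt_codon]
    if codon_index == 1 and ref_codon in START_CODONS and alt_codon not in START_CODONS:
        kind = "start_loss"
    elif ref_aa == alt_aa:
        kind = "synonymous"
    elif alt_aa == "*":
        kind = "stop_gain"
    elif ref_aa == "*":
        kind = "stop_loss"
    else:
        kind = "missense"
    return CodonChange(
        cds_pos=cds_pos, codon_index=codon_index, codon_pos=codon_pos,
        ref_codon=ref_codon, alt_codon=alt_codon,
        ref_aa=ref_aa, alt_aa=alt_aa, kind=kind,
    )


def variant_codon_change(variant: VariantKey, model: GeneModel) -> CodonChange:
    """Project a genomic SNV into its codon and classify the substitution."""
    cds_pos, cref, calt = project_to_cds(variant, model)
    return codon_change(cds_pos, cref, calt, model)


def brute_force_codon_change(variant: VariantKey, model: GeneModel) -> tuple[str, str]:
    """Oracle: rebuild the entire mutant CDS, translate both full sequences
    and diff the proteins. Returns (ref_aa, alt_aa) one-letter codes at the
    (single) differing residue, or (aa, aa) if the proteins are identical.
    Test use only; independent of the codon arithmetic above."""
    cds_pos, cref, calt = project_to_cds(variant, model)
    ref_cds = model.cds_sequence
    alt_cds = ref_cds[: cds_pos - 1] + calt + ref_cds[cds_pos:]

    def _translate(s: str) -> str:
        return "".join(TRANSLATE[s[i : i + 3]] for i in range(0, len(s), 3))

    ref_prot, alt_prot = _translate(ref_cds), _translate(alt_cds)
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if not diffs:
        i = (cds_pos - 1) // 3
        return ref_prot[i], alt_prot[i]
    (i,) = diffs
    return ref_prot[i], alt_prot[i]


def annotate_candidates(
    candidates: list[CandidateVariant],
    models: dict[str, GeneModel],
) -> list[CandidateVariant]:
    """Fill each candidate's ``aa_change`` from its transcript's gene model.

    Candidates without a model (by transcript ID, falling back to a unique
    model for the gene) keep an empty aa_change and are logged. A CDS
    reference mismatch is a hard error naming the variant.
    """
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models.values():
        by_gene.setdefault(m.gene, []).append(m)

    out: list[CandidateVariant] = []
    for c in candidates:
        model = models.get(c.transcript)
        if model is None:
            gene_models = by_gene.get(c.gene, [])
            model = gene_models[0] if len(gene_models) == 1 else None
        if model is None:
            log.warning("no gene model for %s (%s); aa_change left empty",
                        c.variant, c.gene)
            out.append(replace(c, aa_change=""))
            continue
        try:
            change = variant_codon_change(c.variant, model)
        except ValueError as exc:
            raise ValueError(f"{c.variant}: {exc}") from exc
        out.append(replace(c, aa_change=change.aa_change))
    return out
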