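"""Readers and writers for the pipeline's standard-format inputs.

All genomic coordinates are VCF-native: 1-based, fully closed. Only
biallelic SNVs are retained at ingest; multiallelic records are split into
per-alternate biallelic keys and anything that is not a single-base
substitution (indels, MNVs, symbolic/breakend alleles) is excluded and
counted. Genotypes are unordered and unphased: the only representable
calls are 0/0, 0/1, 1/1 and missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

# Genotype codes used throughout the package.
HOM_REF = 0  # 0/0
HET = 1      # 0/1
HOM_ALT = 2  # 1/1
MISSING = -1

GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
STR_GT = {v: k for k, v in GT_STR.items()}
STR_GT["1/0"] = HET  # unordered: 1/0 normalizes to 0/1
STR_GT["0|1"] = HET
STR_GT["1|0"] = HET
STR_GT["0|0"] = HOM_REF
STR_GT["1|1"] = HOM_ALT
STR_GT["."] = MISSING


@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic SNV identified by chromosome, 1-based position and alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"ref/alt must be single bases A/C/G/T, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class GenotypeMatrix:
    """Sites x samples table of diploid genotype calls.

    ``calls`` is an int8 array of shape (n_variants, n_samples) holding the
    codes HOM_REF/HET/HOM_ALT/MISSING.
    """

    variants: list[VariantKey]
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("duplicate variant keys in matrix")
        bad = set(np.unique(self.calls)) - {HOM_REF, HET, HOM_ALT, MISSING}
        if bad:
            raise ValueError(f"invalid genotype codes {bad}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call(self, variant_index: int, sample: str) -> int:
        return int(self.calls[variant_index, self.samples.index(sample)])

    def to_dataframe(self) -> pd.DataFrame:
        """Genotype strings indexed by variant key string, one column per sample."""
        return pd.DataFrame(
            [[GT_STR[int(c)] for c in row] for row in self.calls],
            index=[str(v) for v in self.variants],
            columns=self.samples,
        )


@dataclass
class GroupAssignment:
    """Sample -> phenotype-group mapping with exactly two non-empty groups."""

    mapping: dict[str, str]
    groups: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        labels = sorted(set(self.mapping.values()))
        if len(labels) != 2:
            raise ValueError(f"two groups required, got {labels}")
        self.groups = {g: sum(1 for v in self.mapping.values() if v == g) for g in labels}
        if any(n == 0 for n in self.groups.values()):
            raise ValueError("both groups must be non-empty")

    def members(self, group: str) -> list[str]:
        if group not in self.groups:
            raise ValueError(f"unknown group {group!r}; have {sorted(self.groups)}")
        return [s for s, g in self.mapping.items() if g == group]


ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "effect_class", "gene", "transcript", "strand", "cds_pos",
]


def _recode_genotype(gt: tuple, alt_index: int) -> int:
    """Recode a raw diploid genotype tuple against one alternate allele.

    Alleles equal to ``alt_index`` count as alt (1); every other called
    allele (reference or another alternate) counts as ref (0). Any missing
    allele makes the whole call missing.
    """
    if gt is None or len(gt) != 2 or any(a is None for a in gt):
        return MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    return (HOM_REF, HET, HOM_ALT)[n_alt]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are split into biallelic (chrom, pos, ref, alt)
    keys. Non-SNV alternates are dropped and counted in a log summary.
    Phased separators are normalized away (calls are unordered).

    Raises ``ValueError`` if the VCF lacks a GT FORMAT field or if a
    biallelic key occurs twice.
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        if "GT" not in vcf.header.formats:
            raise ValueError(f"{path}: VCF has no GT FORMAT field")
        samples = list(vcf.header.samples)
        variants: list[VariantKey] = []
        rows: list[list[int]] = []
        seen: set[VariantKey] = set()
        n_excluded = 0
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                if (
                    alt is None
                    or len(rec.ref) != 1
                    or len(alt) != 1
                    or rec.ref not in _BASES
                    or alt not in _BASES
                ):
                    n_excluded += 1
                    continue
                key = VariantKey(str(rec.chrom), int(rec.pos), rec.ref, alt)
                if key in seen:
                    raise ValueError(f"{path}: duplicate variant key {key}")
                seen.add(key)
                variants.append(key)
                rows.append(
                    [_recode_genotype(rec.samples[s].get("GT"), ai) for s in samples]
                )
    if n_excluded:
        log.info("%s: excluded %d non-SNV allele(s)", path, n_excluded)
    calls = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(variants, samples, calls)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
        header.contigs.add(chrom, length=400_000_000)
    for s in matrix.samples:
        header.add_sample(s)
    gt_tuple = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, v in enumerate(matrix.variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            for j, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = gt_tuple[int(matrix.calls[i, j])]
                rec.samples[s].phased = False
            out.write(rec)


def read_group_manifest(path: str | Path, samples: Sequence[str]) -> GroupAssignment:
    """Read a two-column (sample, group) manifest covering ``samples``.

    Manifest samples absent from ``samples`` are dropped with a warning;
    a sample present in ``samples`` but missing from the manifest is a
    hard error, as is any group count other than two.
    """
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>group', got {line!r}")
        sample, group = parts
        if sample not in samples:
            log.warning("%s: sample %r not in matrix, dropped", path, sample)
            continue
        mapping[sample] = group
    missing = [s for s in samples if s not in mapping]
    if missing:
        raise ValueError(f"{path}: samples missing from manifest: {missing}")
    return GroupAssignment(mapping)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the 9-column per-variant annotation TSV.

    Columns: chrom, pos, ref, alt, effect_class, gene, transcript, strand,
    cds_pos. Effect-class strings are preserved verbatim. Keys must be
    unique per (variant, transcript).
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "gene": str, "transcript": str},
        keep_default_na=False,
    )
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
            if not str(row.effect_class).strip():
                raise ValueError("empty effect_class")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    dupes = df.duplicated(subset=["chrom", "pos", "ref", "alt", "transcript"])
    if dupes.any():
        first = df[dupes].iloc[0]
        raise ValueError(
            f"{path}: duplicate (variant, transcript) row at "
            f"{first.chrom}:{first.pos}{first.ref}>{first.alt} {first.transcript}"
        )
    df["pos"] = df["pos"].astype(int)
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ANNOTATION_COLUMNS)


def read_term_sets(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file: term, description, then tab-separated gene symbols.

    Genes are upper-cased for matching; duplicates within a term collapse.
    Terms with zero genes are dropped with a warning.
    """
    terms: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        term = fields[0]
        genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        if not genes:
            log.warning("%s: term %r has no genes, dropped", path, term)
            continue
        terms[term] = genes
    return terms


def write_term_sets(terms: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, "na", *sorted(genes)]) + "\n")


# --- gene models -----------------------------------------------------------

GENE_MODEL_COLUMNS = [
    "seqid", "source", "type", "start", "end", "strand", "phase", "gene", "transcript",
]


@dataclass
class GeneModel:
    """A transcript's CDS: ordered genomic segments plus the spliced sequence.

    ``cds_segments`` are 1-based closed (chrom, start, end) intervals listed
    in coding (5'->3') order; for minus-strand transcripts that is
    descending genomic order and ``cds_sequence`` is the reverse complement
    of the concatenated genomic slices.
    """

    gene: str
    transcript: str
    strand: str
    cds_segments: list[tuple[str, int, int]]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        total = sum(e - s + 1 for _, s, e in self.cds_segments)
        if total != len(self.cds_sequence):
            raise ValueError(
                f"{self.transcript}: segment lengths sum to {total} but CDS is "
                f"{len(self.cds_sequence)} nt"
            )
        if len(self.cds_sequence) % 3:
            raise ValueError(f"{self.transcript}: CDS length not divisible by 3")


def read_gene_models(
    gff_path: str | Path, fasta_path: str | Path
) -> dict[str, GeneModel]:
    """Load gene models from a GFF3-like CDS table plus a FASTA of spliced CDS.

    The table holds one row per CDS segment (type == CDS) with explicit
    gene and transcript columns; FASTA records are keyed by transcript ID.
    Returns a mapping transcript ID -> :class:`GeneModel`.
    """
    df = pd.read_csv(gff_path, sep="\t", dtype={"seqid": str}, keep_default_na=False)
    missing = [c for c in GENE_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{gff_path}: missing columns {missing}")
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    models: dict[str, GeneModel] = {}
    for tx, sub in df[df["type"] == "CDS"].groupby("transcript", sort=False):
        strand = sub["strand"].iloc[0]
        segs = [
            (str(r.seqid), int(r.start), int(r.end))
            for r in sub.itertuples(index=False)
        ]
        # coding order: ascending genomic for +, descending for -
        segs.sort(key=lambda t: t[1], reverse=(strand == "-"))
        if tx not in seqs:
            raise ValueError(f"{fasta_path}: no CDS sequence for transcript {tx}")
        models[tx] = GeneModel(
            gene=str(sub["gene"].iloc[0]),
            transcript=str(tx),
            strand=strand,
            cds_segments=segs,
            cds_sequence=seqs[tx],
        )
    return models


def write_gene_models(
    models: Mapping[str, GeneModel], gff_path: str | Path, fasta_path: str | Path
) -> None:
    rows = []
    for m in models.values():
        for chrom, s, e in sorted(m.cds_segments, key=lambda t: t[1]):
            rows.append(
                {
                    "seqid": chrom, "source": "cosegscan", "type": "CDS",
                    "start": s, "end": e, "strand": m.strand, "phase": ".",
                    "gene": m.gene, "transcript": m.transcript,
                }
            )
    pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS).to_csv(gff_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for m in models.values():
            fh.write(f">{m.transcript} gene={m.gene}\n{m.cds_sequence}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
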