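"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators:

* :func:`generate_cohort` — a two-group cohort VCF whose background sites
  draw each sample's genotype independently under Hardy-Weinberg
  equilibrium at a per-site allele frequency, with a configurable number
  of spiked group-cosegregating variants, plus the matching group
  manifest, annotation table and a truth table of the spiked keys.

* :func:`table1_fixture` — the published worked example: a 9-sample
  cohort (6 non-susceptible NSA, 3 susceptible SA minipigs) carrying the
  eight chromosome-7 missense SNVs in the SLA-1/SLA-2/SLA-3/TAP2 antigen
  presentation genes with their printed genotype vectors, engineered
  minimal CDS gene models reproducing the published amino-acid changes,
  decoy records that must not survive the cosegregation filter, and an
  antigen-processing term set inside a 102-gene universe.

All randomness flows from a single integer seed through one generator and
outputs are canonically sorted, so identical seeds give byte-identical
bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .cosegregation import chance_cosegregation_probability, hwe_genotype_probs
from .variant_io import (
    ANNOTATION_COLUMNS,
    GT_STR,
    HET,
    HOM_ALT,
    HOM_REF,
    GeneModel,
    GenotypeMatrix,
    VariantKey,
    reverse_complement,
    write_annotations,
    write_gene_models,
    write_term_sets,
    write_vcf,
)

# ---------------------------------------------------------------------------
# The published worked example: 8 cosegregating missense SNVs on chromosome 7.
# Per row: position, gene, genomic ref/alt, NSA-group and SA-group shared
# genotypes, the reference codon in coding orientation, the position of the
# substituted base within that codon, the transcript strand, and the expected
# amino-acid change. The codon contexts are synthetic minimal CDS neighbour-
# hoods engineered to be consistent with each (ref, alt, aa change) triple;
# they are not the real Sscrofa11.1 transcripts.
TABLE1_ROWS = [
    # pos, gene, ref, alt, nsa_gt, sa_gt, ref_codon, codon_pos, strand, aa_change
    (22824499, "SLA-1", "C", "G", HOM_REF, HET, "GCC", 2, "+", "Ala > Gly"),
    (22824966, "SLA-1", "T", "A", HET, HOM_REF, "ATG", 2, "+", "Met > Lys"),
    (22824998, "SLA-1", "G", "A", HOM_REF, HET, "GGA", 1, "+", "Gly > Arg"),
    (22916775, "SLA-2", "C", "T", HOM_REF, HET, "CCT", 2, "+", "Pro > Leu"),
    (22958209, "SLA-2", "C", "G", HET, HOM_REF, "ATC", 3, "+", "Ile > Met"),
    (22939351, "SLA-3", "A", "T", HOM_REF, HET, "ACA", 1, "+", "Thr > Ser"),
    (25056205, "TAP2", "G", "C", HOM_ALT, HET, "CTG", 1, "-", "Leu > Val"),
    (25056210, "TAP2", "T", "G", HOM_ALT, HET, "GAG", 2, "-", "Glu > Ala"),
]
TABLE1_CHROM = "7"
CONTROL_SAMPLES = [f"NSA{i}" for i in range(1, 7)]
CASE_SAMPLES = [f"SA{i}" for i in range(1, 4)]
CASE_LABEL, CONTROL_LABEL = "SA", "NSA"

#: (case genotype, control genotype) patterns observed in the worked example.
TABLE1_SPIKE_PATTERNS = sorted({(sa, nsa) for _, _, _, _, nsa, sa, *_ in TABLE1_ROWS})


@dataclass
class FileBundle:
    """Paths of one generated input bundle."""

    vcf: Path
    manifest: Path
    annotations: Path
    truth: Path | None = None
    gene_models: Path | None = None
    cds_fasta: Path | None = None
    gmt: Path | None = None
    universe: Path | None = None


@dataclass
class CohortConfig:
    """Study conditions for a simulated two-group cohort.

    Defaults mirror the study design the pipeline targets: 3 susceptible
    cases against 6 non-susceptible controls, background SNVs at uniform
    alternate-allele frequencies 0.05-0.5, and 8 spiked cosegregating
    variants following the published genotype patterns.
    """

    n_case: int = 3
    n_control: int = 6
    n_background_snvs: int = 5000
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    n_spiked: int = 8
    spike_patterns: list[tuple[int, int]] = field(
        default_factory=lambda: list(TABLE1_SPIKE_PATTERNS)
    )
    fraction_exonic: float = 0.002
    spiked_effect: str = "missense variant"
    fraction_spiked_nonexonic: float = 0.0
    seed: int = 1

    BACKGROUND_CHROM = "1"
    BACKGROUND_POOL = 10_000_000
    SPIKE_CHROM = "7"
    SPIKE_POOL_START = 22_000_000
    SPIKE_POOL = 1_000_000

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both groups need at least one sample")
        if not 0.0 <= self.fraction_exonic <= 1.0:
            raise ValueError("fraction_exonic must lie in [0, 1]")
        lo, hi = self.allele_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("allele_freq_range must satisfy 0 <= lo <= hi <= 1")
        for case_gt, control_gt in self.spike_patterns:
            if case_gt == control_gt:
                raise ValueError("spike patterns must have case != control genotype")
        if self.n_background_snvs > self.BACKGROUND_POOL:
            raise ValueError("n_background_snvs exceeds available positions")
        if self.n_spiked > self.SPIKE_POOL:
            raise ValueError("n_spiked exceeds available positions")

    @property
    def samples(self) -> list[str]:
        return [f"{CONTROL_LABEL}{i}" for i in range(1, self.n_control + 1)] + [
            f"{CASE_LABEL}{i}" for i in range(1, self.n_case + 1)
        ]


def draw_hwe_genotypes(rng: np.random.Generator, p_alt: float, n: int) -> np.ndarray:
    """Draw n independent diploid genotype codes under HWE at frequency p_alt."""
    return rng.choice(3, size=n, p=hwe_genotype_probs(p_alt)).astype(np.int8)


def _random_ref_alt(rng: np.random.Generator) -> tuple[str, str]:
    bases = "ACGT"
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return bases[i], bases[j]


def mean_chance_cosegregation(
    freq_range: tuple[float, float], n_case: int, n_control: int
) -> float:
    """E_p[P(chance cosegregation)] for p ~ Uniform(freq_range)."""
    lo, hi = freq_range
    if hi == lo:
        return chance_cosegregation_probability(lo, n_case, n_control)
    val, _ = quad(
        lambda p: chance_cosegregation_probability(p, n_case, n_control), lo, hi
    )
    return val / (hi - lo)


def expected_background_cosegregants(config: CohortConfig) -> float:
    """Analytic expectation of background sites landing in the discordant set."""
    return config.n_background_snvs * mean_chance_cosegregation(
        config.allele_freq_range, config.n_case, config.n_control
    )


def expected_exonic_background_cosegregants(config: CohortConfig) -> float:
    """Expected background discordant sites that also carry a whitelisted class."""
    return expected_background_cosegregants(config) * config.fraction_exonic


def generate_cohort(config: CohortConfig, outdir: str | Path) -> FileBundle:
    """Emit a cohort bundle: VCF, group manifest, annotation TSV, truth table.

    Background genotypes are sampled independently per (site, sample) under
    HWE at the site's allele frequency; spiked sites receive their pattern
    genotypes exactly. Positions are unique and sorted; identical seeds
    give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    samples = config.samples
    n_samples = len(samples)

    bg_pos = np.sort(
        rng.choice(config.BACKGROUND_POOL, size=config.n_background_snvs, replace=False)
        + 1
    )
    spike_pos = np.sort(
        rng.choice(config.SPIKE_POOL, size=config.n_spiked, replace=False)
        + config.SPIKE_POOL_START
    )

    variants: list[VariantKey] = []
    calls: list[np.ndarray] = []
    ann_rows: list[dict] = []
    truth_rows: list[dict] = []

    freqs = rng.uniform(*config.allele_freq_range, size=config.n_background_snvs)
    for pos, p in zip(bg_pos, freqs):
        ref, alt = _random_ref_alt(rng)
        variants.append(VariantKey(config.BACKGROUND_CHROM, int(pos), ref, alt))
        calls.append(draw_hwe_genotypes(rng, float(p), n_samples))
        exonic = rng.random() < config.fraction_exonic
        ann_rows.append(
            {
                "chrom": config.BACKGROUND_CHROM, "pos": int(pos),
                "ref": ref, "alt": alt,
                "effect_class": "missense variant" if exonic else "intergenic_variant",
                "gene": f"BG{pos:08d}", "transcript": "", "strand": "+", "cds_pos": "",
            }
        )

    control_slice = slice(0, config.n_control)
    case_slice = slice(config.n_control, n_samples)
    for i, pos in enumerate(spike_pos):
        ref, alt = _random_ref_alt(rng)
        case_gt, control_gt = config.spike_patterns[i % len(config.spike_patterns)]
        row = np.empty(n_samples, dtype=np.int8)
        row[control_slice] = control_gt
        row[case_slice] = case_gt
        variants.append(VariantKey(config.SPIKE_CHROM, int(pos), ref, alt))
        calls.append(row)
        nonexonic = rng.random() < config.fraction_spiked_nonexonic
        effect = "intron_variant" if nonexonic else config.spiked_effect
        gene = f"SPIKE{i + 1:02d}"
        ann_rows.append(
            {
                "chrom": config.SPIKE_CHROM, "pos": int(pos), "ref": ref, "alt": alt,
                "effect_class": effect, "gene": gene,
                "transcript": "", "strand": "+", "cds_pos": "",
            }
        )
        truth_rows.append(
            {
                "chrom": config.SPIKE_CHROM, "pos": int(pos), "ref": ref, "alt": alt,
                "case_genotype": GT_STR[case_gt], "control_genotype": GT_STR[control_gt],
                "effect_class": effect, "gene": gene,
            }
        )

    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    matrix = GenotypeMatrix(
        [variants[i] for i in order], samples, np.vstack([calls[i] for i in order])
    )

    bundle = FileBundle(
        vcf=outdir / "cohort.vcf",
        manifest=outdir / "groups.tsv",
        annotations=outdir / "annotations.tsv",
        truth=outdir / "truth.tsv",
    )
    write_vcf(matrix, bundle.vcf)
    _write_manifest(samples, config.n_control, bundle.manifest)
    ann = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    ann = ann.sort_values(["chrom", "pos"], kind="stable")
    write_annotations(ann, bundle.annotations)
    truth_cols = ["chrom", "pos", "ref", "alt", "case_genotype",
                  "control_genotype", "effect_class", "gene"]
    pd.DataFrame(truth_rows, columns=truth_cols).sort_values(
        ["chrom", "pos"], kind="stable"
    ).to_csv(bundle.truth, sep="\t", index=False)
    return bundle


def _write_manifest(samples: list[str], n_control: int, path: Path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(samples):
            fh.write(f"{s}\t{CONTROL_LABEL if i < n_control else CASE_LABEL}\n")


# ---------------------------------------------------------------------------
# Worked-example fixture


def _engineered_models() -> dict[str, GeneModel]:
    """Minimal CDS contexts consistent with the worked example's changes.

    Each transcript gets a 3-bp start-codon segment, one 3-bp segment per
    variant holding its designed reference codon in frame, and a 3-bp stop
    segment, so the CDS is ATG + variant codons + TAA read in coding order.
    """
    by_gene: dict[str, list[tuple]] = {}
    for pos, gene, ref, alt, _, _, codon, cpos, strand, _ in TABLE1_ROWS:
        by_gene.setdefault(gene, []).append((pos, ref, codon, cpos, strand))

    models: dict[str, GeneModel] = {}
    for gene, rows in by_gene.items():
        strand = rows[0][4]
        rows.sort(key=lambda r: r[0], reverse=(strand == "-"))  # coding order
        segments: list[tuple[str, int, int]] = []
        codons: list[str] = []
        positions = [r[0] for r in rows]
        if strand == "+":
            segments.append((TABLE1_CHROM, min(positions) - 60, min(positions) - 58))
            for pos, ref, codon, cpos, _ in rows:
                assert codon[cpos - 1] == ref
                segments.append((TABLE1_CHROM, pos - cpos + 1, pos - cpos + 3))
                codons.append(codon)
            segments.append((TABLE1_CHROM, max(positions) + 58, max(positions) + 60))
        else:
            segments.append((TABLE1_CHROM, max(positions) + 58, max(positions) + 60))
            for pos, ref, codon, cpos, _ in rows:
                assert codon[cpos - 1] == reverse_complement(ref)
                segments.append((TABLE1_CHROM, pos + cpos - 3, pos + cpos - 1))
                codons.append(codon)
            segments.append((TABLE1_CHROM, min(positions) - 60, min(positions) - 58))
        tx = f"{gene}-tx1"
        models[tx] = GeneModel(
            gene=gene, transcript=tx, strand=strand,
            cds_segments=segments,
            cds_sequence="ATG" + "".join(codons) + "TAA",
        )
    return models


def _decoy_records(n_decoys: int, n_control: int, n_case: int):
    """Deterministic records that must never survive the cosegregation filter.

    Cycles through failure modes: within-case discordance, within-control
    discordance, identical consensus in both groups, and a missing call in
    one group.
    """
    bases = "ACGT"
    records = []
    for i in range(n_decoys):
        pos = 30_000_000 + 17 * i
        ref = bases[i % 4]
        alt = bases[(i + 1) % 4]
        control = np.full(n_control, HOM_REF, dtype=np.int8)
        case = np.full(n_case, HET, dtype=np.int8)
        mode = i % 4
        if mode == 0:       # case group internally discordant
            case[-1] = HOM_REF
        elif mode == 1:     # control group internally discordant
            control[-1] = HET
        elif mode == 2:     # identical consensus in both groups
            control[:] = HET
        else:               # missing call breaks the control consensus
            control[0] = -1
        records.append((pos, ref, alt, np.concatenate([control, case])))
    return records


def table1_fixture(
    outdir: str | Path, n_decoys: int = 20, universe_size: int = 102,
    n_extra_terms: int = 5, seed: int = 0,
) -> FileBundle:
    """Emit the published worked example as a complete input bundle.

    The VCF holds the 8 printed chromosome-7 records with their exact
    9-sample genotype vectors plus ``n_decoys`` non-passing decoys; the
    annotation TSV maps each printed record to its gene as a missense
    variant; engineered gene models reproduce the printed amino-acid
    changes; the GMT contains an antigen-processing term holding exactly
    {SLA-1, SLA-2, SLA-3, TAP2} inside a ``universe_size``-gene universe.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = CONTROL_SAMPLES + CASE_SAMPLES

    variants: list[VariantKey] = []
    calls: list[np.ndarray] = []
    ann_rows: list[dict] = []
    for pos, gene, ref, alt, nsa_gt, sa_gt, _, _, strand, _ in TABLE1_ROWS:
        variants.append(VariantKey(TABLE1_CHROM, pos, ref, alt))
        calls.append(
            np.array([nsa_gt] * len(CONTROL_SAMPLES) + [sa_gt] * len(CASE_SAMPLES),
                     dtype=np.int8)
        )
        ann_rows.append(
            {
                "chrom": TABLE1_CHROM, "pos": pos, "ref": ref, "alt": alt,
                "effect_class": "missense variant", "gene": gene,
                "transcript": f"{gene}-tx1", "strand": strand, "cds_pos": "",
            }
        )
    for pos, ref, alt, row in _decoy_records(
        n_decoys, len(CONTROL_SAMPLES), len(CASE_SAMPLES)
    ):
        variants.append(VariantKey(TABLE1_CHROM, pos, ref, alt))
        calls.append(row)
        ann_rows.append(
            {
                "chrom": TABLE1_CHROM, "pos": pos, "ref": ref, "alt": alt,
                "effect_class": "missense variant", "gene": f"DECOY{pos}",
                "transcript": "", "strand": "+", "cds_pos": "",
            }
        )

    order = sorted(range(len(variants)), key=lambda i: variants[i].pos)
    matrix = GenotypeMatrix(
        [variants[i] for i in order], samples, np.vstack([calls[i] for i in order])
    )

    bundle = FileBundle(
        vcf=outdir / "table1.vcf",
        manifest=outdir / "groups.tsv",
        annotations=outdir / "annotations.tsv",
        gene_models=outdir / "gene_models.tsv",
        cds_fasta=outdir / "cds.fasta",
        gmt=outdir / "terms.gmt",
        universe=outdir / "universe.txt",
    )
    write_vcf(matrix, bundle.vcf)
    _write_manifest(samples, len(CONTROL_SAMPLES), bundle.manifest)
    ann = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    write_annotations(ann.sort_values(["chrom", "pos"], kind="stable"), bundle.annotations)
    write_gene_models(_engineered_models(), bundle.gene_models, bundle.cds_fasta)

    candidate_genes = ["SLA-1", "SLA-2", "SLA-3", "TAP2"]
    fillers = [f"GENE{i:03d}" for i in range(1, universe_size - len(candidate_genes) + 1)]
    universe = candidate_genes + fillers
    bundle.universe.write_text("\n".join(universe) + "\n")
    generate_term_sets(
        universe=universe,
        n_terms=n_extra_terms,
        enriched_term=("antigen_processing_and_presentation", candidate_genes),
        seed=seed,
        path=bundle.gmt,
    )
    return bundle


def table1_expected() -> pd.DataFrame:
    """The printed worked-example table for parse-back verification."""
    rows = [
        {
            "chrom": TABLE1_CHROM, "pos": pos, "gene": gene, "ref": ref, "alt": alt,
            "nsa_genotype": GT_STR[nsa], "sa_genotype": GT_STR[sa],
            "effect_class": "missense variant", "aa_change": aa,
        }
        for pos, gene, ref, alt, nsa, sa, _, _, _, aa in TABLE1_ROWS
    ]
    return pd.DataFrame(rows)


def random_gene_model(
    rng: np.random.Generator,
    gene: str = "TOY",
    transcript: str = "TOY-tx",
    max_segments: int = 3,
    max_codons: int = 20,
    chrom: str = "1",
) -> GeneModel:
    """A random toy transcript: <= ``max_segments`` CDS segments on either
    strand, CDS of 2..max_codons codons, arbitrary sequence content."""
    n_codons = int(rng.integers(2, max_codons + 1))
    length = 3 * n_codons
    cds = "".join(rng.choice(list("ACGT"), size=length))
    strand = "+" if rng.random() < 0.5 else "-"
    n_seg = int(rng.integers(1, min(max_segments, length) + 1))
    cuts = sorted(rng.choice(np.arange(1, length), size=n_seg - 1, replace=False))
    bounds = [0, *map(int, cuts), length]
    lengths = [bounds[i + 1] - bounds[i] for i in range(n_seg)]  # coding order

    # lay segments on the genome in ascending order with random gaps; for a
    # minus-strand model the genomic order is the reverse of coding order
    genomic_lengths = lengths if strand == "+" else lengths[::-1]
    segs_genomic: list[tuple[str, int, int]] = []
    pos = int(rng.integers(100, 1000))
    for seg_len in genomic_lengths:
        segs_genomic.append((chrom, pos, pos + seg_len - 1))
        pos += seg_len + int(rng.integers(5, 50))
    coding_order = segs_genomic if strand == "+" else segs_genomic[::-1]
    return GeneModel(
        gene=gene, transcript=transcript, strand=strand,
        cds_segments=coding_order, cds_sequence=cds,
    )


def all_coding_snvs(model: GeneModel):
    """Every possible SNV within a model's CDS segments, as genomic keys."""
    offset = 0
    for chrom, start, end in model.cds_segments:
        for within in range(1, end - start + 2):
            cds_pos = offset + within
            coding_base = model.cds_sequence[cds_pos - 1]
            if model.strand == "+":
                pos, genomic_ref = start + within - 1, coding_base
            else:
                pos, genomic_ref = end - within + 1, reverse_complement(coding_base)
            for alt in "ACGT":
                if alt != genomic_ref:
                    yield VariantKey(chrom, pos, genomic_ref, alt)
        offset += end - start + 1


def generate_term_sets(
    universe: list[str],
    n_terms: int,
    enriched_term: tuple[str, list[str]],
    seed: int,
    path: str | Path,
) -> dict[str, list[str]]:
    """Write a GMT of random terms (sizes 2-30) plus one designated term.

    The enriched term's genes must all be in the universe. Deterministic
    per seed.
    """
    name, genes = enriched_term
    if not set(genes) <= set(universe):
        raise ValueError("enriched term genes must be a subset of the universe")
    rng = np.random.default_rng(seed)
    terms: dict[str, list[str]] = {name: list(genes)}
    for i in range(n_terms):
        size = int(rng.integers(2, min(31, len(universe) + 1)))
        members = rng.choice(len(universe), size=size, replace=False)
        terms[f"RANDOM_TERM_{i + 1:03d}"] = [universe[j] for j in sorted(members)]
    write_term_sets(terms, path)
    return terms
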