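"""End-to-end orchestration: cosegregation -> consequence filter -> gene map
-> enrichment -> amino-acid change, with a machine-readable run report."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .consequence import EffectWhitelist, filter_by_effect, map_to_genes
from .cosegregation import discordant_sites, discordant_to_rows, group_consensus
from .enrichment import enrich
from .protein_impact import annotate_candidates
from .variant_io import (
    GT_STR,
    read_annotations,
    read_gene_models,
    read_group_manifest,
    read_term_sets,
    read_vcf,
)

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunReport:
    """Per-stage counts plus the parameters that produced them."""

    n_input_snvs: int
    set_a_size: int
    set_b_size: int
    set_c_size: int
    n_candidates: int
    n_genes: int
    n_enriched_terms: int | None
    exonic_fraction: float | None  # percent of set C surviving the whitelist
    parameters: dict[str, Any]
    version: str = __version__
    schema_version: int = REPORT_SCHEMA_VERSION


def compute_exonic_fraction(n_whitelisted: int, n_set_c: int) -> float | None:
    """Whitelisted candidates as a percentage of the discordant set, to two
    decimal places; None (JSON null) when the discordant set is empty."""
    if n_set_c == 0:
        return None
    return round(100.0 * n_whitelisted / n_set_c, 2)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def run_pipeline(config: dict[str, Any] | str | Path) -> RunReport:
    """Execute the full analysis described by a config mapping (or YAML/JSON
    file path) and write result tables plus ``report.json`` to ``out_dir``.

    Required keys: vcf, groups, annotations, out_dir. Optional: case_label
    (default SA), control_label (default NSA), max_missing (0), effects
    (whitelist override), split_compound (false), gmt, universe,
    min_term_size (2), max_term_size (500), alpha (0.05), gene_models,
    cds_fasta, seed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    for key in ("vcf", "groups", "annotations", "out_dir"):
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    case = config.get("case_label", "SA")
    control = config.get("control_label", "NSA")

    def stage(name, fn, *args, **kwargs):
        log.info("=== stage: %s ===", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    matrix = stage("read_vcf", read_vcf, config["vcf"])
    assignment = stage(
        "read_groups", read_group_manifest, config["groups"], matrix.samples
    )
    max_missing = int(config.get("max_missing", 0))
    set_a = stage("consensus_case", group_consensus, matrix, assignment, case, max_missing)
    set_b = stage(
        "consensus_control", group_consensus, matrix, assignment, control, max_missing
    )
    set_c = stage("discordant", discordant_sites, set_a, set_b)
    pd.DataFrame(
        discordant_to_rows(set_c, case, control),
        columns=["chrom", "pos", "ref", "alt", f"genotype_{case}", f"genotype_{control}"],
    ).to_csv(out_dir / "set_c.tsv", sep="\t", index=False)
    log.info("set A: %d, set B: %d, set C: %d", len(set_a), len(set_b), len(set_c))

    annotations = stage("read_annotations", read_annotations, config["annotations"])
    whitelist = EffectWhitelist(
        classes=tuple(config["effects"]) if config.get("effects") else
        EffectWhitelist.__dataclass_fields__["classes"].default,
        split_compound=bool(config.get("split_compound", False)),
    )
    candidates = stage("effect_filter", filter_by_effect, set_c, annotations, whitelist)
    genes = stage("gene_map", map_to_genes, candidates)
    log.info("candidates: %d in %d gene(s)", len(candidates), len(genes))

    if config.get("gene_models"):
        models = stage(
            "read_models", read_gene_models, config["gene_models"], config["cds_fasta"]
        )
        candidates = stage("aa_change", annotate_candidates, candidates, models)

    pd.DataFrame(
        [
            {
                "chrom": c.variant.chrom, "pos": c.variant.pos,
                "ref": c.variant.ref, "alt": c.variant.alt,
                f"genotype_{case}": GT_STR[c.genotype_a],
                f"genotype_{control}": GT_STR[c.genotype_b],
                "effect_class": c.effect_class, "gene": c.gene,
                "transcript": c.transcript, "aa_change": c.aa_change,
            }
            for c in candidates
        ],
        columns=["chrom", "pos", "ref", "alt", f"genotype_{case}",
                 f"genotype_{control}", "effect_class", "gene", "transcript",
                 "aa_change"],
    ).to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene": g, "n_variants": n} for g, n in genes.items()],
        columns=["gene", "n_variants"],
    ).to_csv(out_dir / "genes.tsv", sep="\t", index=False)

    n_enriched: int | None = None
    if config.get("gmt"):
        terms = stage("read_terms", read_term_sets, config["gmt"])
        if config.get("universe"):
            universe = {
                g.strip().upper()
                for g in Path(config["universe"]).read_text().split()
                if g.strip()
            }
        else:
            universe = {g.upper() for g in genes}
        alpha = float(config.get("alpha", 0.05))
        result = stage(
            "enrich", enrich,
            {g.upper() for g in genes}, terms, universe,
            int(config.get("min_term_size", 2)), int(config.get("max_term_size", 500)),
        )
        result.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
        n_enriched = int((result["p_raw"] < alpha).sum()) if len(result) else 0
        log.info("enriched terms at p < %s: %s", alpha, n_enriched)

    report = RunReport(
        n_input_snvs=matrix.n_variants,
        set_a_size=len(set_a),
        set_b_size=len(set_b),
        set_c_size=len(set_c),
        n_candidates=len(candidates),
        n_genes=len(genes),
        n_enriched_terms=n_enriched,
        exonic_fraction=compute_exonic_fraction(len(candidates), len(set_c)),
        parameters={
            k: v for k, v in sorted(config.items())
        },
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(asdict(report), fh, indent=2, default=str)
        fh.write("\n")
    return report
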