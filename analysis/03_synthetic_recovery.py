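"""Spike-in recovery on synthetic HWE cohorts.

Simulates 20 cohorts (5,000 neutral background SNVs at p ~ U(0.05, 0.5),
8 spiked variants following the worked example's genotype patterns,
background exonic fraction 0.002), runs the cosegregation + whitelist
filter on each, and compares the background discordant-site counts with
the analytic null-model expectation. Writes results/recovery.tsv.

Finding: the 8 spiked variants are recovered exactly in every replicate;
mean background discordant sites match the analytic expectation within
Monte-Carlo error, and essentially none of them survive the exonic
whitelist.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from cosegscan.consequence import filter_by_effect
from cosegscan.cosegregation import discordant_sites, group_consensus
from cosegscan.synthetic_data import (
    CohortConfig,
    expected_background_cosegregants,
    expected_exonic_background_cosegregants,
    generate_cohort,
)
from cosegscan.variant_io import read_annotations, read_group_manifest, read_vcf

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "recovery.tsv"
BASE = dict(n_background_snvs=5000, n_spiked=8, fraction_exonic=0.002)


def main() -> None:
    mu = expected_background_cosegregants(CohortConfig(**BASE))
    mu_exonic = expected_exonic_background_cosegregants(CohortConfig(**BASE))
    rows = []
    with tempfile.TemporaryDirectory() as tmp:
        for seed in range(1, 21):
            cfg = CohortConfig(**BASE, seed=seed)
            bundle = generate_cohort(cfg, Path(tmp) / str(seed))
            matrix = read_vcf(bundle.vcf)
            groups = read_group_manifest(bundle.manifest, matrix.samples)
            set_c = discordant_sites(
                group_consensus(matrix, groups, "SA"),
                group_consensus(matrix, groups, "NSA"),
            )
            candidates = filter_by_effect(
                set_c, read_annotations(bundle.annotations)
            )
            truth = pd.read_csv(bundle.truth, sep="\t", dtype={"chrom": str})
            spiked = set(zip(truth.chrom, truth.pos))
            recovered = {(c.variant.chrom, c.variant.pos) for c in candidates}
            rows.append(
                {
                    "seed": seed,
                    "set_c": len(set_c),
                    "background_set_c": len(set_c) - len(spiked),
                    "candidates": len(candidates),
                    "spikes_recovered": len(recovered & spiked),
                    "false_candidates": len(recovered - spiked),
                }
            )
    df = pd.DataFrame(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT, sep="\t", index=False)
    se = df.background_set_c.std(ddof=1) / np.sqrt(len(df))
    print(f"wrote {OUT}")
    print(f"spikes recovered: {df.spikes_recovered.min()}-{df.spikes_recovered.max()} of 8 "
          f"across {len(df)} seeds; false candidates total: {df.false_candidates.sum()}")
    print(f"background set-C mean {df.background_set_c.mean():.2f} "
          f"(analytic {mu:.2f}, MC SE {se:.2f})")
    print(f"expected exonic background survivors per cohort: {mu_exonic:.3f}")


if __name__ == "__main__":
    main()
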