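"""Chance cosegregation under the Hardy-Weinberg null model.

Tabulates, for the 3-vs-6 study design and some alternatives, the
probability that a neutral unlinked biallelic site passes the
cosegregation filter by chance, as a function of allele frequency, and
checks the closed form against exhaustive enumeration at small sizes.
Writes results/null_model.tsv.

Finding: at the 3-vs-6 design the per-site chance rate peaks near
2.5e-3 around p = 0.2 and falls as either group grows, so a genome-scale
discordant-site list unavoidably carries a neutral background.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cosegscan.cosegregation import (
    chance_cosegregation_probability,
    enumerate_cosegregation_probability,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "null_model.tsv"


def main() -> None:
    freqs = np.round(np.arange(0.05, 0.51, 0.05), 2)
    designs = [(3, 6), (2, 2), (4, 8), (5, 10)]
    rows = [
        {
            "p_alt": p,
            "n_case": na,
            "n_control": nb,
            "p_chance": chance_cosegregation_probability(float(p), na, nb),
        }
        for na, nb in designs
        for p in freqs
    ]
    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT, sep="\t", index=False)

    # closed form vs brute force at an enumerable size
    worst = max(
        abs(
            chance_cosegregation_probability(p, 2, 3)
            - enumerate_cosegregation_probability(p, 2, 3)
        )
        for p in (0.1, 0.3, 0.5)
    )
    df = pd.DataFrame(rows)
    study = df[(df.n_case == 3) & (df.n_control == 6)]
    print(f"wrote {OUT}")
    print(f"max |closed - enumerated| at (2,3): {worst:.2e}")
    peak = study.loc[study.p_chance.idxmax()]
    print(f"3-vs-6 design peaks at p={peak.p_alt}: {peak.p_chance:.3e} per site")
    print(f"=> expected chance sites per 5,000 neutral SNVs at p~U(0.05,0.5): "
          f"{5000 * study.p_chance.mean():.1f} (grid mean)")


if __name__ == "__main__":
    main()
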