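# cosegscan

Candidate-gene discovery for small two-group cohorts by genotype
cosegregation filtering, with consequence-class filtering, gene-set
enrichment and codon-level amino-acid-change derivation.

## The problem

When a phenotype splits a small, otherwise-matched cohort cleanly into
two groups — the motivating case is diet-induced atherosclerosis in Bama
minipigs, with 3 susceptible (SA) and 6 non-susceptible (NSA) animals —
whole-genome SNP genotypes can be filtered for *cosegregating* variants:
sites where every member of a group carries the identical genotype call
and the two groups' shared calls differ. Formally, with groups of sizes
$n_A$ and $n_B$ and unordered diploid calls $g \in \{0/0,\ 0/1,\ 1/1\}$:

- **set A** — sites with one shared call across all $n_A$ case samples,
- **set B** — likewise across all $n_B$ control samples,
- **set C** — sites in both A and B whose two consensus calls differ
  (a homozygous-reference consensus counts, so 0/0-vs-0/1 is discordant).

Set C is then restricted to exonic/splice consequence classes (5′UTR
premature-start-gain, missense, splice-region and its compounds), mapped
to genes, tested for term over-representation with an upper-tail
hypergeometric test and Benjamini–Hochberg adjustment

$$p = \sum_{i\ge k} \binom{K}{i}\binom{N-K}{n-i} \Big/ \binom{N}{n},$$

and, for missense candidates with gene models, the affected codon is
located in the CDS (strand-aware), substituted, and translated to an
amino-acid change.

A Hardy–Weinberg null model quantifies the filter's chance behaviour: a
neutral unlinked site at alternate-allele frequency $p$ lands in set C
with probability $\sum_{g_1 \ne g_2} P(g_1)^{n_A} P(g_2)^{n_B}$ where
$P(0/0)=(1-p)^2$, $P(0/1)=2p(1-p)$, $P(1/1)=p^2$.

## Worked example

The package ships the published worked example as a generated fixture:
a 9-sample VCF with eight chromosome-7 missense SNVs in the swine MHC
class-I genes *SLA-1*, *SLA-2*, *SLA-3* and the peptide transporter
*TAP2*, plus 20 decoy records that violate within-group concordance.

```bash
python analysis/01_table1_reanalysis.py
```

prints

```
input SNVs:        28
set A (SA):        23
set B (NSA):       18
set C (discordant): 8
candidates:        8
genes:             4
exonic fraction:   100.0%
 chrom      pos ref alt  gene aa_change
     7 22824499   C   G SLA-1 Ala > Gly
     7 22824966   T   A SLA-1 Met > Lys
     7 22824998   G   A SLA-1 Gly > Arg
     7 22916775   C   T SLA-2 Pro > Leu
     7 22939351   A   T SLA-3 Thr > Ser
     7 22958209   C   G SLA-2 Ile > Met
     7 25056205   G   C  TAP2 Leu > Val
     7 25056210   T   G  TAP2 Glu > Ala

top enriched term: antigen_processing_and_presentation (p_raw=2.35e-07)
```

All 28 input records pass through the filter chain; exactly the eight
genuine cosegregating records survive (every decoy fails within-group
concordance or between-group discordance), they map to four genes, and
the antigen-processing term containing those four genes is the top hit
against the 102-gene universe. The amino-acid changes are re-derived
from engineered CDS contexts, including the reverse-strand *TAP2* cases.

The other drivers characterise the method on synthetic data:
`analysis/02_null_model.py` tabulates the chance-cosegregation rate
(peaking near 2.5×10⁻³ per neutral site at p ≈ 0.2 for the 3-vs-6
design) and `analysis/03_synthetic_recovery.py` simulates 20 cohorts of
5,000 HWE background SNVs plus 8 spiked pattern variants, recovering all
spikes in every replicate with background discordant-site counts
matching the analytic expectation (mean 7.65 observed vs 7.70 analytic).

Everything is also scriptable through the `cosegscan` CLI
(`run`, `coseg`, `filter`, `enrich`, `aachange`, `simulate`, `fixture`).

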