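# Methods

## Cosegregation filter

The core procedure treats a multi-sample set of biallelic SNV genotypes
as a sites × samples matrix of unordered diploid calls
{0/0, 0/1, 1/1, missing} and a two-group phenotype assignment. For each
group it computes the *consensus set* — sites where every group member
carries the identical non-missing call — and intersects the two sets,
keeping sites whose consensus calls differ (the discordant set, "set C").
Three interpretive choices are built in:

- **Homozygous reference is a consensus.** "0/0 everywhere in one group,
  0/1 everywhere in the other" is discordant. This is the only reading
  consistent with the worked example, whose rows include 0/0-vs-0/1,
  0/1-vs-0/0 and 1/1-vs-0/1 patterns.
- **Missing calls are strict by default.** Any missing call removes the
  site from that group's consensus set. `max_missing` relaxes this to
  "consensus among the called members, with at most k missing", for
  callers that emit sporadic no-calls; the default is 0 because the
  worked example has no missing calls and strictness is conservative at
  these group sizes.
- **No quality re-filtering.** Depth/quality filtering belongs upstream
  in the variant caller; this package consumes a final VCF.

An alternative reading of "discordant between the groups" — the
symmetric difference of the two consensus sets, i.e. keeping sites
concordant in only one group — cannot be fully excluded from the prose
it derives from, but it is not needed to reproduce any worked-example
row, and the both-consensus reading is the stricter one. We implement
the both-consensus reading only.

## Null model

For interpretation (not as a claim of the original analysis) the package
provides the probability that a neutral, unlinked site passes the filter
by chance, assuming Hardy–Weinberg genotype frequencies and independent
samples:

P(set C) = Σ_{g1≠g2} P(g1)^{n_A} · P(g2)^{n_B}

with P(0/0) = (1−p)², P(0/1) = 2p(1−p), P(1/1) = p². For the 3-vs-6
design this peaks at ≈ 2.5×10⁻³ per site near p = 0.2, which is why a
genome-scale discordant list contains tens of thousands of sites and the
exonic whitelist is the step that does the real narrowing. The closed
form is verified in the tests against exhaustive enumeration of all
3^(n_A+n_B) genotype configurations.

## Consequence filtering

Annotation is taken as a precomputed TSV (variant → effect class, gene,
transcript) because consequence calling is an upstream concern; the one
place the package re-derives biology from sequence is the codon-level
step below. The default whitelist holds the six exonic/splice classes
(5′UTR premature start gain, missense, splice region, and the three
splice-region compounds). Matching normalizes case and whitespace so
"missense variant" and "missense_variant" are equivalent; compound
classes match on the full compound string by default, with
`split_compound` to accept any component. A variant annotated to several
transcripts or genes yields one candidate per (variant, transcript,
gene) pair.

## Enrichment

Over-representation is an upper-tail hypergeometric test per term,
computed by summing the PMF in log space (log-gamma binomials +
log-sum-exp) so that extreme counts do not underflow, followed by
Benjamini–Hochberg step-up adjustment with cumulative-minimum
enforcement. Both are authored here rather than delegated so they can be
validated against independent oracles (draw enumeration for N ≤ 12;
statsmodels for BH). The universe defaults to the gene-mapped discordant
genes — the natural background when the input list is itself the
product of the filter — and is overridable. Terms are size-filtered
(default 2–500) before testing; the significance threshold defaults to
raw p < 0.05 with adjusted values always reported, mirroring the
screening-oriented usage this pipeline targets.

## Protein impact

Candidates are projected into transcript CDS coordinates by summing
segment lengths in coding order; on the minus strand the coding alleles
are reverse complements and the offset counts from the 3′ genomic end.
The affected codon (index ⌈pos/3⌉, within-codon position
((pos−1) mod 3)+1) is substituted and both codons translated under the
standard genetic code (hard-coded; these are nuclear genes), classifying
the change as synonymous, missense, stop gain/loss, or start loss (ATG
at codon 1 losing start status takes precedence). Output format is
three-letter codes with " > " ("Ala > Gly") to match the tabular style
of the worked example. A projection whose reference base disagrees with
the stored CDS is a hard error, not a warning — it means the gene model
and the VCF disagree about the genome.

The worked example's gene models are **synthetic minimal CDS contexts**:
per gene, a start codon segment, one 3-bp segment per variant holding a
codon consistent with the printed base and amino-acid change (SLA-1/2/3
forced to the plus strand, TAP2 to the minus strand by the printed
changes), and a stop segment. Real Sscrofa11.1 transcripts are
deliberately not used: the published table states no transcript IDs or
strands, so validation is against the printed strings, at desk scale,
with no external downloads.

## Synthetic cohorts

`generate_cohort` emulates the study conditions: 3 case vs 6 control
samples; background biallelic SNVs whose genotypes are drawn
independently per sample under HWE at per-site alternate-allele
frequencies ~ U(0.05, 0.5) (a screen of common-to-intermediate
variation; sites rarer than 0.05 are nearly invisible to a 9-sample
design); spiked variants set exactly to the worked example's
(case, control) genotype patterns; and an annotation table marking
spikes as missense and a fraction (default 0.002) of background sites
with whitelisted classes, chosen so the expected number of background
sites that both pass the filter and carry an exonic class stays below
0.05 per cohort at the default 5,000 background sites (the analytic
expectation of background discordant sites is ≈ 7.7; × 0.002 ≈ 0.015).
All randomness flows from one integer seed through one NumPy generator
and outputs are canonically sorted, so equal seeds give byte-identical
bundles.

What the generator does *not* emulate — linkage disequilibrium between
sites, population structure beyond the two groups, genotyping error, and
missingness — bounds what passing tests show: they validate the filter's
logic and its null calibration under independence, not its false-positive
rate on real cohorts, where LD makes chance cosegregants cluster.

## Problem sizes and numerical choices

The test suite and analysis drivers run the recovery experiment at
5,000 background sites × 20 seeds and the codon oracle at 1,000 random
toy models (≤ 3 segments, ≤ 10 codons, both strands, every contained
SNV), sizes at which the Monte-Carlo standard error on the background
discordant-site count is ≈ 0.6 sites and the oracle coverage exceeds
10,000 substitutions. Oracle agreement tolerances are 10⁻¹² (both sides
are essentially exact); the HWE sanity check uses a χ² goodness-of-fit
at n = 50,000 and α = 0.001. Enrichment ties are broken by term ID for
deterministic output; multiallelic VCF records are split per alternate
with other alternates recoded as reference, and anything that is not a
single-base substitution is excluded at ingest with a logged count.

## Known limitations

- The genome-scale counts the method was originally applied to are not
  reproducible here: they derive from unreleased sequencing data. The
  package reproduces the published worked example exactly and
  characterises everything else on synthetic cohorts.
- The filter has no tolerance for genotype error: one miscalled sample
  removes a true site from its group's consensus (quantifiable via
  `max_missing` only for no-calls, not wrong calls).
- Enrichment treats term sets as flat gene lists; there is no ontology
  propagation.
- Protein impact is single-variant: two nearby substitutions in one
  codon are evaluated independently, not as a haplotype.
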