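# Methods

## Turnover model

Each domain of the model genome (a gene or a heterochromatin block) holds a
regular grid of nucleosome positions (one dyad per `nucleosome_spacing` =
150 bp). Every position starts OLD, carrying the locus mark: H3K4me2 in
genes, H3K9me2 in heterochromatin when the Clr4 methyltransferase is
active. A simulation draws a Pol II passage count per domain,
N ~ Poisson(passage_rate × epochs), multiplied by the genotype's
`het_derepression` in heterochromatin (silencing mutants transcribe the
repeats more). Each passage applies, independently per position:

1. eviction with probability `p_loss = p0 · (1 − r)` — any occupied
   nucleosome (OLD or NEW) becomes NAKED;
2. refill of NAKED positions with probability `p_fill`
   (`p_fill_5prime` over the first `k_5prime` positions downstream of the
   TSS) — the position becomes NEW, marked K56ac only.

Assumptions built into this parameterization:

- Eviction and retention are memoryless and identical per passage, so the
  OLD fraction decays geometrically, `E[OLD] = (1 − p_loss)^N`. This is
  the minimal model with one knob per biological actor: `p0` for the bare
  Pol II–nucleosome collision, `r` for chaperone-mediated retention.
- Locus-specific methylation is never re-placed cotranscriptionally;
  K4me2/K9me2 counts are non-increasing in passage number (enforced by
  construction and by property tests).
- K56ac persists on NEW histones for the whole simulation. There is no
  cell cycle and no explicit deacetylation; K56ac functions purely as a
  new-deposition label. This is configurable only in the sense that the
  simulation has no reaction that would remove it.
- N-terminal acetylation (AcH3/AcH4) is not simulated kinetically; its
  ChIP density is a fixed euchromatic baseline (0.5) plus an increment
  (1.0) on NEW histones, so acetylation signal tracks turnover.
- Swi6 ChIP density is proportional to K9me2 density (the HP1 protein
  reads the mark); it has no independent dynamics.
- Pol II ChIP density is the domain's effective passage rate spread
  uniformly over the domain.

## Genotypes

| name            | r (retention) | het_derepression | clr4_active |
|-----------------|---------------|------------------|-------------|
| WT              | 1.0           | 1                | yes         |
| spt6-K20        | 0.5           | 2                | yes         |
| spt6Δ           | 0.0           | 4                | yes         |
| clr3Δ           | 0.85          | 3                | yes         |
| clr4Δ           | 0.85          | 4                | no          |
| spt6-K20 clr3Δ  | 0.425         | 6                | yes         |

`r` is the *overall* cotranscriptional retention efficiency, not a property
of Spt6 alone. Clr3 (and heterochromatin integrity generally) also
restrains turnover, so `clr3Δ`/`clr4Δ` carry a mildly reduced retention
(0.85) in addition to derepressed heterochromatic transcription; modeling
Clr3 loss through derepression alone would give the single `clr3Δ` mutant
zero turnover (r = 1 ⇒ p_loss = 0) and could not produce its elevated
pericentromeric K56ac. The double mutant composes multiplicatively
(retention 0.5 × 0.85, derepression 2 × 3), which is what makes the
parallel-pathway additivity emerge: more passages (from `clr3Δ`) times a
higher per-passage loss (from `spt6-K20`). Only `r` differs between spt6
alleles; whether the hypomorph also affects deposition is not
distinguishable at this level, so `p_fill` is genotype-independent.

## Default parameters

| parameter           | default | units    | role |
|---------------------|---------|----------|------|
| p0                  | 0.3     | prob.    | eviction per passage, unprotected |
| p_fill              | 0.4     | prob.    | refill of a naked position per passage |
| p_fill_5prime       | 0.1     | prob.    | refill over the first nucleosomes |
| k_5prime            | 3       | nucleosomes | extent of the 5' refill deficit |
| epochs              | 1.0     | —        | duration multiplier on passage rates |
| strata rates        | 8/4/2/0.5 | passages | the four transcription strata |
| heterochromatin rate| 1.0     | passages | basal cryptic transcription |
| read_length         | 49      | bp       | single-end read span |
| fragment_length     | 250     | bp       | sonicated fragment span |
| nucleosome_spacing  | 150     | bp       | dyad grid |
| background_fraction | 0.05    | —        | uniform reads; qPCR background term |
| n_reads             | 100 000 | reads    | library size per ChIP sample |
| qpcr_replicates     | 3       | —        | replicate IP efficiencies |
| noise_cv            | 0.15    | —        | lognormal CV of qPCR replicates |

`p0` and the strata rates are chosen so that, at one epoch, the most
highly transcribed quartile in the null-retention mutant loses most of its
old histones (E[OLD] = e^(−8·0.3) ≈ 0.09) while the lowest quartile keeps
most (≈ 0.86), spanning the dynamic range the analyses need; `p_fill` then
sets the compensating occupancy near its stationary value
p_fill/(p_fill + p_loss). The 49-bp single-end read geometry matches the
sequencing layout of the study design this emulates; fragment length and
spacing are ordinary ChIP/chromatin values. Library sizes are scaled to a
~130-kb model genome (40 genes × 2 kb plus gaps and two 6-kb
heterochromatin blocks) so that per-gene coverage — a few thousand
fragments per gene — is comparable in informativeness to tens of millions
of reads on a real genome while keeping simulations fast.

## ChIP read and qPCR sampling

Fragment midpoints are drawn from nucleosome weights for the chosen
antibody target (uniform for input), mixed with `background_fraction`
uniform positions, jittered uniformly within ±spacing/2 of the dyad and
clamped so fragments fit the chromosome; the read is the 5' 49 bases of
either fragment end with equal probability. All reads are "mapped"; there
is no base-level sequence, quality or mappability model. qPCR IP
efficiencies per (mark, amplicon) are the mean target weight per
nucleosome position inside the amplicon plus the background term,
multiplied by mean-one lognormal noise with the configured CV; the table
always includes total-H3 (C-terminal antibody) and total-H4 reference rows.

## Analysis stages: numerical choices

- Coordinates are 0-based half-open everywhere internally; SAM and GFF3
  are converted at the I/O boundary.
- Pileup optionally extends reads to fragment length in the strand
  direction (used for ChIP samples; input is piled up unextended).
- Log-ratio tracks use pseudocount c = 0.5 per-million, keeping ratios
  bounded over read-free regions.
- The region caller estimates window fragment counts as coverage sums
  divided by the library's mean fragment span, and tests them against
  Poisson(λ_local) with λ_local the maximum of the genome-wide control
  rate and the control rate over 1/5/10-kb spans centred on the window,
  scaled by the library-size ratio. Windows of 300 bp slide in 100-bp
  steps; p < 1e−5 (strict) windows are merged across gaps ≤ 300 bp and
  regions shorter than 500 bp dropped. Ties at exactly the threshold are
  excluded. The same λ_local serves both tails; decreases use the lower
  tail on the treatment track.
- Fragment-to-gene assignment is by read midpoint, strand-agnostic, genes
  non-overlapping. Fold changes use pseudocount 0.1 FPKM so silent genes
  stay finite. The 0.8-fold and 2-fold classification cutoffs are strict
  inequalities: a gene at exactly the cutoff is not flagged.
- Expression strata are quartiles of wild-type Pol II FPKM (descending;
  ties broken by gene id), a stand-in for an externally curated gene-set
  definition; the top quartile is "Very high".
- Metagene profiles use the per-offset *median* across genes, windows
  oriented 5'→3', out-of-genome positions treated as missing (never zero),
  offsets supported by fewer than half the class's genes masked. Default
  windows: TSS −500..+2000, TTS −2000..+500, 10-bp output grid. No
  per-gene rescaling before aggregation.
- qPCR replicate series are paired by index and summarized as
  mean-of-ratios with its sample s.d. (rather than ratio-of-means), so the
  reported dispersion reflects replicate scatter; cross-genotype ratios
  propagate s.d. by first-order quadrature. AcH4 must be referenced to
  total H4, every other mark to C-terminal H3; region-relative reporting
  (act1, gene-free region) operates on raw efficiencies with no
  per-histone step.

## What the generator does and does not emulate

It emulates: transcription strata, genotype-dependent eviction and
Spt6-independent K56ac refilling, the 5' refill deficit, heterochromatin
with derepression in silencing mutants, read sampling with uniform
background, and replicate qPCR noise. It does not emulate: replication-
coupled turnover or any cell cycle, nucleosome positioning thermodynamics,
sequence composition or mappability artifacts, duplicate reads, antisense
transcription, or the RNAi machinery. Passing tests therefore demonstrate
that the analysis stages recover the planted turnover signal under clean,
correctly calibrated sampling — not that they are robust to the mapping
and chromatin-preparation artifacts of real libraries.

## Known limitations

- The single λ_local definition (maximum over control spans) is
  conservative for enrichment calls but anti-conservative for depletion
  calls next to locally high control signal: low-coverage inter-genic
  gaps adjacent to covered genes can be reported as "decrease" regions in
  genotype comparisons. The null-calibration bound holds on homogeneous
  backgrounds; structured backgrounds inherit this asymmetry.
- Because tracks and FPKM are normalized per million mapped reads, global
  occupancy loss redistributes signal: weakly transcribed genes can show
  fold changes above 1 even though their absolute occupancy is unchanged.
  This mirrors the behavior of depth-normalized real data and is visible
  in the demo summary.
- Per-gene FPKM uses whole-gene midpoint counts; there is no isoform or
  UTR handling.
- With the default 40-gene genome, class medians rest on 10 genes each;
  ordering assertions in the test suite therefore aggregate over 20
  simulation seeds (median, or a ≥ 90%-of-seeds criterion where a
  per-seed event is asserted).
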