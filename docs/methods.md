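# Methods

## The generative model

The simulator emulates a forward-genetics mapping-by-sequencing
experiment on a recessive, fully penetrant, monogenic trait.

**Genome and genes.** Chromosomes are i.i.d. uniform A/C/G/T sequences
(default: 3 chromosomes × 5 Mb, 150 cM each — a desk-scale stand-in for
a 21-chromosome cereal genome). `n_genes` (default 300) non-overlapping
protein-coding genes are written into the sequence: 1–3 exons, a CDS of
51–253 codons starting with ATG, free of internal stops and ending in a
stop codon, 30 bp UTR flanks, introns of 60–300 bp with GT..AG
boundaries, random strand. Every simulated CDS therefore translates
cleanly, which the effect annotator and its translation oracle rely on.

**Mutations.** The mutagenized line carries `n_mutations` (default 600)
SNPs. With probability `ems_fraction` (default 0.99, the canonical EMS
bias) a mutation is a C→T or G→A transition on the reference strand;
otherwise a random substitution at a random site. Exactly one mutation
is causal: it is re-drawn until it is an EMS transition at a CDS
position whose substitution is missense. Genetic position is physical
position scaled by `chrom_cM / chrom_bp` (uniform map).

**Meiosis and pooling.** Each F2 is the sum of two independent gametes.
A gamete is a crossover mosaic of the two parental haplotypes: crossover
count per chromosome ~ Poisson(`chrom_cM`/100), breakpoints uniform in
genetic position (no interference), starting haplotype a fair coin —
i.e. the Haldane model, chosen as the simplest model consistent with
standard recombination; an interference model could be swapped into
`_simulate_gametes` without touching anything else. An individual is
phenotype-positive iff homozygous mutant at the causal locus. The first
`pool_size` (default 15) positives form the pool; if fewer exist among
the `n_f2` simulated individuals, the simulator raises an error advising
a larger `n_f2`. The default `n_f2` is 200: a study that raises ~69 F2s
observes ~15 positives on average, but a generator that *requires* 15
homozygotes needs headroom, since Binomial(69, ¼) falls below 15 about a
quarter of the time. Pool size, depth and the 1:3 segregation model
follow the study design exactly.

Under this model the expected pooled allele frequency at a marker `d`
Morgans from the causal locus is `1 − r`, `r = ½(1 − e^(−2d))`; the
truth table records this expectation per site (0.5 on unlinked
chromosomes), and the linkage-decay checks measure it on pool genotypes,
where the law is exact, rather than on reads, which add sampling noise
and an error-induced bias of order `seq_error`.

**Read sampling.** Depth per site ~ Poisson(`mean_depth`, default 30).
Each read reports the mutant allele with probability equal to the pooled
allele frequency and is flipped to the other allele with probability
`seq_error` (default 0.01). Zero-depth sites are emitted with AD 0,0.
This two-allele flip model is deliberately simple; see Limitations for
its interaction with the zero-reference-read filter.

**Side tables.** Expression is log-normal TPM (meanlog 2.0, sdlog 1.2 —
median ≈ 7 TPM, a typical transcript abundance scale) over 3 seed, 7
glume and 8 spikelet samples; the causal gene is forced above the 0.5
TPM threshold everywhere, and 30% of other genes are forced below it in
at least one sample so the expression filter has teeth. Orthogroups are
a random grouping of the simulated proteins (~85% assigned, groups of
~5) plus 20 species-tagged foreign "known seed-shape" proteins, one of
which is placed in the causal gene's orthogroup; a few known proteins
are deliberately left without an orthogroup. The background set shares
10% of the non-causal mutations, emulating variants also present in
sibling lines or parents.

All stages draw from `numpy.random.default_rng` seeded from the single
config seed, so every emitted file is byte-stable under a fixed
configuration.

## Analysis defaults and why

| parameter | default | rationale |
|---|---|---|
| window size | 100 variants | standard pooled-scan window; step 1 (maximal resolution) |
| min total depth | 15 | depth condition bound to window membership |
| region `af_min` | 0.7 | see below |
| region `min_windows` | 5 | suppresses single-window noise |
| funnel `min_alt_depth` / `max_ref_depth` | 15 / 0 | homozygous-pool read signature |
| funnel `impact_min` | MODERATE | missense and worse |
| funnel `tpm_min` | 0.5, strict `>` in **every** sample of seed/glume/spikelet | expressed-everywhere requirement |
| Wilcoxon `exact_max_n` | 25 | exact permutation p feasible via subset-sum DP |

**Region threshold.** At the desk-scale map density (~200 variants per
150 cM chromosome) a 100-variant window spans ~75 cM, so the median
member of even the best-centred window sits ~19 cM from the causal
locus, where the expected AF is ≈ 0.84. A 0.9 cutoff would therefore
almost never fire at this density, while the unlinked background — the
median of 100 sites centred on 0.5 — has a standard deviation of ~0.02.
The default 0.7 sits more than 10 SD above background yet is reachable
by the causal peak; on denser maps a higher cutoff is appropriate and is
exposed on the CLI (`--af-min`). Step ii of the funnel can alternatively
use a whole target chromosome (`region_mode="chromosome"`), which is the
natural mode when reproducing a published funnel keyed to a chromosome;
region mode is the default for simulations.

**Funnel semantics.** Steps run in the order impact → location → read
support → expression. A gene qualifies only if one variant passes steps
i–iii simultaneously; the final candidate set is therefore invariant to
step order (verified by test), and only intermediate counts depend on
it. Genes absent from the expression matrix fail step iv.

**Statistics.** The segregation χ² uses no Yates continuity correction:
for 15/69 against 1:3 the uncorrected statistic is 0.391 (the value a
reader can check by hand); the corrected one would be 0.209. The exact
Wilcoxon p is computed by dynamic programming over the subset-sum
distribution of doubled midranks — numerically identical to enumerating
all C(n, n_x) assignments (the test suite proves this by brute force) —
two-sided by doubling the smaller tail, capped at 1. Above
`exact_max_n` a normal approximation with tie-corrected variance and
0.5 continuity correction is used; it tracks the exact p to < 0.01 at
20 + 20. Summary tables report sample SD (n − 1). Per-plant replicate
averages are the test units for seed traits.

## Effect annotation

One effect per overlapping protein-coding transcript (non-coding
transcripts are ignored); intergenic otherwise. CDS positions are
resolved to codon and within-codon offset in transcription order,
minus-strand alleles complemented before lookup. Classification:
start-codon disruption (codon 1 no longer ATG) → start_lost; identical
amino acid → synonymous; new stop → stop_gained; lost stop → stop_lost;
otherwise missense with 1-based residue numbering from the initiator
methionine and three-letter notation (`Pro303Leu`). Intronic positions
within 2 bp of an exon boundary are splice_site; exonic non-CDS
positions are 5'/3' UTR by transcription polarity. Impact tiers:
{intergenic, intron, UTR} → MODIFIER, synonymous → LOW, missense →
MODERATE, {stop gained/lost, start lost, splice site} → HIGH. Per-gene
impact is the maximum over all variants and transcripts. The annotator
guards against coordinate drift by requiring REF to match the reference
base and the gene model to agree with the genome.

The suite checks the annotator against an independent oracle that
translates the entire wild-type and mutant CDS and classifies from the
protein comparison, on both strands, including in the acceptance run
(1000 random CDS SNPs, 100% agreement required).

## What the simulation does and does not show

Passing tests demonstrate that the analysis recovers a causal locus
under the stated generative model: clean biallelic SNPs, a uniform
genetic map, fully penetrant monogenic selection, Poisson depth and a
symmetric two-allele error model. Real pooled resequencing adds mapping
artifacts, polyploid homoeology, copy-number and structural variation,
uneven coverage, imperfect phenotyping and reference bias — none of
which are modelled. Simulation results therefore validate the
*statistical machinery*, not performance on any particular real dataset.

## Known limitations

- **Error model vs the zero-reference-read filter.** With the two-allele
  flip model at 30× and `seq_error` 0.01, a truly fixed causal site
  acquires at least one reference-supporting error read with probability
  `1 − e^(−0.3) ≈ 0.26`, and the strict `max_ref_depth = 0` funnel rule
  then rejects it. Per-replicate funnel recovery of the causal gene is
  therefore capped near 74% at these settings even though the mapping
  signal (argmax chromosome) is recovered essentially always. Real
  variant callers count allele-supporting reads after base-quality
  filtering, where errors rarely register as reference support; a
  three-allele error model or a small `max_ref_depth` tolerance would
  lift the cap, but the defaults here keep the published filter and the
  simple error model as stated.
- Indels, structural variants and multi-allelic sites are out of scope
  (counted and skipped at VCF parsing).
- The crossover model has no interference; map distance is uniform in
  physical position.
- Residue numbering assumes the annotated CDS is complete and in frame.
- The orthogroup screen assumes globally unique protein identifiers.
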