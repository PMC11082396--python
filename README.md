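# oatmap

Mapping-by-sequencing analysis of pooled-F2 mutant experiments.

`oatmap` localizes a recessive, chemically induced (EMS) causal mutation
from pooled whole-genome sequencing of phenotype-selected F2
individuals — the forward-genetics design used to map seed-shape and
plant-architecture mutants in cereals such as hexaploid oat. It is a
Python library first (with an `examples/` directory of short narrative
scripts) and also ships a thin `oatmap` command-line interface for
running the pipeline from a shell.

## The method

An EMS mutant line carries hundreds of induced SNPs, one of which causes
the phenotype. Crossing the mutant to wild type and selfing the F1
yields an F2 population in which a recessive monogenic trait appears in
1/4 of individuals (the 1:3 ratio, checked with a Pearson χ²:
χ²(1) with no continuity correction). Pooling phenotype-positive F2s and
sequencing the pool gives, at every induced SNP, a mutant allele
frequency

    AF = AD_alt / (AD_ref + AD_alt)

whose expectation at a marker `d` Morgans from the causal locus is
`1 − r` with the Haldane recombination fraction
`r = ½(1 − e^(−2d))`: exactly 1 at the causal locus, decaying to ½ on
unlinked chromosomes. A sliding window of 100 consecutive variants
(total allelic depth ≥ 15) per chromosome, step 1, traces the median AF;
runs of high-median windows are called as enriched regions.

Candidate genes are then filtered through a four-stage funnel:

1. **impact** — the gene carries a SNP with MODERATE/HIGH consequence
   (missense, stop gained/lost, start lost, splice site), classified
   codon-by-codon against the gene models;
2. **location** — that SNP lies in the enriched region (or on the target
   chromosome);
3. **read support** — alternate depth ≥ 15 with no reference-supporting
   reads (a homozygous pool signature);
4. **expression** — the gene exceeds 0.5 TPM in every seed, glume and
   spikelet sample.

A single variant must satisfy steps 1–3 simultaneously. Finally an
orthogroup screen transfers known seed-shape genes from Arabidopsis,
rice, wheat and maize into the target species and intersects them with
the impacted genes.

Because real pooled resequencing data is bulky, the package includes a
first-class simulator of the entire design — genome and gene models, EMS
mutation spectrum (C→T/G→A), meiosis with Poisson crossovers (Haldane
model, no interference), phenotype selection, pooled read sampling with
error, and matched expression/orthogroup/background tables — with a
ground-truth table for every run.

## Worked example

```sh
python examples/04_segregation_and_phenotypes.py
```

prints

```
segregation: chi2(1, N = 69) = 0.39, P = 0.53  -> consistent with 1:3 (recessive, single locus)

glume length (mm):
           n  mean   sd
group
wild_type  6 21.60 0.55
mutant     6 10.87 0.36
Wilcoxon rank sum (exact): p = 0.0022 (pairwise table p = 0.0022)
```

The χ² line is the segregation check: 15 phenotype-positive plants among
69 F2s do not deviate from the 1:3 recessive expectation (P = 0.53). The
table compares a phenotype between genotypes; the exact rank-sum p-value
(enumeration over all group assignments, midranks for ties) shows the
mutant glumes are significantly shorter.

`examples/01_simulate_and_scan.py` runs the simulator and AF scan
end-to-end and reports whether the called enriched region contains the
true causal variant; `02_effect_annotation.py` shows consequence calls
(e.g. `chr1:35 C>T missense MODERATE Pro2Leu`); `03_candidate_funnel.py`
walks the funnel on a hand-traced 10-variant fixture (counts 5 → 4 → 2 →
1, candidate `g1`).

From a shell, the same stages are available as `oatmap simulate`,
`oatmap annotate`, `oatmap scan`, `oatmap filter`, `oatmap stats` and
`oatmap run --config run.yaml`.

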