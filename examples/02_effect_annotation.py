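"""Classify SNP consequences against a toy gene model.

A single-exon gene ATG-CCG-CAG-GCA-TAA is hit by four SNPs; each is
classified by codon arithmetic into the four-tier impact scheme. The
Pro->Leu change mirrors the canonical missense notation (e.g. a
kinase's Pro303Leu would print the same way at residue 303).
"""
from oatmap import GeneModels, Transcript, Variant, annotate_variant

cds = "ATG" + "CCG" + "CAG" + "GCA" + "TAA"
genome = {"chr1": "A" * 30 + cds + "A" * 30}
gene = Transcript("gsk1", "gsk1.1", "chr1", "+",
                  exons=((30, 30 + len(cds)),), cds=((30, 30 + len(cds)),))
models = GeneModels([gene])

snps = [
    Variant("chr1", 35, "C", "T", 0, 20),   # CCG -> CTG
    Variant("chr1", 37, "C", "T", 0, 20),   # CAG -> TAG
    Variant("chr1", 42, "A", "G", 0, 20),   # GCA -> GCG
    Variant("chr1", 10, "A", "G", 0, 20),   # upstream of the gene
]
for v in snps:
    (effect,) = annotate_variant(v, models, genome)
    print(f"{v.chrom}:{v.pos} {v.ref}>{v.alt}  {effect.consequence.value:<12} "
          f"impact {effect.impact.name:<8} {effect.protein_change or '-'}")
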