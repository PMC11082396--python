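"""A small hand-traced dataset exercising the candidate-gene funnel.

Ten SNPs over six genes on two chromosomes, built so every funnel step
eliminates at least one gene for a distinct, documented reason. The
expected per-step trace is packaged alongside so examples and tests can
verify the funnel against a by-hand count.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .filtering import FunnelConfig
from .model import (
    Consequence,
    Effect,
    ExpressionMatrix,
    IMPACT_OF,
    Variant,
)


def _effect(gene: str, consequence: Consequence, change: str = "") -> Effect:
    return Effect(
        gene_id=gene,
        transcript_id=f"{gene}.1",
        consequence=consequence,
        impact=IMPACT_OF[consequence],
        protein_change=change,
    )


def demo_funnel_dataset():
    """Return ``(variants, expression, config, expected)``.

    The ten variants, all on the sequenced pool's VCF scale:

    ====  ======  =========  ==========================  ===============
    gene  chrom   AD (r,a)   consequence                 eliminated at
    ====  ======  =========  ==========================  ===============
    g1    chr1    0,20       missense                    — (candidate)
    g2    chr1    0,25       synonymous                  step i (impact)
    g3    chr2    0,22       missense                    step ii (location)
    g4    chr1    2,21       missense                    step iii (ref reads)
    g5    chr1    0,10       missense                    step iii (alt depth)
    g6    chr1    0,30       stop gained                 step iv (expression)
    —     both    various    4 intergenic SNPs           step i
    ====  ======  =========  ==========================  ===============

    Expected per-step surviving gene counts: i=5, ii=4, iii=2, iv=1,
    final candidate g1.
    """
    intergenic = [
        Effect(None, None, Consequence.INTERGENIC, IMPACT_OF[Consequence.INTERGENIC])
    ]
    variants = [
        Variant("chr1", 1_000, "C", "T", 0, 20,
                effects=[_effect("g1", Consequence.MISSENSE, "Pro303Leu")]),
        Variant("chr1", 5_000, "G", "A", 0, 25,
                effects=[_effect("g2", Consequence.SYNONYMOUS)]),
        Variant("chr2", 3_000, "C", "T", 0, 22,
                effects=[_effect("g3", Consequence.MISSENSE, "Gly12Asp")]),
        Variant("chr1", 9_000, "C", "T", 2, 21,
                effects=[_effect("g4", Consequence.MISSENSE, "Ala76Val")]),
        Variant("chr1", 12_000, "G", "A", 0, 10,
                effects=[_effect("g5", Consequence.MISSENSE, "Ser9Asn")]),
        Variant("chr1", 15_000, "C", "T", 0, 30,
                effects=[_effect("g6", Consequence.STOP_GAINED, "Gln40Ter")]),
        Variant("chr1", 2_000, "A", "G", 8, 9, effects=list(intergenic)),
        Variant("chr1", 7_500, "T", "C", 10, 11, effects=list(intergenic)),
        Variant("chr2", 1_500, "C", "T", 12, 13, effects=list(intergenic)),
        Variant("chr2", 8_000, "G", "A", 9, 14, effects=list(intergenic)),
    ]
    samples = {
        "seed_01": "seed", "seed_02": "seed",
        "glume_01": "glume", "spikelet_01": "spikelet",
    }
    tpm = pd.DataFrame(
        np.full((6, 4), 5.0),
        index=pd.Index([f"g{i}" for i in range(1, 7)], name="gene_id"),
        columns=list(samples),
    )
    tpm.loc["g6", "seed_02"] = 0.1  # fails the >0.5 TPM-in-all-samples rule
    expression = ExpressionMatrix(values=tpm, groups=samples)
    config = FunnelConfig(region_mode="chromosome", target_chromosome="chr1")
    expected = {
        "step_counts": {"i": 5, "ii": 4, "iii": 2, "iv": 1},
        "final_genes": ["g1"],
    }
    return variants, expression, config, expected
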