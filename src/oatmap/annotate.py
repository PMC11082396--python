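"""SNP consequence classification against gene models.

Assigns each SNP one effect per overlapping protein-coding transcript
(codon-resolved for CDS positions, strand-aware) and an intergenic effect
when no transcript overlaps. Impact tiers follow the four-tier
MODIFIER/LOW/MODERATE/HIGH scheme used by standard annotators.
"""
from __future__ import annotations

from typing import Iterable, Mapping

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .model import (
    Consequence,
    Effect,
    GeneModels,
    IMPACT_OF,
    Impact,
    ReferenceMismatchError,
    Transcript,
    Variant,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Distance (bp, intron side) from an exon/intron boundary that counts as
#: a splice-site position.
SPLICE_REGION = 2


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def _aa3(aa: str) -> str:
    return seq3(aa)  # '*' -> 'Ter'


class EffectAnnotator:
    """Annotates variants against one genome + gene-model set.

    Caches per-transcript spliced CDS sequences, so reuse one instance
    when annotating many variants.
    """

    def __init__(self, gene_models: GeneModels, genome: Mapping[str, str]) -> None:
        self.models = gene_models
        self.genome = genome
        self._cds_cache: dict[str, str] = {}

    def cds_sequence(self, transcript: Transcript) -> str:
        """Spliced CDS in transcription orientation (5'->3')."""
        cached = self._cds_cache.get(transcript.transcript_id)
        if cached is not None:
            return cached
        chrom_seq = self.genome[transcript.chrom]
        parts = [chrom_seq[s:e] for s, e in transcript.cds]
        seq = "".join(parts)
        if transcript.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        self._cds_cache[transcript.transcript_id] = seq
        return seq

    # -- classification ----------------------------------------------------

    def annotate(self, variant: Variant) -> list[Effect]:
        """Classify one SNP; returns one Effect per overlapping coding
        transcript, or a single intergenic Effect."""
        chrom_seq = self.genome.get(variant.chrom)
        if chrom_seq is None:
            raise ReferenceMismatchError(
                f"chromosome {variant.chrom!r} absent from reference"
            )
        pos0 = variant.pos - 1
        if pos0 >= len(chrom_seq) or chrom_seq[pos0] != variant.ref:
            found = chrom_seq[pos0] if pos0 < len(chrom_seq) else "<out of range>"
            raise ReferenceMismatchError(
                f"{variant.chrom}:{variant.pos} REF {variant.ref!r} does not match "
                f"reference base {found!r}"
            )
        effects = []
        for t in self.models.overlapping(variant.chrom, pos0):
            if not t.cds:  # non-coding transcript models are not classified
                continue
            effects.append(self._annotate_transcript(variant, t, pos0))
        if not effects:
            effects = [
                Effect(None, None, Consequence.INTERGENIC, Impact.MODIFIER)
            ]
        return effects

    def _annotate_transcript(
        self, variant: Variant, t: Transcript, pos0: int
    ) -> Effect:
        in_cds = any(s <= pos0 < e for s, e in t.cds)
        if in_cds:
            return self._coding_effect(variant, t, pos0)
        in_exon = any(s <= pos0 < e for s, e in t.exons)
        if in_exon:
            cds_min = t.cds[0][0]
            cds_max = t.cds[-1][1]
            if t.strand == "+":
                cons = (
                    Consequence.FIVE_PRIME_UTR
                    if pos0 < cds_min
                    else Consequence.THREE_PRIME_UTR
                )
            else:
                cons = (
                    Consequence.FIVE_PRIME_UTR
                    if pos0 >= cds_max
                    else Consequence.THREE_PRIME_UTR
                )
            return self._effect(t, cons)
        # intronic: splice-site if within SPLICE_REGION bp of either boundary
        for (_, prev_end), (next_start, _) in zip(t.exons, t.exons[1:]):
            if prev_end <= pos0 < next_start:
                if pos0 - prev_end < SPLICE_REGION or next_start - 1 - pos0 < SPLICE_REGION:
                    return self._effect(t, Consequence.SPLICE_SITE)
                return self._effect(t, Consequence.INTRON)
        # within span but outside exons and introns cannot happen
        raise AssertionError("unreachable: position inside transcript span")

    def _coding_effect(self, variant: Variant, t: Transcript, pos0: int) -> Effect:
        offset = 0
        if t.strand == "+":
            for s, e in t.cds:
                if s <= pos0 < e:
                    offset += pos0 - s
                    break
                offset += e - s
            alt_base = variant.alt
        else:
            for s, e in reversed(t.cds):
                if s <= pos0 < e:
                    offset += e - 1 - pos0
                    break
                offset += e - s
            alt_base = variant.alt.translate(_COMPLEMENT)
        cds = self.cds_sequence(t)
        codon_i, within = divmod(offset, 3)
        ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
        expected = variant.ref if t.strand == "+" else variant.ref.translate(_COMPLEMENT)
        if ref_codon[within] != expected:
            raise ReferenceMismatchError(
                f"{t.transcript_id}: CDS base at offset {offset} disagrees with REF "
                f"({ref_codon[within]!r} vs {expected!r}); gene model and genome "
                "are inconsistent"
            )
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        ref_aa = _translate_codon(ref_codon)
        alt_aa = _translate_codon(alt_codon)
        residue = codon_i + 1
        change = f"{_aa3(ref_aa)}{residue}{_aa3(alt_aa)}"
        if codon_i == 0 and alt_codon != "ATG":
            cons = Consequence.START_LOST
        elif ref_aa == alt_aa:
            return self._effect(t, Consequence.SYNONYMOUS)
        elif alt_aa == "*":
            cons = Consequence.STOP_GAINED
        elif ref_aa == "*":
            cons = Consequence.STOP_LOST
        else:
            cons = Consequence.MISSENSE
        return self._effect(t, cons, change)

    def _effect(
        self, t: Transcript, cons: Consequence, protein_change: str = ""
    ) -> Effect:
        if cons not in {
            Consequence.MISSENSE,
            Consequence.STOP_GAINED,
            Consequence.STOP_LOST,
            Consequence.START_LOST,
        }:
            protein_change = ""
        return Effect(
            gene_id=t.gene_id,
            transcript_id=t.transcript_id,
            consequence=cons,
            impact=IMPACT_OF[cons],
            protein_change=protein_change,
        )


def annotate_variant(
    variant: Variant, gene_models: GeneModels, genome: Mapping[str, str]
) -> list[Effect]:
    """One-shot convenience wrapper around :class:`EffectAnnotator`."""
    return EffectAnnotator(gene_models, genome).annotate(variant)


def annotate_variants(
    variants: Iterable[Variant],
    gene_models: GeneModels,
    genome: Mapping[str, str],
) -> list[Variant]:
    """Annotate variants in place (effects attached); returns the list."""
    annotator = EffectAnnotator(gene_models, genome)
    out = list(variants)
    for v in out:
        v.effects = annotator.annotate(v)
    return out


def gene_max_impact(variants: Iterable[Variant]) -> dict[str, Impact]:
    """Most severe impact per gene across all variants and transcripts.

    Genes with no annotated variant are absent from the result.
    """
    impacts: dict[str, Impact] = {}
    for v in variants:
        for e in v.effects:
            if e.gene_id is None:
                continue
            cur = impacts.get(e.gene_id)
            if cur is None or e.impact > cur:
                impacts[e.gene_id] = e.impact
    return impacts
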