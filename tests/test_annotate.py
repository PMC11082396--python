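"""SNP consequence classification: hand-built codon cases, strand
symmetry, and agreement with a whole-CDS translation oracle."""
import numpy as np
import pytest
from Bio.Seq import Seq

from oatmap import (
    Consequence,
    EffectAnnotator,
    GeneModels,
    Impact,
    ReferenceMismatchError,
    Transcript,
    Variant,
    annotate_variant,
    gene_max_impact,
    simulate_genome,
)
from oatmap.model import Effect, IMPACT_OF
from oatmap.simulate import SimConfig

from oracles import translation_oracle

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def single_gene_setup(cds_seq, strand="+", flank=30):
    """One single-exon gene embedded in a random-free genome."""
    region = cds_seq if strand == "+" else cds_seq.translate(COMPLEMENT)[::-1]
    genome = {"chr1": "A" * flank + region + "A" * flank}
    t = Transcript(
        gene_id="g1",
        transcript_id="g1.1",
        chrom="chr1",
        strand=strand,
        exons=((flank, flank + len(region)),),
        cds=((flank, flank + len(region)),),
    )
    return genome, GeneModels([t]), t


class TestCodonCases:
    def test_ccg_to_ctg_is_missense_pro_to_leu(self):
        # codon 2 is CCG (Pro); C->T at its middle base makes CTG (Leu)
        genome, models, _ = single_gene_setup("ATG" + "CCG" + "TAA")
        v = Variant("chr1", 35, "C", "T", 0, 10)
        (e,) = annotate_variant(v, models, genome)
        assert e.consequence is Consequence.MISSENSE
        assert e.impact is Impact.MODERATE
        assert e.protein_change == "Pro2Leu"

    def test_cag_to_tag_is_stop_gained_high(self):
        genome, models, _ = single_gene_setup("ATG" + "CAG" + "TAA")
        v = Variant("chr1", 34, "C", "T", 0, 10)
        (e,) = annotate_variant(v, models, genome)
        assert e.consequence is Consequence.STOP_GAINED
        assert e.impact is Impact.HIGH
        assert e.protein_change == "Gln2Ter"

    def test_gca_to_gcg_third_position_is_synonymous_low(self):
        genome, models, _ = single_gene_setup("ATG" + "GCA" + "TAA")
        v = Variant("chr1", 36, "A", "G", 0, 10)
        (e,) = annotate_variant(v, models, genome)
        assert e.consequence is Consequence.SYNONYMOUS
        assert e.impact is Impact.LOW
        assert e.protein_change == ""

    def test_snp_between_genes_is_intergenic_modifier(self):
        genome, models, _ = single_gene_setup("ATGGCATAA")
        v = Variant("chr1", 2, "A", "G", 0, 10)
        (e,) = annotate_variant(v, models, genome)
        assert e.consequence is Consequence.INTERGENIC
        assert e.impact is Impact.MODIFIER
        assert e.gene_id is None

    def test_start_codon_change_is_start_lost(self):
        genome, models, _ = single_gene_setup("ATGGCATAA")
        v = Variant("chr1", 32, "T", "C", 0, 10)  # ATG -> ACG
        (e,) = annotate_variant(v, models, genome)
        assert e.consequence is Consequence.START_LOST
        assert e.impact is Impact.HIGH

    def test_stop_codon_loss_and_retention(self):
        genome, models, _ = single_gene_setup("ATG" + "GCA" + "TAA")
        lost = Variant("chr1", 38, "A", "C", 0, 10)  # TAA -> TCA (Ser)
        (e,) = annotate_variant(lost, models, genome)
        assert e.consequence is Consequence.STOP_LOST
        kept = Variant("chr1", 39, "A", "G", 0, 10)  # TAA -> TAG (still stop)
        (e,) = annotate_variant(kept, models, genome)
        assert e.consequence is Consequence.SYNONYMOUS

    def test_reference_mismatch_is_hard_error(self):
        genome, models, _ = single_gene_setup("ATGGCATAA")
        with pytest.raises(ReferenceMismatchError):
            annotate_variant(Variant("chr1", 31, "C", "T", 0, 10), models, genome)


class TestNonCoding:
    @staticmethod
    def two_exon_setup(strand="+"):
        # exon1: 10 bp UTR + 6 bp CDS; 20 bp intron; exon2: 6 bp CDS + 10 bp UTR
        cds = "ATGCCT" + "GCTTAA"
        if strand == "+":
            region = "T" * 10 + cds[:6] + "G" * 20 + cds[6:] + "T" * 10
        else:
            fwd = "T" * 10 + cds[:6] + "G" * 20 + cds[6:] + "T" * 10
            region = fwd.translate(COMPLEMENT)[::-1]
        genome = {"chr1": "A" * 5 + region + "A" * 5}
        L = len(region)
        if strand == "+":
            exons = ((5, 5 + 16), (5 + 36, 5 + 52))
            cds_iv = ((5 + 10, 5 + 16), (5 + 36, 5 + 42))
        else:
            exons = ((5 + L - 52, 5 + L - 36), (5 + L - 16, 5 + L))
            cds_iv = ((5 + L - 42, 5 + L - 36), (5 + L - 16, 5 + L - 10))
        t = Transcript("g1", "g1.1", "chr1", strand, exons, cds_iv)
        return genome, GeneModels([t]), t

    def test_utr_intron_and_splice_classification_plus_strand(self):
        genome, models, _ = self.two_exon_setup("+")

        def cons(pos):
            v = Variant("chr1", pos, genome["chr1"][pos - 1], "C" if genome["chr1"][pos - 1] != "C" else "A", 0, 5)
            (e,) = annotate_variant(v, models, genome)
            return e.consequence

        assert cons(6) is Consequence.FIVE_PRIME_UTR
        assert cons(48) is Consequence.THREE_PRIME_UTR
        assert cons(22) is Consequence.SPLICE_SITE  # first intron base
        assert cons(23) is Consequence.SPLICE_SITE  # second intron base
        assert cons(30) is Consequence.INTRON
        assert cons(41) is Consequence.SPLICE_SITE  # last intron base

    def test_utr_polarity_flips_on_minus_strand(self):
        genome, models, t = self.two_exon_setup("-")
        pos = t.exons[-1][1]  # genome-last base = transcription-first (5' UTR)
        base = genome["chr1"][pos - 1]
        v = Variant("chr1", pos, base, "C" if base != "C" else "A", 0, 5)
        (e,) = annotate_variant(v, models, genome)
        assert e.consequence is Consequence.FIVE_PRIME_UTR


class TestStrandSymmetryAndOracle:
    def test_strand_symmetry_on_mirrored_genome(self):
        """A gene and its reverse-complement mirror yield identical calls."""
        cds = "ATG" + "CCGGTACAGTGGAAA" + "TAA"
        genome_f, models_f, t_f = single_gene_setup(cds, "+")
        L = len(genome_f["chr1"])
        genome_r = {"chr1": genome_f["chr1"].translate(COMPLEMENT)[::-1]}
        t_r = Transcript(
            "g1", "g1.1", "chr1", "-",
            exons=tuple(sorted((L - e, L - s) for s, e in t_f.exons)),
            cds=tuple(sorted((L - e, L - s) for s, e in t_f.cds)),
        )
        models_r = GeneModels([t_r])
        for pos in range(31, 31 + len(cds)):
            ref_f = genome_f["chr1"][pos - 1]
            for alt_f in "ACGT":
                if alt_f == ref_f:
                    continue
                (e_f,) = annotate_variant(
                    Variant("chr1", pos, ref_f, alt_f, 0, 5), models_f, genome_f
                )
                pos_r = L - pos + 1
                ref_r = ref_f.translate(COMPLEMENT)
                alt_r = alt_f.translate(COMPLEMENT)
                (e_r,) = annotate_variant(
                    Variant("chr1", pos_r, ref_r, alt_r, 0, 5), models_r, genome_r
                )
                assert e_f.consequence is e_r.consequence
                assert e_f.protein_change == e_r.protein_change

    def test_oracle_equivalence_on_random_cds_snps(self):
        """Consequence and residue agree with full-CDS translation on 300
        random simulated CDS SNPs across both strands."""
        cfg = SimConfig(
            n_chrom=1, chrom_bp=120_000, chrom_cM=50.0, n_genes=25,
            n_mutations=10, n_f2=120, pool_size=10, seed=99,
        )
        genome, models = simulate_genome(cfg)
        annotator = EffectAnnotator(models, genome)
        rng = np.random.default_rng(5)
        transcripts = list(models)
        checked = 0
        while checked < 300:
            t = transcripts[rng.integers(0, len(transcripts))]
            s, e = t.cds[rng.integers(0, len(t.cds))]
            pos = int(rng.integers(s, e)) + 1
            ref = genome[t.chrom][pos - 1]
            alt = "ACGT"[rng.integers(0, 4)]
            if alt == ref:
                continue
            v = Variant(t.chrom, pos, ref, alt, 0, 10)
            (eff,) = [x for x in annotator.annotate(v) if x.transcript_id == t.transcript_id]
            cons, residue = translation_oracle(annotator, t, v)
            assert eff.consequence is cons, (t.transcript_id, pos, ref, alt)
            if residue is not None and eff.protein_change:
                got = int("".join(c for c in eff.protein_change if c.isdigit()))
                assert got == residue
            checked += 1


class TestGeneMaxImpact:
    def test_max_rule_and_absent_genes(self):
        def eff(gene, cons, change=""):
            return Effect(gene, f"{gene}.1", cons, IMPACT_OF[cons], change)

        v1 = Variant("chr1", 10, "C", "T", 0, 9,
                     effects=[eff("gA", Consequence.SYNONYMOUS)])
        v2 = Variant("chr1", 20, "C", "T", 0, 9,
                     effects=[eff("gA", Consequence.MISSENSE, "Pro1Leu"),
                              eff("gB", Consequence.INTRON)])
        impacts = gene_max_impact([v1, v2])
        assert impacts == {"gA": Impact.MODERATE, "gB": Impact.MODIFIER}
        assert "gC" not in impacts

    def test_hand_traced_ten_variant_fixture(self):
        from oatmap.demo import demo_funnel_dataset

        variants, _, _, _ = demo_funnel_dataset()
        impacts = gene_max_impact(variants)
        assert impacts == {
            "g1": Impact.MODERATE,
            "g2": Impact.LOW,
            "g3": Impact.MODERATE,
            "g4": Impact.MODERATE,
            "g5": Impact.MODERATE,
            "g6": Impact.HIGH,
        }
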