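"""Generative-model contracts: genome/gene construction, EMS spectrum,
meiosis and pooling statistics, read sampling, and side tables."""
import dataclasses

import numpy as np
import pytest
from Bio.Seq import Seq

from oatmap import (
    Consequence,
    EffectAnnotator,
    SimConfig,
    SimulationError,
    Variant,
    expected_pooled_af,
    haldane_r,
    sample_pool_reads,
    simulate_experiment,
    simulate_f2_pool,
    simulate_genome,
    simulate_mutations,
)
from oatmap.simulate import F2Pool, Mutation


def marker_set(cMs, causal_cM, chrom="chr1"):
    """Markers at given genetic positions; the first is causal."""
    muts = []
    for i, cm in enumerate(cMs):
        muts.append(
            Mutation(chrom, i + 1, "C", "T", cm, is_causal=(cm == causal_cM and i == 0))
        )
    return muts


class TestGenome:
    def test_size_contract(self):
        cfg = SimConfig(n_chrom=1, chrom_bp=10_000, chrom_cM=10.0, n_genes=3,
                        n_mutations=5, n_f2=100, pool_size=5, seed=1)
        genome, models = simulate_genome(cfg)
        assert list(genome) == ["chr1"]
        assert len(genome["chr1"]) == 10_000
        assert len(models) == 3

    def test_every_cds_translates_without_internal_stop(self, small_experiment):
        annotator = EffectAnnotator(small_experiment.models, small_experiment.genome)
        for t in small_experiment.models:
            cds = annotator.cds_sequence(t)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            protein = str(Seq(cds).translate())
            assert protein.endswith("*")
            assert "*" not in protein[:-1]

    def test_fixed_seed_reproduces_files_byte_for_byte(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_experiment(small_config).write(d1)
        simulate_experiment(small_config).write(d2)
        for name in ("reference.fasta", "genes.gff3", "pool.vcf", "background.vcf",
                     "expression.tsv", "orthogroups.tsv", "truth.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_genes_do_not_overlap(self, small_experiment):
        by_chrom = {}
        for t in small_experiment.models:
            by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2


class TestMutations:
    def test_pure_ems_spectrum_is_transitions_only(self):
        cfg = SimConfig(n_chrom=1, chrom_bp=60_000, chrom_cM=30.0, n_genes=10,
                        n_mutations=150, ems_fraction=1.0, n_f2=100, pool_size=5, seed=3)
        genome, models = simulate_genome(cfg)
        mutations, _ = simulate_mutations(genome, models, cfg)
        assert len(mutations) == 150
        assert all((m.ref, m.alt) in {("C", "T"), ("G", "A")} for m in mutations)

    def test_exactly_one_causal_and_it_is_missense(self, small_experiment):
        truth = small_experiment.truth
        assert int(truth.table["is_causal"].sum()) == 1
        causal = truth.causal
        annotator = EffectAnnotator(small_experiment.models, small_experiment.genome)
        probe = Variant(str(causal["chrom"]), int(causal["pos"]),
                        str(causal["ref"]), str(causal["alt"]), 0, 1)
        effects = [
            e for e in annotator.annotate(probe)
            if e.transcript_id == truth.causal_transcript_id
        ]
        assert effects and effects[0].consequence is Consequence.MISSENSE

    def test_positions_reproducible_under_fixed_seed(self):
        cfg = SimConfig(n_chrom=1, chrom_bp=100_000, chrom_cM=50.0, n_genes=15,
                        n_mutations=500, n_f2=100, pool_size=5, seed=11)
        genome, models = simulate_genome(cfg)
        a, _ = simulate_mutations(genome, models, cfg)
        genome2, models2 = simulate_genome(cfg)
        b, _ = simulate_mutations(genome2, models2, cfg)
        assert [(m.chrom, m.pos, m.ref, m.alt) for m in a] == [
            (m.chrom, m.pos, m.ref, m.alt) for m in b
        ]

    def test_truth_expected_af_follows_haldane(self, small_experiment):
        truth = small_experiment.truth.table
        causal = small_experiment.truth.causal
        same = truth[truth["chrom"] == causal["chrom"]]
        d = (same["cM"] - causal["cM"]).abs() / 100.0
        np.testing.assert_allclose(same["expected_af"], expected_pooled_af(d))
        other = truth[truth["chrom"] != causal["chrom"]]
        assert (other["expected_af"] == 0.5).all()


class TestF2Pool:
    def test_phenotype_positive_fraction_near_one_quarter(self):
        """Homozygous-causal F2s occur at the 1:3 recessive rate."""
        cfg = SimConfig(n_chrom=1, chrom_bp=1000, chrom_cM=100.0, n_genes=1,
                        n_mutations=2, n_f2=2000, pool_size=15, seed=21)
        muts = marker_set([50.0, 60.0], causal_cM=50.0)
        pool = simulate_f2_pool(muts, cfg)
        p_hat = pool.n_positive / pool.n_f2
        sd = np.sqrt(0.25 * 0.75 / cfg.n_f2)
        assert abs(p_hat - 0.25) <= 3 * sd

    def test_perfect_linkage_marker_is_fixed_in_pool(self):
        cfg = SimConfig(n_chrom=1, chrom_bp=1000, chrom_cM=100.0, n_genes=1,
                        n_mutations=2, n_f2=200, pool_size=15, seed=22)
        muts = marker_set([50.0, 50.0], causal_cM=50.0)
        pool = simulate_f2_pool(muts, cfg)
        assert (pool.allele_counts == 2 * cfg.pool_size).all()

    def test_mean_pooled_af_matches_haldane_at_0p1_morgan(self):
        """Marker 10 cM away: mean AF over replicate pools ~ 1 - r with
        r = 0.5 (1 - exp(-0.2)) = 0.0906."""
        cfg = SimConfig(n_chrom=1, chrom_bp=1000, chrom_cM=100.0, n_genes=1,
                        n_mutations=2, n_f2=150, pool_size=15, seed=0)
        muts = marker_set([40.0, 50.0], causal_cM=40.0)
        afs = []
        for rep in range(120):
            pool = simulate_f2_pool(
                muts, dataclasses.replace(cfg, seed=1000 + rep)
            )
            afs.append(pool.allele_frequencies[1])
        afs = np.asarray(afs)
        expected = float(expected_pooled_af(0.1))
        assert expected == pytest.approx(1 - 0.0906, abs=5e-4)
        se = afs.std(ddof=1) / np.sqrt(len(afs))
        assert abs(afs.mean() - expected) <= 3 * se

    def test_unlinked_chromosome_mean_af_is_half(self):
        """Markers on a chromosome without the causal locus average AF 0.5."""
        cfg = SimConfig(n_chrom=2, chrom_bp=1000, chrom_cM=100.0, n_genes=1,
                        n_mutations=2, n_f2=150, pool_size=15, seed=0)
        muts = [Mutation("chr1", 1, "C", "T", 50.0, is_causal=True)] + [
            Mutation("chr2", i + 1, "C", "T", cm, is_causal=False)
            for i, cm in enumerate(np.linspace(0, 100, 30))
        ]
        rep_means = []
        for rep in range(20):
            pool = simulate_f2_pool(muts, dataclasses.replace(cfg, seed=500 + rep))
            rep_means.append(pool.allele_frequencies[1:].mean())
        rep_means = np.asarray(rep_means)
        se = rep_means.std(ddof=1) / np.sqrt(len(rep_means))
        assert abs(rep_means.mean() - 0.5) <= 3 * se

    def test_mean_af_decays_monotonically_with_distance(self):
        """Binned replicate-mean AF is non-increasing in map distance."""
        cfg = SimConfig(n_chrom=1, chrom_bp=1000, chrom_cM=100.0, n_genes=1,
                        n_mutations=6, n_f2=150, pool_size=15, seed=0)
        cMs = [0.0, 5.0, 10.0, 20.0, 40.0, 80.0]
        muts = marker_set(cMs, causal_cM=0.0)
        means = np.zeros(len(cMs))
        for rep in range(150):
            pool = simulate_f2_pool(muts, dataclasses.replace(cfg, seed=9000 + rep))
            means += pool.allele_frequencies
        means /= 150
        assert means[0] == 1.0  # causal site itself
        assert (np.diff(means) < 0).all()

    def test_too_few_positives_raises_with_advice(self):
        cfg = SimConfig(n_chrom=1, chrom_bp=1000, chrom_cM=100.0, n_genes=1,
                        n_mutations=2, n_f2=60, pool_size=15, seed=23)
        muts = marker_set([50.0, 60.0], causal_cM=50.0)
        bad = None
        for s in range(200):
            pool_cfg = dataclasses.replace(cfg, seed=s)
            pool = None
            try:
                pool = simulate_f2_pool(muts, pool_cfg)
            except SimulationError as exc:
                bad = str(exc)
                break
        assert bad is not None and "increase n_f2" in bad


class TestReadSampling:
    @staticmethod
    def uniform_pool(f, pool_size=15, n_sites=1):
        count = int(round(f * 2 * pool_size))
        dosages = np.zeros((pool_size, n_sites), dtype=np.int8)
        flat = dosages.reshape(-1, n_sites)
        # distribute `count` mutant alleles over 2*pool_size chromosomes
        for s in range(n_sites):
            alleles = np.zeros(2 * pool_size, dtype=np.int8)
            alleles[:count] = 1
            dosages[:, s] = alleles.reshape(pool_size, 2).sum(axis=1)
        return F2Pool(dosages=dosages, n_f2=100, n_positive=pool_size)

    def test_no_error_and_fixed_site_gives_zero_ref_reads(self):
        cfg = SimConfig(n_chrom=1, chrom_bp=1000, chrom_cM=1.0, n_genes=1,
                        n_mutations=1, n_f2=100, pool_size=15,
                        seq_error=0.0, seed=31)
        pool = self.uniform_pool(1.0, n_sites=200)
        muts = [Mutation("chr1", i + 1, "C", "T", 0.0, i == 0) for i in range(200)]
        variants = sample_pool_reads(pool, muts, cfg)
        assert all(v.ad_ref == 0 for v in variants)

    def test_mean_read_af_matches_pool_frequency(self):
        """Binomial sampling oracle: mean read AF over 1000 sites at f=0.5
        is 0.5 within 3 SE."""
        cfg = SimConfig(n_chrom=1, chrom_bp=5000, chrom_cM=1.0, n_genes=1,
                        n_mutations=1, n_f2=100, pool_size=15,
                        seq_error=0.0, seed=32)
        pool = self.uniform_pool(0.5, n_sites=1000)
        muts = [Mutation("chr1", i + 1, "C", "T", 0.0, i == 0) for i in range(1000)]
        variants = sample_pool_reads(pool, muts, cfg)
        afs = np.array([v.ad_alt / v.total_depth for v in variants if v.total_depth])
        se = afs.std(ddof=1) / np.sqrt(len(afs))
        assert abs(afs.mean() - 0.5) <= 3 * se

    def test_fixed_seed_reproduces_reads(self):
        cfg = SimConfig(n_chrom=1, chrom_bp=1000, chrom_cM=1.0, n_genes=1,
                        n_mutations=1, n_f2=100, pool_size=15, seed=33)
        pool = self.uniform_pool(0.8, n_sites=50)
        muts = [Mutation("chr1", i + 1, "C", "T", 0.0, i == 0) for i in range(50)]
        a = sample_pool_reads(pool, muts, cfg)
        b = sample_pool_reads(pool, muts, cfg)
        assert [(v.ad_ref, v.ad_alt) for v in a] == [(v.ad_ref, v.ad_alt) for v in b]


class TestSideTables:
    def test_expression_sample_design_is_3_7_8(self, small_experiment):
        expr = small_experiment.side.expression
        assert len(expr.samples_in_group("seed")) == 3
        assert len(expr.samples_in_group("glume")) == 7
        assert len(expr.samples_in_group("spikelet")) == 8

    def test_causal_gene_passes_expression_filter_by_construction(self, small_experiment):
        expr = small_experiment.side.expression
        causal = small_experiment.truth.causal_gene_id
        assert expr.expressed_in_all(causal, ("seed", "glume", "spikelet"), 0.5)

    def test_some_genes_fail_expression_filter(self, small_experiment):
        expr = small_experiment.side.expression
        failing = [
            g for g in small_experiment.models.gene_ids
            if not expr.expressed_in_all(g, ("seed", "glume", "spikelet"), 0.5)
        ]
        assert failing

    def test_causal_orthogroup_links_to_known_seed_shape_protein(self, small_experiment):
        og_map = small_experiment.side.orthogroups
        causal_protein = small_experiment.truth.causal_transcript_id
        og = og_map.orthogroup_of(causal_protein)
        assert og is not None
        known_proteins = {p for _, p in small_experiment.side.known_genes}
        members = {p for _, p in og_map.members[og]}
        assert members & known_proteins

    def test_background_shares_sites_with_pool_but_not_causal(self, small_experiment):
        pool_keys = {v.key for v in small_experiment.variants}
        bg_keys = {v.key for v in small_experiment.side.background}
        assert bg_keys and bg_keys <= pool_keys
        causal = small_experiment.truth.causal
        assert (str(causal["chrom"]), int(causal["pos"]), str(causal["ref"]),
                str(causal["alt"])) not in bg_keys
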