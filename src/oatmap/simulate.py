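"""Synthetic mapping-by-sequencing experiments with known ground truth.

Emulates the full study design: an EMS-mutagenized line (C->T / G->A
transition bias) crossed to wild type, F2 individuals produced by meiosis
with Poisson crossovers (no interference; Haldane map function),
selection of phenotype-positive (homozygous-causal) individuals into a
pool, and pooled short-read sampling at a target mean depth with
sequencing error — plus matched gene models, expression, orthogroup and
background-variant side tables, and a truth table recording the causal
variant and the expected pooled allele frequency at every site.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as oio
from .annotate import EffectAnnotator
from .model import (
    Consequence,
    ExpressionMatrix,
    GeneModels,
    OrthogroupMap,
    SimulationError,
    Transcript,
    Variant,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_EMS_CHANGE = {"C": "T", "G": "A"}

_KNOWN_SPECIES = ("arabidopsis", "rice", "wheat", "maize")


def haldane_r(d_morgan: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for map distance d (Morgans), Haldane map
    function: r = 0.5 * (1 - exp(-2 d))."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgan, dtype=float)))


def expected_pooled_af(d_morgan: float | np.ndarray) -> float | np.ndarray:
    """Expected mutant allele frequency in a pool of phenotype-selected
    homozygotes at a marker d Morgans from the causal locus: 1 - r."""
    return 1.0 - haldane_r(d_morgan)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment.

    Defaults are a desk-scale stand-in for the 21-chromosome oat genome:
    3 chromosomes x 5 Mb / 150 cM, 300 genes, 600 EMS mutations, a pool
    of 15 phenotype-positive F2s sequenced to 30x mean depth.
    """

    n_chrom: int = 3
    chrom_bp: int = 5_000_000
    chrom_cM: float = 150.0
    n_genes: int = 300
    n_mutations: int = 600
    ems_fraction: float = 0.99
    n_f2: int = 200
    pool_size: int = 15
    mean_depth: float = 30.0
    seq_error: float = 0.01
    background_fraction: float = 0.1
    low_expression_fraction: float = 0.3
    tpm_meanlog: float = 2.0
    tpm_sdlog: float = 1.2
    expression_samples: tuple[tuple[str, int], ...] = (
        ("seed", 3),
        ("glume", 7),
        ("spikelet", 8),
    )
    n_known_foreign: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ems_fraction <= 1.0:
            raise ValueError("ems_fraction must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.pool_size > self.n_f2 * 0.25:
            raise ValueError(
                f"pool_size {self.pool_size} exceeds the expected number of "
                f"phenotype-positive F2s ({self.n_f2 * 0.25:.1f}); increase n_f2"
            )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass(frozen=True)
class Mutation:
    """One induced SNP with its genetic-map position."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    cM: float
    is_causal: bool = False


@dataclass
class TruthTable:
    """Simulator ground truth: one row per mutation, exactly one causal."""

    table: pd.DataFrame  # chrom, pos, ref, alt, cM, is_causal, expected_af
    causal_gene_id: str
    causal_transcript_id: str

    def __post_init__(self) -> None:
        n_causal = int(self.table["is_causal"].sum())
        if n_causal != 1:
            raise SimulationError(f"expected exactly one causal mutation, got {n_causal}")

    @property
    def causal(self) -> pd.Series:
        return self.table[self.table["is_causal"]].iloc[0]


@dataclass
class F2Pool:
    """Genotypes of the phenotype-selected pool at every mutation site."""

    dosages: np.ndarray  # (pool_size, n_sites) mutant-allele dosage 0/1/2
    n_f2: int
    n_positive: int

    @property
    def pool_size(self) -> int:
        return self.dosages.shape[0]

    @property
    def allele_counts(self) -> np.ndarray:
        return self.dosages.sum(axis=0)

    @property
    def allele_frequencies(self) -> np.ndarray:
        return self.allele_counts / (2 * self.pool_size)


@dataclass
class SideTables:
    expression: ExpressionMatrix
    orthogroups: OrthogroupMap
    known_genes: list[tuple[str, str]]
    background: list[Variant]


@dataclass
class Experiment:
    """Everything one synthetic run produces."""

    config: SimConfig
    genome: dict[str, str]
    models: GeneModels
    mutations: list[Mutation]
    truth: TruthTable
    pool: F2Pool
    variants: list[Variant]
    side: SideTables

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Persist all artifacts as plain-text files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": outdir / "reference.fasta",
            "genes": outdir / "genes.gff3",
            "pool_vcf": outdir / "pool.vcf",
            "background_vcf": outdir / "background.vcf",
            "expression": outdir / "expression.tsv",
            "groups": outdir / "sample_groups.tsv",
            "orthogroups": outdir / "orthogroups.tsv",
            "known_genes": outdir / "known_genes.tsv",
            "truth": outdir / "truth.tsv",
        }
        oio.write_fasta(self.genome, paths["reference"])
        oio.write_gff(self.models, paths["genes"])
        contigs = list(self.genome)
        oio.write_vcf(self.variants, paths["pool_vcf"], contigs=contigs)
        oio.write_vcf(self.side.background, paths["background_vcf"], contigs=contigs)
        oio.write_expression(self.side.expression, paths["expression"])
        pd.DataFrame(
            self.side.expression.groups.items(), columns=["sample", "group"]
        ).to_csv(paths["groups"], sep="\t", index=False)
        oio.write_orthogroups(self.side.orthogroups, paths["orthogroups"])
        oio.write_gene_list(self.side.known_genes, paths["known_genes"])
        truth = self.truth.table.copy()
        truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6f")
        return paths


# ---------------------------------------------------------------------------
# genome and gene models


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return (
        np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, size=length)]
        .tobytes()
        .decode()
    )


def _build_gene_region(
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]]]:
    """Construct one gene in transcription orientation.

    Returns (sequence, exon intervals, CDS intervals), intervals local to
    the region, 0-based half-open. The CDS starts with ATG, has no
    internal stop codon, ends in a stop, and is split over 1-3 exons
    flanked by 30 bp UTRs; introns carry GT..AG boundaries.
    """
    n_internal = int(rng.integers(50, 251))
    codons = rng.choice(len(_NONSTOP_CODONS), size=n_internal)
    cds_seq = (
        "ATG"
        + "".join(_NONSTOP_CODONS[i] for i in codons)
        + _STOPS[rng.integers(0, 3)]
    )
    n_exons = int(rng.integers(1, 4))
    cuts = (
        sorted(rng.choice(np.arange(3, len(cds_seq) - 2), size=n_exons - 1, replace=False))
        if n_exons > 1
        else []
    )
    chunks = [cds_seq[a:b] for a, b in zip([0] + cuts, cuts + [len(cds_seq)])]
    utr5 = _random_seq(rng, 30)
    utr3 = _random_seq(rng, 30)
    parts: list[str] = [utr5]
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    offset = len(utr5)
    for i, chunk in enumerate(chunks):
        exon_start = offset
        cds.append((offset, offset + len(chunk)))
        parts.append(chunk)
        offset += len(chunk)
        if i == len(chunks) - 1:
            parts.append(utr3)
            offset += len(utr3)
        exons.append((exon_start if i > 0 else 0, offset))
        if i < len(chunks) - 1:
            intron_len = int(rng.integers(60, 301))
            intron = "GT" + _random_seq(rng, intron_len - 4) + "AG"
            parts.append(intron)
            offset += intron_len
    return "".join(parts), exons, cds


def simulate_genome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], GeneModels]:
    """Random chromosomes with non-overlapping protein-coding genes.

    Gene loci are written into the chromosome sequence so that every
    simulated CDS translates cleanly (ATG start, no internal stop).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom_arrays = {
        name: bytearray(_random_seq(rng, config.chrom_bp), "ascii")
        for name in config.chrom_names
    }
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_arrays}
    transcripts: list[Transcript] = []
    for g in range(config.n_genes):
        region, exons, cds = _build_gene_region(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            L = len(region)
            region = region.translate(_COMPLEMENT)[::-1]
            exons = sorted((L - e, L - s) for s, e in exons)
            cds = sorted((L - e, L - s) for s, e in cds)
        for _ in range(200):
            chrom = config.chrom_names[rng.integers(0, config.n_chrom)]
            start = int(rng.integers(0, config.chrom_bp - len(region)))
            end = start + len(region)
            if all(e <= start or end <= s for s, e in placed[chrom]):
                break
        else:
            raise SimulationError(
                f"could not place gene {g} without overlap; genome too dense"
            )
        placed[chrom].append((start, end))
        chrom_arrays[chrom][start:end] = region.encode()
        gene_id = f"g{g + 1:04d}"
        transcripts.append(
            Transcript(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.1",
                chrom=chrom,
                strand=strand,
                exons=tuple((start + s, start + e) for s, e in exons),
                cds=tuple((start + s, start + e) for s, e in cds),
            )
        )
    genome = {name: arr.decode() for name, arr in chrom_arrays.items()}
    transcripts.sort(key=lambda t: (t.chrom, t.start))
    return genome, GeneModels(transcripts)


# ---------------------------------------------------------------------------
# mutations


def _genetic_pos(pos: int, config: SimConfig) -> float:
    return pos * (config.chrom_cM / config.chrom_bp)


def simulate_mutations(
    genome: Mapping[str, str],
    models: GeneModels,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Mutation], TruthTable]:
    """Draw the mutagenized line's SNPs and designate one causal missense.

    With probability ``ems_fraction`` a mutation is a canonical EMS
    transition (C->T or G->A on the reference strand); otherwise a random
    substitution at a random site.  The causal mutation is re-drawn until
    it is an EMS transition in a CDS producing a missense change.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    annotator = EffectAnnotator(models, genome)
    chroms = config.chrom_names
    taken: set[tuple[str, int]] = set()
    mutations: list[Mutation] = []

    def draw_site(ems: bool) -> tuple[str, int, str, str]:
        for _ in range(10_000):
            chrom = chroms[rng.integers(0, len(chroms))]
            pos = int(rng.integers(1, config.chrom_bp + 1))
            if (chrom, pos) in taken:
                continue
            ref = genome[chrom][pos - 1]
            if ems:
                if ref not in _EMS_CHANGE:
                    continue
                return chrom, pos, ref, _EMS_CHANGE[ref]
            if ref not in _BASES:
                continue
            alt = _BASES[rng.integers(0, 4)]
            if alt == ref:
                continue
            return chrom, pos, ref, alt
        raise SimulationError("could not place a mutation after bounded retries")

    for _ in range(config.n_mutations - 1):
        chrom, pos, ref, alt = draw_site(ems=bool(rng.random() < config.ems_fraction))
        taken.add((chrom, pos))
        mutations.append(Mutation(chrom, pos, ref, alt, _genetic_pos(pos, config)))

    # causal: EMS transition at a CDS site whose substitution is missense
    causal = None
    causal_effect = None
    coding = [t for t in models if t.cds]
    if not coding:
        raise SimulationError("no coding transcripts to host the causal mutation")
    for _ in range(10_000):
        t = coding[rng.integers(0, len(coding))]
        s, e = t.cds[rng.integers(0, len(t.cds))]
        pos = int(rng.integers(s, e)) + 1
        if (t.chrom, pos) in taken:
            continue
        ref = genome[t.chrom][pos - 1]
        if ref not in _EMS_CHANGE:
            continue
        alt = _EMS_CHANGE[ref]
        probe = Variant(t.chrom, pos, ref, alt, ad_ref=0, ad_alt=1)
        effects = annotator.annotate(probe)
        hit = [x for x in effects if x.transcript_id == t.transcript_id]
        if hit and hit[0].consequence is Consequence.MISSENSE:
            causal = Mutation(
                t.chrom, pos, ref, alt, _genetic_pos(pos, config), is_causal=True
            )
            causal_effect = hit[0]
            break
    if causal is None:
        raise SimulationError(
            "could not place a causal missense mutation after bounded retries"
        )
    taken.add((causal.chrom, causal.pos))
    mutations.append(causal)
    mutations.sort(key=lambda m: (m.chrom, m.pos))

    rows = []
    for m in mutations:
        if m.chrom == causal.chrom:
            d = abs(m.cM - causal.cM) / 100.0
            eaf = float(expected_pooled_af(d))
        else:
            eaf = 0.5
        rows.append((m.chrom, m.pos, m.ref, m.alt, m.cM, m.is_causal, eaf))
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "cM", "is_causal", "expected_af"]
    )
    truth = TruthTable(
        table=table,
        causal_gene_id=causal_effect.gene_id,
        causal_transcript_id=causal_effect.transcript_id,
    )
    return mutations, truth


# ---------------------------------------------------------------------------
# meiosis and the pool


def _simulate_gametes(
    marker_cM: Mapping[str, np.ndarray],
    chrom_cM: float,
    n_gametes: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Simulate crossover-mosaic gametes of a fully heterozygous F1.

    Returns, per chromosome, a (n_gametes, n_markers) 0/1 array: 1 where
    the gamete carries the mutant parental haplotype. Crossover counts
    are Poisson(chrom_cM / 100) with breakpoints uniform in genetic
    position (no interference), starting haplotype a fair coin.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, g in marker_cM.items():
        haps = np.empty((n_gametes, len(g)), dtype=np.int8)
        n_co = rng.poisson(chrom_cM / 100.0, size=n_gametes)
        starts = rng.integers(0, 2, size=n_gametes)
        for i in range(n_gametes):
            if n_co[i]:
                bp = np.sort(rng.uniform(0.0, chrom_cM, size=n_co[i]))
                haps[i] = (starts[i] + np.searchsorted(bp, g)) % 2
            else:
                haps[i] = starts[i]
        out[chrom] = haps
    return out


def simulate_f2_pool(
    mutations: Sequence[Mutation],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> F2Pool:
    """Simulate ``n_f2`` F2 individuals and select the phenotype pool.

    Each F2 genotype is the sum of two independent gametes; an individual
    is phenotype-positive iff homozygous mutant at the causal locus
    (fully penetrant recessive monogenic trait). The first ``pool_size``
    positives form the pool; fewer positives is an error advising a
    larger ``n_f2``.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    order = [(m.chrom, i) for i, m in enumerate(mutations)]
    marker_cM: dict[str, np.ndarray] = {}
    col_of: dict[str, list[int]] = {}
    for chrom in sorted({m.chrom for m in mutations}):
        idx = [i for c, i in order if c == chrom]
        marker_cM[chrom] = np.array([mutations[i].cM for i in idx])
        col_of[chrom] = idx
    causal_idx = next(i for i, m in enumerate(mutations) if m.is_causal)

    g1 = _simulate_gametes(marker_cM, config.chrom_cM, config.n_f2, rng)
    g2 = _simulate_gametes(marker_cM, config.chrom_cM, config.n_f2, rng)
    dosage = np.zeros((config.n_f2, len(mutations)), dtype=np.int8)
    for chrom, idx in col_of.items():
        dosage[:, idx] = g1[chrom] + g2[chrom]

    positive = np.nonzero(dosage[:, causal_idx] == 2)[0]
    if len(positive) < config.pool_size:
        raise SimulationError(
            f"only {len(positive)} phenotype-positive F2s among {config.n_f2}; "
            f"increase n_f2 to reliably obtain a pool of {config.pool_size}"
        )
    selected = positive[: config.pool_size]
    return F2Pool(
        dosages=dosage[selected],
        n_f2=config.n_f2,
        n_positive=int(len(positive)),
    )


def sample_pool_reads(
    pool: F2Pool,
    mutations: Sequence[Mutation],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[Variant]:
    """Pooled short-read sampling at each mutation site.

    Depth is Poisson(``mean_depth``); each read reports the mutant allele
    with probability equal to the pooled allele frequency and is flipped
    to the other allele with probability ``seq_error``.  Zero-depth sites
    are emitted with AD 0,0.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    f = pool.allele_frequencies
    n = len(mutations)
    depth = rng.poisson(config.mean_depth, size=n)
    true_alt = rng.binomial(depth, f)
    flip_to_ref = rng.binomial(true_alt, config.seq_error)
    flip_to_alt = rng.binomial(depth - true_alt, config.seq_error)
    ad_alt = true_alt - flip_to_ref + flip_to_alt
    ad_ref = depth - ad_alt
    return [
        Variant(
            chrom=m.chrom,
            pos=m.pos,
            ref=m.ref,
            alt=m.alt,
            ad_ref=int(ad_ref[i]),
            ad_alt=int(ad_alt[i]),
        )
        for i, m in enumerate(mutations)
    ]


# ---------------------------------------------------------------------------
# side tables


def emit_side_tables(
    models: GeneModels,
    mutations: Sequence[Mutation],
    truth: TruthTable,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> SideTables:
    """Expression, orthogroup, known-gene and background-variant tables.

    Expression is log-normal TPM; the causal gene is guaranteed above the
    0.5 TPM threshold in every sample, and ``low_expression_fraction`` of
    the other genes are forced below it in at least one sample.  The
    causal gene's orthogroup contains at least one known seed-shape
    foreign protein.  The background VCF shares a fraction of the
    non-causal mutations (as seen in sibling lines or parents).
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    genes = models.gene_ids
    samples: list[str] = []
    groups: dict[str, str] = {}
    for group, count in config.expression_samples:
        for i in range(count):
            name = f"{group}_{i + 1:02d}"
            samples.append(name)
            groups[name] = group
    tpm = rng.lognormal(config.tpm_meanlog, config.tpm_sdlog, size=(len(genes), len(samples)))
    tpm = np.round(tpm, 3)
    values = pd.DataFrame(tpm, index=pd.Index(genes, name="gene_id"), columns=samples)
    causal_gene = truth.causal_gene_id
    values.loc[causal_gene] = np.maximum(values.loc[causal_gene], 2.0)
    others = [g for g in genes if g != causal_gene]
    n_low = int(round(config.low_expression_fraction * len(others)))
    low_genes = rng.choice(len(others), size=n_low, replace=False)
    for gi in low_genes:
        values.loc[others[gi], samples[rng.integers(0, len(samples))]] = 0.0
    expression = ExpressionMatrix(values=values, groups=groups)

    # orthogroups: random grouping of oat proteins plus foreign members
    proteins = [t.transcript_id for t in models]
    n_og = max(1, len(proteins) // 5)
    og_names = [f"OG{i:07d}" for i in range(n_og)]
    members: dict[str, list[tuple[str, str]]] = {og: [] for og in og_names}
    assignment = rng.integers(0, n_og, size=len(proteins))
    keep = rng.random(len(proteins)) < 0.85
    causal_og = None
    for p, og_i, k in zip(proteins, assignment, keep):
        gene = p.rsplit(".", 1)[0]
        if gene == causal_gene:
            causal_og = og_names[og_i]
            members[causal_og].append(("oat", p))
        elif k:
            members[og_names[og_i]].append(("oat", p))
    assert causal_og is not None
    known: list[tuple[str, str]] = []
    n_known = config.n_known_foreign
    n_unassigned = max(1, n_known // 8)  # a few queried proteins lack orthogroups
    for i in range(n_known):
        species = _KNOWN_SPECIES[i % len(_KNOWN_SPECIES)]
        protein = f"{species}|SSG{i + 1:04d}"
        known.append((species, protein))
        if i == 0:
            members[causal_og].append((species, protein))
        elif i < n_known - n_unassigned:
            members[og_names[rng.integers(0, n_og)]].append((species, protein))
    orthogroups = OrthogroupMap({og: mem for og, mem in members.items() if mem})

    # background set: non-causal mutations shared with sibling lines/parents
    non_causal = [i for i, m in enumerate(mutations) if not m.is_causal]
    n_bg = int(round(config.background_fraction * len(mutations)))
    bg_idx = sorted(rng.choice(non_causal, size=min(n_bg, len(non_causal)), replace=False))
    background = [
        Variant(
            chrom=mutations[i].chrom,
            pos=mutations[i].pos,
            ref=mutations[i].ref,
            alt=mutations[i].alt,
            ad_ref=int(rng.poisson(15)),
            ad_alt=int(rng.poisson(15)),
        )
        for i in bg_idx
    ]
    return SideTables(
        expression=expression,
        orthogroups=orthogroups,
        known_genes=known,
        background=background,
    )


# ---------------------------------------------------------------------------
# orchestration


def simulate_experiment(config: SimConfig) -> Experiment:
    """Run the whole generative model under ``config.seed``.

    Stage RNGs are derived from the seed with fixed offsets, so every
    artifact is reproducible bit-for-bit under a fixed configuration.
    """
    genome, models = simulate_genome(config)
    mutations, truth = simulate_mutations(genome, models, config)
    pool = simulate_f2_pool(mutations, config)
    variants = sample_pool_reads(pool, mutations, config)
    side = emit_side_tables(models, mutations, truth, config)
    return Experiment(
        config=config,
        genome=genome,
        models=models,
        mutations=mutations,
        truth=truth,
        pool=pool,
        variants=variants,
        side=side,
    )
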