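"""Readers and writers for VCF, GFF3, FASTA and the pipeline's TSV tables.

The VCF codec is a deliberately minimal native implementation covering the
slice of VCF 4.2 this pipeline consumes: biallelic SNP records with a
per-sample ``AD`` FORMAT field (summed across samples) and an optional
pipe-delimited ``ANN`` INFO field carrying effect annotations.  GFF3 is
parsed through gffutils; FASTA through Biopython.
"""
from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, Mapping, Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Consequence,
    Effect,
    FastaFormatError,
    GeneModels,
    GffFormatError,
    IMPACT_OF,
    ExpressionMatrix,
    OrthogroupMap,
    TableFormatError,
    Transcript,
    VcfFormatError,
    Variant,
)

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")
_FASTA_ALPHABET = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# VCF


def _parse_ann(info: str) -> list[Effect]:
    effects: list[Effect] = []
    for field in info.split(";"):
        if not field.startswith("ANN="):
            continue
        for entry in field[4:].split(","):
            parts = entry.split("|")
            if len(parts) != 5:
                raise VcfFormatError(f"malformed ANN entry: {entry!r}")
            gene, transcript, consequence, _impact, protein_change = parts
            cons = Consequence(consequence)
            effects.append(
                Effect(
                    gene_id=gene or None,
                    transcript_id=transcript or None,
                    consequence=cons,
                    impact=IMPACT_OF[cons],
                    protein_change=protein_change,
                )
            )
    return effects


def read_vcf(path: str | os.PathLike) -> list[Variant]:
    """Read biallelic SNPs from a VCF 4.x file.

    Multi-allelic and non-SNP records are skipped (counts logged).  The
    ``AD`` FORMAT value (ref,alt order) is summed across samples.  Records
    whose FORMAT lacks ``AD`` raise :class:`VcfFormatError`; records where
    every sample's AD is missing (``.``) are dropped with a logged count.
    ``ANN`` INFO entries, if present, are parsed into :class:`Effect`.
    """
    variants: list[Variant] = []
    n_skipped_shape = 0
    n_skipped_ad = 0
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if cols[:8] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                ]:
                    raise VcfFormatError(f"{path}: malformed #CHROM header line")
                saw_header = True
                continue
            if not saw_header:
                raise VcfFormatError(f"{path}: record before #CHROM header (line {lineno})")
            fields = line.split("\t")
            if len(fields) < 10:
                raise VcfFormatError(
                    f"{path}: record at line {lineno} has no sample columns"
                )
            chrom, pos, _id, ref, alt, qual, _filt, info, fmt = fields[:9]
            samples = fields[9:]
            if "," in alt or len(ref) != 1 or len(alt) != 1 or not (
                set(ref) <= _DNA and set(alt) <= _DNA
            ):
                n_skipped_shape += 1
                continue
            fmt_keys = fmt.split(":")
            if "AD" not in fmt_keys:
                raise VcfFormatError(
                    f"{path}: record {chrom}:{pos} lacks AD in FORMAT"
                )
            ad_idx = fmt_keys.index("AD")
            ad_ref = ad_alt = 0
            any_ad = False
            for sample in samples:
                values = sample.split(":")
                if ad_idx >= len(values) or values[ad_idx] in {".", ""}:
                    continue
                parts = values[ad_idx].split(",")
                if len(parts) != 2:
                    raise VcfFormatError(
                        f"{path}: record {chrom}:{pos} has non-biallelic AD "
                        f"{values[ad_idx]!r}"
                    )
                ad_ref += int(parts[0])
                ad_alt += int(parts[1])
                any_ad = True
            if not any_ad:
                n_skipped_ad += 1
                continue
            variants.append(
                Variant(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    ad_ref=ad_ref,
                    ad_alt=ad_alt,
                    qual=None if qual == "." else float(qual),
                    effects=_parse_ann(info),
                )
            )
    if not saw_header:
        raise VcfFormatError(f"{path}: missing #CHROM header line")
    if n_skipped_shape:
        logger.info(
            "%s: skipped %d non-SNP/multi-allelic records", path, n_skipped_shape
        )
    if n_skipped_ad:
        logger.info("%s: dropped %d records with missing AD values", path, n_skipped_ad)
    return variants


def _format_effect(e: Effect) -> str:
    return "|".join(
        [
            e.gene_id or "",
            e.transcript_id or "",
            e.consequence.value,
            e.impact.name,
            e.protein_change,
        ]
    )


def write_vcf(
    variants: Iterable[Variant],
    path: str | os.PathLike,
    sample_name: str = "POOL",
    contigs: Optional[Iterable[str]] = None,
) -> None:
    """Write variants as a single-sample VCF 4.2 with GT:AD genotypes.

    Round-trip contract: ``read_vcf`` on the output reproduces
    chrom/pos/alleles/AD/qual and any attached effects exactly.
    """
    variants = list(variants)
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##INFO=<ID=ANN,Number=.,Type=String,Description='
        '"Effect annotation: gene|transcript|consequence|impact|protein_change">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths for the ref and alt alleles">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name,
    ]
    for v in variants:
        info = (
            "ANN=" + ",".join(_format_effect(e) for e in v.effects)
            if v.effects
            else "."
        )
        qual = "." if v.qual is None else f"{v.qual:g}"
        gt = "1/1" if v.ad_ref == 0 else "0/1"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t.\t{info}"
            f"\tGT:AD\t{gt}:{v.ad_ref},{v.ad_alt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str | os.PathLike) -> GeneModels:
    """Parse gene/mRNA/exon/CDS features linked by ID/Parent into GeneModels.

    Intervals are converted from GFF's 1-based inclusive coordinates to
    0-based half-open. A CDS feature whose parent mRNA is absent raises
    :class:`GffFormatError`.
    """
    text = Path(path).read_text()
    if not any(line and not line.startswith("#") for line in text.splitlines()):
        return GeneModels([])
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            raise GffFormatError(
                f"{path}: CDS at {cds.seqid}:{cds.start}-{cds.end} has no parent mRNA"
            )
    transcripts = []
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [mrna.id])
        gene_id = parents[0]
        exons = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="exon")
            )
        )
        cds = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="CDS")
            )
        )
        if not exons:
            exons = cds
        transcripts.append(
            Transcript(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
            )
        )
    return GeneModels(transcripts)


def write_gff(models: GeneModels, path: str | os.PathLike, source: str = "oatmap") -> None:
    """Write GeneModels as GFF3 (1-based inclusive, CDS phase computed)."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[Transcript]] = {}
    for t in models:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gene_id, transcripts in by_gene.items():
        chrom = transcripts[0].chrom
        strand = transcripts[0].strand
        g_start = min(t.start for t in transcripts)
        g_end = max(t.end for t in transcripts)
        lines.append(
            f"{chrom}\t{source}\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\tID={gene_id}"
        )
        for t in transcripts:
            lines.append(
                f"{chrom}\t{source}\tmRNA\t{t.start + 1}\t{t.end}\t.\t{strand}\t.\t"
                f"ID={t.transcript_id};Parent={gene_id}"
            )
            for s, e in t.exons:
                lines.append(
                    f"{chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"Parent={t.transcript_id}"
                )
            cumlen = 0
            for s, e in t.cds_transcription_order():
                phase = (3 - cumlen % 3) % 3
                cumlen += e - s
                lines.append(
                    f"{chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{phase}\t"
                    f"Parent={t.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read sequences, uppercased, restricted to the {A,C,G,T,N} alphabet."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FastaFormatError(f"{path}: duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise FastaFormatError(
                f"{path}: sequence {record.id!r} has non-ACGTN characters {sorted(bad)}"
            )
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV tables


def read_expression(
    path: str | os.PathLike, group_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a genes x samples TPM table (TSV, first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df.astype(float), groups=dict(group_map))


def write_expression(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.3f")


def read_group_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column sample/group TSV (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise TableFormatError(f"{path}: expected columns 'sample' and 'group'")
    return dict(zip(df["sample"], df["group"]))


def read_orthogroups(path: str | os.PathLike) -> OrthogroupMap:
    """Read orthogroup membership: TSV columns orthogroup_id, species, protein_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["orthogroup_id", "species", "protein_id"]
    if list(df.columns[:3]) != required:
        raise TableFormatError(f"{path}: expected columns {required}")
    members: dict[str, list[tuple[str, str]]] = {}
    for og, species, protein in df.itertuples(index=False):
        members.setdefault(og, []).append((species, protein))
    return OrthogroupMap(members)


def write_orthogroups(orthogroups: OrthogroupMap, path: str | os.PathLike) -> None:
    rows = [
        (og, species, protein)
        for og, members in orthogroups.members.items()
        for species, protein in members
    ]
    pd.DataFrame(rows, columns=["orthogroup_id", "species", "protein_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a species-tagged protein list: TSV columns species, protein_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["species", "protein_id"]:
        raise TableFormatError(f"{path}: expected columns 'species' and 'protein_id'")
    return list(zip(df["species"], df["protein_id"]))


def write_gene_list(genes: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    pd.DataFrame(genes, columns=["species", "protein_id"]).to_csv(
        path, sep="\t", index=False
    )
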