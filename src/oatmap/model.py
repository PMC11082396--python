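"""Core data model: variants, effects, gene models, expression, orthogroups.

Coordinate conventions: :class:`Variant.pos` is 1-based (VCF convention);
all interval containers (:class:`Transcript` exons/CDS) are 0-based
half-open in genome order. File readers/writers in :mod:`oatmap.io`
convert at the boundary, so converting a parsed interval back to file
form is the identity.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
import pandas as pd

_DNA = frozenset("ACGT")


class OatmapError(Exception):
    """Base class for all errors raised by oatmap."""


class VcfFormatError(OatmapError):
    pass


class GffFormatError(OatmapError):
    pass


class FastaFormatError(OatmapError):
    pass


class TableFormatError(OatmapError):
    pass


class ReferenceMismatchError(OatmapError):
    """A variant's REF allele disagrees with the reference genome base.

    Raised by the annotator as a guard against FASTA/VCF coordinate drift.
    """


class SimulationError(OatmapError):
    pass


class PipelineError(OatmapError):
    pass


class Impact(enum.IntEnum):
    """Consequence severity tiers; ordering supports max() aggregation."""

    MODIFIER = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3


class Consequence(str, enum.Enum):
    INTERGENIC = "intergenic"
    INTRON = "intron"
    SPLICE_SITE = "splice_site"
    FIVE_PRIME_UTR = "five_prime_UTR"
    THREE_PRIME_UTR = "three_prime_UTR"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed consequence -> impact mapping (four-tier scheme).
IMPACT_OF: Mapping[Consequence, Impact] = {
    Consequence.INTERGENIC: Impact.MODIFIER,
    Consequence.INTRON: Impact.MODIFIER,
    Consequence.FIVE_PRIME_UTR: Impact.MODIFIER,
    Consequence.THREE_PRIME_UTR: Impact.MODIFIER,
    Consequence.SYNONYMOUS: Impact.LOW,
    Consequence.MISSENSE: Impact.MODERATE,
    Consequence.STOP_GAINED: Impact.HIGH,
    Consequence.STOP_LOST: Impact.HIGH,
    Consequence.START_LOST: Impact.HIGH,
    Consequence.SPLICE_SITE: Impact.HIGH,
}

#: Consequences that carry a residue-level protein change annotation.
PROTEIN_CHANGING = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.STOP_GAINED,
        Consequence.STOP_LOST,
        Consequence.START_LOST,
    }
)


@dataclass(frozen=True)
class Effect:
    """Predicted consequence of one SNP on one transcript.

    ``gene_id``/``transcript_id`` are ``None`` for intergenic effects.
    ``protein_change`` uses three-letter notation, e.g. ``"Pro303Leu"``;
    it is non-empty exactly for the protein-changing consequences.
    """

    gene_id: Optional[str]
    transcript_id: Optional[str]
    consequence: Consequence
    impact: Impact
    protein_change: str = ""

    def __post_init__(self) -> None:
        if self.impact is not IMPACT_OF[self.consequence]:
            raise ValueError(
                f"impact {self.impact!r} inconsistent with {self.consequence!r}"
            )
        if bool(self.protein_change) != (self.consequence in PROTEIN_CHANGING):
            raise ValueError(
                "protein_change must be set iff the consequence changes the protein"
            )


@dataclass
class Variant:
    """A biallelic SNP with pooled allelic depths.

    ``ad_ref``/``ad_alt`` are reference/alternate supporting read counts
    summed across VCF samples.  ``effects`` is filled by the annotator.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ad_ref: int
    ad_alt: int
    qual: Optional[float] = None
    effects: list[Effect] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _DNA or self.alt not in _DNA:
            raise ValueError(f"alleles must be single A/C/G/T bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.ad_ref < 0 or self.ad_alt < 0:
            raise ValueError("allelic depths must be non-negative")

    @property
    def total_depth(self) -> int:
        return self.ad_ref + self.ad_alt

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for background subtraction."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def max_impact(self) -> Impact:
        if not self.effects:
            return Impact.MODIFIER
        return max(e.impact for e in self.effects)


@dataclass(frozen=True)
class Transcript:
    """One protein-coding transcript model.

    ``exons`` and ``cds`` are tuples of 0-based half-open intervals in
    genome order (ascending start) regardless of strand; use
    :meth:`cds_transcription_order` for 5'->3' traversal.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name, ivs in (("exon", self.exons), ("CDS", self.cds)):
            for s, e in ivs:
                if not 0 <= s < e:
                    raise ValueError(f"bad {name} interval ({s}, {e})")
        if list(self.exons) != sorted(self.exons) or list(self.cds) != sorted(self.cds):
            raise ValueError("intervals must be sorted in genome order")
        for i in range(1, len(self.cds)):
            if self.cds[i][0] < self.cds[i - 1][1]:
                raise ValueError("CDS intervals overlap")
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(f"CDS interval ({s}, {e}) not contained in an exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_transcription_order(self) -> list[tuple[int, int]]:
        """CDS intervals ordered 5'->3' along the transcript."""
        return list(self.cds) if self.strand == "+" else list(reversed(self.cds))

    def exons_transcription_order(self) -> list[tuple[int, int]]:
        return list(self.exons) if self.strand == "+" else list(reversed(self.exons))


class GeneModels:
    """Collection of transcripts with per-chromosome interval lookup."""

    def __init__(self, transcripts: Iterable[Transcript] = ()) -> None:
        self.transcripts: list[Transcript] = list(transcripts)
        self._index: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
        self._build_index()

    def _build_index(self) -> None:
        by_chrom: dict[str, list[int]] = {}
        for i, t in enumerate(self.transcripts):
            by_chrom.setdefault(t.chrom, []).append(i)
        self._index = {}
        for chrom, idx in by_chrom.items():
            idx.sort(key=lambda i: self.transcripts[i].start)
            starts = np.array([self.transcripts[i].start for i in idx], dtype=np.int64)
            ends = np.array([self.transcripts[i].end for i in idx], dtype=np.int64)
            self._index[chrom] = (starts, ends, idx)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.transcripts:
            seen.setdefault(t.gene_id)
        return list(seen)

    def overlapping(self, chrom: str, pos0: int) -> list[Transcript]:
        """Transcripts whose span contains 0-based position ``pos0``."""
        entry = self._index.get(chrom)
        if entry is None:
            return []
        starts, ends, idx = entry
        hit = (starts <= pos0) & (pos0 < ends)
        return [self.transcripts[idx[i]] for i in np.nonzero(hit)[0]]

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.gene_id == gene_id]


@dataclass
class ExpressionMatrix:
    """TPM expression values (genes x samples) with tissue-group labels."""

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise TableFormatError(f"samples missing from group map: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise TableFormatError("negative TPM values are not allowed")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def expressed_in_all(
        self, gene_id: str, required_groups: Iterable[str], tpm_min: float
    ) -> bool:
        """True iff TPM strictly exceeds ``tpm_min`` in every sample of
        every required group. Genes absent from the matrix fail."""
        if gene_id not in self.values.index:
            return False
        row = self.values.loc[gene_id]
        for group in required_groups:
            cols = self.samples_in_group(group)
            if not cols or not (row[cols] > tpm_min).all():
                return False
        return True


class OrthogroupMap:
    """Orthogroup membership: each protein belongs to at most one group."""

    def __init__(self, members: Mapping[str, Iterable[tuple[str, str]]]) -> None:
        self.members: dict[str, list[tuple[str, str]]] = {
            og: list(mem) for og, mem in members.items()
        }
        self._og_of: dict[str, str] = {}
        for og, mem in self.members.items():
            for _species, protein in mem:
                if protein in self._og_of:
                    raise TableFormatError(
                        f"protein {protein!r} listed in more than one orthogroup"
                    )
                self._og_of[protein] = og

    def __len__(self) -> int:
        return len(self.members)

    def orthogroup_of(self, protein_id: str) -> Optional[str]:
        return self._og_of.get(protein_id)

    def members_of(self, orthogroup_id: str, species: Optional[str] = None) -> list[str]:
        mem = self.members.get(orthogroup_id, [])
        return [p for sp, p in mem if species is None or sp == species]


def default_gene_of_protein(protein_id: str) -> str:
    """Map a protein/transcript identifier to its gene id by stripping the
    trailing dot-separated index (``"g0001.1" -> "g0001"``)."""
    return protein_id.rsplit(".", 1)[0]
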