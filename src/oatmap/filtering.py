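"""Background subtraction, the four-stage candidate-gene funnel, and the
orthogroup seed-shape screen.

Funnel steps, applied in order to genes surviving the previous step:

  i.   the gene carries a variant of at least the configured impact tier
       (MODERATE by default: missense and worse);
  ii.  that variant lies on the target chromosome (chromosome mode) or
       inside a called enriched region (region mode);
  iii. that variant has alternate-allele depth >= ``min_alt_depth`` and
       reference-allele depth <= ``max_ref_depth`` (defaults 15 and 0:
       strong support, no reference reads);
  iv.  the gene is expressed above ``tpm_min`` TPM in every sample of
       every required tissue group.

A gene qualifies only if a single variant satisfies steps i-iii
simultaneously (per-variant conjunction, then gene-level union), which
prevents a gene passing via two different half-qualifying variants.
Because of this conjunction the final candidate set is invariant to step
order; only the intermediate counts depend on it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .mapping import in_any_region
from .model import (
    ExpressionMatrix,
    Impact,
    OatmapError,
    OrthogroupMap,
    Variant,
    default_gene_of_protein,
)

CANDIDATE_COLUMNS = [
    "gene_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ad_ref",
    "ad_alt",
    "consequence",
    "impact",
    "protein_change",
]


@dataclass(frozen=True)
class FunnelConfig:
    min_alt_depth: int = 15
    max_ref_depth: int = 0
    impact_min: Impact = Impact.MODERATE
    tpm_min: float = 0.5
    required_groups: tuple[str, ...] = ("seed", "glume", "spikelet")
    region_mode: str = "region"  # "region" or "chromosome"
    target_chromosome: Optional[str] = None

    def __post_init__(self) -> None:
        if self.min_alt_depth < 0 or self.max_ref_depth < 0:
            raise ValueError("depth thresholds must be non-negative")
        if self.impact_min not in (Impact.MODERATE, Impact.HIGH):
            raise ValueError("impact_min must be MODERATE or HIGH")
        if self.region_mode not in ("region", "chromosome"):
            raise ValueError("region_mode must be 'region' or 'chromosome'")


@dataclass
class FunnelResult:
    """Per-step surviving gene counts plus the final candidate table."""

    step_counts: dict[str, int]
    step_genes: dict[str, list[str]]
    candidates: pd.DataFrame

    @property
    def final_genes(self) -> list[str]:
        return self.step_genes["iv"]


@dataclass
class ScreenResult:
    """Outcome of the orthogroup-based known-gene screen."""

    n_queried: int
    n_with_orthogroup: int
    n_orthogroups: int
    n_oat_proteins: int
    oat_genes: list[str] = field(default_factory=list)
    intersection: list[str] = field(default_factory=list)


def subtract_background(
    variants: Iterable[Variant],
    background_sets: Iterable[Iterable[Variant]] | Iterable[Variant],
) -> list[Variant]:
    """Remove variants matching (chrom, pos, ref, alt) in any background
    set (independent mutant lines, parents). Idempotent."""
    sets = list(background_sets)
    if sets and isinstance(sets[0], Variant):
        sets = [sets]
    blocked = {v.key for bg in sets for v in bg}
    return [v for v in variants if v.key not in blocked]


def _qualifies_location(v: Variant, config: FunnelConfig, regions) -> bool:
    if config.region_mode == "chromosome":
        if config.target_chromosome is None:
            raise OatmapError("chromosome mode requires target_chromosome")
        return v.chrom == config.target_chromosome
    if regions is None:
        raise OatmapError("region mode requires a called-regions table")
    return in_any_region(regions, v.chrom, v.pos)


def apply_funnel(
    variants: Sequence[Variant],
    expression: ExpressionMatrix,
    config: FunnelConfig,
    regions: Optional[pd.DataFrame] = None,
) -> FunnelResult:
    """Run filter steps i-iv over annotated variants.

    ``regions`` (from :func:`oatmap.mapping.call_regions`) is required in
    region mode. Step counts are recorded under keys "i".."iv"; counts
    are non-increasing by construction.
    """
    # per (variant, gene): does this variant's effect on the gene reach
    # the impact threshold?
    q1: list[tuple[Variant, str]] = []
    for v in variants:
        genes = {
            e.gene_id
            for e in v.effects
            if e.gene_id is not None and e.impact >= config.impact_min
        }
        q1.extend((v, g) for g in sorted(genes))

    q2 = [(v, g) for v, g in q1 if _qualifies_location(v, config, regions)]
    q3 = [
        (v, g)
        for v, g in q2
        if v.ad_alt >= config.min_alt_depth and v.ad_ref <= config.max_ref_depth
    ]
    genes_i = sorted({g for _, g in q1})
    genes_ii = sorted({g for _, g in q2})
    genes_iii = sorted({g for _, g in q3})
    genes_iv = [
        g
        for g in genes_iii
        if expression.expressed_in_all(g, config.required_groups, config.tpm_min)
    ]
    rows = [
        (
            g,
            v.chrom,
            v.pos,
            v.ref,
            v.alt,
            v.ad_ref,
            v.ad_alt,
            next(e.consequence.value for e in v.effects if e.gene_id == g),
            next(e.impact.name for e in v.effects if e.gene_id == g),
            next(e.protein_change for e in v.effects if e.gene_id == g),
        )
        for v, g in q3
        if g in set(genes_iv)
    ]
    candidates = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).sort_values(
        ["gene_id", "chrom", "pos"], ignore_index=True
    )
    return FunnelResult(
        step_counts={
            "i": len(genes_i),
            "ii": len(genes_ii),
            "iii": len(genes_iii),
            "iv": len(genes_iv),
        },
        step_genes={"i": genes_i, "ii": genes_ii, "iii": genes_iii, "iv": genes_iv},
        candidates=candidates,
    )


def orthogroup_screen(
    orthogroups: OrthogroupMap,
    known_genes: Sequence[tuple[str, str]],
    impacted_genes: Iterable[str],
    expression: Optional[ExpressionMatrix] = None,
    oat_species: str = "oat",
    gene_of_protein: Callable[[str], str] = default_gene_of_protein,
) -> ScreenResult:
    """Transfer known seed-shape genes to oat through orthogroups.

    Maps each queried foreign protein to its orthogroup (counting those
    without one), collects all oat members of those orthogroups, and
    intersects the corresponding oat genes with ``impacted_genes`` (genes
    carrying at least MODERATE-impact variants). ``expression`` is
    accepted for symmetry with the funnel but does not restrict the
    screen.
    """
    hit_ogs: dict[str, None] = {}
    n_with = 0
    for _species, protein in known_genes:
        og = orthogroups.orthogroup_of(protein)
        if og is not None:
            n_with += 1
            hit_ogs.setdefault(og)
    oat_proteins: list[str] = []
    for og in hit_ogs:
        oat_proteins.extend(orthogroups.members_of(og, species=oat_species))
    oat_genes = sorted({gene_of_protein(p) for p in oat_proteins})
    impacted = set(impacted_genes)
    return ScreenResult(
        n_queried=len(known_genes),
        n_with_orthogroup=n_with,
        n_orthogroups=len(hit_ogs),
        n_oat_proteins=len(oat_proteins),
        oat_genes=oat_genes,
        intersection=sorted(set(oat_genes) & impacted),
    )
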