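"""End-to-end orchestration: simulate/load -> subtract -> annotate ->
scan -> filter -> screen -> stats, with a machine-readable run report.

A single global seed derives per-stage seeds deterministically (stage-
name hashing), so individual stages are rerunnable and a rerun with the
same seed reproduces every intermediate exactly. Report timestamps are
segregated into one field so the rest of the report is diffable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from .annotate import annotate_variants, gene_max_impact
from .filtering import (
    FunnelConfig,
    apply_funnel,
    orthogroup_screen,
    subtract_background,
)
from .mapping import (
    AF_MIN,
    MIN_TOTAL_DEPTH,
    MIN_WINDOWS,
    WINDOW_SIZE,
    call_regions,
    sliding_median,
    top_window,
)
from .model import Impact, PipelineError
from .simulate import Experiment, SimConfig, simulate_experiment
from .stats import segregation_chisq

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """One reproducible pipeline run (synthetic or real input mode)."""

    mode: str = "synthetic"  # "synthetic" or "real"
    outdir: str = "oatmap_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    funnel: FunnelConfig = field(default_factory=FunnelConfig)
    window_size: int = WINDOW_SIZE
    min_total_depth: int = MIN_TOTAL_DEPTH
    af_min: float = AF_MIN
    min_windows: int = MIN_WINDOWS
    # real-mode inputs
    vcf: Optional[str] = None
    background_vcfs: tuple[str, ...] = ()
    fasta: Optional[str] = None
    gff: Optional[str] = None
    expression: Optional[str] = None
    sample_groups: Optional[str] = None
    orthogroups: Optional[str] = None
    known_genes: Optional[str] = None
    segregation: Optional[tuple[int, int]] = None  # (n_mutant, n_total)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw:
            raw["sim"] = SimConfig(**raw["sim"])
        if "funnel" in raw:
            fun = dict(raw["funnel"])
            if "impact_min" in fun:
                fun["impact_min"] = Impact[fun["impact_min"]]
            if "required_groups" in fun:
                fun["required_groups"] = tuple(fun["required_groups"])
            raw["funnel"] = FunnelConfig(**fun)
        if "background_vcfs" in raw:
            raw["background_vcfs"] = tuple(raw["background_vcfs"])
        if "segregation" in raw and raw["segregation"] is not None:
            raw["segregation"] = tuple(raw["segregation"])
        return cls(**raw)


def _config_echo(config: RunConfig) -> dict[str, Any]:
    def encode(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Impact):
            return obj.name
        if isinstance(obj, tuple):
            return [encode(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return encode(config)


def _hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return run

    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages, persist every intermediate under ``outdir``,
    and return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "seed": config.seed,
        "mode": config.mode,
        "config": _config_echo(config),
    }

    if config.mode == "synthetic":
        sim_cfg = dataclasses.replace(config.sim, seed=derive_seed(config.seed, "simulate"))
        experiment = _stage("simulate")(simulate_experiment)(sim_cfg)
        paths = experiment.write(outdir)
        genome, models = experiment.genome, experiment.models
        variants = list(experiment.variants)
        backgrounds = [experiment.side.background]
        expression = experiment.side.expression
        orthogroups = experiment.side.orthogroups
        known = experiment.side.known_genes
        report["truth"] = {
            "causal_gene": experiment.truth.causal_gene_id,
            "causal_chrom": str(experiment.truth.causal["chrom"]),
            "causal_pos": int(experiment.truth.causal["pos"]),
        }
        segregation_obs = (experiment.pool.n_positive, experiment.pool.n_f2)
        input_paths = {k: str(v) for k, v in paths.items()}
    else:
        load = _stage("load-inputs")(_load_real_inputs)
        genome, models, variants, backgrounds, expression, orthogroups, known = load(
            config
        )
        segregation_obs = config.segregation
        input_paths = {
            k: str(v)
            for k, v in {
                "vcf": config.vcf,
                "fasta": config.fasta,
                "gff": config.gff,
                "expression": config.expression,
                "orthogroups": config.orthogroups,
                "known_genes": config.known_genes,
            }.items()
            if v
        }
        for i, bg in enumerate(config.background_vcfs):
            input_paths[f"background_{i}"] = str(bg)
    report["input_hashes"] = {k: _hash_file(p) for k, p in input_paths.items()}

    n_before = len(variants)
    variants = _stage("subtract-background")(subtract_background)(variants, backgrounds)
    report["variant_counts"] = {
        "input": n_before,
        "after_background_subtraction": len(variants),
    }

    variants = _stage("annotate")(annotate_variants)(variants, models, genome)
    oio.write_vcf(variants, outdir / "annotated.vcf", contigs=list(genome))

    track = _stage("scan")(sliding_median)(
        variants, window_size=config.window_size, min_total_depth=config.min_total_depth
    )
    track.to_csv(outdir / "track.tsv", sep="\t", index=False, float_format="%.6g")
    regions = _stage("call-regions")(call_regions)(
        track, af_min=config.af_min, min_windows=config.min_windows
    )
    regions.to_csv(outdir / "regions.tsv", sep="\t", index=False, float_format="%.6g")
    top = top_window(track)
    report["scan"] = {
        "n_windows": int(len(track)),
        "top_window": None
        if top is None
        else {
            "chrom": str(top["chrom"]),
            "start": int(top["start"]),
            "end": int(top["end"]),
            "median_af": float(top["median_af"]),
        },
        "regions": regions.to_dict(orient="records"),
    }

    if expression is None:
        raise PipelineError("stage 'filter' failed: no expression matrix supplied")
    funnel = _stage("filter")(apply_funnel)(
        variants, expression, config.funnel, regions=regions
    )
    funnel.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    report["funnel"] = {
        "step_counts": funnel.step_counts,
        "final_genes": funnel.final_genes,
        "candidates": funnel.candidates.to_dict(orient="records"),
    }

    if orthogroups is not None and known is not None:
        impacted = [
            g
            for g, imp in gene_max_impact(variants).items()
            if imp >= Impact.MODERATE
        ]
        screen = _stage("screen")(orthogroup_screen)(orthogroups, known, impacted)
        report["screen"] = {
            "n_queried": screen.n_queried,
            "n_with_orthogroup": screen.n_with_orthogroup,
            "n_orthogroups": screen.n_orthogroups,
            "n_oat_proteins": screen.n_oat_proteins,
            "intersection": screen.intersection,
        }

    if segregation_obs is not None:
        n_mut, n_tot = segregation_obs
        seg = _stage("stats")(segregation_chisq)(n_mut, n_tot)
        report["segregation"] = {
            "n_mutant": seg.n_mutant,
            "n_total": seg.n_total,
            "statistic": seg.statistic,
            "df": seg.df,
            "pvalue": seg.pvalue,
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def _load_real_inputs(config: RunConfig):
    for name in ("vcf", "fasta", "gff", "expression", "sample_groups"):
        value = getattr(config, name)
        if value is None:
            raise PipelineError(f"stage 'load-inputs' failed: missing {name} path")
        if not Path(value).exists():
            raise PipelineError(f"stage 'load-inputs' failed: {name} file {value!r} not found")
    genome = oio.read_fasta(config.fasta)
    models = oio.read_gff(config.gff)
    variants = oio.read_vcf(config.vcf)
    backgrounds = [oio.read_vcf(p) for p in config.background_vcfs]
    groups = oio.read_group_map(config.sample_groups)
    expression = oio.read_expression(config.expression, groups)
    orthogroups = oio.read_orthogroups(config.orthogroups) if config.orthogroups else None
    known = oio.read_gene_list(config.known_genes) if config.known_genes else None
    return genome, models, variants, backgrounds, expression, orthogroups, known


# ---------------------------------------------------------------------------
# replicate recovery study (in-memory; used by tests and acceptance script)


def recovery_study(
    n_replicates: int,
    base_config: Optional[SimConfig] = None,
    seed: int = 0,
    funnel_config: Optional[FunnelConfig] = None,
    window_size: int = WINDOW_SIZE,
    min_total_depth: int = MIN_TOTAL_DEPTH,
    af_min: float = AF_MIN,
    min_windows: int = MIN_WINDOWS,
) -> pd.DataFrame:
    """Replicate simulations measuring causal-locus recovery.

    For each replicate: simulate an experiment, subtract the background
    set, annotate, scan, call regions, and run the funnel (region mode).
    Returns one row per replicate with columns:

    - ``top_chrom_correct``: genome-wide argmax window median lies on the
      causal chromosome;
    - ``region_called``: at least one enriched region was called;
    - ``causal_in_candidates``: the causal gene survives all four funnel
      steps;
    - ``n_candidates``: final candidate gene count.
    """
    base_config = SimConfig() if base_config is None else base_config
    funnel_config = FunnelConfig() if funnel_config is None else funnel_config
    rows = []
    for rep in range(n_replicates):
        cfg = dataclasses.replace(
            base_config, seed=derive_seed(seed, f"recovery-{rep}")
        )
        exp = simulate_experiment(cfg)
        variants = subtract_background(exp.variants, [exp.side.background])
        variants = annotate_variants(variants, exp.models, exp.genome)
        track = sliding_median(
            variants, window_size=window_size, min_total_depth=min_total_depth
        )
        regions = call_regions(track, af_min=af_min, min_windows=min_windows)
        top = top_window(track)
        causal_chrom = str(exp.truth.causal["chrom"])
        funnel = apply_funnel(variants, exp.side.expression, funnel_config, regions=regions)
        rows.append(
            {
                "replicate": rep,
                "top_chrom_correct": top is not None and top["chrom"] == causal_chrom,
                "region_called": not regions.empty,
                "causal_in_candidates": exp.truth.causal_gene_id in funnel.final_genes,
                "n_candidates": len(funnel.final_genes),
            }
        )
        logger.info("replicate %d/%d: %s", rep + 1, n_replicates, rows[-1])
    return pd.DataFrame(rows)
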