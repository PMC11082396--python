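"""Pooled allele-frequency mapping signal.

Per-variant mutant allele frequencies, the per-chromosome sliding-window
median track, and enriched-region calling. Windows are fixed-size runs
of consecutive depth-filtered variants (step 1) and never span
chromosome boundaries.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import OatmapError, Variant

#: Default window size (number of variants per window).
WINDOW_SIZE = 100
#: Default minimum total allelic depth for a variant to enter a window.
MIN_TOTAL_DEPTH = 15
#: Default region-calling thresholds. ``AF_MIN`` is tuned to the
#: desk-scale genetic map density (see docs/methods.md); override from
#: the CLI for denser maps.
AF_MIN = 0.7
MIN_WINDOWS = 5

TRACK_COLUMNS = ["chrom", "start", "end", "median_af", "n_variants"]
REGION_COLUMNS = ["chrom", "start", "end", "mean_median_af", "n_windows"]


def allele_frequency(variant: Variant) -> float:
    """Mutant (alternate) allele frequency: ad_alt / (ad_ref + ad_alt)."""
    depth = variant.total_depth
    if depth == 0:
        raise OatmapError(
            f"allele frequency undefined at zero depth "
            f"({variant.chrom}:{variant.pos})"
        )
    return variant.ad_alt / depth


def sliding_median(
    variants: Iterable[Variant],
    window_size: int = WINDOW_SIZE,
    min_total_depth: int = MIN_TOTAL_DEPTH,
) -> pd.DataFrame:
    """Sliding-window (step 1) median allele frequency per chromosome.

    Variants with total allelic depth below ``min_total_depth`` are
    excluded before windowing. Chromosomes with fewer retained variants
    than ``window_size`` yield no windows. The median of an even-sized
    window is the mean of the two central order statistics.

    Returns a DataFrame with columns chrom, start, end (positions of the
    first/last member variant), median_af, n_variants.
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    kept = [v for v in variants if v.total_depth >= min_total_depth]
    kept.sort(key=lambda v: (v.chrom, v.pos))
    rows: list[tuple] = []
    by_chrom: dict[str, list[Variant]] = {}
    for v in kept:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, vs in by_chrom.items():
        if len(vs) < window_size:
            continue
        af = np.array([allele_frequency(v) for v in vs])
        pos = np.array([v.pos for v in vs])
        windows = np.lib.stride_tricks.sliding_window_view(af, window_size)
        medians = np.median(windows, axis=1)
        for i, med in enumerate(medians):
            rows.append((chrom, int(pos[i]), int(pos[i + window_size - 1]), float(med), window_size))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def call_regions(
    track: pd.DataFrame,
    af_min: float = AF_MIN,
    min_windows: int = MIN_WINDOWS,
) -> pd.DataFrame:
    """Maximal runs of >= ``min_windows`` consecutive windows with median
    AF >= ``af_min``, merged per chromosome.

    Region span runs from the first member window's start to the last
    member window's end. An empty track yields an empty frame.
    """
    rows: list[tuple] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        above = (sub["median_af"].to_numpy() >= af_min).astype(int)
        if not above.any():
            continue
        boundaries = np.flatnonzero(np.diff(np.concatenate(([0], above, [0]))))
        for run_start, run_end in boundaries.reshape(-1, 2):
            n = run_end - run_start
            if n < min_windows:
                continue
            block = sub.iloc[run_start:run_end]
            rows.append(
                (
                    chrom,
                    int(block["start"].iloc[0]),
                    int(block["end"].iloc[-1]),
                    float(block["median_af"].mean()),
                    int(n),
                )
            )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def top_window(track: pd.DataFrame) -> Optional[pd.Series]:
    """The window with the genome-wide maximum median AF (None if empty)."""
    if track.empty:
        return None
    return track.loc[track["median_af"].idxmax()]


def in_any_region(regions: pd.DataFrame, chrom: str, pos: int) -> bool:
    if regions.empty:
        return False
    hit = (
        (regions["chrom"] == chrom)
        & (regions["start"] <= pos)
        & (pos <= regions["end"])
    )
    return bool(hit.any())


def plot_track(
    track: pd.DataFrame,
    path: str,
    regions: Optional[pd.DataFrame] = None,
    highlight_chrom: Optional[str] = None,
) -> None:
    """Plot median AF against position, one panel per chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(track["chrom"]))
    fig, axes = plt.subplots(
        1, max(1, len(chroms)), figsize=(4 * max(1, len(chroms)), 3), sharey=True
    )
    if len(chroms) <= 1:
        axes = [axes]
    for ax, chrom in zip(axes, chroms):
        sub = track[track["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2e6
        color = "purple" if chrom == highlight_chrom else "steelblue"
        ax.plot(mid, sub["median_af"], ".", ms=2, color=color)
        ax.set_title(chrom)
        ax.set_xlabel("position (Mb)")
        ax.set_ylim(0, 1.05)
        if regions is not None and not regions.empty:
            for _, r in regions[regions["chrom"] == chrom].iterrows():
                ax.axvspan(r["start"] / 1e6, r["end"] / 1e6, alpha=0.2, color="orange")
    axes[0].set_ylabel("median allele frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
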