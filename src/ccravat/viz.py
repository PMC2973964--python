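"""Graphical summaries: the genome-wide Manhattan plot of region p-values
and the quantitative-trait histograms (pooled, and carrier vs non-carrier
per significant region).

The plot data series (positions, -log10 p, highlight mask, bin edges) are
computed by pure functions so they can be tested independently of the raster
backend; the PNG rendering itself is a thin matplotlib layer.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "PlotConfig",
    "ManhattanSeries",
    "manhattan_series",
    "manhattan",
    "fd_bin_edges",
    "trait_histogram",
    "group_histogram",
]

logger = logging.getLogger(__name__)

CARRIER_COLOR = "red"
NONCARRIER_COLOR = "blue"
NEUTRAL_COLOR = "0.35"
HIGHLIGHT_COLOR = "red"


@dataclass
class PlotConfig:
    width: int = 1200  # pixels
    height: int = 600
    point_size: float = 9.0  # marker area in points^2
    highlight_threshold: float = 1e-3
    dpi: int = 100

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plot dimensions must be positive")

    @property
    def figsize(self) -> tuple[float, float]:
        return self.width / self.dpi, self.height / self.dpi


@dataclass
class ManhattanSeries:
    """Backend-independent Manhattan plot data."""

    x: np.ndarray  # concatenated genomic position (bp)
    y: np.ndarray  # -log10 p
    highlight: np.ndarray  # bool, p <= threshold
    chrom: np.ndarray  # chromosome label per point
    chrom_offsets: dict  # chromosome -> additive bp offset


def manhattan_series(
    chroms: Sequence[str],
    midpoints: Sequence[float],
    pvalues: Sequence[float],
    highlight_threshold: float = 1e-3,
) -> ManhattanSeries:
    """Compute the Manhattan scatter: x is the region midpoint with
    chromosomes concatenated end to end (in first-appearance order), y is
    -log10 p.  p = 1 plots at 0; p = 0 is clamped to the smallest positive
    double with a warning."""
    chroms = np.asarray(chroms, dtype=object)
    mid = np.asarray(midpoints, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    if np.any(p == 0):
        logger.warning("p = 0 encountered; clamped to %.3g for plotting",
                       sys.float_info.min)
        p = np.where(p == 0, sys.float_info.min, p)
    order: list[str] = []
    for c in chroms:
        if c not in order:
            order.append(c)
    offsets: dict = {}
    running = 0.0
    for c in order:
        offsets[c] = running
        sel = chroms == c
        if sel.any():
            running += float(mid[sel].max()) + 1.0
    x = np.array([m + offsets[c] for m, c in zip(mid, chroms)], dtype=float)
    y = -np.log10(p)
    return ManhattanSeries(
        x=x, y=y, highlight=p <= highlight_threshold,
        chrom=chroms, chrom_offsets=offsets,
    )


def manhattan(
    chroms: Sequence[str],
    midpoints: Sequence[float],
    pvalues: Sequence[float],
    path,
    config: Optional[PlotConfig] = None,
) -> ManhattanSeries:
    """Render the Manhattan plot to ``path`` and return the data series."""
    config = config or PlotConfig()
    series = manhattan_series(chroms, midpoints, pvalues,
                              config.highlight_threshold)
    fig, ax = plt.subplots(figsize=config.figsize, dpi=config.dpi)
    if series.x.size:
        ax.scatter(series.x[~series.highlight], series.y[~series.highlight],
                   s=config.point_size, c=NEUTRAL_COLOR, linewidths=0)
        ax.scatter(series.x[series.highlight], series.y[series.highlight],
                   s=config.point_size, c=HIGHLIGHT_COLOR, linewidths=0)
    ax.set_xlabel("position (bp, chromosomes concatenated)")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return series


def fd_bin_edges(values: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis histogram bin edges, degrading gracefully for
    constant or tiny samples."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return np.array([0.0, 1.0])
    if np.ptp(v) == 0:
        c = float(v[0])
        return np.array([c - 0.5, c + 0.5])
    return np.histogram_bin_edges(v, bins="fd")


def trait_histogram(
    traits: Sequence[float], path, config: Optional[PlotConfig] = None
) -> np.ndarray:
    """Histogram of the quantitative trait over all non-missing individuals;
    returns the bin edges used."""
    config = config or PlotConfig()
    v = np.asarray(traits, dtype=float)
    v = v[~np.isnan(v)]
    edges = fd_bin_edges(v)
    fig, ax = plt.subplots(figsize=config.figsize, dpi=config.dpi)
    if v.size:
        ax.hist(v, bins=edges, color="0.5", edgecolor="white")
    ax.set_xlabel("trait value")
    ax.set_ylabel("individuals")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return edges


def group_histogram(
    carrier_traits: Sequence[float],
    noncarrier_traits: Sequence[float],
    path,
    config: Optional[PlotConfig] = None,
    title: str = "",
) -> np.ndarray:
    """Overlaid trait histograms for carriers (red) and non-carriers (blue),
    on shared Freedman-Diaconis bins over the pooled sample; returns the bin
    edges."""
    config = config or PlotConfig()
    tc = np.asarray(carrier_traits, dtype=float)
    tn = np.asarray(noncarrier_traits, dtype=float)
    tc = tc[~np.isnan(tc)]
    tn = tn[~np.isnan(tn)]
    pooled = np.concatenate([tc, tn]) if tc.size or tn.size else tc
    edges = fd_bin_edges(pooled)
    fig, ax = plt.subplots(figsize=config.figsize, dpi=config.dpi)
    if tn.size:
        ax.hist(tn, bins=edges, color=NONCARRIER_COLOR, alpha=0.6,
                label="non-carriers")
    if tc.size:
        ax.hist(tc, bins=edges, color=CARRIER_COLOR, alpha=0.6,
                label="carriers")
    ax.set_xlabel("trait value")
    ax.set_ylabel("individuals")
    if title:
        ax.set_title(title)
    if tc.size or tn.size:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return edges
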