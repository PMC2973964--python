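"""Analysis-region construction: gene-based regions with flanks, or sliding
windows anchored at bp 0, plus marker-to-region assignment.

Intervals are 1-based and inclusive at both ends, the linkage/annotation
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats import GeneRecord, Marker

__all__ = ["Region", "build_gene_regions", "build_sliding_windows",
           "assign_markers"]

logger = logging.getLogger(__name__)


@dataclass
class Region:
    """A named genomic interval with its member markers.

    ``marker_indices`` index into the chromosome's sorted marker list;
    ``rare_indices`` is the subset whose MAF falls under the rare-variant
    cutoff (filled in by the collapsing stage).
    """

    name: str
    chrom: str
    start_bp: int
    end_bp: int
    marker_indices: list[int] = field(default_factory=list)
    rare_indices: list[int] = field(default_factory=list)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


def build_gene_regions(
    genes: Sequence[GeneRecord], flank_up: int = 0, flank_down: int = 0
) -> list[Region]:
    """One region per gene, spanning the annotated gene extended by
    ``flank_up`` bp upstream of the start and ``flank_down`` bp downstream of
    the stop (clamped at coordinate 0).  Overlapping genes yield overlapping
    regions, each analysed independently.
    """
    if flank_up < 0 or flank_down < 0:
        raise ValueError("flanks must be non-negative")
    return [
        Region(
            name=g.gene_name,
            chrom=g.chrom,
            start_bp=max(0, g.start_bp - flank_up),
            end_bp=g.stop_bp + flank_down,
        )
        for g in genes
    ]


def build_sliding_windows(
    markers: Sequence[Marker], window_bp: int, step_bp: Optional[int] = None
) -> list[Region]:
    """Sliding windows ``[k*step, k*step + window]`` anchored at bp 0.

    Windows are emitted from the first one reaching the smallest marker
    position up to the first one covering the largest; windows containing no
    markers are kept (they appear in the per-chromosome output with zero
    counts).  ``step_bp`` defaults to ``window_bp // 2``; a step larger than
    the window leaves gaps and is allowed with a warning.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if step_bp is None:
        step_bp = max(1, window_bp // 2)
    if step_bp <= 0:
        raise ValueError("step_bp must be positive")
    if step_bp > window_bp:
        logger.warning(
            "step (%d bp) exceeds window (%d bp): tiling leaves gaps",
            step_bp, window_bp,
        )
    if not markers:
        return []
    chrom = markers[0].chrom
    positions = [m.bp for m in markers]
    lo, hi = min(positions), max(positions)
    # first window whose right edge reaches lo; last = first whose right
    # edge reaches hi
    k_first = max(0, -(-(lo - window_bp) // step_bp))
    k_last = max(k_first, -(-(hi - window_bp) // step_bp))
    out = []
    for k in range(k_first, k_last + 1):
        start = k * step_bp
        end = start + window_bp
        out.append(Region(name=f"{chrom}:{start}-{end}", chrom=chrom,
                          start_bp=start, end_bp=end))
    return out


def assign_markers(markers: Sequence[Marker], region: Region) -> list[int]:
    """Indices of markers with start_bp <= bp <= end_bp (bounds inclusive).

    Markers must already be sorted by bp (done on load); binary search keeps
    this cheap for genome-wide window scans.
    """
    positions = np.asarray([m.bp for m in markers])
    lo = int(np.searchsorted(positions, region.start_bp, side="left"))
    hi = int(np.searchsorted(positions, region.end_bp, side="right"))
    return list(range(lo, hi))
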