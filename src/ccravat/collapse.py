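"""Rare-variant collapsing: per-marker minor-allele frequencies, rare-marker
selection under a MAF cutoff, and the per-individual carrier indicator that
turns a region's rare variants into a single "super-locus".

A carrier is an individual bearing at least one minor allele at at least one
rare marker of the region; carrier status is binary (a homozygous-minor
individual counts once), matching the presence/absence construction of the
collapsing test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .formats import MISSING_ALLELE, GenotypePanel
from .regions import Region

__all__ = [
    "DataError",
    "MafRecord",
    "CARRIER",
    "NON_CARRIER",
    "MISSING",
    "compute_maf",
    "compute_all_mafs",
    "select_rare",
    "collapse_region",
]

logger = logging.getLogger(__name__)

# carrier-vector codes
CARRIER = 1
NON_CARRIER = 0
MISSING = -1


class DataError(ValueError):
    """Genotype data violating the biallelic-marker model."""


@dataclass(frozen=True)
class MafRecord:
    """Minor-allele summary for one marker.

    ``maf`` is NaN when no genotype was called; a monomorphic marker has
    maf 0 and no minor allele.
    """

    marker_index: int
    minor_allele: Optional[str]
    maf: float
    n_called: int


def _maf_mask(panel: GenotypePanel, in_controls: bool) -> np.ndarray:
    """Individuals contributing to allele-frequency estimation."""
    mask = panel.phenotyped()
    if in_controls:
        mask &= panel.is_control()
    return mask


def compute_maf(
    panel: GenotypePanel, marker_index: int, in_controls: bool = False
) -> MafRecord:
    """Minor-allele frequency at one marker over all phenotyped individuals
    (or controls only with ``in_controls``).

    maf = (count of the less frequent allele) / (2 * genotypes called); a
    50/50 tie is broken toward the lexicographically smaller token.
    """
    mask = _maf_mask(panel, in_controls)
    a1 = panel.a1[mask, marker_index]
    a2 = panel.a2[mask, marker_index]
    called = (a1 != MISSING_ALLELE) & (a2 != MISSING_ALLELE)
    alleles = np.concatenate([a1[called], a2[called]])
    n_called = int(called.sum())
    if n_called == 0:
        logger.warning(
            "marker %s: no called genotypes; MAF undefined, marker excluded",
            panel.markers[marker_index].name,
        )
        return MafRecord(marker_index, None, float("nan"), 0)
    uniq, counts = np.unique(alleles, return_counts=True)
    if len(uniq) > 2:
        raise DataError(
            f"marker {panel.markers[marker_index].name}: "
            f"{len(uniq)} alleles observed ({', '.join(uniq)}); "
            "only biallelic markers are supported"
        )
    if len(uniq) == 1:
        return MafRecord(marker_index, None, 0.0, n_called)
    # tie at 0.5: lexicographically smaller token is the minor allele
    if counts[0] == counts[1]:
        minor = min(uniq)
    else:
        minor = uniq[int(np.argmin(counts))]
    maf = float(counts[list(uniq).index(minor)]) / (2 * n_called)
    return MafRecord(marker_index, str(minor), maf, n_called)


def compute_all_mafs(
    panel: GenotypePanel, in_controls: bool = False
) -> list[MafRecord]:
    return [compute_maf(panel, j, in_controls) for j in range(panel.n_markers)]


def select_rare(mafs: Sequence[MafRecord], cutoff: float) -> list[int]:
    """Marker indices with 0 < maf <= cutoff.  Monomorphic markers are
    excluded (no minor allele exists to carry), as are markers with no
    called genotypes."""
    if not (0 < cutoff <= 0.5):
        raise ValueError(f"MAF cutoff must be in (0, 0.5], got {cutoff}")
    return [
        r.marker_index
        for r in mafs
        if not np.isnan(r.maf) and 0 < r.maf <= cutoff
    ]


def collapse_region(
    panel: GenotypePanel,
    region: Region,
    mafs: Sequence[MafRecord],
    strict_missing: bool = False,
) -> np.ndarray:
    """Per-individual carrier status over the region's rare markers.

    Returns an int8 vector with codes CARRIER (>=1 minor allele observed at
    >=1 rare marker), NON_CARRIER, MISSING.  Individuals with a missing
    phenotype are MISSING regardless of genotype.

    Partially missing individuals: by default an individual whose observed
    rare genotypes are all homozygous-major is a non-carrier even if some
    rare genotypes are missing (optimistic call); ``strict_missing`` instead
    marks any individual with a missing rare genotype and no observed minor
    allele as MISSING.  An individual with no observed rare genotype at all
    is always MISSING.  A region with zero rare markers makes every
    phenotyped individual a non-carrier.
    """
    n = panel.n_individuals
    status = np.full(n, NON_CARRIER, dtype=np.int8)
    rare = list(region.rare_indices)
    if rare:
        by_marker = {r.marker_index: r for r in mafs}
        carrier = np.zeros(n, dtype=bool)
        any_missing = np.zeros(n, dtype=bool)
        n_observed = np.zeros(n, dtype=np.int32)
        for j in rare:
            minor = by_marker[j].minor_allele
            a1 = panel.a1[:, j]
            a2 = panel.a2[:, j]
            miss = (a1 == MISSING_ALLELE) | (a2 == MISSING_ALLELE)
            any_missing |= miss
            n_observed += ~miss
            if minor is not None:
                carrier |= ~miss & ((a1 == minor) | (a2 == minor))
        status[carrier] = CARRIER
        status[~carrier & (n_observed == 0)] = MISSING
        if strict_missing:
            status[~carrier & any_missing] = MISSING
    status[~panel.phenotyped()] = MISSING
    return status
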