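"""Synthetic MAP/PED/gene fixture generation.

Genotypes are drawn under Hardy-Weinberg proportions at specified minor
allele frequencies, with no linkage disequilibrium between markers (the
collapsing statistics operate on carrier status only, so independent markers
suffice for testing).  Phenotypes can be generated under the null or with a
planted carrier effect: a logistic odds ratio on carrier status for binary
traits, or an additive mean shift with Gaussian noise for quantitative
traits.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats import (
    GeneRecord,
    GenotypePanel,
    Individual,
    MISSING_ALLELE,
    Marker,
)
from .regions import Region, assign_markers

__all__ = [
    "SimSpec",
    "gen_genotypes",
    "true_carrier",
    "gen_cc_phenotypes",
    "gen_qt_phenotypes",
    "write_fixture",
    "simulate_dataset",
]

MINOR, MAJOR = "A", "G"


@dataclass
class SimSpec:
    """Parameters of a synthetic single-chromosome panel.

    ``mafs`` fixes per-marker minor allele frequencies explicitly; when None,
    each marker's MAF is drawn uniformly from ``maf_range`` (default the
    low-frequency/rare band 0.005-0.05 targeted by the collapsing test).
    """

    n_individuals: int = 2000
    n_markers: int = 10
    mafs: Optional[Sequence[float]] = None
    maf_range: tuple[float, float] = (0.005, 0.05)
    chrom: str = "1"
    bp_start: int = 1000
    bp_spacing: int = 1000
    missing_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.mafs is not None:
            if len(self.mafs) != self.n_markers:
                raise ValueError("len(mafs) must equal n_markers")
            if any(not 0 <= p <= 0.5 for p in self.mafs):
                raise ValueError("MAFs must lie in [0, 0.5]")

    def resolved_mafs(self, rng: np.random.Generator) -> np.ndarray:
        if self.mafs is not None:
            return np.asarray(self.mafs, dtype=float)
        lo, hi = self.maf_range
        return rng.uniform(lo, hi, size=self.n_markers)


def gen_genotypes(spec: SimSpec) -> GenotypePanel:
    """Draw a genotype panel under HWE at the spec's MAFs; phenotypes are
    left missing (NaN) for a downstream phenotype generator to fill."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_individuals, spec.n_markers
    mafs = spec.resolved_mafs(rng)
    # two independent allele draws per genotype = HWE
    a1 = np.where(rng.random((n, m)) < mafs, MINOR, MAJOR)
    a2 = np.where(rng.random((n, m)) < mafs, MINOR, MAJOR)
    if spec.missing_rate > 0:
        miss = rng.random((n, m)) < spec.missing_rate
        a1 = np.where(miss, MISSING_ALLELE, a1)
        a2 = np.where(miss, MISSING_ALLELE, a2)
    markers = [
        Marker(name=f"SNP{j + 1}", chrom=spec.chrom,
               bp=spec.bp_start + j * spec.bp_spacing)
        for j in range(m)
    ]
    individuals = [
        Individual(ped_id=str(i + 1), indiv_id=str(i + 1),
                   father_id="0", mother_id="0", sex=int(1 + (i % 2)))
        for i in range(n)
    ]
    return GenotypePanel(
        individuals=individuals,
        markers=markers,
        a1=a1.astype("U8"),
        a2=a2.astype("U8"),
        phenotype=np.full(n, np.nan),
        trait_mode="binary",
    )


def true_carrier(
    panel: GenotypePanel,
    region: Optional[Region] = None,
    maf_cutoff: float = 0.05,
) -> np.ndarray:
    """Carrier indicator used by the phenotype generators: at least one
    minor allele at any marker of the region whose empirical MAF (over all
    individuals, phenotype ignored) is in (0, cutoff].

    Deliberately independent of the collapse module so that analysis-side
    recovery tests cross two code paths.
    """
    idx = (region.marker_indices or assign_markers(panel.markers, region)) \
        if region is not None else list(range(panel.n_markers))
    carrier = np.zeros(panel.n_individuals, dtype=bool)
    for j in idx:
        a1, a2 = panel.a1[:, j], panel.a2[:, j]
        called = (a1 != MISSING_ALLELE) & (a2 != MISSING_ALLELE)
        if not called.any():
            continue
        n_called = int(called.sum())
        freq = {
            tok: (int(np.sum(a1[called] == tok)) + int(np.sum(a2[called] == tok)))
            / (2 * n_called)
            for tok in (MINOR, MAJOR)
        }
        minor = MINOR if freq[MINOR] <= freq[MAJOR] else MAJOR
        if 0 < freq[minor] <= maf_cutoff:
            carrier |= called & ((a1 == minor) | (a2 == minor))
    return carrier


def gen_cc_phenotypes(
    panel: GenotypePanel,
    region: Optional[Region],
    odds_ratio: float = 1.0,
    case_fraction: float = 0.5,
    seed: int = 1,
    maf_cutoff: float = 0.05,
) -> np.ndarray:
    """Binary affection status from a logistic model on carrier status:
    logit P(case) = logit(case_fraction) + log(odds_ratio) * carrier.
    With odds_ratio 1 the labels are independent of genotype."""
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    rng = np.random.default_rng(seed)
    carrier = true_carrier(panel, region, maf_cutoff)
    b0 = math.log(case_fraction / (1 - case_fraction))
    logit = b0 + math.log(odds_ratio) * carrier.astype(float)
    p_case = 1.0 / (1.0 + np.exp(-logit))
    return np.where(rng.random(panel.n_individuals) < p_case, 2.0, 1.0)


def gen_qt_phenotypes(
    panel: GenotypePanel,
    region: Optional[Region],
    delta: float = 0.0,
    sigma: float = 1.0,
    seed: int = 1,
    maf_cutoff: float = 0.05,
) -> np.ndarray:
    """Quantitative trait = delta * carrier + Normal(0, sigma) noise."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    carrier = true_carrier(panel, region, maf_cutoff)
    return delta * carrier.astype(float) + rng.normal(0.0, sigma,
                                                      panel.n_individuals)


def _format_pheno(v: float, trait_mode: str) -> str:
    if math.isnan(v):
        return "0" if trait_mode == "binary" else "-9"
    if trait_mode == "binary":
        return str(int(v))
    return repr(float(v))  # repr round-trips doubles exactly


def write_fixture(
    panel: GenotypePanel,
    out_dir,
    stem: str = "chr1",
    genes: Optional[Sequence[GeneRecord]] = None,
    map_columns: int = 3,
) -> dict:
    """Write the panel as a MAP/PED pair (plus an optional gene file) that
    the formats readers round-trip exactly.  Returns the paths written."""
    if map_columns not in (3, 4):
        raise ValueError("map_columns must be 3 or 4")
    os.makedirs(out_dir, exist_ok=True)
    map_path = os.path.join(out_dir, f"{stem}.map")
    ped_path = os.path.join(out_dir, f"{stem}.ped")
    with open(map_path, "w") as fh:
        for m in panel.markers:
            if map_columns == 3:
                fh.write(f"{m.chrom} {m.name} {m.bp}\n")
            else:
                gpos = m.genetic_pos if m.genetic_pos is not None else 0
                fh.write(f"{m.chrom} {m.name} {gpos:g} {m.bp}\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(panel.individuals):
            fields = [ind.ped_id, ind.indiv_id, ind.father_id, ind.mother_id,
                      str(ind.sex),
                      _format_pheno(float(panel.phenotype[i]), panel.trait_mode)]
            for j in range(panel.n_markers):
                fields.append(str(panel.a1[i, j]))
                fields.append(str(panel.a2[i, j]))
            fh.write(" ".join(fields) + "\n")
    paths = {"map": map_path, "ped": ped_path}
    if genes is not None:
        gene_path = os.path.join(out_dir, "genes.txt")
        with open(gene_path, "w") as fh:
            for g in genes:
                fh.write(f"{g.gene_id} {g.gene_name} {g.chrom} "
                         f"{g.start_bp} {g.stop_bp}\n")
        paths["genes"] = gene_path
    return paths


def simulate_dataset(
    out_dir,
    n_individuals: int = 2000,
    n_markers: int = 50,
    trait_mode: str = "binary",
    effect: float = 1.0,  # odds ratio (binary) or mean shift delta (qt)
    sigma: float = 1.0,
    case_fraction: float = 0.5,
    missing_rate: float = 0.0,
    maf_cutoff: float = 0.05,
    n_genes: int = 5,
    seed: int = 1,
    map_columns: int = 3,
) -> dict:
    """One-call fixture: simulate a chromosome, plant the effect in the first
    gene's span, and write a ready-to-analyse MAP/PED/gene directory."""
    spec = SimSpec(n_individuals=n_individuals, n_markers=n_markers, seed=seed)
    panel = gen_genotypes(spec)
    # tile the chromosome into equal gene spans
    per_gene = max(1, n_markers // max(1, n_genes))
    genes = []
    for g in range(n_genes):
        j0 = g * per_gene
        j1 = min(n_markers, (g + 1) * per_gene) - 1
        if j0 >= n_markers:
            break
        genes.append(GeneRecord(
            gene_id=str(1000 + g), gene_name=f"GENE{g + 1}", chrom=spec.chrom,
            start_bp=panel.markers[j0].bp, stop_bp=panel.markers[j1].bp,
        ))
    target = Region(name=genes[0].gene_name, chrom=spec.chrom,
                    start_bp=genes[0].start_bp, end_bp=genes[0].stop_bp)
    target.marker_indices = assign_markers(panel.markers, target)
    if trait_mode == "binary":
        panel.phenotype = gen_cc_phenotypes(
            panel, target, odds_ratio=effect, case_fraction=case_fraction,
            seed=seed + 1, maf_cutoff=maf_cutoff,
        )
        panel.trait_mode = "binary"
    elif trait_mode == "quantitative":
        panel.phenotype = gen_qt_phenotypes(
            panel, target, delta=effect, sigma=sigma, seed=seed + 1,
            maf_cutoff=maf_cutoff,
        )
        panel.trait_mode = "quantitative"
    else:
        raise ValueError(f"unknown trait_mode {trait_mode!r}")
    return write_fixture(panel, out_dir, stem=f"chr{spec.chrom}",
                         genes=genes, map_columns=map_columns)
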