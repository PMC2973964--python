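"""Linkage-format I/O: MAP / pre-Makeped PED / gene-coordinate readers and
tab-delimited result writers.

All inputs are whitespace-delimited text, one chromosome per MAP/PED pair.
Coordinates are 1-based base pairs throughout.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "Marker",
    "Individual",
    "GenotypePanel",
    "GeneRecord",
    "MISSING_ALLELE",
    "read_map",
    "read_ped",
    "read_gene_file",
    "load_chromosome",
    "write_cc_summary",
    "write_cc_chromosome",
    "write_cc_permutations",
    "write_qt_summary",
    "write_qt_chromosome",
    "write_region_snplist",
    "fmt_p",
]

MISSING_ALLELE = "0"

#: default missing-phenotype sentinels
MISSING_BINARY_CODES = ("0", "-9")
MISSING_QT_CODES = ("-9",)


class FormatError(ValueError):
    """Malformed input file (wrong field count, bad coordinates, ...)."""


@dataclass(frozen=True)
class Marker:
    """A biallelic marker on one chromosome (bp is 1-based)."""

    name: str
    chrom: str
    bp: int
    genetic_pos: Optional[float] = None


@dataclass(frozen=True)
class Individual:
    ped_id: str
    indiv_id: str
    father_id: str
    mother_id: str
    sex: int  # 1 male, 2 female, 0 unknown


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    gene_name: str
    chrom: str
    start_bp: int
    stop_bp: int


@dataclass
class GenotypePanel:
    """Individuals x markers diploid genotype matrix with one phenotype.

    ``a1``/``a2`` hold the two allele tokens per genotype (unordered; the
    token "0" marks a missing allele, and a genotype is missing iff either
    allele is "0").  ``phenotype`` is a float vector: in binary mode it holds
    1 (control) / 2 (case) with NaN for missing; in quantitative mode the
    trait value with NaN for missing.
    """

    individuals: list[Individual]
    markers: list[Marker]
    a1: np.ndarray  # (n, m) allele tokens
    a2: np.ndarray
    phenotype: np.ndarray  # (n,) float, NaN = missing
    trait_mode: str = "binary"  # "binary" | "quantitative"

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def genotype_missing(self) -> np.ndarray:
        """(n, m) bool mask of missing genotypes (either allele "0")."""
        return (self.a1 == MISSING_ALLELE) | (self.a2 == MISSING_ALLELE)

    def phenotyped(self) -> np.ndarray:
        return ~np.isnan(self.phenotype)

    def is_case(self) -> np.ndarray:
        if self.trait_mode != "binary":
            raise ValueError("case/control status requires binary trait mode")
        return self.phenotype == 2.0

    def is_control(self) -> np.ndarray:
        if self.trait_mode != "binary":
            raise ValueError("case/control status requires binary trait mode")
        return self.phenotype == 1.0


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _rows(path) -> list[tuple[int, list[str]]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if fields:
                out.append((lineno, fields))
    return out


def read_map(path) -> list[Marker]:
    """Read a 3-column (chr, marker, bp) or 4-column PLINK-style
    (chr, marker, genetic pos, bp) map file; the column count is
    auto-detected and must be uniform across the file.
    """
    rows = _rows(path)
    if not rows:
        return []
    ncol = len(rows[0][1])
    if ncol not in (3, 4):
        raise FormatError(
            f"{path}: line {rows[0][0]}: expected 3 or 4 columns, found {ncol}"
        )
    markers: list[Marker] = []
    chroms = set()
    for lineno, f in rows:
        if len(f) != ncol:
            raise FormatError(
                f"{path}: line {lineno}: expected {ncol} columns, found {len(f)}"
            )
        bp_tok = f[2] if ncol == 3 else f[3]
        try:
            bp = int(bp_tok)
        except ValueError:
            raise FormatError(
                f"{path}: line {lineno}: non-integer bp position {bp_tok!r}"
            ) from None
        if bp < 0:
            raise FormatError(f"{path}: line {lineno}: negative bp position {bp}")
        gpos = None
        if ncol == 4:
            try:
                gpos = float(f[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric genetic position {f[2]!r}"
                ) from None
        chroms.add(f[0])
        markers.append(Marker(name=f[1], chrom=f[0], bp=bp, genetic_pos=gpos))
    if len(chroms) > 1:
        raise FormatError(
            f"{path}: map file spans multiple chromosomes: {sorted(chroms)}"
        )
    return markers


def _parse_binary_pheno(tok: str, missing_codes: Sequence[str]) -> float:
    if tok in missing_codes:
        return math.nan
    if tok == "1":
        return 1.0
    if tok == "2":
        return 2.0
    raise FormatError(f"invalid affection status {tok!r} (expected 1, 2 or missing)")


def read_ped(
    path,
    n_markers: int,
    trait_mode: str = "binary",
    missing_trait_codes: Optional[Sequence[str]] = None,
) -> tuple[list[Individual], np.ndarray, np.ndarray, np.ndarray]:
    """Read a pre-Makeped linkage pedigree file.

    Each row: ped id, individual id, father, mother, sex, affection status or
    trait value, then two allele columns per marker.  Returns the individual
    records plus the allele matrices and phenotype vector (see
    :class:`GenotypePanel` for conventions).
    """
    if trait_mode not in ("binary", "quantitative"):
        raise ValueError(f"unknown trait_mode {trait_mode!r}")
    if missing_trait_codes is None:
        missing_trait_codes = (
            MISSING_BINARY_CODES if trait_mode == "binary" else MISSING_QT_CODES
        )
    individuals: list[Individual] = []
    phenos: list[float] = []
    a1_rows: list[list[str]] = []
    a2_rows: list[list[str]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, f in _rows(path):
        if len(f) < 6:
            raise FormatError(f"{path}: line {lineno}: fewer than 6 leading columns")
        ped_id, indiv_id = f[0], f[1]
        alleles = f[6:]
        if len(alleles) != 2 * n_markers:
            raise FormatError(
                f"{path}: individual {ped_id}/{indiv_id}: "
                f"{len(alleles)} genotype columns, expected {2 * n_markers} "
                f"for {n_markers} markers"
            )
        key = (ped_id, indiv_id)
        if key in seen:
            raise FormatError(
                f"{path}: duplicate individual {ped_id}/{indiv_id} at line {lineno}"
            )
        seen.add(key)
        try:
            sex = int(f[4])
        except ValueError:
            raise FormatError(
                f"{path}: line {lineno}: non-integer sex code {f[4]!r}"
            ) from None
        if trait_mode == "binary":
            try:
                pheno = _parse_binary_pheno(f[5], missing_trait_codes)
            except FormatError as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from None
        else:
            if f[5] in missing_trait_codes:
                pheno = math.nan
            else:
                try:
                    pheno = float(f[5])
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric trait value {f[5]!r}"
                    ) from None
        individuals.append(
            Individual(ped_id=ped_id, indiv_id=indiv_id, father_id=f[2],
                       mother_id=f[3], sex=sex)
        )
        phenos.append(pheno)
        a1_rows.append(alleles[0::2])
        a2_rows.append(alleles[1::2])
    n = len(individuals)
    a1 = np.array(a1_rows, dtype="U8").reshape(n, n_markers) if n else \
        np.empty((0, n_markers), dtype="U8")
    a2 = np.array(a2_rows, dtype="U8").reshape(n, n_markers) if n else \
        np.empty((0, n_markers), dtype="U8")
    return individuals, a1, a2, np.asarray(phenos, dtype=float)


def load_chromosome(
    map_path,
    ped_path,
    trait_mode: str = "binary",
    missing_trait_codes: Optional[Sequence[str]] = None,
) -> GenotypePanel:
    """Load one chromosome's MAP/PED pair into a :class:`GenotypePanel`,
    with markers (and their genotype columns) stably sorted by bp position.
    """
    markers = read_map(map_path)
    individuals, a1, a2, pheno = read_ped(
        ped_path, len(markers), trait_mode, missing_trait_codes
    )
    order = np.argsort([m.bp for m in markers], kind="stable")
    markers = [markers[i] for i in order]
    if a1.size:
        a1 = a1[:, order]
        a2 = a2[:, order]
    return GenotypePanel(
        individuals=individuals,
        markers=markers,
        a1=a1,
        a2=a2,
        phenotype=pheno,
        trait_mode=trait_mode,
    )


def read_gene_file(path) -> list[GeneRecord]:
    """Read a 5-column gene coordinate file: id, name, chr, start bp, stop bp."""
    records: list[GeneRecord] = []
    for lineno, f in _rows(path):
        if len(f) != 5:
            raise FormatError(
                f"{path}: line {lineno}: expected 5 columns, found {len(f)}"
            )
        try:
            start, stop = int(f[3]), int(f[4])
        except ValueError:
            raise FormatError(
                f"{path}: line {lineno}: non-integer gene coordinates"
            ) from None
        if start > stop:
            raise FormatError(
                f"{path}: gene {f[1]} (line {lineno}): start {start} > stop {stop}"
            )
        records.append(GeneRecord(gene_id=f[0], gene_name=f[1], chrom=f[2],
                                  start_bp=start, stop_bp=stop))
    return records


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def fmt_p(p: Optional[float]) -> str:
    """Format a p-value: 2 significant figures, scientific below 1e-3."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    if p == 1:
        return "1"
    if p == 0:
        return "0"
    if p < 1e-3:
        return f"{p:.1E}"
    return f"{p:.2g}"


def _fmt_num(x: Optional[float], nd: int = 3) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.{nd}f}"


def fmt_perm(n_exceed: int, n_perm: int) -> str:
    p = n_exceed / n_perm
    return f"Perm: {n_exceed}/{n_perm} = {p:g}"


CC_HEADER = [
    "Gene/Wind", "Chr", "Start", "End_Pos", "N_SNPs",
    "CaseRV", "CaseNoRV", "ContRV", "ContNoRV",
    "ChiSq", "P-val", "FisherExPval",
]

QT_HEADER = [
    "Gene", "Chr", "Start", "End_pos", "SNPs/rvSNPs",
    "QT+RV", "QT-RV", "QT+RV_mean", "QT-RV_mean",
    "p-val", "BetaCoef", "St.Er", "[lowCI - upCI]", "t-test", "t-test_p-val",
]


def _cc_row(r) -> list[str]:
    t = r.table
    if r.fisher_skipped:
        fisher = f"No < {r.min_cell_threshold}"
    else:
        fisher = fmt_p(r.p_fisher)
    return [
        r.region.name, r.region.chrom, str(r.region.start_bp),
        str(r.region.end_bp), f"({r.n_snps_total}/{r.n_snps_rare})",
        str(t.case_rv), str(t.case_norv), str(t.cont_rv), str(t.cont_norv),
        f"{r.chi2:.2f}", fmt_p(r.p_pearson), fisher,
    ]


def _write_table(path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_cc_summary(results, path, sig_threshold: float) -> None:
    """Write the case-control summary file: only regions whose Pearson p is
    at or below ``sig_threshold`` (the full per-chromosome listing is written
    by :func:`write_cc_chromosome`)."""
    rows = [_cc_row(r) for r in results if r.p_pearson <= sig_threshold]
    _write_table(path, CC_HEADER, rows)


def write_cc_chromosome(results, path) -> None:
    """Write the per-chromosome case-control file: one row per region,
    including a permutation column for permuted regions."""
    header = CC_HEADER + ["Permutations"]
    rows = []
    for r in results:
        perm = fmt_perm(r.perm[0], r.perm[1]) if r.perm is not None else ""
        rows.append(_cc_row(r) + [perm])
    _write_table(path, header, rows)


def write_cc_permutations(results, path) -> None:
    """Write the permutation summary (permuted regions only)."""
    header = ["Gene/Window", "Chr", "Start", "End",
              "Case:(RV/NonRV) Control:(RV/NonRV)", "Pval",
              "Permutation Results"]
    rows = []
    for r in results:
        if r.perm is None:
            continue
        t = r.table
        rows.append([
            r.region.name, r.region.chrom, str(r.region.start_bp),
            str(r.region.end_bp),
            f"case: ({t.case_rv}/{t.case_norv}) cont: ({t.cont_rv}/{t.cont_norv})",
            fmt_p(r.p_pearson), fmt_perm(r.perm[0], r.perm[1]),
        ])
    _write_table(path, header, rows)


def _qt_row(r) -> list[str]:
    g = r.groups
    ci = ""
    if not (math.isnan(r.ci_low) or math.isnan(r.ci_high)):
        ci = f"[{r.ci_low:.3f} - {r.ci_high:.3f}]"
    return [
        r.region.name, r.region.chrom, str(r.region.start_bp),
        str(r.region.end_bp), f"({r.n_snps_total}/{r.n_snps_rare})",
        str(g.n_carrier), str(g.n_noncarrier),
        _fmt_num(g.mean_carrier), _fmt_num(g.mean_noncarrier),
        fmt_p(r.p_reg), _fmt_num(r.beta), _fmt_num(r.se), ci,
        _fmt_num(r.t_stat), fmt_p(r.p_t),
    ]


def write_qt_summary(results, path, sig_threshold: float) -> None:
    """Write the quantitative-trait summary file (regression p at or below
    ``sig_threshold``; degenerate regions use the p = 1 convention and are
    therefore excluded unless the threshold is 1)."""
    rows = [_qt_row(r) for r in results if r.p_reg <= sig_threshold]
    _write_table(path, QT_HEADER, rows)


def write_qt_chromosome(results, path) -> None:
    rows = [_qt_row(r) for r in results]
    _write_table(path, QT_HEADER, rows)


def write_region_snplist(region, markers, mafs, path) -> None:
    """Write the per-significant-region SNP list: every marker in the region
    (common markers included) with its MAF."""
    header = ["Marker", "Chromosome", "Position", "MAF"]
    rows = []
    for idx in region.marker_indices:
        m = markers[idx]
        maf = mafs[idx].maf
        rows.append([m.name, m.chrom, str(m.bp),
                     "" if math.isnan(maf) else f"{maf:.3f}"])
    _write_table(path, header, rows)
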