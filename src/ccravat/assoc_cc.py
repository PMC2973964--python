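"""Case-control collapsing statistics: the carrier-by-status 2x2 table,
uncorrected Pearson chi-squared, Fisher's exact test gated by a minimum-cell
rule, and label-permutation empirical p-values.

No Yates continuity correction is applied anywhere: the collapsing test uses
the plain Pearson statistic on 1 df.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .collapse import CARRIER, MafRecord, collapse_region, select_rare
from .formats import GenotypePanel
from .regions import Region, assign_markers

__all__ = [
    "CC2x2",
    "CCResult",
    "CCOptions",
    "carrier_table",
    "pearson_chi2",
    "fisher_exact",
    "min_cell_rule",
    "permute_empirical_p",
    "analyze_region_cc",
    "region_rng",
]


@dataclass(frozen=True)
class CC2x2:
    """Carrier / non-carrier counts among cases and controls."""

    case_rv: int
    case_norv: int
    cont_rv: int
    cont_norv: int

    def cells(self) -> tuple[int, int, int, int]:
        return (self.case_rv, self.case_norv, self.cont_rv, self.cont_norv)


@dataclass
class CCResult:
    region: Region
    table: CC2x2
    n_snps_total: int
    n_snps_rare: int
    chi2: float
    p_pearson: float
    p_fisher: Optional[float]  # None when skipped by the min-cell rule
    fisher_skipped: bool
    min_cell_threshold: int
    perm: Optional[tuple[int, int, float]] = None  # (n_exceed, n_perm, p_emp)


@dataclass
class CCOptions:
    maf_cutoff: float = 0.05
    min_cell: int = 30
    n_perm: int = 0
    perm_trigger: float = 0.05
    seed: int = 1
    strict_missing: bool = False


def carrier_table(carrier: np.ndarray, panel: GenotypePanel) -> CC2x2:
    """Cross-tabulate carrier status against case/control labels, dropping
    individuals with missing carrier status or phenotype."""
    valid = carrier >= 0
    is_carrier = carrier == CARRIER
    case = panel.is_case()
    cont = panel.is_control()
    return CC2x2(
        case_rv=int(np.sum(valid & case & is_carrier)),
        case_norv=int(np.sum(valid & case & ~is_carrier)),
        cont_rv=int(np.sum(valid & cont & is_carrier)),
        cont_norv=int(np.sum(valid & cont & ~is_carrier)),
    )


def pearson_chi2(table: CC2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-squared on 1 df.

    Computed via the 2x2 closed form N(ad-bc)^2 / (r1 r2 c1 c2); any zero
    row or column margin gives chi2 = 0, p = 1 (the convention used for
    regions with no carriers at all).
    """
    a, b, c, d = (float(x) for x in table.cells())
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def fisher_exact(table: CC2x2) -> float:
    """Two-sided Fisher exact p: the total hypergeometric probability of all
    tables with the observed margins no more probable than the observed one.
    Exact at margins of several thousand."""
    a, b, c, d = table.cells()
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def min_cell_rule(table: CC2x2, threshold: int) -> bool:
    """True when Fisher's exact test should run: some observed cell count is
    below ``threshold``.  When every cell is at or above it the asymptotic
    chi-squared is trusted and Fisher is skipped ("No < T")."""
    if threshold < 0:
        raise ValueError("min-cell threshold must be >= 0")
    return min(table.cells()) < threshold


def region_rng(seed: int, region_name: str) -> np.random.Generator:
    """Per-region random stream derived from (seed, region name) so that
    permutation results do not depend on region processing order."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(region_name.encode())])
    )


def permute_empirical_p(
    carrier: np.ndarray,
    phenotype: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """Empirical p by uniform shuffling of case/control labels among
    individuals with observed carrier status and phenotype (margins fixed).

    Exceedance counts replicates whose chi-squared is >= the observed one
    (ties count); p_emp = n_exceed / n_perm with no pseudocount.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    valid = (carrier >= 0) & ~np.isnan(phenotype)
    is_carrier = (carrier == CARRIER)[valid]
    is_case = (phenotype == 2.0)[valid]
    n_case = int(is_case.sum())
    obs = pearson_chi2(_table_from_counts(
        int(np.sum(is_carrier & is_case)), n_case,
        int(is_carrier.sum()), int(valid.sum())))[0]
    carr = is_carrier.astype(np.int8)
    a_perm = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        rng.shuffle(carr)
        a_perm[i] = int(carr[:n_case].sum()) if n_case else 0
    # margins are fixed: chi2 is a function of the case-carrier cell alone
    stats_perm = np.array([
        pearson_chi2(_table_from_counts(int(a), n_case,
                                        int(carr.sum()), int(valid.sum())))[0]
        for a in a_perm
    ])
    n_exceed = int(np.sum(stats_perm >= obs - 1e-12))
    return n_exceed, n_exceed / n_perm


def _table_from_counts(case_rv: int, n_case: int, n_rv: int, n_total: int) -> CC2x2:
    return CC2x2(
        case_rv=case_rv,
        case_norv=n_case - case_rv,
        cont_rv=n_rv - case_rv,
        cont_norv=(n_total - n_case) - (n_rv - case_rv),
    )


def analyze_region_cc(
    panel: GenotypePanel,
    region: Region,
    mafs: Sequence[MafRecord],
    options: Optional[CCOptions] = None,
) -> CCResult:
    """Full per-region case-control analysis: collapse rare variants to
    carrier status, build the 2x2 table, test it, and (when the asymptotic p
    reaches the permutation trigger and permutations are requested) attach an
    empirical p."""
    if options is None:
        options = CCOptions()
    if not region.marker_indices:
        region.marker_indices = assign_markers(panel.markers, region)
    region_mafs = [mafs[j] for j in region.marker_indices]
    region.rare_indices = select_rare(region_mafs, options.maf_cutoff)
    carrier = collapse_region(panel, region, mafs,
                              strict_missing=options.strict_missing)
    table = carrier_table(carrier, panel)
    chi2, p_pearson = pearson_chi2(table)
    skipped = not min_cell_rule(table, options.min_cell)
    p_fisher = None if skipped else fisher_exact(table)
    perm = None
    if options.n_perm > 0 and p_pearson <= options.perm_trigger:
        rng = region_rng(options.seed, region.name)
        n_exceed, p_emp = permute_empirical_p(
            carrier, panel.phenotype, options.n_perm, rng
        )
        perm = (n_exceed, options.n_perm, p_emp)
    return CCResult(
        region=region,
        table=table,
        n_snps_total=len(region.marker_indices),
        n_snps_rare=len(region.rare_indices),
        chi2=chi2,
        p_pearson=p_pearson,
        p_fisher=p_fisher,
        fisher_skipped=skipped,
        min_cell_threshold=options.min_cell,
        perm=perm,
    )
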