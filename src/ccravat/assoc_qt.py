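"""Quantitative-trait collapsing statistics: trait means of carriers versus
non-carriers compared by ordinary least squares on the 0/1 carrier indicator
and (optionally) a two-sample Student's t-test.

For a binary predictor the OLS slope is exactly the carrier minus
non-carrier mean difference and the regression t equals the pooled-variance
two-sample t; both identities are exercised by the test suite.  The slope is
reported with the carrier = 1 coding (beta = carrier mean - non-carrier
mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .collapse import CARRIER, MafRecord, collapse_region, select_rare
from .formats import GenotypePanel
from .regions import Region, assign_markers

__all__ = [
    "QTGroups",
    "QTResult",
    "QTOptions",
    "split_groups",
    "regress_on_carrier",
    "two_sample_t",
    "analyze_region_qt",
]

#: 95% CI multiplier (normal quantile; deterministic across df)
CI_Z = 1.96


@dataclass(frozen=True)
class QTGroups:
    n_carrier: int
    n_noncarrier: int
    mean_carrier: float
    mean_noncarrier: float
    var_carrier: float  # sample variance, ddof=1; NaN for groups of size < 2
    var_noncarrier: float


@dataclass
class QTResult:
    region: Region
    groups: QTGroups
    n_snps_total: int
    n_snps_rare: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_reg: float
    t_stat: float
    p_t: float
    undefined: bool  # degenerate design (empty group / zero residual variance)


@dataclass
class QTOptions:
    maf_cutoff: float = 0.05
    ttest: bool = True
    welch: bool = False
    strict_missing: bool = False


def _group_stats(x: np.ndarray) -> tuple[int, float, float]:
    n = len(x)
    if n == 0:
        return 0, math.nan, math.nan
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1)) if n >= 2 else math.nan
    return n, mean, var


def split_groups(carrier: np.ndarray, trait: np.ndarray) -> QTGroups:
    """Split trait values by carrier status, jointly excluding individuals
    with missing carrier status or missing trait."""
    valid = (carrier >= 0) & ~np.isnan(trait)
    tc = trait[valid & (carrier == CARRIER)]
    tn = trait[valid & (carrier != CARRIER)]
    n1, m1, v1 = _group_stats(tc)
    n0, m0, v0 = _group_stats(tn)
    return QTGroups(n_carrier=n1, n_noncarrier=n0, mean_carrier=m1,
                    mean_noncarrier=m0, var_carrier=v1, var_noncarrier=v0)


def regress_on_carrier(
    carrier: np.ndarray, trait: np.ndarray
) -> tuple[float, float, float, float, float, bool]:
    """OLS of trait on the 0/1 carrier indicator.

    Returns (beta, se, ci_low, ci_high, p, undefined).  beta equals
    mean(carrier) - mean(non-carrier); se comes from the residual variance on
    n - 2 df; the 95% CI is beta +/- 1.96 se; p is the two-sided t
    probability.  A degenerate design (an empty group, fewer than 2 per
    group, or zero residual variance) is flagged undefined with the p = 1
    convention.
    """
    valid = (carrier >= 0) & ~np.isnan(trait)
    is_carr = (carrier == CARRIER) & valid
    is_non = (carrier != CARRIER) & valid
    tc = trait[is_carr]
    tn = trait[is_non]
    n1, n0 = len(tc), len(tn)
    if n1 == 0 or n0 == 0:
        return math.nan, math.nan, math.nan, math.nan, 1.0, True
    beta = float(np.mean(tc) - np.mean(tn))
    if n1 < 2 or n0 < 2:
        return beta, math.nan, math.nan, math.nan, 1.0, True
    sse = float(np.sum((tc - tc.mean()) ** 2) + np.sum((tn - tn.mean()) ** 2))
    df = n1 + n0 - 2
    sigma2 = sse / df
    if sigma2 <= 0:
        return beta, math.nan, math.nan, math.nan, 1.0, True
    se = math.sqrt(sigma2 * (1.0 / n1 + 1.0 / n0))
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), df=df))
    return beta, se, beta - CI_Z * se, beta + CI_Z * se, p, False


def two_sample_t(groups: QTGroups, welch: bool = False) -> tuple[float, float]:
    """Two-sample t comparing carrier and non-carrier trait means.

    Pooled-variance Student's t on n1 + n2 - 2 df by default; Welch's
    unequal-variance form behind the flag.  Two-sided p.  Degenerate groups
    (size < 2 or zero pooled variance) give (nan, 1).
    """
    n1, n0 = groups.n_carrier, groups.n_noncarrier
    if n1 < 2 or n0 < 2:
        return math.nan, 1.0
    v1, v0 = groups.var_carrier, groups.var_noncarrier
    diff = groups.mean_carrier - groups.mean_noncarrier
    if welch:
        se2 = v1 / n1 + v0 / n0
        if se2 <= 0:
            return (0.0, 1.0) if diff == 0 else (math.nan, 1.0)
        t = diff / math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
    else:
        df = n1 + n0 - 2
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
        if sp2 <= 0:
            return (0.0, 1.0) if diff == 0 else (math.nan, 1.0)
        t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    return float(t), float(2 * stats.t.sf(abs(t), df=df))


def analyze_region_qt(
    panel: GenotypePanel,
    region: Region,
    mafs: Sequence[MafRecord],
    options: Optional[QTOptions] = None,
) -> QTResult:
    """Full per-region quantitative-trait analysis.  Degenerate regions
    (e.g. zero carriers) are reported with the undefined flag rather than
    dropped, so genome-wide bookkeeping stays intact."""
    if options is None:
        options = QTOptions()
    if not region.marker_indices:
        region.marker_indices = assign_markers(panel.markers, region)
    region_mafs = [mafs[j] for j in region.marker_indices]
    region.rare_indices = select_rare(region_mafs, options.maf_cutoff)
    carrier = collapse_region(panel, region, mafs,
                              strict_missing=options.strict_missing)
    groups = split_groups(carrier, panel.phenotype)
    beta, se, ci_lo, ci_hi, p_reg, undefined = regress_on_carrier(
        carrier, panel.phenotype
    )
    if options.ttest and not undefined:
        t_stat, p_t = two_sample_t(groups, welch=options.welch)
    else:
        t_stat, p_t = math.nan, (1.0 if undefined else math.nan)
    return QTResult(
        region=region,
        groups=groups,
        n_snps_total=len(region.marker_indices),
        n_snps_rare=len(region.rare_indices),
        beta=beta,
        se=se,
        ci_low=ci_lo,
        ci_high=ci_hi,
        p_reg=p_reg,
        t_stat=t_stat,
        p_t=p_t,
        undefined=undefined,
    )
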