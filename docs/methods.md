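# Methods

## The collapsing (super-locus) model

Both tools summarise a region's low-frequency/rare variant content by one
binary per-individual indicator. Let the region contain markers
*j = 1…M*, with minor-allele frequency (MAF) *p̂ⱼ* estimated from the data,
and let the *rare set* be the markers with 0 < *p̂ⱼ* ≤ *c* (cutoff *c*,
default 0.05; monomorphic markers have no minor allele and are excluded).
Individual *i* is a **carrier** if at least one minor allele is observed at
at least one rare marker. Carrier status is presence/absence, not an allele
count: a homozygous-minor genotype counts once, and no frequency or quality
weighting is applied.

MAFs are computed over all phenotyped individuals jointly (cases and
controls together), so cases and controls share one rare set and the 2×2
construction stays symmetric; `--maf-in-controls` switches to a control-only
reference group. A 50/50 allele-frequency tie is broken toward the
lexicographically smaller allele token, so results are order-independent.

**Case-control test.** The carrier × case/control table
(a, b; c, d) with margins r₁, r₂ (rows) and c₁, c₂ (columns) is tested with
the uncorrected Pearson statistic χ² = N(ad − bc)²/(r₁r₂c₁c₂) on 1 df.
No Yates continuity correction is used — the reference tables this package
reproduces verify the uncorrected form. A zero row or column margin (e.g. a
region with no rare markers, hence no carriers at all) is reported as
χ² = 0, p = 1 rather than dropped. Because the asymptotic χ² is unreliable
at small counts, a two-sided Fisher's exact test (sum of hypergeometric
probabilities of all tables with the observed margins no more probable than
the observed table; computed by `scipy.stats.fisher_exact`, exact at margins
of several thousand) runs whenever the *observed* minimum cell falls below
`--min-cell` (default 30); otherwise the output carries the literal
sentinel `No < T`.

**Permutation.** For regions whose asymptotic p reaches `--perm-trigger`
(default 0.05) and when `--perm N` is set, case/control labels are shuffled
uniformly among individuals with observed carrier status and phenotype
(margins preserved), and p_emp = (#replicates with χ² ≥ observed)/N with no
pseudocount, ties counting as exceedances (conservative). Each region draws
its replicates from a stream seeded by (global seed, CRC32 of the region
name), so empirical p-values do not depend on the order regions are
processed.

**Quantitative-trait test.** Trait values are regressed on the 0/1 carrier
indicator by OLS. For this design the closed form is exact: β = carrier
mean − non-carrier mean, SE² = σ̂²(1/n₁ + 1/n₀) with σ̂² the pooled
within-group residual variance on n − 2 df, and the regression t equals the
pooled two-sample t identically (asserted to machine precision in the
suite). The 95% CI uses the normal multiplier 1.96 rather than the t
quantile — deterministic across df and indistinguishable at the reported
3-decimal precision for the sample sizes this tool targets. The optional
t-test (`--ttest`, on by default) is pooled-variance two-sided; `--welch`
switches to the unequal-variance form. β is reported with carrier = 1
coding, i.e. a positive β means carriers have the higher trait mean; tools
that code the indicator the other way will print the opposite sign on the
same data.

**Degenerate regions** (no carriers, no non-carriers, a group smaller than
2, or zero residual variance) are reported with an explicit undefined flag
and the p = 1 convention, never silently dropped, so every region defined on
a chromosome yields exactly one row in the per-chromosome file.

## Regions

Coordinates are 1-based base pairs and interval membership is inclusive at
both ends (the linkage/annotation convention; gene start/stop annotations
are inclusive spans).

* **Gene mode**: one region per gene record on the current chromosome,
  spanning [max(0, start − flank_up), stop + flank_down]. Overlapping genes
  give overlapping regions analysed independently.
* **Window mode**: windows [k·step, k·step + window] anchored at bp 0 (so
  window identities are reproducible across datasets), emitted from the
  first window whose right edge reaches the smallest marker position up to
  the first window covering the largest. Empty windows are kept and appear
  with `(0/0)` counts. The default step is window/2; a step larger than the
  window is allowed (gapped tiling) with a warning. With inclusive bounds, a
  marker sitting exactly on a shared boundary of a step = window tiling
  belongs to both adjacent windows; at typical marker densities this affects
  a negligible fraction of markers and keeps the single membership rule
  `start ≤ bp ≤ end` everywhere.

Markers are sorted by position on load (stably, with their genotype columns)
and assigned to regions by binary search.

## Missing data

* A genotype is missing iff either allele token is `0`; a half-called
  genotype (`0 A`) is treated as fully missing, since one allele cannot
  establish diploid carrier status.
* Binary phenotypes accept `0` and `-9` as missing; quantitative traits only
  `-9` by default (0 is a legal trait value). Both are configurable.
* Partially missing individuals: an observed minor allele always makes a
  carrier; an individual whose observed rare genotypes are all
  homozygous-major is counted a non-carrier even if some rare genotypes are
  missing (the optimistic call — excluding them would discard most of a
  GWAS panel). `--strict-missing` instead excludes any individual with a
  missing rare genotype and no observed minor allele. Individuals with no
  observed rare genotype, or no phenotype, are excluded from both margins.
* Markers with zero called genotypes are excluded with a warning.

## Output conventions

χ² is printed to 2 decimals; p-values to 2 significant figures, scientific
below 10⁻³; means/β/SE/CI bounds to 3 decimals. The summary files contain
only rows with p ≤ `--sig` (default 10⁻³ — there is no canonical
genome-wide threshold for collapsed rare-variant tests, so the default
simply keeps summary files small; the per-chromosome files always contain
every region). The Manhattan plot uses the region midpoint in bp, with
chromosomes concatenated in input order, y = −log₁₀ p (p = 1 at 0; p = 0
clamped to the smallest positive double with a warning), and points with
p ≤ `--pout` in red. Histogram binning is Freedman–Diaconis on the pooled
sample. Plot data series are computed by pure functions and tested
separately; the PNG rendering is smoke-tested only.

## Synthetic data generator

`rv-simulate` / the `synthgen` module draws genotypes under Hardy–Weinberg
proportions at specified MAFs (default: uniform on 0.005–0.05, the rare band
the collapsing test targets), independently across markers — no linkage
disequilibrium, population structure, relatedness or genotyping-error model.
Binary phenotypes follow a logistic model on the carrier indicator,
logit P(case) = logit(case_fraction) + log(OR)·carrier (OR = 1 gives labels
independent of genotype); quantitative traits are δ·carrier + N(0, σ²).
The generator's carrier definition is implemented independently of the
analysis-side collapsing code, so recovery tests cross two code paths.
Everything is deterministic under a fixed seed.

Passing tests on these panels demonstrates correctness of the collapsing
statistics and calibration under HWE with unrelated individuals; it does not
probe robustness to LD between rare variants, differential missingness, or
genotyping error — on real GWAS-chip data, rare-variant cluster plots should
be inspected before trusting a signal.

## Problem sizes used in the checks

The simulation-based checks run at desk scale: type-I error of the
case-control test over 1,000 null panels of 2,000 individuals × 10 rare
markers (MAF 0.005–0.05) against the 95% binomial envelope at α = 0.05;
power at carrier OR = 4 over 300 panels; quantitative-trait effect recovery
(δ = 0.5, σ = 1) over 200 panels of 1,000 individuals with the null
rejection rate over 500; and byte-level determinism of two repeated
end-to-end runs (300 individuals, 25 markers, 5 genes, 20 permutations).

## Known limitations

* Binary carrier burden only: no allele-count scores, frequency weights, or
  covariate adjustment.
* Asymptotic p-values for the QT regression; no QT permutation test.
* One phenotype per run; families/relatedness are not modelled.
* Text PED/MAP only (no binary PLINK or VCF input).
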