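# Methods

This note records the statistical model behind each estimator, the
conventions and defaults the package commits to, what the synthetic-data
generator does and does not emulate, and the numerical choices a maintainer
would otherwise have to reverse-engineer.

## Data model and the ΔCt transform

A `CpTable` is a genes × observations matrix of raw crossing-point values
(PCR cycles, typically 10–40; one cycle ≈ one log2 expression unit at 100%
amplification efficiency).  Observations carry a condition class, a
biological replicate and a technical replicate; `(class, bio, tech)` must be
jointly unique.  Technical replicates are collapsed by their mean before any
stability analysis (median or no collapsing are available) — the collapsing
rule is a package convention, since replicate handling is rarely reported.

Relative quantities are q = (1+E)<sup>−ΔCt</sup> with ΔCt = Cp − min(Cp)
per gene within the analysis group, so each gene's best-expressed sample has
q = 1 and q ∈ (0, 1].  The default E = 1 gives the classical 2<sup>−ΔCt</sup>;
per-gene efficiencies (fractions in (0.5, 1.5]) are accepted everywhere the
transform is used.  Missing Cp values propagate; statistics use
pairwise-complete observations, and a gene is dropped from a group (with a
warning) when fewer than two complete observations remain, since no
dispersion statistic is defined for it.

Analysis groups default to *treated ∪ control* for each single treatment,
all tissue classes plus the control for the Tissue group, and everything for
Total.  Both conventions (with or without control) are reachable through
explicit `AnalysisGroup` definitions, because published stability studies
are split on which they use.

## geNorm

Pairwise variation V(j,k) is the n−1 standard deviation of
log2(q<sub>j</sub>/q<sub>k</sub>) across samples; M<sub>j</sub> is the mean
V against all other candidates.  Log base 2 is used throughout.  Iterative
ranking removes the highest-M gene and recomputes M on the remainder until
two genes are left; they are reported as joint rank 1–2 (the measure cannot
order the last two) in input order.  An exact tie in the maximal M excludes
the gene *later* in input order — deterministic and stable under
`mergesort`-style sorting.

NF<sub>n</sub> is the per-sample geometric mean of the top-n genes'
quantities; V<sub>n/n+1</sub> = SD(log2(NF<sub>n</sub>/NF<sub>n+1</sub>)),
reported for n = 2 … k−1.  The optimal number of reference genes is the
smallest n with V below the cutoff (default 0.15, configurable — 0.15 is a
guideline, not a hard threshold), or k−1 when nothing passes.

Both M and V are invariant to per-gene scaling and to per-sample (loading)
scaling of all genes; the test suite asserts this numerically.

## NormFinder

Log expression is x = −Cp (any per-gene additive constant cancels).  The
two-way model x<sub>ij</sub> = μ<sub>i</sub> + s<sub>j</sub> +
ε<sub>ij</sub>, Var(ε<sub>ij</sub>) = σ²<sub>i</sub>, is fitted by double
centering; the naive residual variances s²<sub>i</sub> satisfy
E[s²<sub>i</sub>] = σ²<sub>i</sub>(1 − 2/k) + σ̄²/k (each gene's residuals
absorb a share of the others' noise through the sample means), so the
package inverts this by method of moments:
σ̄̂² = k/(k−1) · mean(s²), σ̂²<sub>i</sub> = (s²<sub>i</sub> − σ̄̂²/k) ·
k/(k−2), truncated at zero (standard practice; the truncation slightly
inflates variances near zero and is exercised by a dedicated test).  The
correction needs k ≥ 3 genes.  The identity was derived under the model and
is verified by a simulation-unbiasedness test rather than against any
external binary.

Grouped mode estimates σ̂²<sub>ig</sub> per subgroup, double-centers the
gene × subgroup mean matrix into raw deviations d̂<sub>ig</sub> (which sum
to zero over genes within each subgroup), and shrinks them:
d̃ = d̂ · γ̂²/(γ̂² + σ̂²<sub>ig</sub>/n<sub>g</sub>) with γ̂² the
across-gene variance of d̂ minus its mean sampling contribution, truncated
at zero.  The stability value combines the two sources additively,
ρ<sub>i</sub> = mean<sub>g</sub>(|d̃<sub>ig</sub>| +
√(σ̂²<sub>ig</sub>/n<sub>g</sub>)); the combination rule lives in one place
so a quadrature alternative is a one-line change.  Subgroups with fewer than
two samples are excluded with a warning; with a single usable subgroup the
intergroup term vanishes and the ranking reduces to the ungrouped one.
Default subgrouping is {control, treated} for single-treatment groups and
by condition class for Tissue/Total, both overridable.

NormFinder is not run on samples with missing values: incomplete columns
are dropped with a warning (the two-way fit needs a complete matrix).

## BestKeeper

Computed on raw Cp, deliberately *not* loading-invariant (the test suite
asserts the contrast with the other two methods).  The default dispersion is
the mean absolute deviation from the arithmetic mean — the original tool's
"SD [± Cp]" — with the n−1 sample SD as a first-class alternative
(`sd_convention="sd"`); for Gaussian noise MAD ≈ 0.798·SD.  CV% =
100·SD/mean Cp.  Dispersion above one cycle flags a gene as inconsistent;
the flag never removes the gene from the report.  Ranking is ascending CV,
ties broken by ascending SD, then input order.  The BestKeeper index is the
per-sample geometric mean Cp over member genes, defined only on samples
complete for all members; per-gene Pearson r and two-sided p against the
index require at least three such samples.

## 2^−ΔΔCt validation

The reference Ct of a multi-gene normalizer is the arithmetic mean of the
member genes' Cp — equivalently the geometric mean of their quantities, the
same convention as NF<sub>n</sub>.  ΔΔCt subtracts the mean control ΔCt, so
control fold changes have geometric mean 1 by construction.  Efficiency
correction (Pfaffl-style, per-gene E) is off by default, matching the
common E = 100% assumption of the Livak method.  Comparisons between
normalizer choices use the equal-variance Student's t-test by default
(Welch via a flag) on treated-replicate fold changes, reported with
significance tiers *** p<0.001, * p<0.05, else N.S.; no multiple-testing
correction is applied across comparisons (stated in the report).

## Standard curves

Cp is regressed on x = −log10(dilution factor) (log10 relative template);
either sign convention is accepted since only |slope| enters
E = 10<sup>−1/slope</sup> − 1.  R² is the squared Pearson correlation of
the simple regression.  Fits with E outside [90%, 110%] log a warning;
a slope of the wrong sign marks the fit invalid rather than raising.

## Synthetic generator

`generate()` draws Cp = baseline − loading + shift + bio-noise + tech-noise,
with per-biological-sample loading ~ N(0, loading_sd) shared by all genes,
per-gene biological noise ~ N(0, σ<sub>i</sub>) shared by a replicate's
technical wells, condition-class shifts δ<sub>ig</sub> in cycles (positive =
higher Cp = down-regulation), and technical noise ~ N(0, tech_sd).  Output
is bit-identical for a fixed (design, seed).

The default design emulates a complete survey: 12 genes with baselines
spanning 17–28 cycles, noise SDs 0.15–0.6 log2 units, control + 8
treatments + 2 tissue classes at 3 biological × 3 technical replicates
(1188 Cp values), loading SD 0.5 and technical SD 0.15 cycles — values a
qPCR practitioner would call typical for plant stress experiments.  Shifts
are assigned so classical housekeeping genes (GAPDH, TUB6) are
treatment-responsive and SAND/ACT2/UBC9 are quiet, giving the generator a
known, non-trivial truth.  Ground-truth instability is defined as
√(σ²<sub>i</sub> + var<sub>g</sub>(δ<sub>ig</sub>)) — the generator's own
composite of within- and between-group components.

The `well_separated_design` benchmark (k = 8 genes, σ evenly spaced
0.1–1.5, n = 30 samples, one class) uses a common baseline for all genes so
BestKeeper's CV ranking is not confounded by baseline differences, and a
small loading SD (0.2) because BestKeeper is not loading-invariant;
`recovery_report` measures per-method Spearman correlation between
estimated and true instability plus exact top-2/bottom-2 recovery.

What the generator does **not** emulate: plate/batch effects, inter-run
calibration drift, fluorescence-curve artefacts, Cq-calling error that
correlates with expression level, non-Gaussian outliers, and
heteroscedastic technical noise at high Cp.  Passing recovery tests
therefore show the estimators work under the assumed additive log-scale
model, not that they are robust to instrument-level artefacts.

## Problem sizes in tests

Monte-Carlo tests use panel/sample sizes at which their claims are
statistically decidable: the exact-order M-recovery check runs k = 4 genes
(σ 0.1–1.2, n = 30, 50 seeds) — a prior power analysis shows exact-order
matching at ≥ 90% is unattainable for larger panels at n = 30; the variance
unbiasedness check uses 3000 seeds so the Monte-Carlo SE of the smallest
variance sits well below its 10% band; recovery benchmarks use 10–30 seeds.

## Known limitations

* NormFinder drops incomplete samples rather than fitting with missing data.
* The geNorm final pair is unordered by construction; consensus ranking
  treats both as rank 1.
* BestKeeper's index correlations are descriptive; no regression-based
  "InterGene relations" or sample-integrity z-scores.
* No inter-run calibration, absolute quantification, or plotting; reports
  are delimited text and JSON.
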