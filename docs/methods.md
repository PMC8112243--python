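# Methods

This note documents the models, parameter choices, and numerical decisions
behind `hervlink`, and states what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and annotation

Internal coordinates are 0-based half-open everywhere; GTF I/O converts at
the boundary (GTF is 1-based closed), BED is read as written. Strand is
stored but ignored by all distance computations. HERV loci carry a
`FAMILY_cytoband`-style identifier; the family is the substring before the
first underscore. Coding-potential and enhancer flags are annotation inputs
consumed as given (BED columns 7–8 as 0/1), never computed.

## EM reassignment

Fragments ambiguous within a HERV family group are modelled as draws from a
mixture over candidate loci. The exact read-level generative model used by
locus-resolution TE quantifiers is not fully specified by its published
description, so the fragment likelihood here is an explicit, documented
choice: w(f, ℓ) = exp(λ·(score(f, ℓ) − max_score(f))) with λ = 0.1, so only
score differences within a fragment matter and λ sets how sharply score
gaps translate into odds (λ = 0.1 means a 10-point deficit costs a factor
e). The locus proportions get a symmetric Dirichlet prior whose *total*
pseudo-count is `theta_prior` (default 200,000), split uniformly across
loci — this reproduces the strong shrinkage toward uniform proportions that
the flag's magnitude implies while remaining well defined for any locus
count. Bit-parity with any external tool is a non-goal.

E-step: r(f, ℓ) ∝ π_ℓ · w(f, ℓ) over f's candidates. M-step:
π_ℓ ∝ Σ_f r(f, ℓ) + θ/L. Initialisation is uniform π (deterministic,
consistent with the symmetric prior). Iteration stops when the relative
change of the penalised log-likelihood falls below 1e-6 or at 200
iterations; monotonicity of the penalised log-likelihood is asserted every
sweep. Hard assignment (default, matching the "single locus" reporting
convention) sends each fragment to its argmax-responsibility locus, ties
broken by lexicographically smallest locus id; fractional assignment is
available. Both conserve the fragment total exactly.

## Filtering and normalisation

Size factors are median-of-ratios: factor_j = median_i counts[i,j]/geomean_i
over features positive in every sample. When no such feature exists (common
in sparse HERV matrices) the geometric mean falls back to positive entries
only; disabling the fallback makes that situation a hard error. Factors are
not rescaled afterwards. Size factors are computed on the pre-filter
matrix.

The Jaccard filter scans 100 candidate thresholds, log-spaced in [1, 200]
(count data spans decades; a linear grid is selectable), binarises
normalised counts at each s, and scores s by the mean over conditions of
the mean pairwise Jaccard index across that condition's replicates, with
the Jaccard of two all-zero vectors defined as 1. s* is the argmax, ties to
the smallest s; features whose maximum normalised count exceeds s* are
kept. This is a transparent grid-argmax variant of data-based filtering,
not a numerical clone of any particular package's smoothed estimator.

One practical caveat discovered on sparse matrices: when most features sit
near the detection floor, large thresholds empty the presence vectors,
which then agree trivially, and the argmax drifts to the top of the grid,
discarding nearly everything. The pipeline therefore filters the HERV
feature class with a plain presence rule (max normalised count > s_min) by
default and reserves the Jaccard scan for genes; both paths are selectable
per class.

## Differential expression

Per feature, on size-factor-normalised counts y: group means m_case,
m_ctrl; a method-of-moments dispersion α̂ = (v − m)/m² per condition,
averaged and floored at 1e-8; log₂FC = log₂((m_case + c)/(m_ctrl + c)) with
pseudo-mean c = 0.5 so all-zero groups stay finite; Wald statistic
z = log₂FC/se with se² = Σ_g (m_g + c + α̂(m_g + c)²)/(n_g (m_g + c)² ln²2)
by the delta method; two-sided normal p; BH adjustment. A feature is
flagged DE when q < α (default 0.05) **and** |log₂FC| ≥ 1; the fold-change
threshold is applied post hoc to the flag, not built into the statistic,
and summaries report both the thresholded and q-only counts. The
absolute-value reading of the fold-change rule is used (down-regulated
features can be DE). Dispersion-trend shrinkage and fold-change moderation
are deliberately not implemented: the downstream integration logic consumes
only (log₂FC, q, flag), and numerical parity with heavier DE machinery on
real data is out of scope. Under a simulated global null (n = 50/50, 2,000
features, α_disp = 0.1) the test's p-values are uniform to within binomial
error at the 0.01 and 0.05 quantiles, and on planted data (|log₂FC| = 1.5,
μ ≥ 100) it reaches ≥ 0.9 sensitivity at ≤ 0.10 realised FDR — both are
asserted in the test suite at exactly those sizes.

## Proximity and the distance null

The nearest-gene search first intersects the HERV with the gene index: any
overlap means distance 0, classified exonic if any overlapped gene's exon
touches the HERV, else intronic, with *all* overlapped elements reported
(a HERV can hit an lncRNA exon and a protein-coding intron at once).
Otherwise the window grows from ±500 bp in 500 bp steps (the growth step is
a configurable choice) to an inclusive 10 kb limit; the first non-empty
window contributes the gene with the smallest unstranded gap between
half-open intervals, ties by smallest start then gene id. Records beyond
the limit are `none_within_limit`.

The DE-vs-non-DE distance comparison is a two-sided Mann–Whitney U with
normal approximation and tie correction. The procedure it reimplements is
labelled a signed-rank test in its source description, but the comparison
described is unpaired (two groups of loci, no pairing key), so the
two-sample rank-sum is the defensible reading; `signed_rank_as_printed` is
accepted as an alias and computes the same thing. Loci with no gene inside
the limit are excluded by default or censored at limit + 1 via a flag —
the choice is reported with the result. For the test, the gene universe
defaults to protein-coding only (matching how such nulls are typically
built), while reporting uses all biotypes; both are flags.

## Cross-dataset statistics

The overlap permutation test redraws |DE₁| ids from universe 1 and |DE₂|
from universe 2, uniformly without replacement, 200,000 times, and records
the intersection size. The empirical p uses the add-one rule
(b + 1)/(n + 1), so zero exceedances at 200,000 permutations give exactly
1/200,001 ≈ 5e-6, flagged as an upper bound. The expressed universes may be
nested or overlapping arbitrarily; for nested universes of outer size N the
null mean is |DE₁|·|DE₂|/N, which the tests verify at Monte-Carlo
precision. Fisher's exact test of the dataset-by-DE 2×2 table and Pearson
correlations of per-feature fold changes (all features, or the DE union)
complete the module.

## Associations and enrichment

Expression is transformed to log₂(normalised + 1) (or log₂(CPM + 1)). The
condition model is per-feature OLS on a case indicator; its slope (the
case–control difference on the log scale) is the feature's importance
score. Pair associations are per-pair OLS of gene on HERV with BH across
the tested pair family only (the ≤ 10 kb proximity pairs), plus Spearman ρ
on the same values; significance defaults to q < 0.05. The published
procedure these associations mirror alludes to models that "account for"
other features' expression without giving a formula; absent a specifiable
multivariable model, the univariate fit is the documented default. The
regressions are closed-form simple OLS, vectorised across features, and
cross-checked against a general linear-model fit in the tests.

Set enrichment compares member scores against all other scored features
with a two-sided Mann–Whitney U (Kolmogorov–Smirnov selectable), BH across
tested sets, significance at q < 0.1, and skips sets with fewer than 5
scored members. Scores are signed, so direction (median member score vs
background median) is meaningful. Overrepresentation of DE features per
set is a one-sided Fisher exact test against the expressed universe.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the pipeline assumes:
two case/control datasets (default sizes 25/23 and 99/18) over one feature
universe; NB counts with variance μ + αμ² (α = 0.1, constant across
features — no dispersion trend); lognormal baseline means (log-mean 4.0,
log-sd 1.2) with HERV baselines scaled down 30-fold to mimic the large
expression gap between genes and HERV loci; per-sample size factors uniform
in [0.7, 1.4]; 5% planted DE per feature class, 95% upregulated, |log₂FC| ~
N(1.5, 0.25) truncated at 0.25; dataset 2 reusing 20% of dataset 1's DE
features with identical fold changes and drawing the rest fresh; DE HERVs
placed within 10 kb of a DE gene with probability 0.8 (uniformly
otherwise); family labels from a fixed catalogue; coding/enhancer flags
Bernoulli(0.10); gene sets of 20–60 members with 5 planted sets drawing
≥ 75% of members from DE-up genes; and fragment tables whose candidates are
within-family groups (size 3) where the true locus scores strictly best
with probability 0.7. Every output is a pure function of the config; each
stage draws from its own seeded substream.

It does **not** emulate nucleotide sequence, read-level error, GC/length
bias, batch or sex effects, correlated features, dispersion–mean trends,
or biologically structured gene sets. Passing tests therefore demonstrate
the statistical machinery — calibration, planted-effect recovery, oracle
agreement — not concordance with any particular real dataset's biology.

Because planted fold-change magnitudes are nearly constant, fold-change
*correlations restricted to DE features* are noise-dominated in the
synthetic studies (there is almost no magnitude spread for the correlation
to latch onto); the property that restricting to the DE union raises the
correlation is exercised on constructed heterogeneous effects instead.

## Problem sizes and runtime

The bundled demo uses 2,000 genes and 600 HERV loci with the default
sample sizes; the full pipeline, including two 200,000-iteration
permutation tests, runs in well under a minute on one CPU. Test-suite
simulations use 100–2,000 features as appropriate for the property being
checked; the published-scale overlap recomputation (universes of 13,866 /
12,376) takes a few seconds. These sizes are the package's own choices for
a reproducible desk-scale demonstration.

## Known limitations

- The EM stage models alignment-score structure only; no fragment length,
  mate-pair, or positional information.
- The NB Wald test is anti-conservative for very small groups (< ~5 per
  arm) where the normal approximation and moment dispersion are rough.
- The Jaccard filter's grid argmax is sensitive to the degenerate
  sparse-matrix regime described above; the presence-filter default for
  HERVs is the mitigation.
- Pair associations are univariate; confounding by shared case/control
  status is not removed (a condition covariate is a natural extension).
- Multi-dataset support is pairwise: the integration statistics take
  exactly two datasets.
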