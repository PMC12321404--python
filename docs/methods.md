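# Methods

## Heterogeneity index

For a patient with category counts $n_1,\dots,n_K$ (total $n$), the
heterogeneity index is

$$\mathrm{HI} = 100 \cdot \frac{\binom{n}{2} - \sum_k \binom{n_k}{2}}{\binom{n}{2}},$$

the exact probability that two samples drawn *without replacement* are
discordant. It equals the Gini–Simpson index $1-\sum p_k^2$ only in the
$n\to\infty$ limit; at autopsy sample sizes (median ~11 per patient) the
finite-sampling correction matters (the plug-in index is biased downward by
a factor $(n-1)/n$). Counts are kept as integers and the index is computed
from integer pair counts, so it is exact to one floating-point rounding.
Patients with fewer than two samples get an explicitly undefined result
rather than 0 or NaN arithmetic.

The Ki-67 HI applies the same formula to samples dichotomized at 20%
(values equal to the threshold count as low). The intratumoral variant
pools discordant and total pair counts over cores within the same tissue
block (averaging per-block indices is available as an option).

## Subtyping rules

A sample is AR+ when AR **or** NKX3.1 has H-score ≥ 20 (inclusive), NE+
when SYP **or** INSM1 has H-score ≥ 20. Duplicate cores are combined by
taking the per-marker maximum (mean available); classification happens on
the combined sample by default (`unit="sample"`), or per core. The dominant
subtype is the per-patient modal label; exact ties are broken by the fixed
label order AR+/NE−, AR−/NE+, AR+/NE+, AR−/NE− and flagged
(`dominant_tied`). AR+/NE+ tumors are called amphicrine when the fraction
of coexpressing cells exceeds 0.70 (strict).

## Bootstrap

Cohort mean HIs are summarized with bias-corrected and accelerated (BCa)
95% intervals: the bias term $z_0$ comes from the fraction of bootstrap
means below the observed mean (clamped to $[1/(B{+}1), B/(B{+}1)]$), the
acceleration from jackknife skewness. Inputs are sorted before resampling
so the interval is invariant to row order; all-identical inputs return the
degenerate interval $[v, v]$ with a flag. $B = 1000$ by default. Coverage
of the analytic generator mean is verified at 93–97% over 500 repeats of
200 patients in the test suite.

## Copy-number events

Gene-level ploidy-adjusted copy number (PACN) is thresholded as:
homozygous deletion below $10^{-6}$ (numerical zero), deletion ≤ 0.5,
gain ≥ 1.5, amplification ≥ 2.5, otherwise neutral (boundaries inclusive
on the altered side). A patient's *shared* alteration in a gene is the
least severe non-neutral category present in **every** sequenced
metastasis; genes altered in only a subset are reported as divergent.
Genotype flags (`AR_altered`, …, plus conjunctions such as
`RB1&TP53_altered`) combine copy-number events with mutation-class and
biallelic annotations.

## Site model

NE positivity by anatomic site is modeled as a random-intercept logistic
regression (bone as reference) fitted by maximum likelihood with
Gauss–Hermite quadrature (25 nodes; statsmodels has no ML binomial GLMM).
Start values come from the pooled logit; convergence accepts BFGS
"precision loss" stops when the gradient is flat. Sites with constant
outcomes are reported as non-estimable rather than given divergent
coefficients. With `fix_sigma=0` the model reduces exactly to pooled
logistic regression, which estimates the *marginal* odds ratio — the
estimand pinned by the synthetic generator; the random-intercept
(conditional) odds ratio is systematically larger under clustering, and
the package exposes both.

## Nonparametric comparisons

Group comparisons use Kruskal–Wallis followed by pairwise Mann–Whitney
(exact when min(n) ≤ 25 without ties, otherwise asymptotic with continuity
correction) with Holm step-down adjustment. Shift magnitudes are
Hodges–Lehmann estimates with Mann–Whitney-inverted distribution-free CIs.
A strict Bonferroni gate at $p < 0.05/21$ is provided for pre-specified
21-test batteries.

## Signature scoring

Module scores follow the binned-control construction: genes are ranked by
mean expression and cut into 24 equal-frequency bins; each signature gene
contributes 100 control genes drawn (seeded) from its own bin; the score is
the mean signature expression minus the mean control expression per cell.
This makes scores approximately mean-zero under the null and invariant to
adding a constant to the expression matrix. Cells are called positive for
a program when the score exceeds 0.1 (strict). QC keeps cells with ≥ 200
detected genes and mitochondrial fraction ≤ 0.80 ("MT-" prefix). Agreement
with an independent implementation of the same construction is checked in
the test suite (Pearson r > 0.9).

## Synthetic cohort generator

The generator is the package's study-condition model; its defaults are
fixed a priori, not tuned to test outcomes:

- **Cohort shape**: 52 patients; samples per patient rounded lognormal
  (median 11, σ = 0.62) clipped to [2, 37]; 2 cores per sample.
- **Dominant subtypes**: Categorical(0.65, 0.23, 0.08, 0.04) over
  AR+/NE−, AR−/NE+, AR+/NE+, AR−/NE−.
- **Within-patient mixing**: sample labels are Dirichlet-multinomial with
  α = 10 × (mixture), where the mixture puts 0.75 on the dominant label
  (0.88 in AR-altered patients — lower mixing with AR alteration) and
  splits the rest by fixed affinities (AR+/NE− co-occurs mostly with
  AR+/NE+). These values were calibrated analytically — via the exact DM
  homogeneity probability averaged over the sample-size law — so that
  ~71–72% of patients are heterogeneous; E[HI] is closed-form
  ($100(1-\sum\alpha_k(\alpha_k{+}1)/A(A{+}1))$, independent of n) and the
  cohort mean is ≈ 27.7.
- **Sites**: given a sample's NE status, sites are drawn from
  $q_s\,e^{\mathrm{NE}\cdot \log\mathrm{OR}_s}$ (normalized), which makes
  the *marginal* NE odds ratios vs bone exactly the configured 4.8
  (liver), 3.6 (lymph node), 7.8 (abdominal soft tissue).
- **Ki-67**: hierarchical — each patient draws a center per subtype from a
  Beta law with medians 20/60/30/30% (concentration 5), samples draw
  around the center (concentration 8), cores add N(0, 5) noise clipped to
  [0, 100]. The hierarchy makes Ki-67 positivity correlated within
  patients, putting the cohort mean Ki-67 HI near 30 instead of the iid
  maximum (~50, because the dominant subtype's median sits at the 20%
  threshold).
- **H-scores**: truncated normals on [20, 200] (mode 150) for positive
  markers and [0, 19] (mode 5) for negative; `boundary_flip_prob`
  (default 0) injects misclassification noise for robustness studies.
- **Genomics**: per-gene alteration probabilities conditional on the
  dominant subtype (AR overall ≈ 54%, RB1/TP53 enriched in AR−/NE+);
  3 sequenced metastases per patient with a 5% divergent-event rate;
  6 patients without genomics.
- **Clinical**: lognormal milestone durations with subtype-dependent
  bone-metastasis-to-death medians (2.7/1.9/7.9/0.9 years).

Limits: the generator draws sample subtypes exchangeably within a patient
(no lineage/tree structure), treats markers as conditionally independent
given the subtype, has no missing data mechanism beyond the no-genomics
subset, and models anatomic site only through NE status. The marginal
sample-level Ki-67 median is not exactly the configured center median
(Beta compounding and max-of-cores combination shift it by up to ~+5);
recovery tests therefore estimate the center median via per-patient
medians of core-level values.

## Problem sizes and numerical choices

Default sizes are the package's own choice: 52-patient cohorts (~640
samples) run end-to-end in a few seconds; recovery experiments use 500
label-level cohorts plus 4–24 full cohorts and complete in about a minute.
All randomness flows from a single seed through
`numpy.random.default_rng`; derived seeds stay below $2^{31}$. Exact
rational arithmetic is used where feasible (HI pair counts); logistic
likelihoods use log-sum-exp; bootstrap and quadrature node counts
(1000, 25) balance accuracy against the one-CPU budget.
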