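# Methods

`corrlit` implements a complete computational chain for characterizing the
Pearson correlation coefficients reported in a body of scientific articles:
mining them from plain text, auditing their claimed significance, summarizing
their distribution, and translating the observed effect sizes into power and
sample-size requirements. A synthetic-literature generator with known ground
truth stands in for real article corpora in all tests.

## Statistical model

Everything rests on the bivariate-normal sampling model for the Pearson
correlation. For a sample of N pairs (df = N − 2 degrees of freedom):

* **Null distribution.** Under ρ = 0 the sample correlation r has density
  f₀(r | df) = (1 − r²)^((df−2)/2) / B(½, df/2) on (−1, 1); equivalently
  t = r·√df / √(1 − r²) is Student-t with df degrees of freedom, and
  r² ~ Beta(½, df/2). Exact p-values use the t form; two-sided p is twice
  the upper tail, one-sided p takes the observed direction as the
  hypothesized one (so it is always half the two-sided p — an upper bound
  on significance, which is the conservative convention for auditing mined
  claims whose hypothesized direction is unknown).
* **Critical boundary.** r_crit(df, α, sides) inverts the t quantile:
  r_crit = t_crit / √(t_crit² + df). Significance means p ≤ α, so a value
  exactly on the boundary is significant. Self-consistency
  (exact_p(r_crit) = α) holds to 1e−8 across df ∈ [5, 2000].
* **Non-null distribution.** Under ρ ≠ 0 the density of r is Hotelling's
  exact form with a Gauss ₂F₁ hypergeometric factor, evaluated in log space
  (gammaln, log1p) so it is stable to N in the thousands. Power is the
  integral of this density over the rejection region (adaptive quadrature);
  required N is found by integer bisection on the monotone power curve and
  is the smallest N whose power reaches the target — no fractional-N
  rounding is involved.

### Required sample size: exact model vs Fisher-z

For a two-sided α = 0.05 test at 80% power the exact model gives N = 84 at
ρ = 0.3 (power(84) = 0.8003) and N = 269 at ρ = 0.17 (power(268) = 0.79952,
narrowly below target; power(269) crosses it). The widely quoted value for
ρ = 0.17 is 268, which is what the Fisher-z approximation with small-sample
bias correction produces when its fractional solution (268.45) is rounded to
the nearest integer; that same approximation yields 84.07 → 85 at ρ = 0.3.
No single convention reproduces both 84 and 268; `required_n` mandates the
exact model (84 and 269) and exposes the Fisher-z route only as a labelled
cross-check (`method="fisher"`), documented to differ by ±1–2 participants.

### Expected non-significant |r| under the null

If the null were true everywhere, the average magnitude of *non-significant*
correlations at a given df is the conditional mean
E[|r| · 1{|r| < r_crit}] / P(|r| < r_crit), computed from the closed-form
antiderivative ∫₀^c u(1−u²)^((df−2)/2) du = (1 − (1−c²)^(df/2))/df. The
normalized (conditional) form is the default since a mean of non-significant
values is conceptually conditional on non-significance; the raw unnormalized
integral is available via `normalized=False`. The two differ by the factor
P(|r| < r_crit) = 1 − α for a two-sided boundary. As α → 0 the boundary
tends to 1 and the conditional mean tends to the unconditional
E[|r|] = 2/(df·B(½, df/2)).

## Synthetic literature generator

`generate_records` emulates the statistical structure of a published
correlational literature; `render_corpus` serializes it into pseudo-article
text. Defaults, with units and rationale:

| parameter | default | rationale |
|---|---|---|
| sample_size_median | 230 | reference corpus median N |
| sample_size_sigma | 1.033 (log scale) | least-squares fit to N quartiles 140/230/564; a 2-parameter log-normal cannot match the asymmetry exactly, so both quartile residuals are balanced |
| records_per_study_median | 26 | reference corpus median r values per study |
| null_fraction (π₀) | 0.1 | share of exact-null true effects; calibrated so the generated marginals (~52% significant, \|r\| quartiles ≈ 0.06/0.15/0.28) approach the observed literature (58%, 0.08/0.17/0.33) under the fixed effect distribution |
| effect distribution | Beta(1.2, 5) on \|ρ\|, Rademacher sign | right-skewed small effects; sign is immaterial because analyses are sign-blind |
| base_text_prob | 0.03 | non-significant records appear in text ~2–3% of the time (94% of records sit in tables) |
| text_emphasis_odds | 3.8 | multiplicative odds that a significant record lands in text; back-calculated from 83% significant in text vs 59% in tables at a 6% overall text share |
| misreport_rate | 0.005 | probability a significance label is flipped |
| unspecified_rate | 0.03 | probability a record carries no significance claim |

Observed r values are produced by actually simulating N bivariate-normal
pairs per record (data-level ground truth); an O(1)-per-draw sampler from the
exact distribution of r, built on the sufficient-statistic decomposition
(χ²-and-normal construction), is available as `method="exact"` and agrees
with the data-level route in distribution (two-sample KS check).

**What the generator does not emulate:** within-study dependence between the
r values of a correlation matrix (records are conditionally independent
given N), rounding/heaping of reported values, study-level publication bias
(every generated study is "published"), journal layout and tables, and any
relationship between effect size and sample-size planning. Passing tests
therefore demonstrate correctness of the pipeline mechanics and directional
reproduction of reporting-bias signatures — not that real literatures have
these exact parameter values.

**A deliberate subtlety:** even with every reporting bias switched off, the
*observed* |r| is negatively rank-correlated with df (Spearman ρ ≈ −0.05 to
−0.08 at 50 000 records) because sampling noise inflates |r| more in small
samples. The generator's *true* effects are exactly independent of df
(ρ ≈ 0.002). Tests assert independence at the true-effect level and bound
the observed association by this mechanical noise floor, an order of
magnitude below the ≈ −0.3 association that significance selection induces.

## Text extraction

The miner searches NFKC-normalized text (with Unicode minus/dash variants
mapped to ASCII) for a standalone lowercase `r` — not preceded or followed
by a letter, digit or underscore — optionally followed by a parenthesized
token, then `=`, ignoring ASCII spaces. From each match it takes a window of
at most 56 characters starting at the `r`, terminated at the first newline.
The correlation is the first numeric token directly after `=` (optional
sign, leading-dot decimals); values outside [−1, 1] are rejected, a
parenthesized non-negative integer becomes df (non-integers drop df but keep
r), and a following `p =/<,>` token in [0, 1] becomes the p-value report.

Consequences, all deliberate:

* line breaks inside a report defeat the parse (a `join_lines` option
  exists, off by default);
* subscripted symbols (`r_extraversion =`) and verbal reports
  ("correlation was 0.38") are invisible;
* uppercase `R`, `r2`/`r²` (NFKC folds the superscript) never match, so
  regression coefficients of determination cause no false positives;
* mined signs are unreliable in PDF-extracted text, so the default
  *strict-absolute* mode stores |r| only.

On rendered corpora restricted to covered formats the miner attains recall
1.0 with zero false positives; mixing in ~7% line-break/subscript variants
drops recall to ≈ 0.93, with every miss attributed to its variant.
Validation matches a parsed hit to a truth annotation when offsets agree
within ±2 characters and |r| agrees to two decimals.

## Distribution summaries

* Quantiles use linear interpolation of order statistics at position
  1 + (n−1)p (numpy default, R type 7) so results are reproducible against
  R-based analyses. Summaries are never weighted by sample size.
* The cumulative curve evaluates quartiles of |r| over all records with
  df ≤ d at every distinct df value d (no binning); records lacking df are
  excluded from the curve but retained in overall summaries.
* Bootstrap CIs for medians use the "standard normal interval":
  (2·m − mean(m*)) ± z·sd(m*) over resampled medians m*. Coverage on
  Gaussian samples of n = 1000 at 10 000 resamples is ≈ 94–95%; at small n
  the interval undercovers moderately, a known property of normal-interval
  bootstrap for medians, not a defect of the implementation.
* Yearly Spearman |r|-vs-df associations use average ranks for ties; the CI
  is the Fisher-z normal approximation with SE = 1/√(n−3). Years with fewer
  than 10 usable records, or constant inputs, are emitted with the
  association absent rather than NaN.

## Consistency audit

A record claiming significance whose |r| falls below the two-sided critical
boundary for its df is labelled TOO_SMALL_FOR_SIG; a claimed non-significant
|r| at or above the boundary is TOO_LARGE_FOR_NONSIG. The two-sided boundary
is the audit criterion (the one-sided boundary is recorded alongside), and
flags are read as *suspects*, never errors — a legitimate multiplicity
adjustment can shift an author's own threshold. A bare `p < v` report with
v ≤ α and no explicit label is audited as a significance claim. Records
lacking both N and df are UNRESOLVABLE; records with no claim at all are
resolved separately by exact-p recomputation under both sidedness
conventions.

## Numerical choices and problem sizes

Quadrature uses `scipy.integrate.quad` with limit=200 on the (smooth,
integrable) r density; the hypergeometric factor is evaluated directly and
the rest of the density in log space. Degenerate inputs error explicitly
(df < 1, |r| ≥ 1 where a transform requires the open interval, n < 3 for
simulation, fewer than 2 values for a bootstrap). Monte-Carlo checks in the
test suite use 30 000–100 000 replicates (power and type-I calibration),
10⁶ draws for conditional-mean oracles via the Beta(½, df/2) representation,
and a 1200-study (~50 000-record) literature for parameter recovery; these
sizes keep Monte-Carlo error well inside each assertion's tolerance.

## Known limitations

* The exact-power integrand is not vectorized over N; required-N searches
  are O(log N) quadratures and remain sub-second, but batch power surfaces
  over thousands of (r, N) pairs would benefit from caching.
* The extraction grammar covers the dominant reporting formats; it does not
  attempt table reconstruction, OCR repair, or non-English templates.
* Reading externally deposited record tables requires a column mapping when
  the deposit's headers differ from the canonical schema; the mapping must
  be supplied by the user (`data/deposited/column_map.yaml` for the audit tests).
* The generator draws one shared N per study; literatures where sub-analyses
  have differing N within a study are not represented.
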