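# Methods

## The composite and its assumptions

The package builds a census-tract opportunity index from a tract-by-measure
table in five deterministic stages: per-measure z-standardization
(sample SD, divisor n−1), within-domain averaging, within-domain rank
scaling, an exponential transformation of the scaled ranks onto [0, 100],
and a weighted aggregation reversed so that higher means more opportunity.
The construction assumes that (i) each constituent measure is a noisy,
monotone indicator of its domain's deprivation once reverse-coded measures
are negated; (ii) domains are commensurable after rank scaling, so equal
weights are meaningful; and (iii) relative position among the analyzed
tracts — not the absolute level of any measure — is what the index should
encode. Rank scaling makes the index ordinal at the domain level:
information about the *distance* between tracts on a domain is discarded
by design, which is what makes scores comparable across domains with
wildly different marginal distributions.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `delta` (exponential constant) | 23 | index points | the classic multiple-deprivation choice; controls how strongly the deprived tail is stretched (smaller δ → stronger stretch). The internal constant is written `100/δ`, so the transform's endpoints are exactly 0 and 100 for *any* positive δ. |
| `weights` | 1/8 per domain | — | equal weighting; a general non-negative vector summing to 1 is accepted for sensitivity analysis. |
| `rescale_final` | on | — | the weighted composite `100 − Σ w_d X_d` need not attain 0 or 100 on its own (domain extremes rarely coincide in one tract); a final min–max rescale delivers an exact 0–100 span. Toggle off to keep the raw Eq.-style composite. |
| septile tie-break | (score, fips) lexical | — | determinism; ties at a quantile boundary fall to the lower-numbered group. |

Preprocessing order is fixed: zero-population tracts are dropped first, so
column medians used for imputation reflect analyzed tracts only; then each
measure's missing cells take its median (midpoint convention for even
counts); then reverse-coded measures are negated. Negating raw values
before standardization is equivalent to flipping the z-scores afterwards
(z(−x) = −z(x)) and keeps the standardization step untouched.

## Numerical choices and degenerate inputs

- A constant measure column carries no deprivation signal: it standardizes
  to all zeros with a warning rather than an error, and contributes nothing
  to its domain mean.
- Rank scaling uses average ranks for ties and `(rank−1)/(n−1)`, the only
  affine scaling whose extremes are exactly 0 and 1; combined with the
  `100/δ` constant this yields the exact 0/100 endpoints of the transform
  (the r = 0 and r = 1 endpoints are returned analytically to avoid
  `log` round-off at the top end).
- Fewer than 7 tracts: the composite is still built (the step-by-step
  pipeline is well defined from n = 2), but septiles are left unassigned
  (label 0) with a logged warning, since a seven-group quantile split is
  undefined.
- Zero-variance inputs to the correlation matrix yield NaN entries, not
  errors; the diagonal is pinned to 1.
- Weights are validated to sum to 1 within 1e−9.

## Monotonicity: where it holds

Downstream of standardization the composite is monotone: increasing one
tract's deprivation z-score on one measure (others fixed) never increases
that tract's composite and never decreases any other tract's, because the
domain mean is increasing in the z, ranks respond monotonically, and the
exponential transform is strictly increasing. The same statement applied
to a *raw* measure is **not** true in general: re-standardizing the
perturbed column shifts its mean and SD, which rescales every other
tract's z-score on that measure and can reorder other tracts among
themselves. The test suite therefore checks affine invariance at the raw
stage (z-scores are invariant to positive affine maps of a raw column) and
monotonicity at the standardized stage.

## Synthetic data: what it emulates, and what it does not

The generator draws a latent opportunity factor `L ~ N(0, latent_sd)` per
tract and produces each measure as
`dir(m) · (λ·L + γ·D_{d(m)} + ε)`, affinely mapped into a plausible range
for its units (proportions clipped to [0, 1]). `λ` (`domain_loading`,
default 0.6) ties every measure to the common factor; the domain factor
`D` (`domain_factor_sd`, default 0.5) makes within-domain correlation
exceed between-domain correlation, the grouping structure that domain
averaging presumes; `ε` (`noise_sd`, default 1) is measurement noise.
`dir(m)` is −1 for deprivation-pointing measures and +1 for reverse-coded
ones. Defaults emulate a statewide file: 2,952 tracts with 12 of zero
population (`zero_pop_fraction = 12/2952`), 2% completely-at-random
missing cells (real-world missingness rates are not published for such
files; 2% is a repository choice), synthetic 11-character GEOIDs under the
fictional state prefix 99. Outcomes: life expectancy
`75 + 3·L + N(0, 1.5)` years; percent Black and minority via logistic
links decreasing in `L`, with minority ≥ Black enforced per tract; and an
external-style reference index linear in `L` for criterion-validity
exercises. The two-period generator evolves the latent by
`drift × shock` on a configurable fraction of tracts with fresh
measurement noise per period, and records the shocked tracts as ground
truth.

What the generator does **not** emulate: the real marginal distributions
of individual measures (means/SDs of published tables are documentation,
not fit targets), spatial autocorrelation between neighbouring tracts,
informative missingness, and population-size-dependent measurement error.
Passing tests therefore demonstrate that the pipeline implements the
transformations correctly and recovers a latent gradient under a
single-factor world — not that the index is valid on any particular real
state's data.

## Temporal comparison

Each period is standardized and ranked **within itself** on the registry's
common-measure subset (37 of the 53 packaged measures carry the earlier
period's tag), then compared tract by tract. Under within-period ranking a
constant shift of every measure in one period leaves that period's scores
unchanged, so cross-period level differences reflect changes in rank
structure, not absolute change — the documented trade-off of rank-based
indices. Thresholds default to 10 points for notable tract-level change
and 3 points (on the 0–100 domain scale) for notable domain-level change.
Note the retained per-domain scores are deprivation-direction (higher X =
more deprived), so a positive domain delta means deterioration.

## Validation battery

Construct validity: OLS of each outcome on six septile indicators
(septile 1, the least advantaged, as reference). The model is a saturated
one-way layout, so fitted values equal within-septile means exactly and
the septile-7 coefficient *is* the 7-vs-1 contrast. The test of trend is
OLS on the septile coded 1–7 — the simplest trend operationalization
consistent with an OLS battery; its slope t-statistic and two-sided p are
reported separately from the dummy regression. p-values carry no
multiplicity correction. Criterion validity: squared Pearson correlation
between the built index and a reference index, invariant to affine maps of
either argument.

## Problem sizes used in the checks

The latent-recovery check builds 3,000 tracts with generator defaults and
requires Spearman ≥ 0.8 against the latent factor (defaults achieve ≈
0.92). The null-calibration check permutes septile labels in 200
replicates of 700 tracts each and requires the trend test's rejection rate
at α = 0.05 to land in [0.02, 0.09] (binomial tolerance around the
nominal rate; the statistic's null distribution does not depend on n, so
700 tracts per replicate is ample). Oracle-equivalence checks run the full
pipeline against an independent straight-line reimplementation on
instances of up to 10 tracts at 1e−9 tolerance. The statewide smoke check
uses 2,952 tracts with 12 zero-population.

## Known limitations

- Equal weighting is a normative choice; the package offers general weight
  vectors but no data-driven (factor-analytic) weighting.
- Median imputation is only defensible under simple missingness; no
  model-based or multiple imputation.
- No spatial statistics: tracts are exchangeable rows here.
- Septile group sizes differ by one when n is not divisible by 7; with
  heavy score ties, quantile groups can deviate further from equality.
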