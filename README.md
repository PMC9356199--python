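# ocoi

Construction, validation, and temporal comparison of a census-tract
**children's opportunity index** — an area-level composite of social
determinants of health (SDoH) in the style of the Ohio Children's
Opportunity Index and the UK Index of Multiple Deprivation family of
measures.

## Who this is for

Public-health analysts and researchers who need to build, audit, or stress
an area deprivation/opportunity composite from a tract-by-measure table:
one row per 11-digit FIPS/GEOID census tract, one column per constituent
measure. The real source tables such an index is built from (Medicaid
claims, ACS pulls, HUD indices, vital statistics, crime feeds) are
restricted or composite, so the package also ships a synthetic-tract
generator that emulates their statistical structure, making every stage of
the pipeline runnable and testable end to end.

## The method

Given raw measures `x` grouped into 8 domains *d* (family stability, infant
health, children's health, access, education, housing, environment,
criminal justice; 53 measures in the packaged catalogue, 11 reverse-coded):

1. **Standardize** — `Z_{d,i} = (x − μ_i) / σ_i` per measure (sample SD).
   Reverse-coded measures are negated first, so higher always means more
   deprivation.
2. **Domain averaging** — `Domain_d = Σ_i Z_{d,i} / N_d`, the mean of a
   tract's z-scores over the `N_d` measures in domain *d*.
3. **Rank and scale** — within each domain, tracts are ranked by domain
   score (average ranks for ties) and scaled `R = (rank − 1)/(n − 1)` so
   the most deprived tract gets exactly 1.
4. **Exponential transformation** —
   `X = −δ · ln{1 − R · (1 − e^(−100/δ))}` with δ = 23, mapping [0, 1] onto
   [0, 100] exactly and stretching the deprived tail.
5. **Equal weighting and reversal** — `COI = 100 − Σ_d X_d / 8` (general
   weight vectors supported), then min–max rescaled across tracts to span
   [0, 100]. Higher = more opportunity. Tracts are classified into
   **septiles** (7 quantile groups); septile 1 is the least advantaged.

Validation: OLS of tract outcomes (life expectancy, percent Black, percent
minority) on septile indicators with septile 1 as reference, a test of
trend across ordered septiles, septile-7-vs-1 contrasts, and criterion R²
against an external reference index. Temporal comparison rebuilds two
periods on their 37 common measures and flags tracts moving by more than 10
points and domains moving by more than 3 points.

## Worked example

```sh
ocoi simulate --n-tracts 2952 --seed 1 --out demo/
ocoi build --measures demo/measures.csv --out demo/index.csv
ocoi validate --index demo/index.csv --outcomes demo/outcomes.csv \
     --reference-index reference_index --report demo/validation.json
```

The build log reports:

```
built index: 2952 tracts in, 12 excluded (zero population), 3031 imputed cells, 2940 out
```

i.e. of 2,952 simulated tracts, the 12 zero-population tracts were dropped
and the ~2% missing cells median-imputed; 2,940 tracts receive scores.
`demo/index.csv` holds `fips, ocoi_score, septile` and the eight per-domain
exponential scores; composite scores span exactly 0–100 with 420 tracts per
septile. In `demo/validation.json` the life-expectancy coefficients rise
monotonically across septiles 2–7 (the septile-7 coefficient is 8.7 years on
the generator's default 3-years-per-latent-SD gradient), the trend p-value
is far below 0.001, and the contrasts for percent Black and minority are
negative — the qualitative pattern an opportunity index must reproduce.

The same pipeline is available as a library:

```python
import ocoi

registry = ocoi.default_registry()                      # 53 measures, 8 domains
table, truth = ocoi.generate_tract_frame(ocoi.SyntheticConfig(seed=1))
result, panel, log = ocoi.build_index(table, registry)  # scores + audit trail
```

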