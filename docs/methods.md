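# Methods

## Models

### Rank-size (Zipf) estimation

For one year's resource values across cities, sizes are sorted descending
(stable sort, so ties keep input order), assigned ranks `1..n`, and
`ln(size)` is regressed on `ln(rank)` by ordinary least squares; the
reported coefficient `q` is the negated slope.  Two rank conventions are
supported:

* `plain` — regress on `ln(R)`; exact on a noiseless power-law series
  (returns the generating exponent to machine precision with R² = 1).
* `shifted` (default) — regress on `ln(R − ½)`, the standard correction for
  the small-sample bias of the rank-size slope when the data are a *sample*
  from a heavy-tailed law.  On an exact deterministic series the shift
  widens the log-rank spacing at the top of the hierarchy, so the fitted
  magnitude is weakly smaller than with plain ranks; the two conventions
  converge as `n` grows.  Because published rank-size coefficients rarely
  state which convention produced them, reproduction checks accept either.

Non-positive sizes have no logarithm; they are dropped and counted in
`n_dropped` rather than raising, since yearbook panels have gaps.  A
distribution with all sizes equal has an undefined log-log slope; the fit is
returned with `q = 0`, `r2 = 0` and a `degenerate` flag instead of an error.
Interpretation bands: `q < 1` balanced, `q = 1` (within 1e−9) canonical
Zipf, `q > 1` concentrated.  The slope p-value is the standard OLS t-test.

### Allometric scaling

The power law `A = k·G^b` between a resource `A` and economic output `G` is
fit as `ln A = k + b·ln G` by OLS; `R²` is unadjusted.  Two orientations:

* **vertical** — across all cities of one year (cross-sectional);
* **horizontal** — across the years of one city inside an inclusive window.
  The default estimator pools the city's in-window years into a single
  log-log OLS (7 points for the default windows), the simplest estimator
  consistent with the model; an endpoint growth-rate-ratio estimator
  `ln(A_end/A_start) / ln(G_end/G_start)` is available behind a flag as a
  sensitivity check (it uses only two points and reports no R²).

Pairs with a non-positive member are dropped; fewer than 3 valid pairs or a
zero-variance predictor raise typed errors.  A constant response returns
`b = 0`, `k = ln A`, `r2 = 0` exactly rather than relying on the numerical
slope of a flat regression.

The exponent is banded into six ordered levels with **inclusive lower
bounds**: `b ≥ 2` Positive3, `2 > b ≥ 1` Positive2, `1 > b ≥ 0.85`
Positive1, `0.85 > b ≥ 0.5` Negative1, `0.5 > b ≥ 0` Negative2, `b < 0`
Negative3.  The 0.85 threshold is the conventional equal-rate point for
urban scaling; levels at or above it mean the resource grows at least as
fast as the economy.  The grade scale orders Negative3 = 1 through
Positive3 = 6; a city's transition between two windows is typed from the
signed grade difference — 0 stable, ±1 upgrade/decline, |Δ| ≥ 2
fast_upgrade/fast_decline.  Window summaries report counts and shares
(`count/total·100`, two decimals).

### Map-preparation transforms

* **Percent-of-total normalisation** — `value / Σvalues · 100`; requires
  non-negative inputs with a positive sum; output sums to 100 within 1e−9.
* **Jenks natural breaks** — the exact optimisation: among all contiguous
  partitions of the sorted values into `k` classes, the one minimising the
  total within-class sum of squared deviations, solved by the standard
  O(n²k) dynamic program with prefix sums.  Ties are broken
  deterministically toward earlier (smaller) break values.  This is the
  exact optimum; heuristic GIS implementations can differ on ties, which is
  acceptable because the classes feed only descriptive reports.  Default
  `k = 5` with labels lagging / low / intermediate / good / leading.
* **Percent change** — `(end − start)/start · 100`, sign preserved,
  rounded to two decimals in reports.

## Synthetic panel generator

The generator emulates a yearbook-style panel: `n_cities` cities observed
annually over an inclusive year range, each with strictly positive GDP,
beds and doctors.  Structure:

* base-year city GDPs are heavy-tailed — lognormal with log-mean 9 and
  log-sd 1 (arbitrary currency units) by default, with a Pareto option for
  Zipf-consistent tails;
* each city's GDP follows a geometric random walk: i.i.d. lognormal growth
  factors with mean log growth 0.10/yr and sd 0.05/yr, matching the rough
  ×3.5 aggregate growth over 13 years typical of fast-developing
  agglomeration panels;
* resources derive from GDP through the allometric link
  `ln A = k + b_year·ln G + ε`, `ε ~ N(0, noise_sd²)`, with defaults
  `b = 1.2` (beds) and `1.25` (doctors), intercepts 5.0 and 5.8, and
  `noise_sd = 0.3`; an optional linear drift `b_drift_per_year` moves the
  true exponent over time.

Noise is applied on the log scale (multiplicative lognormal), which makes
log-log OLS the correct estimator, so noiseless configurations recover the
true exponents to machine precision and noisy ones are unbiased.  Defaults
(41 cities, 2009–2022) mirror a typical agglomeration panel's dimensions.
Randomness comes from one seed; each city draws from a substream keyed by
`(seed, city index)`, so identical configs are bit-identical and adding
cities never perturbs existing ones.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: spatial correlation between neighbouring
cities, administrative reclassifications or boundary changes, reporting
artifacts (rounded or imputed yearbook counts), business-cycle co-movement
of GDP across cities, and any feedback from resources to the economy.  It
validates the estimators, not the empirical claims one might make with them.

## Numerical and design choices

* Natural logarithms throughout.
* OLS via `scipy.stats.linregress`; the test suite checks every fitted slope
  and intercept against an independent normal-equations solve (1e−10 on
  small instances).
* Report rounding: coefficients to 4 decimals, percentages to 2; re-running
  the pipeline on the same inputs produces byte-identical CSVs.
* Missing city-years are excluded per analysis (pairwise deletion), not by
  dropping the city everywhere, matching per-year cross-sectional fitting.
* Per-year totals are computed by summing each year's column slice directly
  so they equal the panel's column sums exactly.
* Default analysis windows 2009–2015 and 2016–2022, configurable; default
  rank convention `shifted`, with `plain` exposed since published
  coefficients may have used either.
* GDP is taken as given (nominal); no deflation is applied.

## Simulation sizes

The recovery study uses 500 replicate panels of 41 cities at `noise_sd =
0.3` (the package's default study conditions) and checks mean bias of the
vertical exponent within ±0.02 and ≥ 93 % empirical coverage of the nominal
95 % OLS slope interval.  Natural-breaks optimality is verified against
exhaustive partition search on 50 random instances with `n ≤ 12`, `k ≤ 4`,
where enumeration is cheap and exact.

## Known limitations

* The horizontal estimator pools few points (7 per default window); its
  sampling error is large and level assignments near band boundaries are
  sensitive to noise.
* Band edges are knife-edge inclusive; an exponent estimated at exactly a
  threshold classifies deterministically but small data perturbations can
  flip the level.
* The six-level taxonomy and the 0.85 equal-rate threshold are conventions
  of the urban-scaling literature, not estimated quantities.
* No spatial structure, population variable, or causal identification: the
  package measures scaling relationships, it does not explain them.
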