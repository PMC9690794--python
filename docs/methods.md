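# Methods

This note records the statistical conventions, defaults and numerical
choices implemented in `ordnet`, and what the synthetic-data tests do and do
not demonstrate.

## Latent-Gaussian model for ordinal items

Each of p ordinal items (default K = 5 categories) is modelled as a
discretised standard-normal variable: item j has strictly increasing
thresholds τ_j1 < … < τ_j,K−1 and the observed score is the index of the
interval containing the latent value. Dependence between items is the
latent correlation matrix; conditional dependence is read from its inverse.
This is exactly the assumption under which polychoric correlations are
consistent, so the generator and the estimator share one model.

## Polychoric estimation (`ordnet.polycor`)

* **Two-step estimator.** Thresholds are fixed at Φ⁻¹ of the marginal
  cumulative proportions; the correlation then maximises the
  bivariate-normal likelihood of the K×K contingency table by bounded Brent
  search on (−0.999, 0.999) (tolerance 1e−5 on ρ). Full joint ML is not
  implemented; the two-step variant is the convention in psychometric
  software and its extra variance is negligible at questionnaire scale.
* **Rectangle probabilities** come from an Owen's-T implementation of the
  bivariate normal CDF (`ordnet._bvn`), vectorised over the threshold grid
  and accurate to ~1e−14 (cross-checked against quadrature in the tests).
  Cell probabilities are floored at 1e−12 inside the log-likelihood so
  sparse cells cannot produce −∞.
* **Pairwise deletion.** Element (i, j) uses rows complete for that pair;
  the per-pair counts are kept, and the EBIC later uses their mean as the
  effective n. Each pair must retain ≥ 10 complete cases and ≥ 2 observed
  categories per margin, otherwise an error names the offending pair.
* **Positive definiteness.** Pairwise deletion can break PD; if the
  smallest eigenvalue falls below 1e−8 the matrix is repaired by eigenvalue
  clipping (floor 1e−6) and rescaling to unit diagonal, and flagged
  `repaired`. Clipping is the minimal intervention; no smoothing toward a
  target structure is applied.
* Correlations at the ±0.999 search bound signal near-duplicate items and
  are left as estimated (they are visible in logs and bootstrap tables).

## Network estimation (`ordnet.ggm`)

* **Solver.** `ordnet._glasso` implements the standard block coordinate
  descent for the graphical lasso, numba-compiled, with the reference
  stopping rule (mean absolute change of the working covariance below
  1e−5 × mean|off-diagonal|; inner lasso tolerance 1e−6). The penalty path
  is warm-started from large to small λ. The test suite cross-checks the
  solver against an independent implementation of the same convex problem
  (scikit-learn) for support identity and value agreement, and against
  direct matrix inversion in the λ→0 limit.
* **Path and selection.** 100 log-spaced penalties from
  λ_max = max|R_ij| down to λ_max/100; EBIC with γ = 0.5 by default
  (γ = 0 reduces to BIC). The likelihood is evaluated at the penalised
  estimate (no refit). Entries with |w| < 1e−8 are exact zeros.
* **Effective n.** Under pairwise deletion the EBIC n is the mean of the
  pairwise complete-case counts; it is configurable because no single
  convention is canonical.
* A solver failure at one penalty (possible at tiny λ on near-singular
  repaired matrices) skips that path point with a log record; the fit fails
  only if every penalty fails. This keeps long bootstrap loops from
  aborting on one pathological replicate while still surfacing the events.

## Description of the estimated network

* **Clustering.** Weighted global clustering defaults to the Zhang–Horvath
  coefficient on max-normalised absolute weights, averaged over nodes with
  ≥ 2 neighbours; Onnela and Barrat variants sit behind a switch.
* **Centrality.** Strength Σ|w|, eigencentrality (Perron vector of |W| on
  the largest connected component, scaled to max 1), bridge strength
  (Σ|w| to other communities). All use absolute weights — the convention
  for signed psychological networks; betweenness/closeness are deliberately
  excluded because conditional associations are not distances. z-scores use
  the sample SD.
* **Communities.** Walktrap (t = 4 random-walk steps, the common default)
  on absolute weights, run per connected component, dendrogram cut at
  maximum weighted modularity, isolates as singletons. The parametric
  bootstrap re-simulates ordinal data from the estimated network (precision
  with unit diagonal and −w off-diagonal, inverted and rescaled; thresholds
  re-estimated from the observed margins) and re-runs the *entire*
  pipeline — polychorics, EBIC-glasso, walktrap — per replicate, so all
  estimation uncertainty propagates into the community-count CI. Both a
  2.5/97.5 percentile CI and a normal-approximation CI around the mean
  count are reported: on integer counts the percentile CI is typically
  degenerate ([3, 3]) while the normal CI is the convention that can
  produce intervals tighter than one integer (e.g. [2.99, 3.01]).
* **RMSEW.** For every community pair (including a community with itself),
  the root mean squared edge weight over *all* node pairs of the block,
  zero edges included, plus mean and SD of |w| for the same pairs. Including
  zeros matches block summaries whose SD exceeds the mean (zero-inflated
  blocks).
* **MST.** Gower transform d = √(2(1−w)) on the signed partial correlation
  (an absolute-value switch exists; the transform choice only rescales
  distances, never reorders them, so the tree topology is unaffected —
  asserted on random networks). Kruskal with union-find and lexicographic
  tie-breaks makes the tree deterministic.

## Stability (`ordnet.stability`)

Nonparametric edge bootstrap (default 2500 replicates) resamples
respondents with replacement and records each edge's distribution.
Case-dropping bootstrap: drop grid 0.05..0.75 in steps of 0.05, 250
subsamples per level by default, Pearson correlation between the subsample
statistic and the original (over originally nonzero edges, or all node
strengths); CS = largest drop fraction with ≥ 95% of correlations ≥ 0.7.
Per-level seeds are spawned from one master seed. Replicate failures are
skipped and counted; > 5% failures is an error.

## Sample-size planning (`ordnet.power`)

Sensitivity is TP/(TP+FN) against the true edge support (false positives do
not enter the denominator). For the search, true networks are drawn by
`generate_random_ggm`: support uniform over pairs at the target density, raw
weights U(0.5, 1) with 90% positive signs, precision diagonal set to
1.5 × the maximum absolute column sum, then standardised — the construction
used by Monte-Carlo sample-size tools for psychological networks. It yields
uniformly weak partial correlations (~0.05–0.11), the regime in which EBIC
selection is genuinely hard and required sample sizes land in the
thousands. Data can be simulated as 5-category ordinal with the full
polychoric pipeline (`mode="ordinal"`) or as continuous Gaussian with a
Pearson matrix (`mode="gaussian"`, ~5× faster; with balanced categories the
two give closely similar selections). The per-n fraction of replications
meeting the sensitivity target is smoothed by isotonic regression before
selecting the smallest qualifying n; if no grid point qualifies the result
is flagged and the largest candidate reported. EBIC selection on uniformly
weak edges is knife-edge (empty versus dense models), so the power curve
rises steeply and the selected n is sensitive to the generator's weight
conventions — a caveat inherent to this style of planning, not to the
implementation.

## Synthetic study generator (`ordnet.synth`)

`generate_true_ggm` emulates a 17-item instrument (7 stress, 6 coping, 4
support items; the 7/6 split of the 13 stress/coping items is configurable
since either split is defensible) with exactly round(density·136) edges.
Defaults, chosen once to mirror reported questionnaire-network structure:

* Sign pattern: positive within communities, negative stress–coping and
  stress–support, positive coping–support.
* Magnitudes U(0.2, 0.4) within communities, U(0.3−1.0) of that — U(0.03,
  0.10) — between; edge placement tilts within-community pairs by 3.5× in a
  largest-remainder allocation (within-community edge density ≈ 0.79,
  between ≈ 0.22). Both choices reproduce the strong within/weak between
  contrast real subscale networks show (within-block RMSEW several times
  the between-block value) and make the planted communities genuinely
  modular — with a single uniform magnitude range and proportional
  allocation the "communities" would be sign patterns only, undetectable by
  any modularity-based algorithm even noise-free.
* Positive definiteness by diagonal dominance (diagonal = absolute row sum
  + 0.1) followed by standardisation; thresholds default to
  equal-probability categories (Φ⁻¹(k/5)).
* Missingness is MCAR only (`inject_missing`), matching the pairwise-
  deletion estimator; no MAR/MNAR mechanisms.

With these defaults, an n = 367 synthetic study yields estimated networks
with density ≈ 0.53–0.55 and three recoverable communities, i.e. the
generator lands in the empirical regime questionnaire analyses report.

What passing tests show: the pipeline recovers structure it should recover
(planted supports, signs, communities; oracle agreement on closed forms)
and is internally consistent (determinism, invariances, CI coverage of its
own bootstrap). What they cannot show: behaviour under non-Gaussian
copulas, informative missingness, local dependence beyond the latent-normal
model, or real-data idiosyncrasies (response styles, floor effects) — the
generator does not emulate those.

## Pipeline and reproducibility

`run_pipeline` executes polychorics → EBIC-glasso → density/clustering →
walktrap (+ parametric bootstrap) → RMSEW → centrality → MST → edge
bootstrap → CS coefficients, writing CSV/GraphML artifacts and a versioned
JSON report. A single master seed is fanned out to stage seeds via
`SeedSequence.spawn`, so identical (data, config, seed) give byte-identical
reports. Default replicate counts follow the usual analysis settings
(2500 bootstrap replicates; 250 subsamples per drop level); tests and
examples scale these down (tens to hundreds of replicates, n up to 5000)
to keep runs desk-scale — the statistical behaviour they assert is already
stable at those sizes. The acceptance script uses 100 replications per
candidate n on a 250..3000 grid with the continuous-Gaussian fast mode.

## Known limitations

* The polychoric step is O(p²) bounded searches per fit; for p much beyond
  ~50 a vectorised or analytic-gradient estimator would be needed.
* EBIC γ is fixed per run, not data-adaptive; γ = 0.5 is conservative and
  can return empty networks for uniformly weak signals at small n (this is
  a property of the criterion, reported as such).
* The community-count CI conventions differ across software; both computed
  variants are reported rather than adjudicated.
* No graphics: the package computes; plotting (e.g. force-directed layouts)
  is left to downstream tools reading the GraphML/CSV exports.
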