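# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical choices, and the known limits of what the test suite can
show.

## Estimation pipeline

Respondent-level questionnaire data pass through five stages:

1. **Ingestion and completeness.** Item responses are validated against a
   codebook (scale membership, reverse-key flags, per-item ranges: 1–7 for
   the ten personality items, 0–3 for the sixteen symptom items).  Only
   fully answered questionnaires are retained; there is no imputation.
   Retention is reported as `n_valid / n_submitted` with the percentage
   rounded half-up to two decimals.
2. **Scoring.** Reverse-keyed items are recoded as `min + max − x`.  Each
   personality dimension node is the *mean* of its two recoded items
   (keeping it on the 1–7 scale; correlation-based estimation is invariant
   to this affine choice), and each symptom item is its own node.  The
   fixed node order is EXT, AGR, CON, NEU, OPE, A1–A7, D1–D9.
3. **Network estimation.** Pearson correlations by default (Spearman
   optional; polychoric correlation is a documented non-feature).  The
   graphical lasso penalizes only off-diagonal precision entries, so
   λ = 0 reproduces the unpenalized MLE `inv(S)` and
   λ ≥ max|S_offdiag| yields the empty network.  A descending log-spaced
   grid (default 100 points, min/max ratio 0.01, never including 0) is
   fitted with warm starts; each fit is scored by EBIC with γ = 0.5; the
   minimizer is selected, ties breaking toward the sparser (larger-λ)
   model.  The reported log-likelihood omits the additive
   −(np/2)·log 2π constant, which cancels in model comparison.  Partial
   correlations below 1e−10 in magnitude are stored as exact zeros.
4. **Bridge centrality.** One-step bridge expected influence over the two
   theory-given communities; no data-driven community detection and no
   other bridge indices.
5. **Robustness.** All bootstrap procedures re-run the full estimator with
   identical settings (γ, method, grid) — no shortcut estimators — and are
   pure functions of (data, config, seed).

## Solver

The graphical-lasso solver is a numba-compiled Friedman block coordinate
descent (outer sweeps over columns of the working covariance, inner cyclic
soft-threshold lasso).  Convergence is declared when the largest absolute
change of the working covariance in a sweep falls below 1e−6 (inner lasso
tolerance one order tighter).  The precision matrix is recovered from the
final column regressions and symmetrized.  The test suite cross-checks the
solver against scikit-learn's `graphical_lasso` at interior penalties, the
matrix inverse at λ = 0, the p = 2 soft-threshold closed form, and a
generic Nelder–Mead optimization of the penalized objective.  A whole
100-point path on 21 nodes costs ~10 ms, which is what makes the
case-dropping bootstrap (thousands of re-estimations) practical.

## Bootstrap conventions

* **Edge accuracy**: rows resampled with replacement, B = 1000 by default;
  percentile intervals at α = 0.05 (linear-interpolation quantiles).  A
  replicate with a zero-variance column is redrawn (at most 10 times).
* **Case-dropping stability**: drop proportions default to ten equally
  spaced values in [0.05, 0.75]; for each, B subsamples of
  ⌈(1−q)·n⌉ rows without replacement; Pearson correlation between
  replicate and full-sample BEI, undefined correlations (constant BEI)
  recorded as missing.  The CS coefficient is the largest q whose pass
  fraction (share of replicates with correlation ≥ 0.7) is at least 0.95
  *contiguously from the smallest tested proportion* — the contiguity rule
  prevents spurious passes at large drops due to sampling noise.  There is
  no interpolation between tested proportions.
* **Difference tests**: percentile intervals of replicate-wise differences
  for all pairs of edges or of node BEI values; significant iff the
  interval excludes zero; no multiplicity correction.
* A fully constant BEI vector (an estimate with no bridge edges) leaves
  every subsample correlation undefined.  `cs_coefficient` refuses such
  input; the pipeline records `cs: null` in `stability.json`, and the
  acceptance script reports this situation as zero measurable stability.

## Synthetic data model

The generator is a latent Gaussian copula: a known sparse precision matrix
defines the latent correlation structure, respondents are multivariate
normal draws, and each node is discretized through fixed thresholds.  This
is the standard generative model under which Pearson/polychoric network
estimation of ordinal data is studied, and it gives analytic control of
marginal category frequencies.

* **Truth construction.** Requested partial correlations are written into
  a unit-diagonal precision as K_ij = −ρ_ij; positive definiteness is
  enforced by diagonal inflation to a minimum eigenvalue of 0.05 followed
  by rescaling to unit partial variances.  Realized designated bridges
  must land within ±0.02 of their targets or the construction refuses.
* **Study-like configuration** (`paper_like_config`): 21 nodes, two
  communities of 5 and 16; intra-community edges placed with probability
  0.25 and weights uniform in ±[0.1, 0.3] — the magnitude range typical of
  reported symptom-network edges; six designated bridge edges
  (EXT–D4 −0.06, AGR–D9 −0.06, CON–A2 −0.05, NEU–A3 +0.14, NEU–A6 +0.11,
  OPE–D6 −0.06), making the neuroticism analogue the only node with a
  sizable positive true BEI (+0.25).
* **Marginals.** Symptom thresholds default to standard-normal quantiles
  of cumulative proportions (0.55, 0.80, 0.93), skewing responses toward
  low severity as non-clinical student samples show (item means around
  0.5–0.95 on the 0–3 scale).  Personality nodes default to
  quasi-continuous values clipped to [1, 7] centred at 4 (real dimension
  scores are two-item means and nearly continuous); seven-level
  discretization is available by flag.  These marginal choices are
  plausibility settings, not a calibration to any particular dataset.
* **What the generator does not emulate**: item-level factor structure for
  the personality inventory (dimension nodes are simulated directly),
  demographic covariates, non-MCAR missingness, and the richer
  cross-community dependence of real survey data.  In particular, with
  only six weak true bridges, discretized n ≈ 507 samples often yield an
  estimated network whose weakest bridges (|ρ| ≈ 0.05) fall below the
  EBIC detection threshold; recovery tests therefore use large-sample
  continuous draws, and passing them shows estimator correctness, not that
  a 507-respondent survey pins down bridges of that size.

## Design choices on genuinely open points

* The personality inventory's item-to-dimension map and reverse-key set
  are administration-specific; a default following the original ten-item
  instrument convention (pairs k and k+5; items 2, 4, 6, 8, 10
  reverse-keyed) ships in `default_codebook`, and the codebook is a
  required, overridable input.  The orientation of the neuroticism node
  follows whatever keying the supplied codebook encodes.
* Correlation type defaults to Pearson on node scores; the rank option
  covers ordinal robustness.  Internal covariance uses the
  maximum-likelihood (divide-by-n) convention for consistency with the
  glasso likelihood; descriptive SDs use n−1.  At n ≈ 500 the selection is
  insensitive to this distinction.
* Synthetic datasets are written as node-level score CSVs (same delimiter
  and header dialect as the item reader); the pipeline accepts
  `input_kind: items` (26 item columns, scored internally) or
  `input_kind: scores` (21 node columns).  Item-level simulation is out of
  scope, so end-to-end pipeline tests run on the scores dialect.
* Stage seeds are derived as master seed + fixed offsets (edge bootstrap
  +1, case-dropping +2, layout +3), so each stage is independently
  reproducible and the whole report bundle is byte-identical across reruns
  with the same config.

## Problem sizes used in the test and acceptance suites

Oracle checks run at p ≤ 8 within seconds.  Parameter recovery uses ten
seeds of n = 4000 continuous draws (sign agreement on true edges with
|ρ| ≥ 0.10, vectorized truth–estimate correlation, top-BEI-node
identification).  Stability behavior uses a deliberately
strong-bridge truth (eight cross edges, |ρ| up to 0.3) at n = 3000 versus
n = 100 with B = 50 subsamples per drop proportion; bootstrap unit tests
use B between 8 and 200.  The acceptance script runs retention accounting
at the 536-questionnaire scale, a full n = 507 study-like analysis with
B = 250 case-dropping, and one n = 4000 recovery run.

## Known limitations

* Pearson (or rank) correlations on 0–3 items attenuate latent
  associations relative to polychoric estimation; estimated edge
  magnitudes on discretized data are biased toward zero (a property the
  test suite asserts).
* The CS coefficient is reported only on the tested proportion grid; a
  value between grid points is never interpolated.
* EBIC selection with γ = 0.5 is conservative at moderate n: true edges
  below roughly √(log n / n) in partial-correlation magnitude are
  routinely set to zero.  This is inherent to the method, not a defect of
  the implementation.
* No mixed graphical models, moderated networks, Bayesian structure
  learning, severity banding, or demographic adjustment.
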