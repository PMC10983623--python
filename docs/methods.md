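# Methods

## The model

The package estimates a Gaussian graphical model (GGM) over ordinal
questionnaire items. The working assumption is a latent Gaussian
(copula) model: each item $X_j \in \{0,\dots,K_j-1\}$ is a
discretization of a latent standard-normal variable $Z_j$ at item
thresholds $\tau_{j,1} < \dots < \tau_{j,K_j-1}$, and the latent vector
$Z$ is multivariate normal with correlation matrix $\Sigma$. Under that
model the polychoric correlation of a pair of items is the latent
correlation $\Sigma_{ij}$, and the conditional-independence structure
of $Z$ is encoded by zeros of the precision matrix $K = \Sigma^{-1}$.

Estimation proceeds in two stages:

1. **Polychoric correlation matrix.** For each item, thresholds are set
   to $\Phi^{-1}$ of the cumulative category proportions (Olsson's
   two-stage approach). For each unordered pair, the correlation
   maximizes the multinomial log-likelihood of the two-way contingency
   table, with cell probabilities given by bivariate-normal rectangle
   probabilities. The 1-D search is bounded derivative-free
   optimization on $(-0.999, 0.999)$ with `xatol = 1e-8`.
2. **EBIC graphical lasso.** The precision matrix solves
   $\max_K \; \log\det K - \mathrm{tr}(SK) - \lambda \sum_{i\neq j} |K_{ij}|$
   along 100 logarithmically spaced penalties from
   $\lambda_{\max} = \max_{i\neq j}|S_{ij}|$ down to
   $0.01\,\lambda_{\max}$. The Extended Bayesian Information Criterion,
   $\mathrm{EBIC} = -2\ell + E\log n + 4E\gamma\log p$ with
   $\ell = \tfrac n2(\log\det K - \mathrm{tr}(SK))$ and $E$ the number
   of edges, selects the penalty; ties go to the larger penalty so
   selection is deterministic. The selected precision is reported as
   partial correlations $w_{ij} = -K_{ij}/\sqrt{K_{ii}K_{jj}}$.

Downstream statistics are simple functionals of the weight matrix:
expected influence $EI(i) = \sum_j w_{ij}$ (one-step, signed; equal to
strength when all edges are positive), bridge expected influence
(the same sum restricted to nodes outside $i$'s community, communities
being the two instruments), and nodewise predictability (R² of each
standardized item regressed on all others by OLS, treating items as
continuous — consistent with the Gaussian working model; a
regularized-neighborhood variant is deliberately not the default).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `gamma` | 0.5 | EBIC sparsity weight; the field-standard default for this pipeline. 0 reduces EBIC to BIC. |
| `n_lambda`, `lambda_min_ratio` | 100, 0.01 | penalty path resolution and lower end, the common convention for EBIC-glasso. |
| PD floor | 1e-6 | minimum eigenvalue enforced on the polychoric matrix before glasso; smoothing clips eigenvalues (iterating, because the rescale to unit diagonal can undo a single clip) and reports the largest entry shift. |
| edge tolerance | 1e-8 | $|K_{ij}|$ above this counts as an edge. |
| bootstrap defaults | B = 1000 edge CIs; 250 replicates per drop proportion; grid 0.10–0.75 step 0.05 | conventions of the case-drop stability methodology; all config-exposed. |
| CS threshold | r = 0.7, confidence 0.95 | CS = largest drop proportion at which the original-vs-subsample centrality correlation stays ≥ r with the stated probability. Above 0.5 ideal, below 0.25 unacceptable. |
| cutoffs | burnout > 34 (strict); depression ≥ 5 (inclusive) | read literally from the instruments' screening rules; both configurable, as is optional reverse scoring of the positively worded MBI10–15. |

## Numerical choices

* **Bivariate normal CDF.** A vectorized Gauss–Legendre quadrature
  (Drezner–Wesolowsky, with Genz's reformulation for $|\rho| \ge
  0.925$) evaluates all grid points of a contingency table in one call.
  Agreement with scipy's adaptive integration is at machine precision
  across the correlation range; the target accuracy is 1e-7.
* **Graphical lasso.** scikit-learn's coordinate-descent solver, with
  two adjustments: the inner lasso tolerance is tightened to 1e-7
  (at the default 1e-4 the outer dual gap stalls near 1e-3 and the
  solver burns its iteration budget without formally converging) and
  solutions are warm-started along the descending penalty path. Outer
  dual-gap tolerance 1e-6, at most 500 outer iterations; a fit that
  still has not converged raises rather than returning silently.
* **Degenerate inputs.** Empty categories are collapsed into their
  lower neighbour before thresholding (the lowest collapses upward);
  single-category items raise, or are dropped on request with a
  report. Pairs whose ML search fails fall back to the Spearman rank
  correlation and are flagged. Perfectly duplicated items clip at
  $\rho = 0.999$, the boundary of the ML domain.
* **Rounding.** Reported percentages round half-up (1 decimal for
  prevalence, integer for retention) to match how screening tables are
  conventionally printed; tests compare full-precision values at 1e-9
  except where a printed value is itself the oracle.

## The synthetic-data generator

`CohortSpec.from_network_and_moments` emulates the study cohort:
n = 616 respondents, the published 24-item partial-correlation network,
and the published per-item means/SDs. The latent correlation matrix is
constructed by inverting the partial-correlation parameterization
(precision with unit diagonal and $K_{ij} = -w_{ij}$, inverted and
rescaled), so the generator's implied partial correlations equal the
target network *exactly* — the model under which polychoric + glasso
estimation is consistent, which makes recovery experiments a fair test
of the estimator rather than of misspecification.

Thresholds are calibrated in probability space: any K-point category
distribution is reachable under normal discretization, so a
maximum-entropy pmf $p_k \propto \exp(ak + bk^2)$ is solved to match
the target mean exactly and the SD as closely as the integer support
allows. Several published SDs are infeasible for integer scores (e.g.
an item with mean 0.20 cannot have SD below 0.40 on a 0–3 scale); the
generator then clips to the nearest feasible SD and reports the
residual (strict mode raises with the feasible interval).

What the generator does **not** emulate: shared variance beyond the
sparse partial-correlation structure (real items load on common
factors, so nodewise R² on synthetic cohorts runs far below the ~0.67
average seen on real data), demographic covariates, missing-data
mechanisms, and any misreporting behaviour. Passing recovery tests
therefore demonstrate estimator correctness under the stated latent
model, not robustness to real-survey artefacts.

## Verification strategy and scaled-down problem sizes

The raw survey data are not public, so validation splits in two:

* Everything downstream of the published edge matrix (edge rankings,
  EI/BEI values and orderings, prevalence arithmetic, the
  predictability average) is checked **exactly** against printed
  values, using the shipped fixture. The fixture's single transcription
  conflict (the MBI1–MBI2 cell appears as 0.406 in one triangle and
  0.041 in the other) is resolved to 0.406 — the value consistent with
  the published ranking of within-burnout edges and with MBI2 having
  the highest expected influence; the raw transcription ships alongside
  and the loader reports the conflict. The published per-item
  "expected influence" column is internally inconsistent with the edge
  matrix's row sums and with the published ranking narrative; it is
  carried in the item-info fixture for reference but never used as an
  oracle.
* Estimation from raw data is checked by independent oracles
  (grid search for the polychoric ML, a proximal-gradient solver for
  the glasso objective, closed forms for EBIC and Gaussian R²) and by
  simulation recovery at the study's scale. Pilot runs (20 seeds,
  n = 616) put edge recovery at 69–79% with sign agreement ≥ 98% on
  recovered edges and 93–98% of estimated edges positive; the recovery
  tests assert the floors 70% / all-recovered-positive / 90% at the
  default seed. Small spurious negative edges are an expected feature
  of glasso output at this sample size, so "all edges positive" is
  asserted as this stochastic bound, not literally.

Problem sizes in the test suite and acceptance script are the
package's own choices for routine verification: recovery runs use
single cohorts at n = 616 (plus a 10-seed batch in the acceptance
script), and case-drop stability uses an n = 2000 cohort with drop
grid {0.1, 0.2, 0.3} × 50 replicates — enough resolution to verify the
CS ≥ 0.25 acceptability floor (and capping reportable CS at 0.3 by
construction); production analyses should use the full default grid
and replicate counts.

## Known limitations

* Predictability treats ordinal items as continuous; the mixed-model
  (categorical) nodewise estimation used by some packages is out of
  scope and would give different absolute R² values.
* The polychoric fallback for non-convergent pairs (Spearman) is a
  pragmatic patch, flagged in output, not a principled estimator.
* Difference tests use uncorrected percentile CIs of bootstrap
  differences, matching the convention of the stability methodology
  they mirror; they are descriptive, not familywise-error-controlled.
* The latent-normal model cannot represent items whose published SD is
  infeasible on integer support; those items are simulated at the
  nearest feasible SD with the residual logged.
* CS coefficients depend on the drop grid: a coefficient can only take
  values on the grid, so coarse grids quantize the answer.
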