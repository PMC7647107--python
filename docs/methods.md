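# Methods

`hwtbbn` implements a complete analysis chain for studying the determinants
of household water treatment (HWT) behaviour from a one-visit household
survey: index construction by principal components, quantile discretization,
a three-layer discrete Bayesian belief network estimated by EM, exact
probabilistic interrogation of that network (what-if ΔP inference, CPT
parameter sensitivity, cross-validated prediction), and the supporting
classical statistics (forced-entry OLS, chi-square tests). A synthetic
survey generator with a known ground-truth network makes every stage
testable without access to field data.

## The model

The network has three layers and 14 nodes:

* **Socio-economic characteristics (SEC), 8 root nodes** — recent
  water-related health problem in the household (No/Yes), information
  access (Difficult/Medium/Easy), mother's and father's education
  (None/Primary/Secondary/Higher), relative wealth (Poor/Middle/Rich),
  religion (Christian/Islam), accessibility of the dwelling
  (Difficult/Easy), and distance to the water source (Far/Medium/Close).
* **RANAS psychosocial factors, 5 intermediate nodes** — Risk, Attitude,
  Norm, Ability, Self-regulation, each discretized Low/Moderate/High.
* **HWT behaviour, 1 outcome node** — non-user / irregular user / regular
  user.

Every SEC node is a parent of every RANAS node and the five RANAS nodes are
the only parents of the outcome: SEC influence on behaviour is modelled as
fully mediated by psychology. The mediation structure is a substantive
assumption, not a learned one; `NetworkSpec` accepts any alternative DAG
from a YAML file, and `validate_spec` checks acyclicity and (when layer tags
are present) layer conformance.

## Index construction and discretization

Each construct is summarized by the score on the first principal component
(PC1) of its standardized items: the binary asset checklist for wealth (the
DHS wealth-index construction), the 3–4 survey items of each RANAS factor,
and the five behaviour items for the outcome. Choices the score layer
makes:

* **Correlation-matrix PCA.** Items are z-scored (sample SD, n−1) before
  decomposition, because items sit on heterogeneous scales (1–5 Likert,
  0/1 binary). Scores are therefore invariant to affine rescaling of any
  item.
* **Sign orientation.** PC1 is defined up to sign; the score is oriented to
  correlate non-negatively with the unweighted mean of its (standardized)
  items, so "higher score = more of the construct". Reverse-worded items
  (declared in the codebook) are flipped onto the construct's polarity
  before scoring.
* **Missing items.** A household missing fewer than half of a construct's
  items has the gaps filled with the item's sample mean; a household
  missing half or more gets a missing score, which propagates to a missing
  network state handled by EM. This keeps all households in the network
  stage while leaving the regression to its own listwise deletion.
* **Discretization.** Scores are cut by rank: cutpoints sit at ranks
  ⌈q₁·m⌉ and ⌈(q₁+q₂)·m⌉ of the m non-missing scores (40/40/20 for wealth,
  tertiles otherwise), and a household takes the lowest state whose
  cutpoint value is ≥ its score. Ties at a cutpoint all take the lower
  state — with every score identical the whole sample lands in the lowest
  state — so category counts deviate from the quantile targets by at most
  the number of tied boundary values, and the pipeline is deterministic:
  the same survey always yields a byte-identical discrete dataset.

## CPT estimation

With complete data, each conditional probability table (CPT) cell is
`(count + s/k) / (row_total + s)` where `k` is the node's state count and
`s` (`prior_ess`) is a symmetric Dirichlet pseudo-count per row; rows never
observed (and `s = 0`) fall back to uniform. Under missing states, EM
alternates exact inference (each household's posterior over the missing
members of each node family, by variable elimination given that household's
observed nodes) with the same smoothed re-estimation. Households are
grouped by identical observation patterns so inference runs once per
pattern. Rows with no observed node at all are dropped with a warning —
they contribute nothing to the likelihood.

* **Default `prior_ess` = 1.** The SEC→RANAS CPTs have 3,456 parent
  configurations each; a small survey determines almost none of their rows,
  and unsmoothed maximum likelihood would leave most rows undefined. The
  cost is visible shrinkage: on a 202-household survey the learned ΔP
  spreads sit well below the generating model's. The parameter-recovery
  experiment uses `prior_ess = 0` instead, because a consistency check
  measures the estimator's convergence to the generating CPTs and a fixed
  prior would bias it at any finite n.
* **Initialization** defaults to uniform CPTs (deterministic); seeded
  random Dirichlet restarts are available.
* **Convergence**: relative change of the EM objective below `tol = 1e-6`,
  `max_iter = 500`. With `prior_ess > 0` the objective EM maximizes (and
  the quantity asserted monotone on every run) is the Dirichlet log
  posterior; with `prior_ess = 0` it is the raw log-likelihood. Both traces
  are stored in the model metadata.

## Inference

Two exact routes: brute-force enumeration of the factored joint (an oracle,
guarded to ≤ 10⁷ configurations) and variable elimination with a min-degree
ordering and lexicographic tie-breaks (the production path). They agree to
1e-9 on randomized network suites. Evidence with zero probability raises an
explicit "impossible evidence" error rather than returning NaNs.

## Model interrogation

* **ΔP predictive inference.** For each non-outcome node and each of its
  states, the node is clamped as hard evidence and the updated
  P(outcome = regular user) recorded in percent; a node's ΔP is the spread
  (max − min) across its states. Updated probabilities are reported at
  integer precision, but ΔP is computed on unrounded values and rounded
  last, so the printed spread is consistent with the printed column up to
  rounding.
* **Scenario propagation** returns the full outcome posterior when a node
  follows an arbitrary state distribution: degenerate distributions are
  hard evidence; otherwise the posterior is the distribution-weighted
  mixture of per-state posteriors, so clamping a node at its own marginal
  is a no-op.
* **Parameter sensitivity.** Under proportional co-variation (moving one
  CPT entry θ while rescaling the row's complement to keep the row a
  distribution), P(target | evidence) is a ratio of two functions linear in
  θ. The per-parameter route fits that linear-fractional form exactly from
  three evaluations and differentiates it analytically. The full-report
  route exploits multilinearity instead: replacing a node's CPT with an
  all-ones table, a single unnormalized variable-elimination pass over
  (target ∪ family) yields ∂P/∂θ for all of that node's parameters at once.
  Both routes agree with central finite differences to 1e-6; parameters at
  0 or 1 get one-sided perturbation (uniform complement redistribution at
  θ = 1). The per-node aggregate is the maximum absolute derivative.
* **Cross-validation.** Stratified k-fold (default k = 10, seed 0) on the
  observed outcome states; households with a missing outcome always train,
  never score. Each fold's model is EM-learned on the remaining folds and
  held-out households are scored from all their observed non-outcome nodes.
  AUC is one-vs-rest by the rank (Mann–Whitney) statistic with ties counted
  half, summarized as the unweighted macro average — the multiclass
  aggregation is a reporting choice, stated here because common practice
  varies. Accuracy is the argmax hit rate (ties broken by state order). If
  a training split loses an outcome state entirely, folds are rebuilt with
  an incremented seed and a warning.

## Supporting statistics

The forced-entry regression puts all 16 RANAS items simultaneously on the
continuous behaviour score, with listwise deletion; it reports
unstandardized B, SE(B), standardized β = B·sd(x)/sd(y), t, two-sided p
(starred at 0.05/0.01/0.001), and adjusted R². The binary barrier-planning
item enters as raw 0/1. Rank-deficient designs are rejected with the
collinear columns named. Chi-square tests of independence are Pearson
(no continuity correction) on the cross-table of two discrete columns,
dropping pairs with a missing side.

## The synthetic generator

`generate` samples each household's 14 node states ancestrally from a
ground-truth network, then emits observable survey answers: Likert items as
`round(clamp(Normal(μ_state, σ), 1, 5))` with state means (2, 3, 4) and
σ = 0.8 by default; binary items (barrier planning, self-reported
treatment) and assets as Bernoulli draws with state-dependent
probabilities; SEC answers directly as the sampled category. Every emitted
cell is independently masked missing with probability ρ (default 0.015,
matching a survey in which roughly a fifth of households have at least one
gap across the 17 regression variables). Everything is reproducible from a
single seed.

Ground-truth CPTs use a monotone softmax parameterization: parent states
map to centred levels in [−1, 1], and a weighted sum of parent levels
shifts the child's distribution through a per-state slope, with one weight
per edge. The default weights and offsets were calibrated once, by running
exact inference on the model itself, so the true model encodes the study
conditions: no-evidence baseline P(regular user) = 31%; ΔP spreads 19
(self-regulation), 16 (ability), 11 (attitude), 10 (norm), 6 (risk), 10
(mother's education, acting through attitude and ability), ≈2–3 for the
remaining active SECs, and exactly 0 for child diarrhea and distance to
water; RANAS marginals near (0.40, 0.35, 0.25); outcome marginal near
(0.36, 0.33, 0.31), with a self-reported-treatment rate near 38%. SEC
marginals use the study's reported descriptives where available (55%
recent child diarrhea, 16.8%/25.7% of mothers/household heads without
formal education, 45.5% in-dwelling tap) and realistic values elsewhere;
wealth is (0.40, 0.40, 0.20) by construction of the index.

**What the generator does not emulate.** Item-level response styles
(acquiescence), missing-not-at-random mechanisms, and — importantly — the
strong direct item-to-behaviour correlations a real survey exhibits: all
dependence flows through the discrete latents, so the synthetic regression
R² and cross-validated AUC are far below what a real survey of this kind
yields. Passing tests on synthetic data therefore demonstrate correctness
of the machinery and consistency of the estimators, not field-data effect
sizes for the regression/CV diagnostics.

## Recovery experiment and test problem sizes

`recovery_experiment` generates a survey, runs the full pipeline
(scores → discretize → EM), and compares the learned model to the truth by
(a) per-CPT reach-weighted mean L1 row distance — rows weighted by the
probability of their parent configuration under the truth, summarized as
the median over the 14 CPTs (the 3,456-row SEC→RANAS tables are reported
individually too: at n = 5000 they average ~1.5 observations per row and
their row-wise error is necessarily large, which the median deliberately
does not hide) — and (b) whether the learned ΔP ordering agrees with the
truth for every node pair at least 5 points apart.

Test and acceptance runs use: n = 5000, ρ = 0, σ = 0, ML estimation,
20 seeds for recovery (median CPT L1 ≈ 0.026, ranking agreement 19/20); a
single n = 100,000 run for the null-model check, sized so the Monte-Carlo
noise floor of a clamped posterior (~0.26 percentage points) sits well
below the 1-point tolerance asserted; and n = 202 with the default
σ = 0.8, ρ = 0.015 for the study-sized pipeline runs. These sizes are the
package's chosen experimental design and are encoded in the tests and in
`scripts/acceptance.py`.

## Numerical conventions and edge cases

* CPT rows must sum to 1 within 1e-9; posteriors are normalized once at the
  end of elimination.
* Zero-variance items are dropped from PCA with a warning; an all-constant
  item matrix is an error.
* Argmax and elimination-order ties break deterministically (state order,
  node name).
* Percentages are reported on the 0–100 scale; probabilities on 0–1.

## Known limitations

* No structure learning, continuous/hybrid nodes, or approximate inference;
  the joint interrogations assume the shipped mediation DAG or a
  user-supplied alternative.
* With 8-parent CPTs and survey-sized n, the Dirichlet default shrinks
  SEC-layer effects hard; learned ΔP at n ≈ 200 understates generating
  effects substantially. This is a bias-variance choice, not an estimator
  defect (the recovery experiment quantifies the ML behaviour).
* One-way sensitivity only; no value-of-information analysis.
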