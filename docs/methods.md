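# Methods

## Generating model

Each simulated dataset has three ordered groups on a single continuous
predictor. Group k draws x from N(μ_k, 1) with equally spaced means
μ = (0, d, 2d), so the standardized mean difference between adjacent groups
is exactly d (population variance 1 within every group). Cut-points sit at
the adjacent-mean midpoints (d/2, 3d/2), the equal-variance, equal-cost
boundary. Group labels are assigned first at the exact design counts
(ratio scaled to the total n and permuted), then scores are drawn given the
labels.

Design factors and defaults (the study conditions):

| factor | levels |
|---|---|
| confusion topology | BC, AB/BC |
| total n | 150, 1500 |
| group-size ratio | 50:50:50, 25:25:100, 25:100:25, 100:25:25 |
| adjacent-group separation d | 0.2, 0.5, 0.8, 1.6 |
| injected mislabeling π | 0, 0.10, 0.20, 0.30 |
| replications per cell | 1000 (default grid) |

## Label-noise injector

The injector emulates cut-score mislabeling: the probability that a case's
observed label is wrong decreases with the case's cumulative position inside
its own group, oriented toward the boundary it can be confused across.

- Edge group whose confusable neighbor lies above: p = 1 − F_g(x);
  below: p = F_g(x); middle group with both neighbors:
  p = 2·min(F_g(x), 1 − F_g(x)), where F_g is the within-group normal CDF.
  This is the unique simple construction making p exactly Uniform(0,1)
  within each group (probability integral transform), which the calibration
  below requires.
- A case flips when an independent u ~ U(0,1) exceeds k·p. Since p and u
  are independent uniforms, P(flip) = P(U > kP) = 1/(2k) for k ≥ 1, so
  k = 1/(2π) realizes any target π ≤ 0.5 exactly in expectation, and k = 1
  flips about half the cases. The closed form is verified against a
  10⁶-draw Monte Carlo oracle in the test suite.
- A flipped case moves to the group it is next most likely to belong to:
  edge groups move one step inward; the middle group moves down when
  x < μ_2 and up otherwise. The extreme confusion (group 1 ↔ group 3)
  never occurs under either topology.
- Calibration is per eligible case (non-differential): every eligible group
  flips at rate π. Under AB/BC all three groups are eligible; under BC in
  `strict` mode group 1 is never flipped, while the `uniform` mode makes
  every case eligible with the nearest adjacent group as destination. The
  default is `strict`, the reading in which a topology's ineligible group
  is untouched; all calibrated-rate analyses here use AB/BC cells, where
  the two readings coincide.

One caveat the implementation makes explicit: "boundary-proximal" means low
own-group membership probability, not literally small |x − cut-point|. For
the middle group the flip-prone region is both tails, so flipped middle
cases are on average *farther* from the cuts than the unflipped center mass,
while for the edge groups the literal distance comparison holds. The tests
assert the membership-probability property for all groups and the distance
property for the edge groups.

## Classifiers

All methods fit on the observed (noisy) labels of an (n, 1) predictor
matrix and predict total labels; score ties break deterministically toward
the lower-ordered group.

- **LDA** — per-class scores C_k(x) = c_k0 + c_k x + ln(n_k/N) with
  c_k = μ̂_k/s², c_k0 = −μ̂_k²/(2s²); s² is the pooled maximum-likelihood
  within-group variance (denominator N, which makes the mixture-discriminant
  degeneracy below exact).
- **QDA** — same Gaussian discriminant with a separate ML variance per group.
- **LR** — multinomial (softmax) logistic regression by maximum likelihood
  (scikit-learn, unpenalized). The two-group log-odds model extends to three
  groups class-symmetrically.
- **CART** — greedy binary splitting minimizing the summed child deviance
  D_m = −2 Σ_k n_mk ln p_mk (0·ln 0 ≡ 0); growth stops when no split lowers
  deviance or the size guards bind (min-split 20, min-terminal 7 — standard
  recursive-partitioning defaults, needed because pure deviance descent
  never stops on a continuous predictor). Equal-deviance split ties take
  the lowest threshold. Terminal nodes predict their plurality group.
- **RF** — n_trees (default 1000; 200 in the desk-scale profile) fully
  grown deviance trees on with-replacement case bootstrap samples of size
  n, majority vote. With one predictor the predictor-subsampling step is
  vacuous. Implementation note: a fully grown tree on distinct 1-D points
  is exactly the 1-nearest-neighbor rule with midpoint thresholds over its
  bootstrap sample (purity forces a cut between every adjacent
  opposite-label pair, and extra cuts cannot change predictions), so each
  tree is evaluated by nearest-bootstrap-neighbor lookup. The test suite
  checks this equivalence label-for-label against an explicitly grown
  tree. Forest trees are fully grown rather than size-guarded; that is
  what makes the forest's resubstitution error ≈ 0 on clean labels and
  ≈ π under injected noise.
- **GAM** — class logits are cubic B-spline expansions (10 basis functions,
  equally spaced knots) fitted by penalized multinomial likelihood with a
  second-order difference penalty of weight λ = 1.4 (the conventional
  default, exposed in config). The penalty nullspace is exactly
  {constant, linear}, so λ → ∞ recovers the multinomial-logit fit. The
  quadratic penalty is whitened through its eigenbasis before quasi-Newton
  descent; without that rescaling the optimizer stalls at large λ.
- **MIXDA** — each class is a mixture of Gaussian subgroups (default 3 per
  class) fitted by EM: subgroup means, mixing proportions, and either one
  common variance across all subgroups (default) or one per class.
  Initialization draws distinct subgroup centers from the class's own
  points using the classifier's RNG stream; tolerance 1e−6 on the total
  log-likelihood, at most 500 iterations, non-convergence flagged with the
  best iterate kept. Classification is by prior × mixture density. With one
  subclass and common variance the model reduces exactly to LDA.
- **NNET** — one logistic hidden layer (5 units) and logistic outputs,
  trained to minimize Σ_i Σ_k (y_ik − ŷ_ik)² plus a weight-decay penalty
  0.1·Σw² via back-propagated gradients and L-BFGS from small random
  initial weights; a non-finite fit restarts from a fresh draw (at most 3).
  Defaults are small-problem conventions, exposed in config.

## Evaluation protocol

Predictions are made on the training cases (resubstitution) and scored
against the **true** pre-noise labels, overall and per group — the reference
can be switched to the observed labels in config. Resubstitution against
truth is what makes the forest a noise meter: its votes reproduce the
observed labels almost perfectly, so its group-k error equals the fraction
of group-k labels that were flipped (≈ π), and ≈ 0 on clean data.

## Experiment runner and ANOVA

The runner crosses all factors (256 cells by default), simulates each
(cell, replication) from a dedicated SeedSequence child of the master seed
(classifier randomness gets a further derived stream), and emits one row of
rates per (method, cell, replication). Marginal tables are simple means at
each factor level — valid because the design is balanced. Degenerate fits
are logged and skipped as missing rows.

The ANOVA treats each (cell, replication) as a subject measured under every
method: method is the within-subject factor, the four design factors are
between-subject factors, and the classical balanced split-plot decomposition
is used (between terms tested against subjects-within-cells, method terms
against method × subject; no sphericity correction). Effect size is
classical η² = SS_term/SS_total — "proportion of variation explained" — and
a term is flagged important when p < 0.05 and η² ≥ 0.1. Unbalanced tables
are rejected with a diagnostic rather than silently reweighted. The
between-subject stratum is verified against an ordinary least-squares ANOVA
on subject means in the tests.

## Desk-scale profile and reproduction targets

The published headline numbers are Monte Carlo marginal means over the
balanced design, so they are reproducible at reduced replication counts
within sampling error. `scripts/acceptance.py` uses 50 replications/cell
with 200-tree forests for the noise-level marginals and 100
replications/cell for the zero-noise marginals — sizes at which the Monte
Carlo standard error of a marginal over ≥1600 rows is well below 0.01.

What this model can and cannot reproduce:

- The forest's noise-tracking marginals (group-1 rate ≈ 0.1/0.2/0.3 at the
  three injection levels over AB/BC cells, ≈ 0 at π = 0) reproduce tightly,
  as do the qualitative patterns: rates fall monotonically with separation
  for the discriminants and the forest is flat (range < 0.02) across
  separation.
- The published zero-noise per-group marginals for the discriminants and
  the tree are **not** attainable under this generating model, for a
  structural reason: the model is exactly symmetric under reversing the
  group order (equally spaced means, unit variances, a ratio set closed
  under reversal), so every zero-noise marginal over ratios must give equal
  group-1 and group-3 rates, and equal generating variances force LDA and
  QDA to agree asymptotically. The published zero-noise row is strongly
  asymmetric in exactly those places, so it reflects some asymmetry of the
  original (undocumented) generator. The acceptance script reports this
  package's measured values for those targets (LDA ≈ (0.47, 0.65, 0.47),
  QDA ≈ the same, CART group 1 ≈ 0.36), which also match closed-form
  normal-theory boundary calculations to Monte Carlo error.
- Under this model the non-forest overall rates rise steadily with the
  injected proportion (LDA marginal ≈ 0.34, 0.36, 0.40, 0.43 over
  π = 0…0.3); the published pattern of no impact below π = 0.3 does not
  appear, consistent with the zero-noise discrepancy above.

## What the generator does not emulate

Real cut-score data differ from this model in ways that bound what passing
tests show: predictors are rarely exactly normal or homoscedastic, true
group structure is rarely equally spaced, mislabeling can be differential
across groups, and applied classification is usually judged on held-out
cases rather than resubstitution. Results here quantify method behavior
under the idealized mechanism, not field accuracy of any method.

## Numerical choices

Ties in classification scores and votes break toward the lower group;
variance floors (1e−8 of the total variance) guard EM against subclass
collapse; the tree's "no deviance decrease" stop uses a 1e−9 absolute
tolerance; spline fitting clamps prediction inputs to the training range;
the logistic-regression and spline optimizers run to machine-practical
tolerances (ftol 1e−12, gtol 1e−8). All randomness flows from
numpy SeedSequence spawning, so every cell, replication and classifier
stream is reproducible from one master seed.
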