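# Methods

## Model and scope

`ubiqtree` quantifies the uncertainty of SHAP feature attributions for
*bagged* tree ensembles (random forests and hand-built forests of
classification trees). Boosted ensembles are out of scope: the hypothesis
reading — each tree is an exchangeable, independently plausible account of
the data — holds for bagging but not for stage-wise boosting.

The pipeline has five stages. Each is implemented as an independently
testable module; the CLI and `run_ubiqtree` only compose them.

### Tree reliability and the base measure

Per-tree out-of-bag (OOB) accuracy is the fraction of rows outside a tree's
bootstrap sample it classifies correctly (argmax over per-class scores,
lowest index on ties). For scikit-learn forests the bootstrap membership is
reconstructed by replaying the estimator's recorded RNG draw
(`randint(0, n, n)`), which reproduces scikit-learn's own sampling exactly;
for ensembles without recoverable membership a user-supplied holdout set is
required. A tree with an empty OOB set falls back to full-training-set
accuracy and the event is recorded as a warning.

The per-tree accuracy score (not a one-vs-rest AUC) feeds a softmax with
temperature β ≥ 0: β = 0 gives uniform weights, larger β concentrates
weight on reliable trees. Accuracy is the overall multiclass accuracy;
a per-class variant was considered and rejected because the sampling layer
needs a single simplex over trees.

### Hypothesis sampling

Sub-ensembles are finite-dimensional Dirichlet draws: π ~ Dirichlet(α·w)
with the parameter vector floored at 1e-8 (gamma-sampler stability), then
`n_draw` tree indices i.i.d. Categorical(π) with replacement. Defaults:
α = 0.5, β = 5, S = 30 hypothesis samples, `n_draw = K`. The `n_draw = K`
default keeps a sub-ensemble's prediction variance on the scale of the
parent forest and matches the Bayesian-bootstrap reading of the posterior;
it is configurable.

The α direction follows the Dirichlet mathematics: E[π] = w for every α;
small α concentrates each draw's mass on few trees, large α makes draws hug
the base measure. Because prose summaries of concentration parameters are
frequently contradictory, the package exposes `effective_diversity` (the
exponential of the Shannon entropy of a sample's index frequencies) so the
realized behaviour is directly observable; the test suite pins the ordering
(diversity increases with α, π-variance decreases).

Seeding: one root `SeedSequence` spawns a child stream per sample, so
growing S extends the sample list without perturbing earlier samples.

### Interventional SHAP with an exhaustive oracle

The value function is interventional:
v(S) = mean over background rows b of f(x_S, b_∖S). For a single decision
tree this has an exact closed form by enumerating leaves: per leaf, path
conditions are intersected into one interval per feature; against a given
background row each path feature is then *irrelevant* (both x and b
satisfy), *required* (only x satisfies), *forbidden* (only b), or kills the
leaf (neither). The restricted game is a conjunction game whose Shapley
values are ±leaf·(r−1)!f!/(r+f)! (required) and −leaf·r!(f−1)!/(r+f)!
(forbidden), averaged over the background. Cost is
O(leaves × path features × |X| × |B|), vectorized over instances and
background rows; weights are tabulated via log-gamma so deep paths cannot
overflow.

The interventional convention (rather than the path-dependent one) was
chosen because it admits a clean independent oracle: `brute_force_shapley`
enumerates all 2^d coalitions (d ≤ 12) under the *same* value function, and
the suite requires agreement within 1e-8 on hundreds of random trees.
Local accuracy (Σφ + base = f(x)) holds to machine precision by
construction and is asserted for every tensor cell.

Per-class probability outputs are explained; all downstream statistics are
per class. The background defaults to a fixed-seed subsample of the
training matrix capped at 128 rows: interventional SHAP is linear in the
background distribution, so a modest cap bounds cost without biasing the
estimate beyond Monte-Carlo error.

Sub-ensemble aggregation (one hypothesis sample): per-slot tree SHAP
(multiplicity respected), slot mean φ_mean, between-tree feature covariance
Σ per instance and class, and the interaction-adjusted
φ_adj = φ_mean + ½·diag(Σ). φ_adj breaks local accuracy by design (it adds
half a variance), so it is reported as a separate quantity and never fed
into the decomposition, which consumes the raw per-tree distributions.
Per-tree values are cached per distinct tree across all samples, so the
tensor cost is K tree explanations regardless of S.

### Variance decomposition

Within-sample replicates are the per-tree SHAP values of a sub-ensemble;
between-sample units are sub-ensemble means. A = mean of within-sample
variances, E = variance of within-sample means, C = covariance of the two,
total = A + E − C. All moments use the population (divide-by-n) convention
— chosen once, consistently with the SHAP layer, so the law-of-total-
variance identity (pooled variance = A + E when C = 0) is exact in tests
rather than approximate.

The population-level decomposition of attribution variance and the finite-S
estimator computed here are distinct objects: the estimator is what the
package reports, and `total = A + E − C` is defined from the estimator, not
forced to equal any pooled variance. The decomposition runs per instance
and is averaged over the explanation set for the class-level report
(aggregation order is a genuine free choice; per-instance output remains
available in the API).

One estimator subtlety matters for nulls: across i.i.d. sub-ensembles,
E[C] is proportional to the *third central moment* of the per-tree SHAP
distribution, so C is unbiased-zero only when that distribution is
symmetric. The independence-null test therefore uses a label-swap-closed
forest on a label-symmetric two-class scenario — for such data, training on
the swapped labels yields identical splits with exchanged leaf
probabilities, so the mirrored trees are exactly the trees the same
algorithm would produce on the swapped dataset, and the per-tree attribution
distribution is symmetric by construction.

### Aggregation and classification

Per feature/class the sample fed to the summary statistics is the
per-sub-ensemble mean SHAP (one value per hypothesis sample). Reported:
mean; population std; 95% credible interval by linear-interpolation
percentiles; differential entropy; sign stability; category and action.

*Entropy estimator.* Gaussian KDE with Scott's-rule bandwidth, evaluated on
a 512-point grid over [min, max] with boundary reflection (density at g is
kde(g) + kde(2·min − g) + kde(2·max − g)), renormalized and integrated as
−∫p log p. The reflection term removes the O(h) boundary bias that a plain
KDE suffers on compactly supported samples — without it the entropy of
Uniform(0,1) at n = 5000 is overestimated by ≈ 0.10 nats; with it the
estimator is within ~0.01 of the closed forms for uniform and Gaussian
samples and is exactly translation-invariant and scale-equivariant. Zero
spread returns a −inf sentinel with a degenerate flag; fewer than 10
samples are refused (the KDE is meaningless below that).

*Sign stability.* Fraction of samples matching the majority sign; zeros
count with the majority (an attribution of exactly zero contradicts
neither sign); an exact positive/negative tie is 0.5. Categories:
high ≥ 0.90 > moderate ≥ 0.67 > low — the inclusive-from-above monotone
reading of the three-band scheme. Action bands on the epistemic std:
automated ≤ 0.05 < expert_verification ≤ 0.1 < retrain. Published
three-band threshold prose is often internally inconsistent; both mappings
here are the monotone repairs and are property-tested as monotone step
functions.

Both the percentile credible interval (tables) and the ±2σ band (plots) are
produced, since both conventions are in common use.

### Evidence layer

The frame of discernment is M equal-width cells over the observed SHAP
range (default M = 10 — enough resolution to localize a distribution at
S = 20–50 sources without starving cells of evidence; configurable). Each
evidence source is a sub-ensemble and its focal element is the *set* of
cells its per-tree values hit, with mass 1/n_sources. This set-valued
construction is deliberate: assigning each source's mass additively over
cells would make the mass function a probability measure, collapsing
belief = plausibility and forcing the conflict measure to zero. With
set-valued evidence, point sources reproduce the classical
proportion-of-trees singleton assignment exactly, while dispersed sources
generate genuine Bel < Pl gaps. Out-of-range queries (possible when a
partition built on one sample set is queried with another) clamp to the
nearest cell with a warning.

Belief/plausibility satisfy Bel ≤ Pl, Bel(A) + Pl(Ω∖A) = 1, and the
frequency limit: as i.i.d. point sources grow, singleton belief converges
to the true cell probability (asserted at 50/500/5000 sources with strictly
shrinking error). Dempster's rule of combination is intentionally not
implemented — no stage combines mass functions across bodies of evidence.

The uncertainty distribution Γ is the empirical CDF of the per-sample SHAP
values (0 below the observed minimum, 1 at the maximum, monotone, crossing
0.5 at the median). Its entropy reuses the shared KDE estimator. The
acquisition ranking orders features descending by SHAP variance with
Γ-entropy as tie-break: the variance is the leading-order rate at which
additional data reduces uncertainty entropy, so the top of the list is
where new data buys the most certainty. Expected-posterior-entropy
acquisition over candidate instances is not implemented; only the
variance-based ranking is.

## Synthetic scenarios

`make_dataset` draws standardized numeric features (categoricals as integer
codes with per-level effects), computes sparse linear logits over the
informative set, adds log-ratio intercepts for the class mix, samples labels
from the softmax, and optionally flips labels uniformly at the noise rate.
The coefficient scale default (2.0, four informative of ten features, three
classes) puts baseline Bayes accuracy near 0.85 — high enough that
attributions are meaningful, low enough that the noise and sample-size
sweeps visibly move the aleatoric and epistemic components.

Presets: `baseline`; `label_noise_{0,0.1,0.2,0.3}`; `n_{200,500,2000}`;
`imbalance` (four classes at 60/20/15/5, the shape of registry-scale risk
strata); `collinear` (exactly duplicated column). Rows are i.i.d. — the
generator does not emulate longitudinal or hourly structure, so passing
tests say nothing about serially correlated clinical data; nor does it
model missingness, measurement error or covariate shift. What the tests do
establish: the decomposition's components move in the right direction along
the noise and sample-size axes, attributions concentrate on truly
informative features, and every statistic is exactly reproducible per seed.

`make_fixture_forest` builds ensembles from hand-written node tables with
hand-chosen bootstrap masks, so OOB accuracies and SHAP values are countable
by hand in the oracle tests.

## Numerical choices and degenerate inputs

- Population variance everywhere; percentile CIs by linear interpolation.
- Softmax with max-subtraction; Dirichlet parameters floored at 1e-8.
- Argmax ties resolve to the lowest class index (determinism).
- Single-slot sub-ensembles have Σ = 0 by definition; S < 2 is an error
  (epistemic variance undefined).
- Zero-spread sample sets: degenerate partition flag, −inf entropy
  sentinel, flagged-null Pearson ρ.
- Conflict is clamped to [0, 1] against float-summation drift.
- Problem sizes in the default test and acceptance runs (K = 50 trees,
  S = 20 samples, 100 explained instances, 128 background rows) were chosen
  as comfortable desk-scale settings; all are configurable upward, and the
  S = 500 header-scale setting is a flag away (`--n-samples 500`).

## Known limitations

- Only bagged ensembles are first-class; boosting-specific weighting is
  unsupported.
- SHAP interaction values (pairwise) are not computed; the ½·diag(Σ)
  adjustment is a between-tree dispersion correction, not an interaction
  index.
- The Gaussian-process large-K limit of the sampled SHAP distribution is
  not checked quantitatively.
- The entanglement estimator's null is exactly zero only under symmetric
  per-tree attribution distributions (see above); on skewed problems a
  small systematic C of either sign is expected and real.
- Explanations are computed against per-class probabilities; margin or
  log-odds outputs would need a different tree-value mapping.
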