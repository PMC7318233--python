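# Methods

## Model and pipeline

The package analyzes an n×p matrix of binary symptom indicators under the
standard psychometric-network model for dichotomous data.  The generative
assumption is a latent-Gaussian threshold (probit) model: patient i carries
a latent vector zᵢ ~ N(0, R) with correlation matrix R, and item j is
scored present when zᵢⱼ exceeds a threshold tⱼ.  Under this model the
tetrachoric correlation *is* the population parameter Rⱼₖ, which makes the
whole pipeline — and its validation by parameter recovery — internally
consistent.

### Tetrachoric correlation

Estimation is two-step, per pair: thresholds are fixed at tⱼ = Φ⁻¹(1 − p̂ⱼ)
from the marginal proportions, then ρ maximizes the multinomial
log-likelihood of the 2×2 table over (−0.999, 0.999) by bounded Brent
search (xatol 1e-8).  Joint ML over (ρ, t₁, t₂) differs negligibly at
cohort-scale n and is three times slower.  Choices:

- **Zero cells**: 0.5 is added to every cell when any cell is zero
  (continuity correction; keeps the likelihood finite).  Configurability
  was considered and rejected — the correction only matters for tables the
  estimator cannot otherwise handle.
- **Degenerate margins** (an item always present/absent): ρ is not
  identified; the pair is set to 0 with a warning and the item is flagged.
- **Bivariate normal CDF**: Genz's hybrid Gauss–Legendre scheme
  (`_bvn.py`), deterministic with absolute error ≈ 5e-16.  scipy's 2-D
  `multivariate_normal.cdf` is QMC-based and therefore neither as fast nor
  bit-reproducible; it serves as a cross-check in the tests instead.
- **Bound ±0.999**: keeps the downstream matrix inversion finite.
- **PSD repair**: a pairwise-assembled matrix can be indefinite; if the
  smallest eigenvalue is below the floor (default 1e-6), eigenvalues are
  clipped at the floor and the matrix rescaled to unit diagonal.  The
  repair is recorded (`psd_repaired`, `min_eigenvalue_before_repair`).

### Penalized network estimation

The network is the Gaussian graphical model fitted to the tetrachoric
matrix: edge weights are partial correlations wᵢⱼ = −κᵢⱼ/√(κᵢᵢκⱼⱼ) of the
precision matrix κ.  κ maximizes the L1-penalized log-likelihood
`logdet κ − tr(Sκ) − λ Σᵢ≠ⱼ|κᵢⱼ|` (diagonal unpenalized).  The solver is
the classic block coordinate descent over the working covariance with
soft-thresholded inner lasso sweeps, compiled with numba (`_glasso.py`);
convergence when the largest parameter change in a sweep is < 1e-6.  A
dedicated solver is used because sklearn's coordinate-descent backend
fails its own duality-gap stopping rule on a large fraction of penalty
values for tetrachoric inputs, and its LARS backend is ~500× slower than
needed for bootstrap re-estimation.  The solver is validated in the test
suite against a generic Nelder–Mead optimizer on 3-node problems
(objective within 1e-6) and against sklearn's LARS solutions during
development (objective agreement ~4e-13).

The penalty path has 100 log-spaced values from λ_max = max|S_offdiag|
down to 0.01·λ_max, warm-started downward.  Model selection minimizes
`EBIC = −2ℓ + E log n + 4 E γ log p` with ℓ = (n/2)(logdet κ − tr(Sκ)),
E = number of nonzero edges (|w| > 1e-10 — the lasso produces exact zeros;
the tolerance guards float noise), and γ = 0.5, the established default
for this pipeline.  Ties go to the larger λ (sparser model).  n is the
number of complete-case rows.

The force-directed layout is a plain Fruchterman–Reingold annealer using
|w| as attraction strength, without post-hoc rescaling, so that a more
strongly tied pair genuinely ends closer; networkx's `spring_layout`
rescales its output, which destroys that contract across graphs.

### Spin-glass communities

Communities minimize a signed-weight Reichardt–Bornholdt Potts
Hamiltonian: H(σ) = −Σᵢ<ⱼ δ(σᵢ,σⱼ)·Bᵢⱼ with couplings B = W − γ·ssᵀ/(2m),
where the null-model strengths s and total weight m are computed from
absolute weights (the LASSO network can contain negative edges; a variant
with separate positive/negative null terms is available via
`null_model="signed"`).  Optimization is single-spin-flip simulated
annealing with the published parameterization (start temperature 1, stop
0.01, geometric cooling 0.99, at most 17 spin states — honored as an upper
bound, capped at p).  After annealing, a deterministic greedy
best-single-move descent runs to a local optimum, and the all-singleton
and one-community partitions are always evaluated as candidates, so the
returned energy is never worse than either trivial partition.  One restart
by default; more are configurable.  Community ids are contiguous from 1 in
order of first appearance; partitions are compared as set partitions, not
by label values.

`isolate_outliers` flags nodes whose total absolute connection weight is
below tolerance.  An isolated node has zero coupling everywhere, so its
community placement is energy-neutral; the largest-cluster report excludes
flagged isolates.

### Centrality

- strength: Σⱼ|wᵢⱼ| (absolute weights by default; the signed variant,
  "expected influence", via `signed=True`),
- closeness: with edge distance 1/|w| and Dijkstra shortest paths,
  closeness_i = (rᵢ/(p−1)) / Σⱼ dᵢⱼ over the rᵢ reachable nodes — the
  reachability scaling penalizes small components and isolates score 0,
- betweenness: Brandes on the same distances, fractional credit for tied
  shortest paths, endpoints excluded, unnormalized.

The 1/|w| distance transform is the toolchain convention for this kind of
analysis; −log|w| alternatives are out of scope.  Each index is reported
raw, z-standardized (sample sd), and dense-ranked (ties share a rank).

### Stability

The CS-coefficient uses the case-dropping bootstrap: for each drop
proportion q in {0.05, 0.10, …, 0.75}, n_boot subsamples of size
⌈(1−q)·n⌉ are drawn without replacement, the entire pipeline (tetrachoric
→ EBIC-GLASSO → centrality) is re-run, and the subsample centralities are
correlated with the full-sample ones.  CS is the largest q such that the
correlation is ≥ 0.7 in ≥ 95% of bootstraps at q *and every smaller
tested q* (0 if the smallest fails); the 0.75 grid maximum is why CS can
top out at 0.75.  Proportions are evaluated in increasing order and the
scan stops once every index has failed, which cannot change any
CS-coefficient.  Correlation is product-moment by default with a Spearman
option (the rank-correlation reading of the rule); a replicate whose
subsample is smaller than 3p, or whose centrality vector is constant, is
counted as failing/skipped rather than imputed.  Interpretation flags
follow the convention: interpretable above 0.25, preferred above 0.5.
n_boot defaults to 1000 and is reduced for desk-scale runs.  One master
seed derives an independent stream per (proportion, replicate), so any
replicate is reproducible in isolation.

The difference test resamples cases with replacement, re-estimates the
network, and forms percentile 95% CIs of every pairwise edge–edge and
strength–strength difference; a difference is significant when its CI
excludes 0.  Resamples in which an item becomes constant are skipped and
counted.

### Orchestration

`run_analysis` runs the full pipeline on the overall cohort and on each
declared subgroup level, skipping subgroups below a minimum n (default
150 — small-subgroup networks of this kind are known to be unstable).  A
single YAML config and one seed fully determine a run; the JSON report is
byte-identical across repeated runs except for its timestamp, and carries
a config hash, seed, and package version as provenance.

## Synthetic cohorts: what they emulate and what they do not

`simulate.generate` draws latent multivariate normals (Cholesky), applies
the prevalence-implied thresholds, and optionally assigns subgroup labels
with per-level overrides of prevalences and/or latent correlation
(largest-remainder apportionment of level sizes).  The default template
uses the published ten-item prevalence margins of the reference depression
cohort (n = 1174; e.g. persistent sadness 73.2%, guilt 15.8%) so synthetic
cohorts have realistic marginal imbalance.

Three planted structures give downstream stages exact ground truth:

- `make_planted_network`: block-constant latent correlation with a known
  community partition (community-detection truth),
- `make_matching_precision`: disjoint conditionally dependent pairs with
  equal moderate partial correlations (0.35).  This is the edge-recovery
  benchmark: every true edge is comfortably detectable at n = 5000 while
  noise edges remain sub-threshold, so sensitivity/FPR measure the
  selection rule rather than borderline detectability,
- `make_hub_chain_precision`: a hub, a chain of weakening ties, and an
  isolate, spanning node strengths from ~1.2 to 0.  This is the stability
  benchmark: case-dropping stability is about preserving a node *ordering*
  under subsampling, which requires genuinely differentiated strengths.

What the simulator does **not** reproduce: item non-response, clustered
sampling by site or country, ordinal severity information collapsed into
the binary coding, or any non-Gaussian latent dependence (a single
Gaussian copula only).  Passing recovery tests therefore demonstrates
correctness of the estimators under the model that defines them, not
robustness of the substantive findings of any particular published cohort
to violations of that model.

## Problem sizes and numerical choices in the validation suite

The test and acceptance runs use: 200 random 2×2 tables against a
likelihood grid of step 1e-4 (agreement within 1e-3); 3-node penalized
problems against Nelder–Mead (within 1e-6); exhaustive partition
enumeration up to p = 6 (≥95% of 100 seeded annealing runs reach the
global optimum); edge recovery at n = 5000 (sensitivity ≥ 0.8,
FPR ≤ 0.2) and latent-ρ recovery at n = 50000 (bias < 0.02 for
ρ ∈ {−0.5, 0, 0.3, 0.7}); CS-coefficients with n_boot = 100 on a
structured n = 5000 cohort (CS = 0.75, the grid maximum) and a noise
n = 200 cohort (CS = 0).  These sizes were chosen so each property is
measured with comfortable statistical margin while a full validation run
stays in the minutes range on one core.

## Known limitations

- The published study quantities that depend on its raw patient data (its
  specific 29-of-45 edge set, CS = 0.594, the per-subgroup centrality
  orderings) cannot be recomputed without that cohort; the package
  reproduces the reporting arithmetic from the published count tables and
  validates the estimators on synthetic ground truth instead.
- EBIC model selection inherits the information content of tetrachoric
  correlations: binary data carry less information per case than
  continuous data, so false-positive edge rates at a given n are somewhat
  higher than Pearson-input glasso; the recovery benchmark quantifies
  this.
- Only binary items (tetrachoric); no polychoric/polyserial extension, no
  imputation (listwise deletion), no Ising or nonparanormal alternatives,
  no cross-validated penalty selection, and no directed centralities.
- "Average edge" terminology seen in some published descriptions of this
  pipeline is interpreted as the partial-correlation edge weight itself.
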