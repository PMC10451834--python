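# Methods

## Scope and model

`symptomnet` estimates Gaussian graphical models over questionnaire
items and provides the surrounding inference toolkit (stability,
comparison, simulation). Nodes are items — nine ordinal depression
symptoms (0–3) and optionally two continuous intolerance-of-uncertainty
dimension scores (1–5) — and edges are regularized partial correlations.
The working assumption is the standard one in psychometric network
analysis: observed items are monotone functions of a latent multivariate
normal, so rank correlations capture the dependence structure and the
precision matrix's zeros encode conditional independence.

## Correlation input

The estimator consumes the **Spearman rank correlation** matrix (average
ranks for ties), applied identically to ordinal and near-continuous
columns. Polychoric maximum-likelihood correlation is deliberately not
implemented: it is substantially heavier, and its absence is the main
caveat for strongly skewed items (see *Limitations*). If the rank
correlation matrix is not positive definite it is repaired by clipping
eigenvalues at 1e−6 and rescaling to unit diagonal; the repair is
idempotent and flagged on the estimate.

In the resampling hot loops, an item that happens to be constant inside
a resample carries no rank information; its correlations are set to 0
(the node simply acquires no edges in that resample) rather than
aborting the resample. The user-facing estimator still rejects constant
columns loudly.

## Network estimation

The graphical lasso penalizes off-diagonal precision entries only and is
solved by block coordinate descent (column-wise lasso subproblems with a
synchronized working covariance) to duality-gap tolerance 1e−6, at most
500 sweeps; off-diagonal entries below 1e−8 are snapped to zero so edge
counts are well defined. The solver is written against small p
(9–11 nodes) and numba-compiled because the bootstrap/permutation
procedures re-estimate the model ~10⁵ times; it matches
`sklearn.covariance.graphical_lasso` to ~1e−5 (their convergence floor),
and the test suite keeps sklearn as an independent oracle for both the
single-penalty solution and the whole EBIC path selection.

Model selection fits a descending log-spaced path of 100 penalties from
`λ_max = max_{i≠j} |S_ij|` to `λ_max/100` with warm starts and picks the
minimum of `EBIC = −2ℓ + E log n + 4 E γ log p`, `γ = 0.5`; ties break
toward the larger penalty (sparser model). The likelihood constant is
dropped: EBIC is only compared along one path, so additive constants
cancel. Path length, min-ratio and γ are the long-standing defaults of
this estimator family and are all configurable.

Covariate adjustment includes one covariate as an extra node and returns
the symptom×symptom submatrix — conditioning via the joint model — with
`network_similarity` (Pearson r of vectorized edge weights) to quantify
how little the adjusted network moved. Regressing items on covariates
first is a reasonable alternative but is not the default.

## Node metrics

Distances are `d = 1/|w|` over nonzero edges. Closeness is **harmonic**
(sum of inverse shortest-path distances), so networks with isolated
nodes or multiple components remain well defined — classical closeness
is undefined there; this is a deliberate deviation risk to note when
comparing against toolchains that use the classical form. Betweenness is
Brandes' shortest-path betweenness with fractional credit for ties
(verified against exhaustive path enumeration on ≤ 6-node graphs).
Predictability is in-sample R² from OLS of each item on all remaining
items; with collinear predictors the minimum-norm solution is used.
Standardized (z) centralities are computed across nodes within one
network; cross-network z-comparisons are left to the caller.

The flow decomposition is a breadth-first partition from the focal node
on the nonzero-edge graph. Both the layer partition (direct / indirect /
unreached) and the |weight|-ranked list of direct edges are exposed, so
either common reading of a flow diagram ("directly associated" vs
"strongest associated") is reproducible.

## Resampling

Edge accuracy uses the nonparametric bootstrap (subjects with
replacement, identical estimator settings, percentile 95% CIs —
percentile, not BCa, matching the convention of this literature).
Difference tests for edge pairs and node-centrality pairs flag
significance when the 95% percentile CI of the bootstrap difference
excludes zero; no multiple-testing correction is applied, matching the
described procedure (per-edge NCT tests, by contrast, offer optional
Holm correction). One artifact worth knowing: for an edge selected in
fewer than 2.5% of resamples both percentile bounds are exactly 0 while
the bootstrap mean can sit just outside — the usual ordering
`lower ≤ mean ≤ upper` holds only up to this sparsity effect.

Case-dropping stability draws subsets without replacement on a drop grid
of 0.05–0.75 in steps of 0.05 (the standard stability-plot range),
correlates subset centralities (strength or expected influence,
separately) with the full-sample ones, and reports the CS coefficient:
the largest drop fraction at which P(r ≥ 0.7) ≥ 0.95. Fractions whose
retained subset would fall below p + 5 subjects are skipped; subsets
whose estimation does not converge are excluded and the fraction is
dropped if more than half fail. `B` defaults to 1000 and is configurable
down to ~200, which the stability benchmarks use.

All resampling is seed-deterministic: same seed and inputs, bit-identical
outputs.

## Network comparison test

Both group networks are estimated with identical settings;
`S = |GS_A − GS_B|` (global strength = summed |edge weights|) and
`M = max |w_A,ij − w_B,ij|` are referred to their permutation
distributions (group labels permuted on the pooled sample, sizes
preserved, both networks re-estimated per permutation). P-values are
one-sided exceedance with +1 smoothing, hence never zero; `n_perm`
defaults to 1000. The pooled matrix is canonicalized (lexicographic row
sort) and split at `min(n_A, n_B)`, which makes `nct(A, B)` and
`nct(B, A)` bit-identical at the same seed without changing the test.
Permutations whose estimation fails are redrawn, capped at 5%.

## Synthetic data generator

The generator emulates a two-group ordinal survey with known ground
truth:

1. **Truth**: edge positions drawn to an exact density, |weights|
   uniform in a range (default 0.2–0.4), optional negative-sign
   probability. The precision is `I − W`; if its smallest eigenvalue
   falls below 0.05 the weights are shrunk uniformly to the feasibility
   boundary, and the draw is rejected and redrawn if that shrink would
   move any partial correlation by more than 0.02. (Any rescaled
   precision standardizes back to `I − W` by congruence, so a uniform
   shrink is the only honest repair; iteratively inflating the diagonal
   and rescaling cannot converge when `I − W` is indefinite.)
2. **Marginals**: latent normals are discretized per item by thresholds
   calibrated from a two-parameter rounded-severity family (cuts at
   0.5/1.5/2.5 on `μ + σZ`, solved to match a target mean and SD). The
   default targets reproduce the right-skewed marginals typical of a
   community adolescent depression sample — item means ≈ 0.3–0.9 on the
   0–3 scale with suicidal ideation rarest (mean ≈ 0.27, skew ≈ 2.5) —
   and map the two uncertainty dimensions affinely onto 1–5
   (means ≈ 2.4–2.5, SD ≈ 0.8).
3. **Group difference**: every edge weight multiplied by a common factor
   for the second group — the minimal mechanism that shifts global
   strength without changing structure. Scaling requires spectral
   headroom (`I − cW` must stay positive definite), so scaling
   benchmarks draw base weights from 0.1–0.25; `scalable_to` on the spec
   rejection-samples truths that tolerate the requested factor. Default
   group sizes are 439 and 1049, a deliberately unbalanced design.

What the generator does **not** emulate: item-level response styles,
differential item functioning between groups, missingness mechanisms,
or local dependence beyond the latent GGM. Passing benchmarks therefore
demonstrate correctness of the machinery under the latent-Gaussian
ideal, not robustness to those real-data features.

## Benchmarks and problem sizes

The acceptance battery (tests/test_acceptance.py, scripts/acceptance.py)
uses: 200 null splits (n = 1488 split 744/744) with 200 permutations
each for the type-I check; 50 replications at group scale 1.5 with
n = 1000/group for power; 20 truths at n = 2000 for edge recovery; and
B = 200 case-dropping curves at n = 2500 and n = 60. These sizes keep
each run at a few CPU-minutes while leaving the binomial bands narrow
enough to be informative. Observed values (seed 1): type-I rate 0.05,
power 1.00, CS 0.75 (n = 2500) vs 0.10 (n = 60), determinism exact.

## Known limitations

- **Specificity of edge detection.** With skewed ordinal items, rank
  correlations of the discretized variables imply small but genuinely
  nonzero partial correlations (up to ≈ 0.08 at the population level in
  our default conditions) on pairs whose *latent* partial correlation is
  zero. A consistent estimator of the observed-variable network
  therefore accumulates weak false-positive edges as n grows; lasso
  shrinkage bias on strong edges compounds this by dragging the selected
  penalty down. Measured against the latent truth at n = 2000, median
  sensitivity is 1.0 and median edge-weight correlation ≈ 0.96, but
  median specificity is only ≈ 0.4. Polychoric correlations would remove
  the discretization component; they are out of scope here, and users
  should read weak edges (|w| ≲ 0.05) with corresponding caution.
- Estimated global strength ratios exaggerate a true uniform scaling
  between groups, because selection drops more borderline edges in the
  weaker group; the permutation test is the calibrated comparison.
- Closeness is harmonic, not classical; values are not comparable to
  toolchains using the classical definition on connected graphs.
- The t-test is pooled-variance Student (not Welch) and the 2×2
  chi-square is uncorrected Pearson — the variants standard in this
  survey literature; both are exposed as plain functions so alternatives
  are easy to bolt on.
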