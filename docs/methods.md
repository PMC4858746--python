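# Methods

This note documents the models the package implements, the choices made
where the design was genuinely open, the study conditions used by the
validation experiments, and what those experiments do and do not show.

## The trait model

The color pattern is a binary character (0 = cryptic, 1 = red–black
banded) evolving on a rooted, time-scaled phylogeny under a continuous-time
Markov chain with instantaneous gain rate `q01` and loss rate `q10`
(events per lineage per Myr). Transition probabilities use the closed
form `P(t) = Π + (I − Π) e^{−(q01+q10)t}` with stationary rows
`π1 = q01/(q01+q10)`; tip-data likelihoods use Felsenstein's pruning
algorithm with per-node rescaling. The root is handled either by the
stationary frequencies of the root partition's matrix (default) or a
fixed prior probability of state 1 (the empirical analysis used 0.05; the
rationale there was that the trait's observed frequency near the root
partition is ~0.02 and its stationary frequency under the fitted rates is
similarly small).

### Rate partitions

A `PartitionModel` attaches one `(q01, q10)` matrix to each branch via
clade shifts. **Convention:** a shift at node *v* governs the branches
strictly inside *v*'s subtree (crown); *v*'s own stem branch stays with
the parent partition, and nested shifts override outer ones on their own
crowns. The alternative stem-inclusive convention was tried first and
rejected: it lets a new matrix with a near-infinite gain rate absorb the
single founding gain event of a monomorphic-derived clade, which is worth
roughly `−ln P(gain on the stem)` log-likelihood units at no data cost
and produced spurious shift acceptances on rate-homogeneous data. The
simulator and the likelihood share one convention, so planted and
inferred shifts mean the same thing.

### Stepwise-AIC shift search

Greedy forward selection: candidates are internal non-root nodes with at
least 5 descendant tips that are not already shift nodes. Each candidate
is scored by optimizing only the new matrix's rates (background rates
frozen at the incumbent MLE; two deterministic starts at 1× and 10× a
parsimony-based rate heuristic); the best candidate is accepted when its
AIC improves on the incumbent by more than 2, after which all rates are
re-optimized jointly (three starts). Parameter count for an *m*-matrix
model is `k = 2m + (m − 1)`: two rates per matrix plus one topological
location per shift. Rates are optimized in log space with bounds
[1e−8, 1e3] per Myr; boundary solutions (e.g. `q01 → 0` when no gains
are observed) are legitimate outputs.

Candidate scoring uses inner/outer partial caching: for the incumbent
model the likelihood factorizes at any node v as Σ_i O_i(v)·L_i(v), with
the outer conditionals O computed once per scan step, so scoring a
candidate only re-evaluates the partials inside its own subtree. The
cached score equals the full pruning likelihood to machine precision
(tested) and makes the 300-tip search run in seconds. Candidates whose
subtree contains an already-accepted shift fall back to the full fit,
since their crown mixes matrices.

Stepwise AIC with a ΔAIC > 2 threshold is known to be a liberal selector
when many candidate shifts are scanned; the calibration experiment below
quantifies this under the package's study conditions rather than assuming
nominal behavior.

## Bayesian rates and stochastic mapping

With shift locations frozen (the hybrid ML/Bayesian design), rates get
independent exponential priors whose mean is `multiplier × r̂` (default
10×), where `r̂` is the whole-tree symmetric ML rate (`q01 = q10`
constrained fit). Sampling is Metropolis–Hastings on log-rates with a
joint Gaussian random-walk proposal adapted during the 25% burn-in toward
20–40% acceptance; chains are thinned to at most 5,000 stored samples and
per-parameter ESS (autocorrelation-time method, via arviz) below 100
triggers a warning, not an error.

Stochastic maps condition on the observed tips: the root state is drawn
from prior × root conditionals, node states top-down in proportion to
transition probability × subtree conditional likelihood, and each branch
history exactly, given both endpoint states, by uniformization (dominating
Poisson rate `μ = max(q01, q10)`, jump count drawn from its conditional
distribution, state ladder by forward filtering against powers of the
uniformized kernel). Uniformization was chosen over rejection sampling
because it stays exact and efficient when endpoint states differ and
rates are small. Ensemble summaries: trait frequency at `n_time = 1000`
equally spaced times (fraction of lineages alive at *t* in state 1 —
pointwise in *t*, so refining the grid never changes shared values; at
the final time it equals the observed tip frequency by construction);
per-branch mean gains/losses; and a "maximum credibility" configuration
defined here as the sampled map maximizing the sum over branches of the
log marginal frequency of its per-branch (gains, losses) pair — the
external toolkit the empirical study used does not document its scoring
rule, so this package declares its own.

## Geography

**Ranges.** Record-count dispatch: ≥5 records → alpha hull; 3–4 → minimum
convex hull; 1–2 → union of 0.5°-radius planar disks. The boundary case
n = 5 goes to the alpha hull. Alpha shapes are the union of Delaunay
triangles with circumradius ≤ α; α starts at the mean nearest-neighbor
distance and grows ×1.5 per iteration until the shape is one connected
polygon covering at least ⌈0.99 n⌉ records (boundary points count). The
growth schedule is a declared choice — only the contract (contiguity +
containment) is specified, so polygon detail may differ between
implementations. Collinear/degenerate inputs fall back to the convex
hull or buffer, logged.

**Rasters.** Cells are planar lon/lat squares; presence requires the
range to cover ≥50% of the cell (inclusive, exact polygon–cell
intersection area, with a 1e−12 relative guard against floating-point
ties); off-land cells (midpoint not on the land polygon) carry no values;
point records bin by half-open intervals [west, east) × [south, north).
Abundance ratios use `log2((m+1)/(c+1))`.

**Spatial regression.** Neighbor weights are great-circle distance bands
(haversine, R = 6371 km) in binary, distance (w = d) and inverse-distance
(w = 1/d) flavors, all row-standardized (the source analysis does not
state whether its weights were standardized; row-standardization keeps λ
interpretable on (1/λ_min, 1)). The SAR error model is fit by maximum
likelihood with the log-determinant from the eigenvalues of W (the
row-standardized matrix is similar to a symmetric one, so its spectrum is
real); β and σ² are concentrated out; λ's standard error comes from the
curvature of the profile likelihood; AIC counts β's + λ + σ². The
neighborhood search starts at the smallest 50-km multiple at which every
cell has a neighbor and grows in 50-km steps.

**Permutation null.** Species tags of all non-model polygons are shuffled
without replacement; per-species presence rasters are computed once, so
each null iteration is a re-labelled column sum — which is also why the
null preserves range shapes, per-cell totals and the model raster
*exactly*, not approximately. The per-iteration regression is OLS of
mimic richness on model + total richness (SAR is reserved for the primary
fit); the additive model is the default because the interaction term
explained negligible variance in the source analysis. `p = (#null ≥
observed)/n_iter` as printed, with the conservative `(b+1)/(n+1)` bound
reported alongside so `p = 0` outcomes can be cited as `P < 1/(n+1)`.
Standardized residual maps use `z = (f − f̄)/√f̄` (the χ²-framework
residual; the source's exact formula is redacted in the available text,
so a null-SD denominator is offered as an option).

**Latitudinal history.** Ancestral latitudinal midpoints come from
single-rate Brownian motion by GLS (the marginal ML estimates; verified
against direct numerical optimization of the joint Gaussian density).
The empirical study used a multi-rate BM from an external program; the
package replaces it with single-rate GLS plus an optional per-clade σ²
map in the simulator — a declared divergence. Events interpolate linearly:
latitude = δ·(descendant) + (1−δ)·(parent) with δ the fractional position
along the branch; the source text's variable naming for the two endpoints
is self-contradictory, and this identification is the unique one
consistent with its stated anchors (δ = 0.5 → midpoint, δ = 0.1 → 10%
from the parent). Zone summaries use tropics [−23°, 23°] (closed) and
northern temperate (23°, 35°] (half-open) — no double counting at 23°.
Conservatism: variance of standardized independent contrasts against a
tip-permutation null (z score and lower-tail p); polytomies are resolved
arbitrarily with zero-length branches.

## The synthetic-data layer

What it emulates: time-scaled trees (pure-birth, ultrametric — the real
analysis used a fixed dated tree, so any time-scaled source suffices);
rare, clade-heterogeneous binary trait histories (exact Gillespie
simulation per branch); phylogenetically conserved latitudes (BM);
and a virtual continent (fixed irregular polygon ~50°×56°) where model
and background species ranges are buffered random walks clipped to land,
and the number of mimic species per 5°-region is Poisson with mean
`a + b_model·(model richness) + c_total·(other richness)` evaluated at
region centroids. Mimic and "other" ranges use one shared, tighter clump
process (walk of 3 × 1.2° steps, 1.5° buffer) so the two classes are
exchangeable under `b_model = 0` — the exchangeability the permutation
null relies on; model ranges are broader (6 × 2.5° steps, 1.8° buffer),
mirroring the carefully hand-compiled model ranges of the real data.
Occurrences are uniform within ranges, Poisson(25)+1 per species.

What it does not emulate: habitat and climate structure, coastline
complexity, range-size/latitude correlations, taxonomic error, sampling
bias in occurrence records. Passing recovery tests on this generator
shows the estimators are correct and calibrated under their assumptions,
not that those assumptions hold for real snakes.

## Validation experiments (study conditions)

Replicate counts are sized for a single CPU; each experiment's conditions
are fixed here and reused identically by the test suite and
`scripts/acceptance.py`.

- **Pruning vs enumeration:** 200 random trees of 3–5 tips, uniform
  random rates in (0.01, 2); agreement to 1e−10. Closed-form `P(t)` vs
  `scipy.linalg.expm` on 200 random cases to 1e−12.
- **Shift-search calibration:** 300-tip Yule trees (birth 0.05/Myr,
  depth ≈ 100 Myr), background rates (0.005, 0.01)/Myr, root state 0.
  Homogeneous data and planted-clade data (one 45–75 tip clade at 10×
  both background rates); 20 replicates each. Success for recovery = an
  accepted shift within two nodes of the planted clade root. Under these
  conditions the planted shift is recovered reliably and localized to
  within a node or two. The homogeneous-data false-positive rate,
  however, is high — see the limitation below — and the experiment
  reports it as measured.
- **MCMC:** prior-only sampling (likelihood off) must reproduce the
  exponential prior mean within 5% at 100k steps; credible-interval
  coverage uses 20 datasets of 100-tip trees with rates (0.01, 0.05) and
  6,000-step chains, checking both rates per dataset against ~95%
  nominal coverage with binomial slack.
- **Stochastic maps:** endpoint-conditioned mean event counts vs the
  quadrature oracle `E[N|a,b] = Σ_{i≠j} q_ij ∫ P_ai(s) P_jb(t−s) ds /
  P_ab(t)` over 10k draws per case (within 3 Monte-Carlo SE); tip-time
  frequency must equal the observed tip frequency exactly.
- **Permutation type-I error:** 100 virtual continents with
  `b_model = 0`, 199 iterations each; the rejection rate at p ≤ 0.05
  must lie in [0.01, 0.11].
- **Coupling recovery:** 40 continents with `b_model = 2`; OLS of
  regional mimic counts on model + other richness with HC3
  (heteroscedasticity-robust) intervals — appropriate because the
  generator's counts are Poisson, whose variance grows with the mean —
  must cover the planted slope in ≥90% of replicates. SAR λ = 0.7 on a
  20×20 half-degree grid, 50 replicates, Wald intervals from the profile
  curvature, same ≥90% bar.

## Known limitations

- All geometry is planar in degrees; the 0.5° buffer and cell areas are
  not geodesic (matching the degree-based rules of the source pipeline).
- The SAR implementation is dense-matrix; practical up to a few thousand
  cells, which covers the 2° analyses (the source also restricted SAR to
  the 2° resolution).
- Stepwise AIC inherits the optimism of greedy model selection, and on
  this problem the effect is severe. A calibration sweep across nine
  rate regimes (gains 0.0005–0.02/Myr, losses 0.001–0.05/Myr, tree
  depths ~30 and ~100 Myr, fixed and stationary roots) found that on
  rate-homogeneous 300-tip data the search accepts at least one spurious
  shift in roughly half to nearly all replicates, in every regime
  tried. The mechanism: with ~100 candidate nodes and maximum-likelihood
  fits free to reach the rate bounds, almost every realized history
  contains some ≥5-tip clade — typically a monomorphic-derived clade
  whose founding gain (or persistence) probability a clamped extra
  matrix absorbs, or a chance-enriched clade — for which the dedicated
  3-parameter matrix improves the log-likelihood by more than the 4
  units the ΔAIC > 2 rule demands. Shift detections from this procedure
  should therefore be treated as hypotheses, corroborated by the
  parsimony cross-check and the Bayesian rate posteriors, not as
  calibrated tests; the planted-shift experiment shows real 10× shifts
  are found and well localized, while the false-positive experiment
  quantifies the over-acceptance instead of assuming nominal behavior.
- The latitude pipeline treats the latitudinal midpoint as a 1-D BM
  character; full range evolution is out of scope.
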