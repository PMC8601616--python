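# Methods

## The problem

A genome-scale metabolic model (GEM) defines, for each set of nutrient
constraints, a steady-state flux polytope

    P = { v : S v = 0,  lb <= v <= ub }

where `S` is the stoichiometric matrix (metabolites x reactions) and the
bounds are in mmol gDW⁻¹ h⁻¹. Without an objective function — which for
human tissue models is rarely defensible — the natural description of a
metabolic state is the uniform distribution over `P`. This package
characterises that distribution per condition, decomposes it into
reaction modules, and identifies the modules that differ between two
conditions.

## Condition construction

All reversible reactions are reset to [-1000, 1000] and irreversible
ones to [0, 1000], exchange reactions included regardless of their
original (typically closed) bounds; reversibility is taken from the SBML
flag, which wins over stored bounds because the reset overwrites them
anyway. A condition is then a named set of per-reaction overrides, the
canonical perturbation being `lb = ub = 0` (blocked uptake). Blocking
takes precedence over capacity overrides when both name the same
reaction, since blocking is the perturbation under study.

## Preprocessing

Flux variability analysis (two LPs per reaction, HiGHS via scipy, with
1e-9 feasibility tolerances) yields each reaction's attainable range.
Reactions with both `|vmin|` and `|vmax|` below `tol = 1e-6`
mmol gDW⁻¹ h⁻¹ are blocked and removed; that tolerance is the
conventional magnitude for GEM FVA and is configurable. Surviving
reactions keep their FVA ranges as box bounds — the tightest axis-aligned
box containing the polytope — which is what the moment approximation
consumes. The polytope dimension is reported as
`n_reactions - rank(S)`, with the rank cut at 1e-10 of the largest
singular value.

## Moment approximation

### Expectation propagation

The uniform density on `P` is approximated by a multivariate Gaussian
via expectation propagation. The mass balance enters as a soft Gaussian
likelihood `exp(-beta/2 ||S v||²)` with `beta = 1e8`; each box
constraint is a site factor `exp(-(v_i - a_i)²/(2 d_i))` whose
parameters are chosen so the Gaussian marginal matches the mean and
variance of the tilted marginal (cavity Gaussian truncated to the box).
Defaults mirror the standard settings for this algorithm: at most 1000
sweeps, convergence when no site mean or variance moves by more than
1e-5. Updates are parallel with damping 0.9 on the natural parameters;
fluxes are affinely rescaled to the unit box per reaction before EP so
conditioning does not depend on the spread of the FVA ranges. Reported
per-reaction means and variances are the tilted (truncated-Gaussian)
moments; the reported covariance takes its correlation structure from
the global Gaussian with the diagonal rescaled to the tilted variances
(a congruence transform, so positive semidefiniteness is preserved),
followed by symmetrisation and clipping of numerically negative
eigenvalues.

Two numerical points deserve emphasis:

* **Fully coupled reactions.** When several reactions have collinear
  null-space directions (enzyme subsets; any linear pathway), their box
  constraints act on the same one-dimensional projection. Placing one EP
  site per reaction is then the classic duplicate-factor situation where
  EP splits the truncation across sites and understates the variance
  (for a two-reaction pathway the fixed point gives 0.064 instead of the
  exact 1/12). The boxes of each coupled group are therefore intersected
  onto a single representative site before EP — an exact rewriting of
  the target density, after which the pathway fixture is reproduced
  exactly. Groups whose intersection is empty make the polytope
  infeasible and raise.
* **Truncated moments in the flat-cavity regime.** When a cavity is
  nearly flat over its box, the closed-form truncated-Gaussian variance
  is a difference of O(1) terms of size (width)² and loses all
  precision in double arithmetic. Standardised intervals narrower than
  1e-3 are integrated by 24-point Gauss-Legendre quadrature in a centred
  coordinate instead, which is cancellation-free; wider intervals use
  scipy's formulas.

Zero-width reactions (FVA-pinned) are excluded from EP, reported at
their fixed value with variance at the floor (1e-10). Non-convergence
is recorded in the result and surfaced as a warning, never silently.

### Sampling oracle

The independent cross-check is uniform hit-and-run sampling in
null-space coordinates: a strictly interior start point is found by a
max-slack LP, directions are isotropic in the null space, and each step
moves uniformly along the feasible chord. Warm-up is `10·dim` steps and
thinning `dim` steps between retained samples; 1e5 samples bound the
Monte-Carlo error on the fixture variances to a few percent. EP and the
sampler share no code beyond the space definition, so their agreement
(means within 5% of the range, covariance correlation >= 0.9 on
fixtures) is a genuine dual-route check. On fully coupled fixtures the
covariance matrix is constant and the Pearson correlation undefined;
agreement is then checked elementwise.

## Differential flux statistics

Per shared reaction, `z = (E₂ - E₁) / sqrt(Var₁ + Var₂)` with a
two-sided Gaussian p-value `p = 2(1 - Φ(|z|))`; two-sided because a
shift in either direction is a change. No multiple-testing correction is
applied — the method reports raw `p < alpha` (default 0.05) — and
reactions unblocked in only one condition are flagged rather than
scored. A zero pooled variance with equal means gives `z = 0` by
convention; with unequal means the reaction is flagged degenerate.

## Decomposition into modules

The flux covariance is eigendecomposed; variance fractions are
eigenvalues over the trace after clipping numerically negative
eigenvalues at zero, and eigenvector signs are fixed by making each
column's largest-magnitude entry positive. The smallest k components
reaching 99.9% cumulative variance are varimax-rotated (raw varimax, no
Kaiser normalisation, SVD ascent with relative tolerance 1e-8, at most
1000 sweeps) on the variance-scaled loadings, so rotated columns carry
variance and the rotation is orthogonal — row communalities are
preserved to 1e-8. A module is the set of reactions whose absolute
loading is at least half of the component's maximum, threshold
inclusive; the union over components forms the condition's global
modules.

## Comparing conditions

The two rotated loading matrices are concatenated over the union of
reactions (zero-filled where a reaction is absent from one condition).
With `m_r` the per-reaction maximum absolute loading, rows with
`m_r < median(m) + mean(|m - mean(m)|)` are dropped; the mean absolute
deviation is taken about the mean. The remaining matrix is treated as
mixed signals over reactions and decomposed by symmetric fastICA with
the pow3 (cube) contrast:

1. **Stability scan.** For each candidate N (default 2..90), fastICA is
   repeated (default 100 runs) from random initial conditions, each run
   fitted on a bootstrap resample of the reactions and evaluated on the
   full data. Bootstrapping is essential at desk scale: with a fixed
   dataset and restarts alone, the optimiser deterministically
   rediscovers the same sample-specific noise optima and over-complete N
   looks perfectly stable. Pooled estimates are clustered by average
   linkage on `1 - |corr|` into N clusters; each cluster's stability is
   the icasso index (mean within-cluster |corr| minus mean
   between-cluster |corr|). Runs that fail outright are excluded and
   logged; runs that merely hit the iteration cap are kept — their
   scatter is the signal that N is too large.
2. **Optimal N.** All stability values, indexed by cluster rank, are
   split by exact 1-D 2-means into a high- and a low-stability group.
   Because a 1-D 2-means split is a threshold, the group-mean curves
   over rank cannot cross; the two-line intersection is therefore read
   from the groups' occupancy curves: the optimal N is the last rank at
   which the high-stability group holds the majority of that rank's
   values.
3. **Estimation frequencies.** fastICA is re-run many times (default
   9000) at the optimal N with explicit per-run seeds
   `master_seed + run_index`. Components whose excess (Fisher) kurtosis
   lies outside (-1, 1) — clearly non-Gaussian — are assigned to the
   input column with the largest absolute mixing weight (ties to the
   lower index), accumulating per-column counts.
4. **Knee selection.** Frequencies are sorted descending and the point
   of maximal distance to the chord joining the endpoints located. Above
   the chord it is the last point of a plateau and selection includes
   it; below the chord it is the first point after a cliff and selection
   stops before it. This one rule handles both the plateau-then-cliff
   and the convex few-winners curve shapes; a flat or exactly linear
   curve has no knee and yields an empty selection with a warning.

Selected columns are traced to their condition and component; the
corresponding modules are the distinct modules of the comparison. All
randomness derives from the master seed, so the whole stage is
bit-reproducible.

## Networks

Two reactions are connected when they share a reactant or product that
is not in the ubiquitous-metabolite list (53 currency species: CoA,
ubiquinol/ubiquinone, NH₃, O₂, H₂O, H⁺, the nucleotide phosphate
family, Pi/PPi, NAD(P)(H), FAD(H₂), CO₂, Na⁺, HCO₃⁻), matched by base
name irrespective of compartment. Node attributes carry the module
count, module list, subsystem, chemical equation, condition tag,
significance flag and first-neighbour flag; extracellular-transport
nodes can be flagged hidden rather than removed. Multi-metabolite
sharing is collapsed to a single edge labelled with every shared
metabolite. First-neighbour expansion adds model reactions sharing a
non-ubiquitous metabolite with any node. Metabolic maps are bipartite
substrate/product digraphs for chosen subsystems with compartment
attributes on metabolites (ubiquitous metabolites hidden by default).
Exports are lexicographically sorted semicolon tables plus GraphML with
identical content, so they are byte-stable.

## Synthetic fixtures and what they do (and do not) show

* **Chain** (linear pathway, bounds [0,1]): the polytope is a segment;
  every reaction has mean 1/2, variance 1/12 and perfect mutual
  correlation. Exercises the fully-coupled EP path.
* **Triangle** (one branch point): the polytope is the unit triangle in
  the two outflows; E[v2] = 1/3, Var[v2] = 1/18, Cov(v2,v3) = -1/36,
  E[v1] = 2/3 by direct integration. Exercises genuine multivariate
  geometry.
* **Star** (hub with 10 inflows/outflows): a 19-dimensional polytope,
  the smallest family whose covariance supports a multi-component
  PCA/ICA exercise; used for end-to-end pipeline runs with staggered
  capacity bounds, because a perfectly symmetric star gives every
  reaction an identical loading profile and degenerates the low-loading
  filter.
* **Planted loadings**: two 8-column loading matrices over 1000
  reactions, every column a linear mixture of 3 sources (one shared,
  one specific per condition) plus Gaussian noise of sd 0.02. Sources
  are sparse Laplace-weight vectors (25% support, excess kurtosis about
  6/0.25 - 3 = 21): sparsity mimics varimax-concentrated loadings and —
  unlike dense Laplace sources, whose tails the low-loading row filter
  truncates — keeps the planted components strongly super-Gaussian
  after filtering.

Passing on these fixtures demonstrates correctness of the mechanics
(moment accuracy on known polytopes, source recovery under the stated
noise model, determinism, export fidelity). It does not demonstrate that
a genome-scale model's flux space yields biologically meaningful
modules: real GEM covariances have heavy-tailed spectra, thousands of
reactions and subsystem structure no fixture reproduces.

## Problem sizes and defaults

Fixture analyses run the sampler at 1e5 samples and the comparison stage
at reduced replication (N range 2..10, 20 scan runs, 200 final runs) —
the package's chosen desk-scale study conditions; genome-scale defaults
(N range 2..90, 100 scan runs, 9000 final runs, EP at 1000 iterations /
1e-5 precision / beta 1e8, PCA threshold 99.9%, kurtosis bound 1,
blocked tolerance 1e-6) are the reference settings and are what the
pipeline uses unless configured otherwise.

## Known limitations

* EP variances on strongly non-axis-aligned polytopes are approximate
  (the triangle branch variance is about 2% low); the sampler is the
  arbiter when the two routes disagree.
* The LP layer is dense; models beyond a few thousand reactions would
  want a sparse LP interface and a sequential EP update with low-rank
  covariance maintenance.
* Thermodynamic (loop-law) consistency of the preprocessed spaces is
  not checked.
* The ICA stage compares exactly two conditions; multi-condition
  comparison would require a different feature-attribution scheme.
* The optimal-N rule assumes the stability landscape has one dominant
  transition; data with several plateaus would need manual inspection
  of the scan profiles (written as TSV for that purpose).
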