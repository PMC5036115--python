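# Methods

## Model

A metabolic pathway is a directed graph whose nodes are metabolite pools
and whose edge (i, j) carries the catalytic rate k_ij(t) ≥ 0 of the
enzymatic conversion of metabolite i into j. Concentrations X_i(t) obey
the linear mass-balance system

    dX_i/dt = −Σ_j k_ij X_i + Σ_j k_ji X_j + b_i,        b = (b1, 0, …, 0),

or compactly dX/dt = A(t)X + b with A_ij = k_ji off the diagonal and
A_ii = −Σ_j k_ij, so every column of A sums to zero (mass leaving one pool
enters another). A single root node receives a constant influx b1
(concentration·time⁻¹). Because the catalytic rate lumps the enzyme
concentration with its kinetic constants, and enzyme levels change over
development, rates are modeled as quadratics in time,
k_ij(t) = α t² + β t + γ, constrained non-negative at the measurement
times. The model assumes first-order (substrate-proportional) kinetics,
unit stoichiometry, irreversible conversions, and no hidden pools.

### Trees and pointwise estimability

On a *tree* (no undirected cycle, one parent per non-root node, edges
oriented away from the root) the parameter count — one influx plus one
rate per edge — equals the node count. Substituting measured X and
estimated dX/dt into the model at a single time point and exchanging the
roles of states and parameters yields a square linear system B·θ = dX/dt
for θ = (b1, k_ij). Ordering equations by a breadth-first node order and
assigning each non-root node's column to its unique incoming edge makes B
upper triangular with diagonal (1, X_parent(edge), …): det B is the product
of squared parent concentrations, nonzero whenever concentrations are, so
θ is uniquely solvable at every time point — the structural-identifiability
certificate for trees. Concentrations below 1e-9 × max|X| raise a
singularity error at that time point (the solve divides by them); callers
mask such points.

## Estimation schemes

* **Scheme 1 (pointwise).** P-splines are fitted per node; at each
  measurement time the triangular system is solved exactly using the
  smoothed concentrations and spline derivatives. Negative pointwise
  values (possible under noise) are floored at zero, then an ordinary
  degree-2 polynomial is fitted through each rate's series; b1 is the mean
  of its pointwise series. On non-trees (only via `allow_non_tree=True`)
  the pointwise system is underdetermined and solved in the minimum-norm
  least-squares sense — exactly the ambiguity that costs identifiability
  off trees.
* **Scheme 2 (gradient matching).** The quadratic rate model is
  substituted into the right-hand side and the squared mismatch with the
  derivative estimates is minimized over all times at once. The objective
  is quadratic in the coefficients: the unconstrained solution is one
  linear least-squares solve, accepted when it satisfies the constraints,
  otherwise a quadratic program (trust-region with an exact KKT polish on
  the active set — the interior-point iterate alone stalls ~1e-7 short of
  machine precision, which matters when profile curves are compared
  against a tiny floor). When scheme 2 fits the smoothers itself it uses
  the smoothed concentrations as regressors (errors-in-variables
  mitigation: the concentrations are "fixed first" by the splines); raw
  data are used when derivatives are injected.
* **Scheme 3 (trajectory fitting).** For candidate coefficients the ODE is
  integrated and the summed squared per-time Euclidean distance to the
  measurements is minimized by Nelder–Mead from multiple log-uniform
  random starts (seeded; default 5 restarts), with a quadratic penalty
  (weight 1e5) on negative rate evaluations. A final simplex restart from
  the incumbent ("polish") is on by default — a single adaptive NM run
  stalls in a shrunken simplex at ~19 parameters — but the benchmark
  disables it to mirror the original comparison protocol, which ran the
  simplex search without post-processing. The objective norm is squared-L2
  by default (`objective_norm="l2"` gives the unsquared sum of distances).

All schemes return rates satisfying k_ij(t_k) ≥ 0 at the measurement
times; a final projection lifts a polynomial's constant term by any
residual violation. Decay terms (below) are deliberately exempt.

Integration uses adaptive RK45 (rtol 1e-8, atol 1e-10, LSODA fallback at
tighter tolerances); optimization inner loops use a fixed-step RK4
(3 substeps per measurement interval, ~1e-4 relative error) on the
polynomial form A(t) = A2 t² + A1 t + A0.

## Derivative estimation

Forward finite differences (exact on affine series; per-interval steps on
non-equidistant grids) or P-splines: cubic B-splines with interior knots
at the data points trimmed not-a-knot style (t[2:-2]), so the basis has
exactly m functions and the unpenalized fit is the unique interpolant with
boundary-stable derivatives. The penalty is second-order *divided*
differences of the coefficients over the Greville sites, rescaled to
plain-difference magnitude: on non-uniform knots this keeps straight lines
penalty-free, so large penalties shrink exactly to the line fit. The
"auto" penalty minimizes leave-one-out cross-validation over a log grid
(1e-4…1e4, 17 points), holding out interior points only — boundary
hold-outs are extrapolation and bias selection toward over-smoothing.
With fewer than four points the degree drops to the largest the data
support (the 5-point seedling grid matters here). Solves use the
augmented (QR) form, stable for extreme penalties.

## Identifiability and sloppiness

Practical identifiability is probed by profile likelihood: one parameter
is fixed on an 11-point grid spanning ±50% around its estimate (an
absolute ±0.5·scale span for near-zero estimates) and all others are
re-optimized. For gradient-matching fits each profile point is an exact
reduced constrained least-squares solve; other fits re-run Nelder–Mead.
A parameter is identifiable when the profile rises past the
likelihood-ratio threshold χ²(0.95, 1)·σ̂² on both sides, with σ̂² the
residual variance at the optimum (absolute floor 1e-8 for noise-free
fits). This threshold, unlike a fixed fraction of the optimum residual,
does not conflate a noise-dominated optimum with parameter uncertainty.

An *unconstrained decay* — a first-order outflow from a product node to an
implicit sink, free of sign constraints — voids the tree certificate
(`decay_nodes` on `Network`) and, on the short 5-point series, makes the
decay coefficients tradeable against the incoming rate: their profiles
stay flat below the threshold, reproducing the loss of practical
identifiability such a term causes.

Sloppiness: the numerical Hessian of the residual at the optimum (central
differences, per-parameter step 1e-4·max(|θ|, 0.01), symmetrized) is
eigendecomposed; because the residual sums pointwise mismatches over the
measurement times, it equals the number of times multiplied by the
time-average of pointwise sensitivity products, so the eigenstructure is
the time-averaged one. Eigenvectors of near-zero eigenvalues point at
ill-determined parameter combinations — on constructed data with one
~100× diluted node, at that node's parameters, since the unweighted
objective barely sees them.

## Synthetic data generator

`SimulationSpec` fixes the study conditions: a random rooted tree (each
node picks a parent among its predecessors) or that tree plus a
forward edge closing an undirected cycle; per-edge quadratic coefficients
drawn uniformly from α ∈ [−0.02, 0.02] day⁻³, β ∈ [−0.1, 0.1] day⁻²,
γ ∈ [0.1, 1.0] day⁻¹ (rejection-sampled until the curve is non-negative on
the grid), b1 ∈ [0.5, 2.0], root x0 ∈ [1, 5], other x0 ∈ [0.1, 0.5].
These ranges keep trajectories positive and on the O(0.1)–O(10) scale of
the motivating quercetin-glycoside concentrations. Grids: 20 equidistant
points on [0, 10] days for method benchmarking (dense enough for stable
splines), and a 5-point "seedling" preset on days 5–9 matching the
motivating data's sampling. Noise is multiplicative uniform,
noisy = clean·(1 + u), u ~ U(−0.10, 0.10) i.i.d. — "±10%" read as
relative. One seed feeds three independent sub-streams (topology, rates,
noise); datasets are bit-reproducible. Exact derivatives are evaluated
from the ODE right-hand side, not by differencing.

What the generator does *not* emulate: measurement-process artifacts
(LC-MS peak shapes, detection limits), biological replicates, missing
values, or non-first-order kinetics. Passing tests therefore show the
estimators work when the model class is correct and noise is bounded and
multiplicative — not that the linear model suits any particular pathway.

## Gene selection

Candidate genes are ranked by the Pearson correlation (Spearman by
config) between their standardized expression series and each
standardized estimated rate curve at the shared times; a gene's score is
its best edge's correlation (signed — anticorrelated genes rank last),
optionally down-weighted by replicate dispersion. Zero-variance series
are excluded explicitly, never silently zeroed.

The synthetic panel for validating the procedure stores positive
unit-mean abundance curves: planted genes are the true rate curves scaled
to unit mean plus Gaussian noise (so one positive scale factor maps them
back onto the rates — the relationship the procedure assumes), and decoys
are smooth Gaussian-process draws (squared-exponential kernel, length
scale a quarter of the window) shifted positive. Decoys must not be
random quadratics: those span the same 2-D standardized-shape family as
the rate model and would mimic rate curves by construction.

MCMC validation compares two disjoint gene sets (by rank windows, e.g.
1–10 vs 11–20). For each set, independent Metropolis chains explore
edge→gene assignments (repeats allowed) and per-edge positive scales;
k_e(t) = s_e·ĝ(t) with ĝ the gene's quadratic least-squares approximation
(keeps the fast polynomial integrator applicable), lifted if it dips
negative. Scales initialize at the least-squares match to the reference
rate curve and re-initialize on reassignment; proposals flip one edge's
gene or perturb one scale log-normally (σ = 0.2); the temperature is
calibrated from a 20-proposal pilot to ~0.4 initial acceptance. Each
chain contributes its best residual; the two collections are compared
with a Welch t-test (means) and an F-test (variances; Levene by config).

## Numerical and design notes

* Tie-breaks: BFS child order follows edge declaration order; gene
  ranking sorts by score descending with Python's stable sort.
* Degenerate inputs: single-node networks are valid trees; constant
  series are rejected by `standardize`; m = 2, 3 reduce the spline degree.
* The trajectory objective deliberately omits per-series
  standard-deviation weighting, so low-abundance series contribute
  little — the price is the sloppiness structure above; a weighted mode
  is out of scope.
* Problem sizes in the shipped tests: the scheme comparison runs 20
  replicates per condition (the full study design crosses
  {tree, cyclic} × {0, 10%} noise), and the MCMC validation runs 20
  seeded panels of 10 chains × 200 steps; these are the package's default
  desk-scale settings, with larger sizes available through the same APIs.
* Config files are JSON; tabular outputs TSV with full-precision floats;
  every random operation takes an explicit seed.

## Known limitations

* Non-tree networks are supported by least-squares fallbacks, not by any
  identifiability repair; the point of the benchmark is precisely that
  schemes 1–2 degrade there.
* The P-spline boundary derivative on sharp initial transients is the
  dominant error source of the spline-fed schemes (~3–7% of the signal
  norm on noiseless 20-point data); injected exact derivatives recover to
  machine precision, isolating the smoother as the bottleneck.
* Scheme 3's simplex search is local; multi-start plus polish is a
  heuristic, not a global guarantee.
* The MCMC chain design (proposal mix, temperature rule) is a declared
  construction; other samplers would give different absolute residual
  distributions, though the A/B comparison is the quantity of interest.
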