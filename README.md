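# kinetree

Estimation of **time-varying catalytic rates** in tree-structured
metabolic networks, with identifiability diagnostics and a
correlation-based screen for the genes behind the enzymatic reactions.

## The problem

In pathways such as quercetin glycosylation in tomato seedlings, each
conversion of metabolite *i* into *j* is catalyzed by an enzyme whose
concentration changes over development. Modeling the pathway as a linear
mass-balance ODE system

&nbsp;&nbsp;&nbsp;&nbsp;Ẋ = A(t) X + b,&nbsp;&nbsp; A<sub>ij</sub> = k<sub>ji</sub> (i ≠ j),&nbsp;&nbsp; A<sub>ii</sub> = −Σ<sub>j</sub> k<sub>ij</sub>,&nbsp;&nbsp; b = (b₁, 0, …, 0),

with quadratic-in-time rates k<sub>ij</sub>(t) = α t² + β t + γ captures
that drift while keeping the estimation tractable. The package's central
observation: when the network is a **tree** (no undirected cycle, edges
oriented root→leaves), the number of unknowns (b₁ plus one rate per edge)
equals the number of metabolites, and at every single time point the
parameters solve an upper-triangular linear system B·θ = Ẋ whose
determinant is a product of squared concentrations — so time-resolved
rates are *uniquely* estimable. Three estimators build on this:

1. **Scheme 1** — fit P-splines, solve the triangular system at each time
   point, fit a quadratic through the pointwise rate series;
2. **Scheme 2** — substitute the quadratic rate model into the equations
   and gradient-match against spline derivatives (a constrained linear
   least-squares problem);
3. **Scheme 3** — integrate the ODE and fit trajectories to the data by
   seeded multi-start Nelder–Mead.

Around the estimators: structural identifiability certificates (tree /
triangularity), practical identifiability by profile likelihood,
sloppiness analysis via the residual Hessian spectrum, a simulation
benchmark over random tree and cyclic networks, and a
glycosyltransferase-style candidate-gene screen that correlates expression
time courses with the estimated rate curves and validates the ranking by
Metropolis substitution of expression into the kinetics.

Audience: systems biologists with metabolite time series (optionally plus
expression data) on small pathway-scale networks, and methodologists
studying gradient matching vs trajectory fitting.

## Worked example

```python
from kinetree import scheme2, structural_identifiability
from kinetree.simulate import SimulationSpec, generate

spec = SimulationSpec(n_nodes=7, topology="tree", noise_level=0.10, seed=42)
ds = generate(spec)                      # network, true rates, noisy series
fit = scheme2(ds.network, ds.noisy)      # gradient matching
print(f"b1: estimated {fit.rateset.b1:.3f}, true {ds.rateset.b1:.3f}")
for e in ds.network.edges[:3]:
    est, tru = fit.rateset.rates[e], ds.rateset.rates[e]
    print(f"k_{e[0]}->{e[1]}(7) estimated {est(7.0):.3f}, true {tru(7.0):.3f}")
print(f"residual (gradient-matching SSR): {fit.residual:.4f}")
print("structurally identifiable:", structural_identifiability(ds.network).identifiable)
```

prints

```
b1: estimated 1.019, true 1.002
k_X1->X2(7) estimated 0.757, true 0.736
k_X1->X3(7) estimated 1.426, true 1.409
k_X3->X4(7) estimated 0.680, true 0.642
residual (gradient-matching SSR): 2.9901
structurally identifiable: True
```

i.e. from one noisy (±10%) 20-point series the influx and the mid-window
rate values are recovered to a few percent, and the tree property
certifies that those estimates are the unique solution of the model.

The same functionality is available from the shell:

```bash
kinetree simulate --nodes 7 --noise 0.1 --seed 42 --out run/
kinetree fit --network run/network.json --data run/noisy.tsv --scheme 2 --out run/fit.json
kinetree rank-genes --fit run/fit.json --expr expression.tsv --out run/ranking.tsv
```

Input formats: network JSON (`nodes`, `edges`, `influx_node`) or 2-column
edge list; concentration/expression tables as TSV with a numeric-time
header row.

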