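# cldic — robust model selection for composite likelihoods

When the full likelihood of an *m*-variate observation is intractable,
inference often proceeds through a **composite likelihood**: a weighted
product of low-dimensional marginal densities,

    CL(θ, y) = ∏_k f_{A_k}(y_j, j ∈ A_k; θ)^{w_k},

over index sets A_k.  Choosing *between* candidate composite models is then
a model-selection problem, and criteria built on the composite
log-likelihood (the composite Akaike criterion, CAIC) inherit the
non-robustness of maximum likelihood: a few outlying observations can flip
the selected model.

`cldic` implements a robust alternative based on the **density power
divergence** (DPD) with tuning exponent α ≥ 0,

    d_α(g, f) = ∫ f^{1+α} − (1 + 1/α) f^α g + (1/α) g^{1+α} dy,

which interpolates between Kullback–Leibler (α → 0) and the L2 distance
(α = 1).  Its empirical kernel against a candidate composite density,

    W_{n,α}(θ) = ∫ CL(θ, y)^{α+1} dy − (1 + 1/α) · (1/n) Σ_i CL(θ, Y_i)^α,

is minimized to obtain the **composite minimum density power divergence
estimator** (CMDPDE) θ̂_cα; at α = 0 this is the composite MLE.  The
selection criterion adds a sandwich trace penalty built from the tilted
sensitivity and variability matrices

    H_α(θ) = ∫ CL^{α+1} u uᵀ dy,
    J_α(θ) = ∫ CL^{2α+1} u uᵀ dy − (∫ CL^{α+1} u dy)(∫ CL^{α+1} uᵀ dy),

with u(θ, y) = ∂ log CL/∂θ the composite score, giving

    CLDIC_α(M_k) = W_{n,α}(θ̂_cα) + (α+1)/n · tr(J_α H_α⁻¹),

minimized over the candidate models M_1, …, M_ℓ.  At α = 0 the criterion
reduces to CAIC.  Larger α buys robustness to contamination at a small
efficiency cost; a pilot-estimator MSE rule (`cldic.select_alpha`) chooses
α from the data.

The package ships the building blocks (bivariate normal and Student-t
blocks, generic user blocks, closed-form and quadrature/QMC power
integrals), the estimators, the criterion, a Monte-Carlo simulation engine
for mixture-of-normal/t studies that doubles as a synthetic-data
generator, and a worked discriminant-analysis example on Fisher's Iris
data.

## Worked example

Select between a paired-marginal composite normal and a composite t₅
candidate on 100 observations drawn from a 75/25 normal/t mixture:

```python
from cldic import sample, select
from cldic.scenarios import scenario_dgp, scenario_models

candidates = scenario_models("1a", nu=5)
dgp = scenario_dgp("1a", rho=-0.15, omega=0.75, nu=5)
data = sample(dgp, n=100, seed=7)

result = select(candidates, data, alpha=0.3,
                estimation="mixture", weights=(0.75, 0.25))
print(result.table().to_string(index=False))
print("selected:", result.selected_name)
```

prints

```
 model        wn  penalty     cldic  failed
normal -0.502598 0.001925 -0.500673   False
     t -0.097922 0.002452 -0.095470   False
selected: normal
```

`wn` is the empirical divergence kernel W_{n,α} of each candidate at the
shared CMDPDE ρ̂ (fitted under the known-weight mixture of the
candidates), `penalty` the trace term (α+1)/n · tr(J_α H_α⁻¹), and
`cldic` their sum — the normal candidate attains the smaller value despite
25% of the rows coming from the far-centered t component.

The same functionality is available from the shell:

```sh
cldic simulate --scenario 1a --alphas 0 0.3 --reps 200 --seed 42 --out table1.csv
cldic iris-example --alphas 0 0.2 0.3 0.4 0.5 0.8
cldic fit --model model.yaml --data data.csv --alpha 0.3
```

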