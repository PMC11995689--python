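# proximpute

Multiple imputation for measurement error in neighborhood
proximity-to-healthy-foods measures, with Poisson prevalence-ratio and
spatial CAR outcome models.

## The problem

Studies linking food access to neighborhood health outcomes need the
distance from each neighborhood's population center to its nearest
healthy food store. The straight-line (great-circle) proximity X\* is
essentially free to compute for every neighborhood–store pair, but it
systematically understates the routed, map-based proximity X people
actually travel — so a Poisson regression of case counts on X\* gives a
biased prevalence ratio. Querying X from a routing service for *every*
neighborhood is slow and expensive.

`proximpute` implements the middle path: query the accurate X for a
small subset of neighborhoods (Phase II of a two-phase design), then
multiply impute X for the rest from a congenial linear imputation model

    X | X*, Y, Z  ~  Normal(α₀ + α₁X* + α₂ log Y + α₃ᵀZ, σ²),

fit the analysis model

    log E(Y | X, Z) = β₀ + β₁X + β₂ᵀZ + log(Pop)

to each of B completed datasets, and pool by Rubin's rules, so that
exp(β₁) — the adjusted prevalence ratio per mile — is estimated with
nearly the accuracy of fully queried data at a fraction of the querying
cost. The package also provides the geodesic machinery (haversine
distances, the straight-line shortlist rule that bounds routed queries),
the full synthetic data-generating process used to validate the method,
Moran's I residual diagnostics, and a proper-CAR mixed Poisson model for
spatially autocorrelated outcomes.

It is intended for spatial epidemiologists and health-geography analysts
working with aggregate (e.g., census-tract) outcome data.

## Worked example

Simulate a 387-neighborhood region with severe additive error
(σ_U = 0.8 miles), query 10% of neighborhoods, and compare the four
analyses:

```python
import numpy as np
from proximpute import SimConfig, simulate_dataset, run_analysis

cfg = SimConfig(n=387, sigma_u=0.8, q=0.1, seed=7)
data = simulate_dataset(cfg)
rng = np.random.default_rng(7)
for method in ("gold", "naive", "complete_case", "imputation"):
    res = run_analysis(data, method, b=20, rng=rng)
    row = res.table.loc["x"]
    print(f"{method:>13}: PR = {row['pr']:.4f}"
          f"  (95% CI {row['pr_ci_lower']:.4f}, {row['pr_ci_upper']:.4f})")
```

```
         gold: PR = 1.0102  (95% CI 1.0085, 1.0119)
        naive: PR = 1.0108  (95% CI 1.0089, 1.0126)
complete_case: PR = 1.0094  (95% CI 1.0006, 1.0182)
   imputation: PR = 1.0101  (95% CI 1.0076, 1.0126)
```

The data were generated with a true prevalence ratio exp(0.01) ≈ 1.0101
per mile. The gold standard (true X for all units) is the unattainable
benchmark; the naive analysis (straight-line X\* everywhere) overshoots;
the complete case (only the 39 queried units) is unbiased but has a CI
almost five times wider; the imputation analysis recovers nearly the
gold-standard point estimate and most of its precision while querying
only 10% of neighborhoods.

A command-line interface wraps the same functions:

```bash
proximpute simulate-data --n 387 --seed 7 --out data.csv
proximpute analyze --data data.csv --method mi --out results.csv
proximpute distances --neighborhoods tracts.csv --stores stores.csv --out prox.csv
proximpute simulate --sigma-u 0.8 --q 0.1 --replicates 1000 --seed 1 --out metrics.csv
```

## Layout

| module | contents |
| --- | --- |
| `proximpute.geo` | haversine distances, proximity minima, shortlist rule, distance-provider contract |
| `proximpute.synth` | simulation data-generating processes, region emulator, road-inflation provider |
| `proximpute.twophase` | Phase-II sampling designs (simple random, stratified), dataset assembly |
| `proximpute.mi` | imputation model, imputed draws, Rubin pooling, the four named analyses |
| `proximpute.models` | Poisson GLM with offset, Moran's I, proper-CAR mixed Poisson (Laplace) |
| `proximpute.simstudy` | replication engine, bias/ESE/ASE/CP/RE metrics, table rendering |

See `docs/methods.md` for the statistical details and design choices.
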