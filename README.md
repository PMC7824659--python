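# moverstayer

Mover–stayer Markov modelling of intra-urban residential relocation.

Cities redistribute their populations internally: every year a fraction
of residents changes suburb while the total population stays (to first
approximation) fixed.  `moverstayer` treats this as a closed-system
Markov chain on zone populations,

```
X(t+1) = X(t) · P,      P = (1 − ε) I + ε H,
```

where `ε` is the yearly relocation frequency and `H` the row-stochastic
*spatial kernel* of destination choices conditional on moving.  The
stationary vector `X_eq` of `P` — equivalently of `H` alone — is the
"equilibrium city": the long-run spatial structure implied by current
relocation behaviour.  Relaxation towards it is formally diffusive,
`Q(t) = U(t) · L` with driving force `U = X − X_eq`, rate
`Q = X(t+1) − X(t)` and transport matrix `L = P − I = −ε(I − H)`, and
decays at the spectral rate `log |λ₂(P)|`.

The package is for quantitative geographers, urban economists and
modellers who have origin–destination relocation tables (census-style
flow counts) and want to:

- estimate spatial kernels from flow tables and predict the equilibrium
  population structure,
- diagnose how fast a city relaxes towards it (spectral decay of the
  driving force),
- calibrate a **two-component mobility mixture** from one-year and
  five-year stayer shares — a homogeneous population cannot reconcile
  the two (compounding a one-year stayer share `s₁ ≈ 0.9` predicts a
  five-year share `s₁⁵ ≈ 0.6`, well below the ~0.73 observed), whereas
  two groups with distinct frequencies `ε₁, ε₂` solving

  ```
  α(1−ε₁)  + (1−α)(1−ε₂)  = s₁
  α(1−ε₁)⁵ + (1−α)(1−ε₂)⁵ = s₅
  ```

  fit both windows exactly,
- test the rival "refractory" explanation (no moves for τ years after a
  move) and see it fail in the opposite direction,
- generate synthetic toy cities (linear distance-decay cities, random
  destination-block kernels, destination-split decompositions of a real
  kernel) for experiments without any external data.

## Worked example

Calibrate the two-component model to big-city stayer shares
(`s₁ = 0.91`, `s₅ = 0.73`, slow-component share `α = 0.95`) and read off
the implied long-horizon stayer curve:

```python
from moverstayer import StayerShares, solve_two_component, stayer_curve

result = solve_two_component(StayerShares(s1=0.91, s5=0.73), alpha=0.95)
print(result.epsilon1, result.epsilon2)
# 0.051321908423497375 0.8248837399535496
print([round(float(s), 4) for s in stayer_curve(result, [1, 5, 10, 30])])
# [0.91, 0.73, 0.5609, 0.1956]
```

The slow 95% of the population moves about once every 19 years
(`ε₁ ≈ 0.051`), the mobile 5% almost every year (`ε₂ ≈ 0.82`).  The
curve passes through both observed shares by construction and predicts
that roughly 20% of residents would still be in their current zone
after 30 years, whereas the naive single-frequency model calibrated to
the one-year share alone would predict `0.91³⁰ ≈ 0.06` — decaying far
too fast, just as it already does at the five-year window.

Equilibrium and relaxation on a synthetic 99-zone linear city:

```python
import numpy as np
from moverstayer import (LinearCitySpec, PopulationVector, RelocationModel,
                         evolve, linear_city_kernels, relaxation_diagnostics,
                         stationary_distribution)

h_center, _ = linear_city_kernels(LinearCitySpec(n_zones=99, beta=0.1, center=50))
eq = stationary_distribution(h_center, total=100_000)
print(eq.x_eq.zone_ids[int(np.argmax(eq.x_eq.values))], round(eq.x_eq.values.max(), 1))
# z50 5031.4

model = RelocationModel(0.2, h_center)
x0 = np.zeros(99); x0[0] = 100_000.0
trace = evolve(PopulationVector(x0), model, 60)
est = relaxation_diagnostics(trace, eq, model)
print(round(est.fitted_slope, 6), round(est.predicted_slope, 6))
# -0.223144 -0.223144
```

The equilibrium city is unimodal around the central zone, and the
fitted decay slope of `log ‖U(t)‖` matches the spectral prediction
`log |λ₂(P)| = log 0.8` to six decimals.

The same operations are available from the shell:

```
moverstayer calibrate --s1y 0.91 --s5y 0.73 --alpha 0.95 --json
moverstayer toy-city linear --n 99 --beta 0.1 --out H.csv
moverstayer equilibrium --kernel H.csv --total 100000 --out eq.csv
moverstayer immobility --s1y 0.91 --tau 3 --horizon 5
```

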