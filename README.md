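# agestage

Age-stage, two-sex life tables with predation-rate demography, bootstrap
inference and deterministic population projection.

## What problem this solves

Laboratory cohort studies of arthropod predators follow every individual
daily from egg to death, recording developmental stage, sex at adult
emergence, eggs laid and prey consumed.  The standard analysis of such data
is the age-stage, two-sex life table (Chi & Liu 1985; Chi 1988), which keeps
both sexes and variable developmental rates in the bookkeeping instead of
collapsing to a female-only age schedule.  `agestage` implements that
analysis end to end for predator cohorts — the motivating system is the
ladybird *Harmonia axyridis* reared on *Spodoptera litura* eggs at four
constant temperatures (15/20/25/30 °C), cohorts of 50 eggs each — together
with a synthetic cohort generator that emulates the published summary
statistics of that experiment, so the full pipeline is testable without the
(undeposited) raw records.

Intended users: insect demographers and biological-control researchers who
would otherwise run TWOSEX/CONSUME/TIMING-style analyses and want a
scriptable, tested, open implementation.

## The model

With `n_xj` the number of individuals alive in stage *j* at age *x* (days)
out of `n_01` starting eggs:

* `s_xj = n_xj / n_01`, `l_x = Σ_j s_xj`
* `m_x = Σ_j s_xj f_xj / Σ_j s_xj` with `f_xj` the mean daily eggs of
  (x, j) occupants — males and preadult deaths stay in the denominator
* `R0 = Σ_x l_x m_x`; the intrinsic rate *r* solves the Euler–Lotka
  equation `Σ_x e^{−r(x+1)} l_x m_x = 1` (age indexed from 0);
  `λ = e^r`; `T = ln R0 / r`
* life expectancy `e_xj` and reproductive value `v_xj` per age-stage cell
  (a newborn's `v` equals λ, a built-in cross-check)
* predation: `c_xj` (mean daily prey per (x, j) occupant),
  `k_x = Σ_j s_xj c_xj / l_x`, `q_x = l_x k_x`, net predation rate
  `C0 = Σ_x q_x`, transformation rate `Qp = C0 / R0`, stable age-stage
  distribution `a_xj ∝ λ^{−x} s_xj`, stable predation rate
  `ψ = Σ a_xj c_xj` and finite predation rate `ω = λψ`
* uncertainty: bootstrap over whole individuals (percentile method, paired
  bootstrap tests between scenarios at the 5% level)
* projection: day-stepped expected-value dynamics from empirical
  (x, j) → (x+1, y) transition frequencies, giving N(t) and the predation
  potential P(t) = Σ c_xj n_xj(t), with confidence bands re-projected from
  the bootstrap resamples at the 2.5th/97.5th percentiles of λ.

## Worked example

```python
from agestage import (LifeTableModel, PredationModel,
                      default_scenarios, generate_cohort)

cohort = generate_cohort(default_scenarios()[3], seed=42)   # 30C scenario
res = LifeTableModel(cohort).fit()
res.bootstrap(B=2000, seed=0)
print(res.summary())
pred = PredationModel(cohort, lifetable=res).fit()
print(pred.summary())
```

prints

```
Age-stage two-sex life table: 30C (n_01 = 50)
--------------------------------------------
R0                 116.12 ± 23.79
r                  0.1353 ± 0.0094
lambda             1.1449 ± 0.0107
T                  35.15 ± 1.48
F                  322.56 ± 27.66
Od                 15.22 ± 1.29
APOP               11.59 ± 2.58
TPOP               27.24 ± 2.55
preadult_survival  0.78 ± 0.06

Predation rates: 30C
------------------------------------
C0    6939.42
Qp    59.7608
psi   53.5466
omega 61.3035
...
```

Reading: a cohort of 50 eggs at the 30 °C scenario yields ≈116 offspring
per initial individual (`R0`), grows 14.5% per day once the age-stage
distribution stabilises (`λ`), and an average cohort member consumes ≈6 900
prey eggs over its life (`C0`), needing ≈60 prey per offspring produced
(`Qp`).  The `±` values are bootstrap SEs over 2 000 resampled cohorts.
Compare the published study's 30 °C row: r = 0.1378 d⁻¹, λ = 1.1477 d⁻¹,
T = 35.55 d, C₀ = 7 126 — the synthetic emulation reproduces the magnitudes
and the temperature ordering, not the exact values (the raw cohort was
never published).

The same pipeline runs from a shell:

```sh
agestage generate --scenario 25C --seed 1 --out cohort.csv
agestage lifetable cohort.csv --out-table lt.csv --out-params params.csv
agestage project cohort.csv --horizon 90 --bands --out proj.csv
agestage all --outdir out/ --seed 1 -B 2000     # full 4-scenario report
```

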