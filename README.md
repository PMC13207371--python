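# cigrowth — contact-inhibition models of cell population growth

Cultured cancer cell populations are routinely summarized by one of a handful
of classical growth laws — exponential, radial (Von Bertalanffy), fractal,
generalized logistic (Richards), or Gompertz — yet these laws are usually
chosen empirically. `cigrowth` implements a unifying mechanistic picture: all
five laws arise from a single on-lattice birth–death–migration process in
which **division is blocked when a cell's local birth neighborhood is fully
occupied**. Which macroscopic law emerges depends only on how cells move and
how large the neighborhood is.

The package is intended for modelers and quantitative biologists who fit
growth curves (e.g. plate-reader confluency series), who build lattice
agent-based models and want to know which mean-field law their rules imply,
or who study competition between subclones that differ in how easily they
place daughter cells.

## The model

Cells occupy sites of a lattice with `l` sites; `n(t)` cells are present and
`u = n/l` is the confluency. Each cell divides at rate λ into a uniformly
chosen empty site of its birth neighborhood (ω sites: Von Neumann ω=4, Moore
ω=8, second-order variants ω=12/24) and dies at rate δ. Writing P(ω|n) for
the probability that a focal cell's neighborhood is completely full,

    du/dt = λ u (1 − E[P(ω|n)]) − δ u.

The migration regime sets E[P(ω|n)]:

| regime | E[P(ω|n)] | emergent law |
|---|---|---|
| well mixed (fast migration) | hypergeometric; ≈ (n/l)^ω | generalized logistic: u̇ = λu(1 − u^ω̄) − δu |
| well mixed, ω̄ → 0 at fixed g = λω̄ | — | Gompertz: u̇ = −g·u·ln u − δu |
| no migration, compact cluster | (1 − n^(−1/d))^d | radial: ṅ = λd·n^((d−1)/d) − δn |
| no migration, rough boundary | 1 − d·n^(−1/d), surface n_s ∝ n^(D/d) | fractal: ṅ = λa·n^(D/d) − δn |
| neighborhood spans the lattice | indicator 1{n ≥ l} | exponential until saturation |

Because the Gompertz law only identifies the composite rate g = λω̄, fitting
exposes g for Gompertz and (λ, ω̄) for the generalized logistic. Gompertz is
a valid approximation only when 2ω̄/(σ_ω²+ω̄²) ≫ |ln u| — i.e. not at low
confluency — which predicts that Gompertz fits should *improve* as the
initial seeding confluency rises. The package tests that prediction end to
end on synthetic data via the AIC ratio AIC_Gompertz/AIC_GenLog.

Modules: `occupancy` (closed-form blocked probabilities + brute-force
oracles), `laws` (right-hand sides, closed forms, ODE solutions), `abm`
(numba-accelerated lattice simulator with blocked/surface/fractal-dimension
estimators), `gillespie` (exact well-mixed birth–death chain and
drift/diffusion estimation), `fitting` (nonlinear calibration, AIC, the
confluence and λ–ω regressions), `competition` (two coupled subpopulations,
invasion analysis), `synthetic` (in-vitro-like and in-silico dataset
generators), `cli` (command-line front end `cigrowth`).

## Worked example

Generate one synthetic cell line (true law: generalized logistic, λ = 0.02/h,
ω̄ = 8, 2% measurement noise) at two seeding confluencies and compare fits:

```python
import numpy as np
from cigrowth import fitting, synthetic

design = synthetic.SyntheticDesign(seed=1, n_cell_lines=1,
                                   u0_levels=(0.05, 0.4), replicates=1)
exp = synthetic.generate_invitro_dataset(design)
for key, ts in exp.series():
    fg = fitting.fit_growth_law(ts, "gompertz")
    fl = fitting.fit_growth_law(ts, "gen_logistic")
    r = fitting.normalized_aic(fg, fl)
    print(f"u0={key[1]}: lam_hat={fl.estimates['lam']:.4f} "
          f"omega_hat={fl.estimates['omega_bar']:.3f} ratio={r.ratio:.3f}")
```

prints

```
u0=0.05: lam_hat=0.0199 omega_hat=9.138 ratio=0.583
u0=0.4: lam_hat=0.0203 omega_hat=6.700 ratio=0.847
```

The generalized-logistic fit recovers the true (λ, ω̄) to within noise at
both seedings. The AIC ratio (Gompertz AIC divided by generalized-logistic
AIC; both negative, larger is better for Gompertz) rises from 0.58 to 0.85
as the seeding confluency grows from 5% to 40% — the Gompertz validity
condition at work: at low confluency |ln u| is large and the Gompertz
approximation degrades, at high confluency the two laws become nearly
equivalent.

The same analyses are available from the shell, e.g.

```
cigrowth synth --seed 1 --out plates.csv
cigrowth compare-aic --in plates.csv --out aic.json
cigrowth simulate-abm --width 64 --height 64 --lam 0.1 --m 0 \
    --birth-nbhd moore --seed 7 --steps 500 --out traj.csv
```

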