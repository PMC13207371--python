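# Methods

This note records the modeling assumptions, numerical choices and design
decisions behind `cigrowth`, in the spirit of a model-description appendix.

## Microscopic model

The simulator (`cigrowth.abm`) evolves an exclusion process on a 2-d lattice
(periodic by default; closed boundaries truncate neighborhoods). Per time
step `dt` (default 1), the cells present at the start of the step are
visited in uniformly shuffled order and each cell:

1. **migrates** with probability min(m·dt, 1) to a uniformly chosen empty
   site of its migration neighborhood, if one exists;
2. **divides** with probability min(λ·dt, 1), placing a daughter on a
   uniformly chosen empty site of its birth neighborhood, if one exists — a
   cell that just migrated may still divide this step;
3. **dies** with probability min(δ·dt, 1) — evaluated only when no daughter
   was placed, so a successful division shields a cell from the death draw
   that step, while a division attempt blocked by crowding does not.

Newborns act from the next step on (the shuffled list is a snapshot), which
prevents within-step cascades. All randomness flows from one seeded
generator in a fixed order (shuffle; then per cell: migration draw,
migration site, birth draw, birth site, death draw), so a (config, seed)
pair reproduces a bit-identical trajectory. Empty sites are tracked in a
swap-remove list, making full-domain migration (the well-mixed limit) an
O(1) uniform draw over all vacancies rather than a rejection loop. The step
loop is compiled with numba; a 64×64 lattice runs ≈1500 steps in well under
a second.

`full_domain` neighborhoods mean "every other site": migration to any
vacancy, or (for births) blocking only when the lattice is literally full.

## Occupancy theory

Under exchangeable cell positions the number of occupied sites among the ω
neighborhood sites of a focal cell is hypergeometric (population l−1, ω
marked sites, n−1 draws). The float path evaluates it through scipy's
log-gamma based hypergeometric pmf (stable to l = 10⁶ and beyond); the
exact path uses integer binomials and `fractions.Fraction` and serves as
the bit-exact reference. Infeasible placements return probability 0, making
the pmf total over x = 0..ω. An exhaustive enumeration oracle — literally
placing n−1 cells on l−1 abstract sites — and a uniform-configuration
sampler are kept deliberately independent of the closed forms; tests compare
the two routes as rationals for all l ≤ 12.

The radial blocked probability is the bulk fraction n₀/n = (1 − n^(−1/d))^d
of a compact cluster; its first-order expansion 1 − d·n^(−1/d) is clamped at
0 since it is only valid for n ≫ 1. The full-neighborhood case is the
indicator 1{n ≥ l}, which equals the hypergeometric expression at ω = l−1.

## Growth laws and solutions

`cigrowth.laws` implements the five laws plus second-order "corrected"
variants of the generalized-logistic and Gompertz forms that retain the
(ln u)² term weighted by the neighborhood-size variance σ_ω². For the
corrected generalized logistic the variance correction multiplies the u^ω̄
saturation factor, u̇ = λu(1 − u^ω̄(1 + ½σ_ω²(ln u)²)) − δu; this is our
reading of an ambiguity in how the bracket could be placed, chosen so the
correction vanishes smoothly as σ_ω → 0 inside the saturation term.

Closed forms: the generalized logistic is solved through the Bernoulli
substitution w = u^(−ω̄) (linear ODE in w), assembled in log space with
`logaddexp` so that u₀^(−ω̄) never overflows even at ω̄ ≈ 10²; the λ = δ
case gets its own limiting branch. Gompertz is solved in v = ln u. The
radial law with d = 2, δ = 0 integrates to n(t) = (√n₀ + λt)². The
indicator (exponential-saturating) law is integrated *analytically* as a
piecewise solution — exponential at rate λ−δ until u = 1, then sliding
along u = 1 while λ > δ — rather than handing a discontinuous right-hand
side to the ODE solver; the analytic route is exact and avoids integrator
chatter on the sliding mode. All other numeric trajectories use LSODA at
rtol 1e-8 / atol 1e-10 and are tested against the closed forms to 1e-6
sup-norm.

The Gompertz law is parametrized by the composite rate g = λω̄ throughout,
because a Gompertz curve cannot identify λ and ω̄ separately; the validity
condition 2ω̄/(σ_ω²+ω̄²) ≫ |ln u| is operationalized with a configurable
strictness factor (default 10), since "much greater" has no canonical
threshold.

## Fitting and model comparison

Fits minimize Σ(u_obs − u_model)² over the closed forms with scipy's
bounded trust-region least squares, restarted from a deterministic grid
(λ ∈ {0.01, 0.1, 1} × ω̄ ∈ {0.5, 2, 8} for the generalized logistic,
g ∈ {0.01, 0.1, 1} for Gompertz; u₀ starts at the first observation); the
best residual wins, ties to the first found, so fits are reproducible
without stochastic restarts. δ is fixed (default 0) unless explicitly
fitted — with ≤ 50-point single curves a free δ trades off against λ and
destroys identifiability. u₀ is free by default because seeding confluency
is itself noisy.

Model comparison uses the least-squares AIC, n·ln(RSS/n) + 2(k+1), counting
the error variance as a parameter; a zero RSS is floored at 1e-30 and
flagged. The Gompertz/generalized-logistic AIC ratio is interpretable in
the "> 1 favors Gompertz" sense only when both AICs are negative; any other
sign pattern is flagged non-interpretable rather than silently reported.
The confluence–AIC and ln ω–ln λ regressions are ordinary least squares
(statsmodels), reporting slope, intercept and adjusted R².

## Competition model

The two-subpopulation model couples the laws through the **total**
confluency u = u₁+u₂ in the saturation/log term while each subpopulation
keeps its own λ_i, ω_i — the minimal shared-space coupling consistent with
competition for a common dish, under which a larger birth neighborhood
(shallower saturation in u) confers a per-capita advantage at high
crowding. Gompertz subpopulation rates use the product λ_iω_i, consistent
with the composite-rate parametrization. Invasion outcomes integrate to a
numerically stationary state (max |u̇_i| < 1e-9, horizon-capped with a
flag) and classify the invader's share with tolerance 1e-3. The
classification agrees with the analytic per-capita criterion
sign(λ₂(1 − u*^ω₂) − δ) at the resident steady state, which the tests
verify away from the threshold.

## Synthetic data: what it emulates and what it does not

The in-vitro generator mimics a multi-line plate experiment: 7 lines, each
measured from five seeding confluencies {0.01, 0.05, 0.1, 0.2, 0.4} with 3
replicates on 50 samples over 240 h. Line birth rates are log-spaced over
0.02–0.06 h⁻¹ (doubling times ≈ 12–35 h, typical of cultured cancer lines)
and paired with mean neighborhood sizes descending from 8 to 1, so the
panel spans the inverse λ–ω relationship the regression stage looks for.
Measurement error is multiplicative Gaussian (CV 2%, the scale of
plate-reader confluency estimates) with clipping to (10⁻⁶, 1]; true
parameters are recorded in a manifest for recovery tests. The generator
does **not** emulate plate-edge effects, systematic segmentation bias,
batch-to-batch drift, or non-stationary growth (lag phases), so passing
recovery and direction-of-effect tests demonstrates correctness of the
pipeline, not robustness to every artifact of real imaging data.

The in-silico generator reruns the lattice model across ω ∈ {4, 8, 12, 24}
with λω fixed (default 0.1) and δ = 0.001 on a 64×64 lattice, averaging 10
seeded replicates per ω — a deliberately smaller domain than the 201×201
single-cell runs used for the spatial-regime figures, chosen so the
full pipeline (simulate → fit → regress) runs in seconds while the mean
curve is still smooth enough for stable fits.

## Estimator conventions

The per-step blocked-cell count divided by n estimates E[P(ω|n)] and is the
default normalization; division by l is also exposed since some analyses
normalize per lattice site. When validating the well-mixed limit, blocked
fraction is compared to (n/l)^ω **as a function of density**, pooling
(u, blocked) samples across replicates into u-bins: replicate-to-replicate
timing jitter (large when growth starts from one cell) makes a time-wise
comparison of ensemble means fail by a Jensen effect even when the
occupancy theory is exact. Mid-growth windows are u ∈ [0.2, 0.8] for the
well-mixed check and u ∈ [0.25, 0.75] for the no-migration radial check —
clear of both the small-n fluctuation regime and saturation/wrap-around.
The fractal dimension estimator is D̂ = d·ln n_s / ln n from the surface
scaling n_s ∝ n^(D/d), applied per time point.

## Known limitations

* The simulator is 2-d and ignores nutrient fields and cell–cell adhesion;
  the mean-field comparisons hold in the migration regimes stated above and
  degrade at low migration, where spatial correlations are the point.
* The drift/diffusion estimator uses forward increments; its O(dt_window)
  discretization bias is kept below statistical error by the default
  window, but very long windows will bias drift near the carrying capacity.
* The AIC ratio changes meaning if either AIC changes sign; the package
  flags but does not resolve this (use AIC differences for borderline
  cases).
* Invasion classification near the critical birth rate is limited by the
  finite horizon; runs that have not equilibrated are flagged.
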