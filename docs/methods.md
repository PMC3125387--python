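# Methods

## Model

The group mean exposure is estimated by a mean of means over a balanced,
three-stage nested design (`n_s` subjects × `n_d` occasions × `n_q`
quanta). Its variance, the objective to minimize, is

    s²_μ = s²_BS/n_s + s²_BD/(n_s·n_d) + s²_q/(n_s·n_d·n_q)

This is distribution-agnostic: only the variance components of the
random-effects decomposition enter, no normality or log-normality is
assumed, and the components are treated as known (estimating them from
data, e.g. by ANOVA or REML, is out of scope). Data are assumed balanced;
`balanced_mean` rejects ragged input rather than approximating.

Stage costs follow power laws derived from homogeneous production
capabilities: recruiting `n_s` subjects costs `π_s·n_s^α`, occasions
`π_d·n_d^β` per subject, quanta `π_q·n_q^γ` per occasion, giving total
variable cost `c = π_s·n_s^α + n_s·π_d·n_d^β + n_s·n_d·π_q·n_q^γ`.
Exponents of 1 make the marginal cost constant; α > 1 models increasingly
reluctant recruits, α < 1 word-of-mouth recruitment that gets easier.
Fixed costs are assumed already deducted from the budget `R`; they shift
feasibility, never the optimal allocation.

`n_q` is not a choice variable (the three-variable problem is not
treated). `reduce_to_two_stage` folds a predetermined `n_q` into
`s²_μWD = s²_q/n_q` and `c_q = π_q·n_q^γ`, after which everything is a
two-variable integer program in `(n_s, n_d)`.

## Optimization

Writing `W = s²_BD + s²_μWD` and `P = π_d + c_q`:

* **Case A (α = β = 1).** Substituting the (active) budget constraint
  gives the convex one-variable objective
  `f(n_s) = s²_BS/n_s + W·P/(R − π_s·n_s)`. Its derivative signs at the
  choice-set boundaries yield two screens: `s²_BS·(R − π_s)² < W·P·π_s`
  puts the optimum at `n_s = 1`; `s²_BS·P ≥ π_s·W` (budget-independent;
  always true when π_s = 0) puts it at `n_d = 1` with
  `n_s = R/(π_s + P)`. Otherwise the interior stationary point is
  `n_s* = R/(π_s + sqrt(W·P·π_s/s²_BS))`, `n_d* = sqrt(π_s·W/(P·s²_BS))`
  — note `n_d*` does not depend on `R`. Ties in the `n_d = 1` screen are
  classified as boundary-optimal, which matches the integer optimum on
  the knife-edge grid scenario (variances = costs = (11, 5.5, 5.5)).
* **Cases B/C (one exponent ≠ 1).** The substituted objective has no
  closed-form minimizer, but its derivative at the lower boundary is
  analytic: for α = 1, `s²_BS·(β·π_d + c_q) − W·π_s − W·(1−β)·π_d > 0`
  means one occasion per subject; for β = 1,
  `s²_BS·(R − π_s)² < W·P·π_s·α` means one subject. Both reduce to the
  Case A conditions as the exponent → 1. Convexity of the α = 1
  objective holds analytically for β ≥ 2 and is otherwise decided by a
  second-difference scan (tolerance 1e-9 relative — float noise must not
  flag spurious concavity).
* **Case D and the integer authority.** Variance is strictly decreasing
  in `n_d` at fixed `n_s` (when W > 0), so the integer optimum always
  lies on a budget-saturating pair `(n_s, n_d_max(n_s))`. The optimizer
  enumerates exactly these, `n_s = 1 … n_s,max`, finding each
  `n_d_max` by doubling plus integer bisection on the monotone cost
  (no root-finders on the continuous relaxation). This enumeration is
  the authority in *all* cases: the analytic paths above act as
  screening/diagnostics (case label, solution locus, method), and any
  closed-form result is validated against it. When W = 0 the scan
  short-circuits to `(n_s,max, 1)`.

The solution locus follows the standard taxonomy for a one-variable
objective on a choice set: interior minimum of a convex objective (I1),
boundary forced by concavity (I2, decided by comparing the boundary
values), or a monotone convex objective optimal at the lower (E1) /
upper (E2) boundary.

### Numerical choices

* **Feasibility tolerance.** `cost ≤ R·(1 + 1e-12) + 1e-9`. `n^α` is
  irrational for non-integer α; exact `≤` would misclassify
  budget-exact designs.
* **Integer refinement.** The continuous Case A optimum can sit away
  from the integer optimum in either direction (n_s* = 12.5 refines up
  to 13 at R = 500; n_s* = 21.8 refines down to 18 at R = 1000 for the
  medium-variance/medium-cost scenario), so refinement evaluates every
  budget-saturating candidate — still O(n_s,max) — plus the floor/ceil
  neighborhood of the continuous point, and is cross-checked against
  full enumeration. A one-sided neighborhood anchored at
  floor(n_s*) − 1 provably misses the R = 1000 case above.
* **Tie-break.** Among allocations with variance equal to 1e-12
  relative, prefer larger `n_s`, then lower cost — spreading
  measurements over subjects is the field's default preference. The
  source study states no tie rule; this one reproduces all 225 printed
  optima.
* **Safety cap.** 10^7 candidate evaluations per scenario; exceeding it
  raises an error rather than truncating silently.
* **Display rounding.** Half away from zero to 2 decimals for variances
  (matches the printed study values, e.g. 0.3248 → 0.32, 0.923 → 0.92);
  full precision is kept internally and in CSV output.
* **Percentiles.** Linear interpolation between order statistics
  (numpy's default); the convention is recorded in the summary object.

## The scenario study

`build_grid` constructs the 225-scenario grid: variance triples
(2, 10, 10), (11, 5.5, 5.5), (20, 1, 1) — small, medium, large
between-/within-subject variance ratio — crossed with the same triples
as unit costs and with α, β ∈ {0.50, 0.75, 1.00, 1.25, 1.50}, budget
500. Every triple sums to 22, so the cost and the variance of the
minimal design (1, 1) are 22 in every scenario; this normalization makes
variances comparable across the grid. `run_grid` optimizes each scenario
(table order: variance triple, cost triple, β, α); `summarize` reports
utilization percentiles and the count of single-occasion optima;
`compare_budgets` counts how optima shift between two budgets.

Two printed summary values are not exactly reproducible and are reported
rather than absorbed:

* The recomputed median utilization is 97.96% (97.9 is obtained only by
  truncating, not rounding, the displayed value). The recomputed 95th
  percentile is 100.0%. The printed 5th percentile of 92.3 equals the
  8th-smallest of the 225 utilizations (92.27%); no standard percentile
  convention maps that to the 5th percentile of 225 values — every
  numpy convention gives 93.5–94.2%.
* The claim that, for variances (2, 10, 10), costs (2, 10, 10) and
  α = β = 0.75, every feasible strategy outside n_s ∈ {12, 13} has
  variance ≥ 1.09 holds only for the strategies adjacent to the optimum
  (n_s = 10, 11, 14): exact enumeration finds (23, 1) at variance 0.956
  (cost 481.0) and (9, 3) at 0.963 (cost 485.5). The corresponding
  acceptance test asserts the stated bound and is intentionally left
  failing, with this analysis as its docstring.

The full 225-cell table of optima and two-decimal variances is kept as a
hand-transcribed CSV fixture (`tests/data/reference_grid_optima.csv`) and
reproduced cell-for-cell by the regression test.

## Random scenario generator

`fixture_scenarios(n, seed)` drives the property tests: variance
components and unit costs log-uniform on [0.1, 50] (spanning cheap/noisy
to expensive/stable stages over two-and-a-half orders of magnitude),
exponents uniform on [0.3, 2.5] (well beyond the study's 0.5–1.5 band),
and a budget drawn so the affordable subject count lies in [1, 500].
Draws whose full feasible integer rectangle exceeds 2·10^5 pairs are
redrawn (deterministically, from the same generator) so that the
brute-force rectangle oracle — which evaluates *every* feasible pair
without monotonicity assumptions — stays affordable; 200 scenarios
cross-check in about a second. The generator emulates parameter regimes,
not data: it cannot reveal defects in the variance model itself (e.g.
unbalanced designs, crossed components, estimated rather than known
variance components), only in the optimization machinery.

## Known limitations

* Balanced designs only; unbalanced or crossed measurement models are
  not supported.
* `n_q` is an input, never optimized.
* Variance components and cost parameters are taken as exact; no
  uncertainty propagation (Monte Carlo/bootstrap) is provided.
* With zero occasion costs (`π_d + c_q = 0`) the occasion count is
  unbounded under any budget; the search raises its cap error instead
  of answering.
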