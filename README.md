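# expoalloc

Cost-optimal allocation of exposure measurements under a fixed budget.

## The problem

Epidemiological and occupational-health studies estimate a group's mean
exposure from a balanced, hierarchical sample: `n_s` subjects, each
measured on `n_d` occasions (days), each occasion made of `n_q` sampling
quanta (minutes, work cycles). With known variance components — between
subjects `s²_BS`, between occasions within subject `s²_BD`, and within
occasion `s²_q` — the precision of the estimated group mean is

    s²_μ(n_s, n_d, n_q) = s²_BS/n_s + s²_BD/(n_s·n_d) + s²_q/(n_s·n_d·n_q)

Measurements cost money, and costs need not be linear in the number of
units: recruiting the 40th subject can be harder (or easier) than the
first. Stage costs are modelled as power laws, giving the total variable
cost

    c(n_s, n_d, n_q) = π_s·n_s^α + n_s·π_d·n_d^β + n_s·n_d·π_q·n_q^γ

With the quanta count fixed in advance (`s²_μWD = s²_q/n_q`,
`c_q = π_q·n_q^γ`) the design question is: **which integer pair
(n_s, n_d) minimizes s²_μ subject to c(n_s, n_d) ≤ R**, where `R` is the
variable-cost budget?

`expoalloc` answers this exactly for any positive exponents:

* **Linear costs (α = β = 1)** admit a closed-form analysis: boundary
  rules (`s²_BS·(π_d + c_q) ≥ π_s·(s²_BD + s²_μWD)` means "measure as
  many subjects as possible, once each"), and an interior optimum
  `n_d* = sqrt(π_s·W/(P·s²_BS))` that is independent of the budget
  (`W = s²_BD + s²_μWD`, `P = π_d + c_q`).
* **Non-linear costs** are screened by derivative-sign conditions and
  solved by exact integer enumeration: because variance decreases in
  `n_d` at fixed `n_s`, only the budget-saturating pairs
  `(n_s, n_d_max(n_s))` need be examined — one candidate per affordable
  subject count.

The package also reproduces a 225-scenario numerical study (3 variance
triples × 3 unit-cost triples × 5 α levels × 5 β levels) with budget
utilization summaries and budget-comparison counts.

## Worked example

A scenario with small between-subjects variance `(s²_BS, s²_BD, s²_μWD) =
(2, 10, 10)`, expensive recruitment `(π_s, π_d, c_q) = (20, 1, 1)`,
strongly increasing marginal costs `α = β = 1.5`, and a budget of 500:

```sh
$ expoalloc optimize --s2-bs 2 --s2-bd 10 --s2-mu-wd 10 \
    --pi-s 20 --pi-d 1 --c-q 1 --alpha 1.5 --beta 1.5 --budget 500
optimal allocation : n_s = 5 subjects, n_d = 12 occasions/subject
mean variance      : 0.733333
cost               : 491.453 (98.3% of budget)
case / locus       : D / interior
method             : enumeration
```

Five subjects measured on twelve occasions each: the accelerating
recruitment cost makes extra subjects so expensive that the budget is
better spent on repeat occasions, even though between-occasion variance
averages out more slowly. The discrete design cannot spend the budget
exactly — 98.3% is used. Under linear costs (`--alpha 1 --beta 1`) the
same scenario instead yields `(n_s, n_d) = (13, 9)` with variance 0.325.

The same from Python:

```python
import expoalloc as ea

scn = ea.Scenario(ea.VarianceComponents2(2, 10, 10),
                  ea.CostModel2(20, 1, 1, alpha=1.5, beta=1.5),
                  ea.Budget(500))
res = ea.optimize(scn)
res.allocation          # Allocation(n_s=5, n_d=12, n_q=1)
round(res.variance, 2)  # 0.73
```

Other subcommands: `evaluate` (variance/cost of a given design), `table`
(the full scenario grid as CSV plus a summary), `sweep` (the
budget-saturating profile for deviation analysis), `compare-budgets`
(single-occasion-optimum counts at two budgets).

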