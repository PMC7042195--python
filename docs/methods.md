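# Methods

## Model structure

`sibscreen` couples a four-strategy decision tree to a two-state Markov
cohort model.

**Decision tree.** A birth cohort of high-risk infant siblings is
resolved, per strategy, over three chance levels: ASD status (prevalence
`prevalence_asd`, identical across strategies), receipt of early
intensive behavioral intervention (EIBI) before age 4, and — conditional
on ASD — co-occurring intellectual disability (ID). In the Status Quo,
EIBI reaches a child with ASD with probability `p_early_intervention`.
In a test strategy every child is screened once; screen-positives
receive EIBI, and screen-negative children with ASD are monitored as
under the Status Quo, i.e. they still receive EIBI with
`p_early_intervention`. False positives receive EIBI (and its cost) but
no other effect, and Treat All assigns EIBI to everyone. Conditional ID
risk is `p_id_without_ei` without EIBI and `p_id_without_ei ×
rr_id_with_ei` with it. Every cohort member lands in exactly one of
three terminal classes: ASD+ID, ASD without ID, non-ASD.

**Markov model.** Each terminal class enters an alive/dead cohort model
at age 6 with annual cycles to a terminal age of 110. Cycle mortality is
the life-table annual death probability transformed on the
cumulative-hazard scale, `q' = 1 − (1 − q)^HR` — naive multiplication
would exceed 1 for the ASD+ID hazard ratio at old ages. Rewards accrue
at cycle start with no half-cycle correction; this convention is chosen
for bit-reproducibility and documented rather than argued — under linear
within-year accrual the expectation is unchanged. Discounted QALYs are
`Σ_t S(t)·w(age_t)/(1+r)^t` and costs substitute the age-banded annual
cost for the weight. Life expectancy is `Σ_{t≥1} S(t)` (expected whole
remaining years). Upfront costs (MRI at the scan age, EIBI before age 4)
enter undiscounted at model start because they precede the age-6 cohort;
a configuration switch (`discount_upfront_to_birth`) instead discounts
the MRI from its scan age (0.5 or 1 y) and EIBI from a nominal age of 3
for sensitivity exploration.

**Cost-effectiveness assembly.** Strategy expected cost/QALYs are the
terminal-mixture-weighted Markov payoffs plus upfront costs. Strategies
are ordered by effectiveness; strong dominance (no more effective, no
cheaper, strictly worse in one) is removed first, then extended
dominance (an incremental ICER at or above a more effective successor's)
iteratively, leaving strictly increasing frontier ICERs. Ties on
effectiveness break toward lower cost and on cost toward higher
effectiveness. The decision rule at a willingness-to-pay (WTP) threshold
selects the most effective non-dominated strategy whose incremental ICER
does not exceed the threshold; this coincides with maximising net
monetary benefit `E·WTP − C` on the frontier (property-tested).

## Parameters

All defaults live in `src/sibscreen/data/default_config.yaml`; monetary
units are 2018 USD throughout.

| parameter | default | units / meaning |
|---|---|---|
| `prevalence_asd` | 0.15 | ASD prevalence among high-risk siblings |
| `sens_mri_6` / `spec_mri_6` | 0.82 / 1.00 | 6-month MRI test characteristics |
| `sens_mri_12` / `spec_mri_12` | 0.88 / 0.95 | 12-month MRI test characteristics |
| `p_early_intervention` | 0.62 | status-quo EIBI probability before age 4 |
| `p_id_without_ei` | 0.37 | P(ID \| ASD, no EIBI) |
| `rr_id_with_ei` | 0.61 | ID risk ratio under EIBI |
| `hr_asd` / `hr_asd_id` | 2.18 / 5.78 | mortality hazard ratios |
| `qol_asd` / `qol_asd_id` | 0.68 / 0.46 | utility weights (non-ASD = 1, death = 0) |
| `cost_mri` | $1,814 | one-time screen cost |
| `cost_ei` | $148,367 | two years of EIBI-related costs |
| annual costs | $58,526 / $69,889 / $54,154 (ASD), $95,983 / $127,718 / $96,247 (ASD+ID) | ages 6–17 / 18–21 / 22+ |
| `discount_rate` | 0.03 | annual, applied to costs and QALYs |

Two small derivations are provided as library functions. The utility
pair (0.68, 0.46) is the exact solution of decomposing a pooled ASD
utility of 0.6096 at a comorbid-ID prevalence of 0.32 with an ID
decrement of 0.22 (`decompose_qol_weights`). `derive_id_risk_ratio`
computes P(IQ+gain < 70)/P(IQ < 70) under a Gaussian base IQ
distribution; it is informational — the literature behind the 0.61 base
case does not publish its base distribution or gain numerically, so the
pipeline consumes the configured value directly.

Adult utility weights are widely believed to decline with age, but no
quantitative schedule is available for this population, so the per-year
adult decrement defaults to 0 (`qol_decline_per_year`, from age 18, with
a floor); enabling an uncited default would silently shift every output.

**Perspectives.** The annual cost streams are societal totals. The
health-care and educational perspectives bear configurable fractions of
them (defaults 0.23 and 0.12, loose calibrations from the ratio of
published status-quo lifetime-cost levels after removing upfront EIBI)
and 100% of the direct EIBI and MRI costs. A detailed per-perspective
cost inventory is not available, so per-perspective lifetime cost levels
are configuration-dependent and should be treated as illustrative; the
societal perspective is the primary analysis.

## Sensitivity analyses

**One-way / tornado.** Each parameter in the `ranges` section is set to
its low and high end with everything else at base case, and the target
ICER (default: Test & Treat 6-month vs Status Quo, societal) is
recomputed; bars are sorted by |ICER_high − ICER_low|. Test
characteristics of strategies outside the target comparison are skipped.
At the upper end of the ID-risk-ratio range (rr = 1) the comparison has
exactly zero incremental QALYs and the ICER is reported as infinite,
making that bar the widest by construction as well as in substance. The
two `annual_cost_scale_*` pseudo-parameters implement the ±25% variation
of the cost schedule. A structural note: varying a mortality hazard
ratio moves the affected class's QALY payoff and cost payoff in
compensating directions, so over their narrow tested ranges the
hazard-ratio bars come out narrower than the MRI-cost bar — MRI cost is
the narrowest *cost* bar but not the narrowest bar overall in this
implementation.

**Probabilistic.** The eight distribution-specified parameters (tree
probabilities, the ID risk ratio, hazard ratios, utility weights) are
drawn independently from beta or gamma distributions moment-matched to
their configured mean/SD; test characteristics and all costs are held
fixed. Each of the n draws re-runs the full pipeline and records the
incremental (cost, QALY) pair of the comparator vs the baseline. Every
parameter has its own random substream keyed by (master seed, SHA-256 of
the parameter name), so results are bitwise reproducible and adding a
parameter never perturbs the others' draws. The two utility weights are
sampled independently with their ordering constraint relaxed — their
wide, overlapping distributions are what produce the minority of draws
with negative incremental QALYs, as intended. CE-plane summaries report
exact quadrant shares and, conditional on a QALY gain, the share of
draws with ICER below each WTP threshold (cost-saving draws count as
below every threshold). The default PSA size is 10,000 draws, which runs
in a few seconds on one core.

## Synthetic life table

The bundled fixture is a Gompertz–Makeham table, hazard
`h(x) = λ + a·e^{bx}`, integrated exactly over each year of age:
`q(x) = 1 − exp(−λ − (a/b)·e^{bx}(e^b − 1))`, ages 0–110 with the
terminal entry forced to 1. Defaults are λ = 4×10⁻⁴ (background, sets
the near-flat child/young-adult mortality level), b = 0.0955/yr (adult
log-mortality slope), and a solved once by bisection so remaining life
expectancy at age 6 equals 73.2 years — the 2012 U.S. both-sexes
period-table value, inside the 70–75-year window the engine assumes.
The frozen constant is checked against the bisection oracle in the test
suite, and `calibrate_senescent_hazard` / the `make-lifetable` command
re-solve for any other target.

What the fixture reproduces: realistic child mortality levels, the
exponential adult rise, and the life expectancy that anchors all
lifetime sums. What it does not: the federal table's exact `qx` values,
infant-mortality hump, accident hump, or sex stratification. Absolute
lifetime costs and QALYs therefore differ from analyses run on the
federal table (by roughly the ratio of discounted survivorships), while
the decision-tree outcomes are fixture-independent and the frontier
shape, strategy ranking, WTP decision and CE-plane proportions are
robust to any table in the calibration window. Concretely: the societal
base-case ICER computes to ~$45,100/QALY here vs a published ~$49,300 on
the federal table, and lowering 6-month specificity to 0.98 raises it to
~$95,500 vs a published ~$102,000 — same decisions, fixture-scale
differences. Users wanting closer replication can pass the real table as
an `age,qx` CSV.

## Numerical conventions and degenerate inputs

- All internal arithmetic is double precision; reported tables round
  costs to whole dollars and QALYs/prevalences/risk ratios to 4 d.p.
- An ICER with zero incremental QALYs raises an explicit error in the
  public `icer()` API; inside tornado sweeps it is reported as a signed
  infinity so sorting remains total. A comparator that saves money while
  gaining QALYs is flagged as dominant rather than given a ratio.
- Beta moment matching requires sd² < mean·(1−mean); infeasible inputs
  fail with the bound named. Gamma matching uses shape = (mean/sd)²,
  scale = sd²/mean. Both round-trip to 1e−9 relative.
- Life tables must be gap-free with q ∈ [0,1] and terminal q = 1;
  violations fail at construction with the offending age named.
- A zero-prevalence cohort yields identical QALYs across strategies and
  an undefined ID relative risk, reported as missing rather than raised.

## Known limitations

- Severity is collapsed to the ID dichotomy; utility weights derived
  from children are assumed stable (or configurably declining) into
  adulthood.
- No negative effect of false-positive labelling or of intervention
  beyond cost; no repeat or sequential screening protocols; no budget
  impact analysis.
- PSA draws are mutually independent; no correlation structure is
  published for these parameters.
- Per-perspective cost splits are configurable approximations (see
  above), so health-care and educational lifetime cost levels are
  indicative only.
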