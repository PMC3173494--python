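# Methods

## Model

`copdsim` implements a patient-level (Monte-Carlo) multi-state Markov model
of chronic obstructive pulmonary disease (COPD) in a cohort of English
smokers. The living states are the four GOLD severity stages
(GOLD1 < GOLD2 < GOLD3 < GOLD4); death is absorbing. The cycle length is one
year and each patient is followed from cohort entry (ages 40–89) until death
or age 110.

Within a cycle the order of events is fixed:

1. **Smoking turnover** — a smoker quits with probability 0.047, an
   ex-smoker relapses with probability 0.026, constant over age and stage.
   Turnover applies from the first cycle onward, including to patients an
   intervention has just switched to ex-smoker (fresh quitters may relapse
   in their first year). Turnover can be disabled, which turns the arms into
   continuous smokers / sustained quitters.
2. **Exacerbation** — a Bernoulli draw per stage (25.0/39.45/44.10/65.70 %
   for GOLD1–4). The flag lasts one cycle and affects the death probability
   and the utility of that cycle only — not progression and not cost. In the
   reference case it does not depend on smoking status; two sensitivity
   scenarios split it by status.
3. **Competing progression/death** — a single categorical draw with
   `p_die = death_prob(stage, age band, smoking, exac)`,
   `p_progress = progression_prob(stage, age band, smoking) · (1 − p_die)`,
   and `p_stay` the remainder. Death is resolved first so the three
   probabilities always sum to 1 without clamping. GOLD4 cannot progress.

**Accrual convention.** A patient alive at cycle start accrues the full
year — one life-year, the utility of the stage/exacerbation state occupied
that cycle, and the stage's annual cost — even if death occurs in that
cycle. There is no half-cycle correction; this makes the geometric
closed form (expected lifetime `1/q` under a constant death probability `q`)
exact, which the test suite exploits.

**Discounting.** Costs and QALYs are discounted at 3.5 %/year (the NICE
reference case) with cycle 0 undiscounted; a `discount_from_cycle_one`
configuration flag shifts the schedule for users who prefer the alternative
convention. Life-years are reported undiscounted: the published convention
discounts monetary and QALY streams only, and undiscounted life expectancy
is the quantity comparisons are stated in.

## Parameters and derived tables

All scalar inputs (severity distribution 35.08/48.17/13.96/2.79 %, turnover
rates, exacerbation rates, utilities, annual costs 220/726/3758/9470 £,
discount rate, maximum age) are the published reference-case values.
Utilities use the four-decimal values (0.8971/0.7511/0.7481/0.5493 stable;
0.8951/0.7364/0.7261/0.5357 exacerbated); the three-decimal rounding seen in
some summaries is below output precision.

The stage-progression and mortality tables are keyed by (stage, 10-year age
band, smoking status[, exacerbation flag]). Sources report probabilities
while the modifying factors are relative hazards, so the builders compose on
the rate scale:

    rate(p)   = −ln(1 − p)
    progression p[s, b, m]    = 1 − exp(−modifier_m · rate(baseline[s, b]))
    death p[s, b, m, e]       = 1 − exp(−excess_s · smoking_m · exac_e · rate(all_cause_b))

which keeps every derived probability in [0, 1] for any positive hazard and
makes monotonicity in each hazard automatic. Single-year ages map to their
containing band; ages beyond the last band reuse it (logged once). Age bands
are configuration, not code.

### The bundled table reconstruction

Per-cell progression and mortality tables for English COPD patients are not
available as published numbers, so the bundled defaults are a **synthetic
reconstruction** built by the package's own builders from documented
component inputs:

* all-cause mortality 0.002 → 0.35 per year over bands 40–49 … 100+,
  approximating a recent UK life table;
* COPD excess-mortality hazards 1.2/1.5/2.6/4.2 for GOLD1–4, with upper and
  lower sensitivity limits at ±30 % (exposed as plain configuration scalars);
* a smoker-vs-ex-smoker mortality hazard of 1.45;
* an exacerbation death hazard of 1.25;
* smoker progression baselines rising with age (GOLD1 0.030–0.050,
  GOLD2 0.045–0.065, GOLD3 0.012–0.026 per year) and an ex-smoker
  progression modifier of 0.5, reflecting lung-function decline roughly
  twice as fast in continuing smokers.

Component values were chosen once so that the model reproduces the
published *qualitative* behaviour it is validated against: mean entry ages
of 60/57/60.5/64.6/64.6 years (all-stage and per-stage cohorts, GOLD3 and
GOLD4 age distributions identical, ages uniform within each 10-year class),
cell-wise ex-smoker dominance of both tables, a monotone severity gradient
of the QALY gain from cessation, and headline magnitudes of the right scale
(all-stage QALY gain ≈ 0.67 with relapses allowed; ten-year national burden
in the hundreds of millions of pounds with ≈ 4×10⁵ QALYs lost for 1.4
million smokers). Exact reproduction of published table-level outputs is
*not* claimed and the test suite deliberately asserts only signs, orderings
and order-of-magnitude for reconstruction-dependent quantities. Users with
access to better transition/mortality estimates can supply them directly
via the `progression_table` / `mortality_table` configuration keys.

What the synthetic defaults do **not** emulate: cohort-level heterogeneity
beyond (stage, age band, smoking), secular trends in treatment or mortality,
comorbidity costs, and incident COPD cases entering after initialisation.
Passing tests therefore demonstrate internal consistency and fidelity to the
published arithmetic and orderings, not predictive accuracy for real English
patients.

## Evaluation routes and their cross-check

Every comparison can be computed two ways:

* **Microsimulation** (`simulate_cohort`) — vectorised over patients. The
  random stream consumes exactly `3n` uniforms per cycle whether or not
  patients remain alive, so two arms simulated with the same seed share
  event draws cycle-for-cycle (common random numbers). Arms of a comparison
  reuse the same cohort and stream; deltas therefore have far lower variance
  than independent runs, and a parameter change that affects nothing (for
  example a null intervention) yields exactly zero deltas.
* **Expectation propagation** (`cohort_expectation`) — exact forward
  propagation of occupancy probabilities over (stage, age, smoking) through
  the same cycle rules, taking expectations over the exacerbation mixture
  (legitimate because the cycle's event probabilities are linear in the
  exacerbation indicator). Occupancy conservation is checked to 1e-9 every
  cycle. This is the deterministic oracle: the suite requires Monte-Carlo
  means at n = 10⁵ to sit within three standard errors of it.

## Economics

Incremental results are intervention minus comparator means; the ICER is
`(Δcost + programme_cost)/ΔQALY`, with the programme cost charged once per
cohort member at entry, undiscounted, regardless of quit success — this is
what makes the ICER affine in the programme cost with slope `1/ΔQALY` and
reproduces the published grid arithmetic (e.g. `(−606 + 1000)/0.228 = 1728`).
A zero QALY difference returns a NaN sentinel (with an explanatory note)
rather than raising, so dominance bookkeeping can proceed. Displayed ICERs
and costs are rounded to integer £ and LY/QALY to 2–3 decimals, mirroring
the published tables; machine-readable output keeps full precision.

## Scenarios

The intervention grid crosses initial abstinence rates {1, 1/3, 1/6, 1/12}
with programme costs {0, 100, 200, 500, 1000} £; each (stratum, rate) pair is
simulated once and every cost column re-prices the same deltas.

Sensitivity scenarios A–K perturb the reference case one parameter at a
time: exacerbation-free uplifts of +30 %/+15 % for ex-smokers (A, E) or all
patients (H), interpreted multiplicatively on the exacerbation-free
probability `1 − p` and clamped at 1 with a warning; excess-mortality upper
and lower limits (B, D), which rebuild the mortality table from the stored
components; death probabilities ×1.30 (C); discounting off (F) or at 5 %
(I); GOLD1 management cost zero (G); all costs ×1.15 (J); and progression
×1.30 (K), applied on the rate scale (`p' = 1 − (1−p)^1.3`) for consistency
with the hazard framework. Published summaries disagree internally on
whether letter G or J denotes the GOLD1-zero-cost scenario; this package
follows the figure-caption assignment (G = GOLD1 cost zero, J = +15 % costs)
and additionally exposes every scenario under a descriptive name
(`gold1_cost_zero`, `all_costs_times_1_15`, …) so the lettering ambiguity is
harmless. Where a perturbation would push death + progression past the
one-cycle budget in the oldest bands (C, K can), progression is shrunk to
fit and a warning is logged.

The population-burden analysis compares continuous smokers to sustained
quitters over the first 10 cycles only (per-year traces truncated at the
horizon), scales per-patient excess cost and QALY loss to 1.4 million
patients, and discounts at the NICE rate by default; whether to discount is
exposed as a flag since conventions differ for budget-impact figures.

## Numerical and design choices

* Entry ages are integer years, class lower bound plus a uniform offset;
  cycle length is one year so finer granularity adds nothing.
* Cohort sampling is by independent draws (an exact-quota switch exists for
  variance-reduced tests).
* Stage, age-band and smoking lookups are exact array indexing — no
  interpolation anywhere.
* Default problem sizes: 10⁵ patients per arm for headline runs and the
  oracle cross-check, 2–5×10⁴ for secondary directional checks; at 10⁵ the
  standard error of a QALY delta under common random numbers is well below
  the smallest gradient gap asserted.
* Seeds: a single integer seed spawns independent child streams for cohort
  sampling, intervention assignment and simulation, so arms stay paired
  while stages of the pipeline stay independent.

## Known limitations

* The reconstruction of the progression/mortality tables is plausible, not
  estimated from microdata; absolute costs and ICERs shift with it (the
  all-stage ICER is robustly negative, but its magnitude is
  reconstruction-dependent).
* No probabilistic sensitivity analysis; the scenario suite is one-way and
  deterministic, matching the scope of the original analysis.
* No treatment effects beyond smoking status, no inter-patient interaction,
  no incident cases after initialisation.
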