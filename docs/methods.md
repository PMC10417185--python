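# Methods

## Model structure

The engine (`colcea.engine`) is a discrete-time cohort Markov model
with 1-month cycles and a horizon of `min(300, 12 × (85 − start_age))`
cycles (base start age 60, so 300 cycles / 25 years). The cohort
starts disease-free after curative resection. States:

- `DISEASE_FREE`;
- `RECURRENCE`, divided into three pathways fixed at entry —
  hepatectomy (fraction 1/3 × 1/3 = 1/9 of recurrences: liver-only and
  resectable), first-line palliative chemotherapy, second-line
  palliative chemotherapy — each represented as a tunnel array indexed
  by months since recurrence, because post-recurrence death
  probabilities are time-since-event indexed. At 300 cycles the tunnel
  costs ~300 floats per pathway, so no compression is attempted;
- `DEAD_CC` and `DEAD_OTHER`, absorbing.

Colon cancer death is only reachable from the recurrence states;
disease-free patients die only of background causes, matching the
model's state diagram.

**Within-cycle competing risks.** From every alive state, background
death is applied first and the disease event (recurrence, or cancer
death in the tunnels) second: `P(recurrence in cycle t) =
(1 − p_other[t]) × p_recur[t]`. The published description is silent on
ordering; this convention is used consistently in the engine and in the
micro-simulation test oracle, and it makes the disease-free survival
round trip against the source curve exact (see *Internal validation*).

**Half-cycle correction.** State-time for cycle `t` is the trapezoid
`(occupancy(t) + occupancy(t+1)) / 2`. It is applied to overall
survival, per-state-time costs and disability time. One-time
transition quantities (course costs at line entry, hepatectomy,
adverse events, deaths) are flows within the cycle and are not
half-cycle corrected.

**Chemotherapy lines.** The source material caps palliative treatment
at two lines but does not print a first-line progression rate. Design
choice: first-line patients who survive a fixed
`first_line_duration_months` (default 8, configurable) move to second
line; the transition affects costs and event flows only. Survival
after recurrence is always governed by the stratum curve indexed by
months since recurrence — the same choice the model makes for
hepatectomy patients, for whom no separate post-resection survival
curve exists.

## Calibration

`colcea.calibration` converts survival information to monthly
probabilities.

- Curves are resampled to the monthly grid by linear interpolation of
  log-survival (exact for exponential segments); the monthly
  probability is the discrete hazard `p[t] = 1 − S(t+1)/S(t)`. If the
  curve reaches zero the schedule terminates with probability 1.
- Recurrence schedules are truncated to zero after the last observed
  curve time (60 months for the shipped fixtures), mirroring the
  disease-free-survival plateaus of the source trials rather than
  extrapolating; recurrence risk is treated as exhausted.
- Hazard ratios use the grouped-data proportional-hazards transform
  `p' = 1 − (1 − p)^HR` (identity at HR = 1, multiplicative
  composition). The single-agent/no-adjuvant post-recurrence stratum
  is the doublet stratum adjusted with HR = 1.61.
- The abridged life table is looked up by the band containing the exact
  fractional attained age, with `p_month = 1 − (1 − q_annual)^(1/12)`,
  so twelve cycles inside a band compound back to the band's annual
  probability exactly. No smoothing between bands.

## Internal validation (5-year DFS round trip)

`validate_dfs` compares the model's 5-year disease-free survival
against the curve its recurrence schedule came from. The model adds
background mortality on top of the trial curve, so the disease-free
occupancy is divided by the cumulative background survival along the
disease-free path, `Π(1 − p_other[t])`, which the engine records on the
trace. Under the declared competing-risk ordering this cancellation is
exact: the round trip reproduces the curve to floating-point precision,
and any deviation measures genuine mis-calibration. (Normalising by
`1 − cumulative DEAD_OTHER` instead would under-correct, because
patients who die of cancer can no longer die of background causes; the
residual error of that variant approaches the 1.5% validation bound on
high-recurrence arms, defeating the purpose of the check.) The shipped
fixtures pass at ~1e-13 relative; the 1.5% bound is the published
internal-validation criterion.

## Economics

- **Currency.** Costs are accounted in 2021 ZAR and divided by the
  2021 purchasing-power parity 7.097 ZAR/I$; display values are rounded
  half-up to the nearest dollar, internal values are never rounded.
- **Discounting.** Per-cycle factor `(1 + r)^(−t/12)` (exact 5% annual
  compounding; the simple `r/12` monthly rate is rejected because
  twelve months would not compound to the annual rate). A cost at
  cycle 12 is discounted by exactly 1.05. Rate 0 reproduces
  undiscounted sums identically.
- **Cost attachment.** The adjuvant course is spread uniformly over
  its 3 or 6 treatment months, paid by the disease-free fraction still
  on treatment. Metastatic course costs attach once at line entry,
  hepatectomy at pathway entry. Adverse-event costs attach at
  incidence during treatment months. Surveillance items (bloodwork,
  CT, colonoscopy) follow a configurable visit calendar applied to
  disease-free occupancy; the default is a standard 5-year programme
  (bloodwork q3mo years 1–2 then q6mo years 3–5, annual CT, colonoscopy
  at years 1 and 4) — the original's calendar lives in an unavailable
  supplement. Indirect societal costs (transport 41 + lost wages 138
  ZAR per person-day) attach per visit-day: CT one person-day,
  colonoscopy and treatment visits two (patient + caregiver); monthly
  adjuvant visits, and a fixture 8 visit-days per metastatic course.
  The grade 2/3 residual-neuropathy annuity (206 ZAR/year) accrues
  monthly for 36 months post-treatment.
- **DALYs.** `DALY = YLL + YLD`, discounted, no age weighting. YLL
  accrues `DEAD_CC` state-time at weight 1 up to the horizon — the
  within-horizon weight-1 convention of the source parameter table,
  *not* the GBD standard-life-expectancy formula; this materially
  changes DALY magnitudes and is deliberate. Background death accrues
  nothing. YLD: recurrence state-time (all pathways, including
  post-hepatectomy) at annual weight 0.451; adverse events at their
  weights for one month per event; residual neuropathy at 0.133 for
  36 months in affected patients.
- **Frontier.** Strategies are sorted by ascending cost (ties broken
  toward higher effectiveness and logged); strictly dominated
  strategies (costlier, no more effective) are excluded; sequential
  ICERs are computed on the remaining list; a strategy whose ICER
  exceeds that of the next-costlier strategy is extended-dominated.
  Reported ICERs are **not** recomputed after extended-dominance
  removal — the only convention consistent with the published stage II
  table (ICER 250 rather than the recomputed 629); the textbook
  recomputation is available via `recompute_after_extended=True`. The
  recommended strategy is the costliest retained one with ICER ≤ WTP,
  cross-checked in tests against NMB maximisation.
- **Display rounding.** Costs/NMB/ICER to the nearest I$, DALYs and
  life years to 2 decimals, matching the published table format.

## Sensitivity analyses

- **One-way deterministic.** Costs −50%/+100%, probabilities ±25%
  (as hazard-scale multipliers), discount rate 0–0.10 absolute.
  Tornado bars are sorted by |ICER_high − ICER_low|; no symmetry is
  asserted or expected. Threshold finding is plain bisection on the
  multiplier to relative tolerance 1e-4; absence of a crossing in the
  bracket is reported as "no threshold", not an error.
- **Probabilistic.** Distributions per the published table: beta for
  probabilities and incidences (method of moments, sd = 10% of base),
  gamma for costs (sd = 25% of base), classical PERT (shape 4) over
  printed min/mode/max for disability weights. Time-varying schedules
  are perturbed by a single scalar per draw: a beta draw around the
  schedule's mean monthly probability, converted to a hazard multiplier
  — "varied simultaneously" at the parameter level while keeping each
  curve coherent. WTP and the discount rate are excluded from draws
  (handled by the WTP grid and the deterministic sweep). One joint
  draw per iteration applies to all strategies; shared parameters are
  common across arms. RNG: one root seed spawning per-iteration child
  streams (`numpy.random.SeedSequence`), recorded in the output
  metadata; identical seeds give bit-identical outputs. Iterations
  producing invalid configurations are rejected, logged and counted
  (the hazard-multiplier and beta/gamma constructions make this
  essentially impossible by design). The configured default is 5,000
  iterations (the published analysis ran 100,000); tests and examples
  use tens to hundreds, which is ample for the structural assertions
  they make.
- **Subgroups.** Per-strategy recurrence hazard multipliers via the
  proportional-hazards transform. The true subgroup adjustments
  (PATTERN- and IDEA-derived) are in unavailable supplements; the
  shipped values in `colcea.synthetic.SUBGROUP_MULTIPLIERS` are
  documented synthetic stand-ins built on two qualitative facts: T4/N2
  disease roughly doubles recurrence risk, and longer doublet therapy
  retains relatively more benefit in higher-risk disease. The
  operation accepts arbitrary multipliers so real values can be
  substituted.
- **Scenario.** The all-capecitabine scenario swaps every
  FOLFIRI-bearing metastatic line to XELIRI at the XELIRI course cost,
  leaving survival schedules unchanged (regimens treated as
  equivalent). Regimen labels are assigned so FOLFIRI appears exactly
  where the scenario applies: first line after CAPOX adjuvant therapy
  and second line after no adjuvant therapy.

## Synthetic fixtures: what they emulate, and what they do not

The original model was calibrated to Kaplan–Meier curves digitized
from randomized-trial figures; those traces were never deposited. The
printed evidence is the *range* of each arm's implied monthly
recurrence probability, all costs, and the disability weights.
`colcea.synthetic` therefore generates:

- **DFS curves**: Weibull by default, with shape and scale root-solved
  (Brent) so the first and last monthly probabilities over the 60-month
  support hit the printed range endpoints (aimed a relative 1e-6 inside
  the endpoints so floating-point noise cannot leave the closed range).
  Shape > 1 reproduces the rising-then-exhausted recurrence hazard of
  the source trials; the schedule is zero after 60 months. Exponential
  and piecewise-exponential families are kept for analytic tests. A
  variant solves the scale for a target 5-year survival at fixed shape
  and validates range containment, erroring with the attainable range
  when infeasible.
- **Post-recurrence survival**: exponential for the doublet stratum
  with fixture medians of 30 months (stage II) and 21 months
  (stage III), HR 1.61 applied for the single-agent/none stratum.
- **Life table**: 5-year bands, ages 40–85, annual probabilities
  0.009 → 0.085, shaped after South African total-population mortality.
- **Strategy specifications** with the printed ZAR costs; adverse-event
  incidences, residual-neuropathy incidence, metastatic visit-days and
  the XELIRI course cost (20,750 ZAR) are synthetic fixtures chosen
  once from the trial-safety literature and stated in
  `colcea.synthetic`.

Consequences for interpretation: the printed stage II ranges differ by
only 0.0001/month between the CAPOX durations, so under
endpoint-pinned curves CAPOX 6 months is *slightly less* effective than
CAPOX 3 months at base case (its residual-neuropathy burden outweighs
the small recurrence advantage), whereas the published analysis — with
access to the full curves — found it marginally more effective (+0.07
DALYs averted). Absolute lifetime costs, survival and DALY totals are
likewise not reproducible from ranges. Passing tests therefore
demonstrate the *machinery* (calibration round trips, frontier
arithmetic, dominance labelling, discounting, distributional sampling)
exactly, and the published *findings* directionally: survival ordering
(CAPOX arms > capecitabine > none), CAPOX 3 months recommended at base
case in both stages with no-adjuvant and CAPOX 6 months dominated in
stage III, escalation to CAPOX 6 months in high-risk subgroups, and
robustness of the recommendation to the XELIRI scenario and to start
ages 40–80. The stage III printed ranges overlap at the earliest
months (capecitabine min 0.0015 < CAPOX-6 min 0.0017), so the
cross-strategy hazard ordering is asserted pointwise for stage II but
on cumulative 5-year hazard for stage III.

## Numerical choices

- Occupancy conservation is enforced to 1e-9 per row; absorbing-state
  occupancies must be non-decreasing.
- Root solves (Weibull calibration) use `scipy.optimize.brentq` with
  xtol 1e-12; shape is bracketed in (1, 12].
- Hazard multipliers compose multiplicatively
  (strategy-specific × global).
- Equal-cost frontier ties are broken toward higher effectiveness and
  logged; exact duplicates keep the first entry.
- File outputs use fixed float formatting (`%.12g`) and sorted keys;
  run manifests contain no wall-clock fields, so identical
  configuration + seed re-runs are byte-identical.
- Post-recurrence schedules extend 360 months; the engine pads a short
  cancer-death schedule only past the horizon (never silently within
  it — a schedule shorter than the horizon is a named error).

## Known limitations

- Tunnel pathways share one post-recurrence survival curve per
  stratum; hepatectomy patients get no distinct (better) survival, and
  line transitions are cost events only.
- The DALY YLL convention is horizon-limited, not standard-life-table
  based; DALY magnitudes are not comparable to GBD-style estimates.
- Fixture curves bound, but do not reproduce, the true trial time
  profiles; absolute published totals are out of reach by construction.
- External validation against the local prospective cohort used by the
  original analysis requires data that are not publicly available; only
  the model-output side of such a comparison exists here.
- No EVPI, no correlated draws beyond shared parameters, no budget
  impact, QALYs or age-weighted DALYs.
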