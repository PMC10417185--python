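# colcea

Markov cohort cost-effectiveness analysis of adjuvant chemotherapy for
high-risk stage II and stage III colon cancer in a public-sector health
system (South African setting, 2021 costs).

After curative resection of locally advanced colon cancer, four
strategies compete: capecitabine + oxaliplatin (CAPOX) for 3 months,
CAPOX for 6 months, capecitabine alone for 6 months, and no adjuvant
chemotherapy. `colcea` implements the decision model that compares
their lifetime costs and health losses and identifies the
cost-effective strategy at a willingness-to-pay threshold, for health
economists and oncology policy analysts working in resource-constrained
settings.

## The model

A monthly-cycle cohort Markov model with half-cycle correction.
Patients start disease-free at age 60 and transition among

- `DISEASE_FREE` — post-resection, under surveillance;
- `RECURRENCE` — metastatic recurrence, split at entry into a
  curative-intent hepatectomy pathway (1/3 of recurrences are
  liver-only, 1/3 of those resected) and first-/second-line palliative
  chemotherapy (at most two lines), modelled as tunnel states indexed by
  months since recurrence;
- `DEAD_CC` / `DEAD_OTHER` — absorbing death states (colon cancer vs
  background causes).

The model runs for 300 months or until age 85. Transition probabilities
come from survival curves via the discrete hazard
`p[t] = 1 − S(t+1)/S(t)`; post-recurrence survival for the
single-agent/no-adjuvant stratum is adjusted with the
proportional-hazards transform `p' = 1 − (1 − p)^HR` at HR = 1.61;
background mortality comes from a WHO-style abridged life table.

Outcomes per strategy:

- discounted lifetime cost (societal perspective, 2021 ZAR, converted
  to international dollars at 7.097 ZAR/I$), discounted at 5%/year with
  exact monthly compounding;
- DALYs = YLL + YLD (no age weighting), where YLL accrues
  colon-cancer-death state-time at weight 1 within the horizon and YLD
  accrues recurrence time at weight 0.451 plus treatment adverse-event
  disability;
- undiscounted overall survival in life years;
- `ICER = ΔCost / ΔDALYs averted` between successive strategies on the
  cost-sorted frontier, with strict and extended dominance labelling;
- `NMB = WTP × DALYs averted − Cost` at WTP I$13,764/DALY averted
  (2021 GDP per capita).

Sensitivity machinery: one-way deterministic ranges with tornado
output and ICER/WTP threshold search; probabilistic analysis with
beta (sd 10%), gamma (sd 25%) and PERT draws, cost-effectiveness
acceptability curves over WTP from I$6,882 to I$41,292; subgroup
re-parameterisation via per-strategy recurrence hazard multipliers; an
all-capecitabine (XELIRI) metastatic scenario.

Because the digitized trial curves behind the original calibration were
never published, the `colcea.synthetic` module generates survival-curve
fixtures pinned to the published per-month recurrence probability
ranges; see `docs/methods.md` for exactly what those fixtures do and do
not emulate.

## Worked example

```python
from colcea import make_full_config, run_base_case

config = make_full_config("stage_iii", seed=1)
report = run_base_case(config)
print(report.to_display_dataframe().to_string(index=False))
print("recommended:", report.recommended)
```

prints

```
   strategy  total_cost_intl  total_cost_zar  os_years  dalys  dalys_averted  icer   dominance  nmb_intl  recommended
   cape_6mo           5799.0         41159.0     11.37   4.54           2.47   NaN   REFERENCE   28251.0        False
  capox_3mo           6155.0         43682.0     13.23   3.13           3.88 252.0 UNDOMINATED   47317.0         True
no_adjuvant           6193.0         43955.0      8.24   7.02           0.00   NaN   DOMINATED   -6193.0        False
  capox_6mo           7990.0         56702.0     12.72   3.57           3.45   NaN   DOMINATED   39472.0        False
recommended: capox_3mo
```

Reading the table: with the synthetic stage III fixtures, forgoing
adjuvant therapy is *dominated* — it costs more (metastatic treatment
of the many recurrences) and averts nothing. CAPOX for 3 months averts
3.88 DALYs per patient versus no adjuvant therapy and costs I$252 per
additional DALY averted relative to capecitabine; since that is far
below the willingness-to-pay of I$13,764, it is the recommended
strategy. CAPOX for 6 months adds cost and toxicity without added
benefit here and is dominated.

The same analyses are scriptable from the shell:

```sh
colcea make-fixtures --stage 3 --seed 1 --out fixtures/stage3
colcea base-case --config fixtures/stage3 --out out/base
colcea dsa       --config fixtures/stage3 --out out/dsa
colcea psa       --config fixtures/stage3 --iterations 1000 --seed 1 --out out/psa
colcea subgroup  --config fixtures/stage3 --subgroup t4_or_n2 --out out/sub
colcea scenario  --config fixtures/stage3 --out out/scenario
```

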