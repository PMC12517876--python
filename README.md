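# upfsim

Microsimulation of **ultra-processed food (UPF) purchase restrictions in
SNAP** (the U.S. Supplemental Nutrition Assistance Program), for diet-policy
analysts who want a transparent, fully seeded pipeline from 24-hour-recall
food records to projected cardiometabolic risk changes.

Ultra-processed foods — NOVA group 4: industrial formulations with
additives and little intact whole food — supply over half of U.S. caloric
intake, and SNAP participants consume disproportionately more of them.
`upfsim` asks: *if a fraction f of UPF intake were replaced isocalorically
by minimally processed alternatives, how would sodium, added sugar and
fiber intake shift, and what blood-pressure and disease-risk changes would
follow?*

## The model

1. **NOVA classification.** Each recalled food description is assigned a
   NOVA group by a priority-ordered, whole-word keyword rule table
   (auditable: every assignment logs the rule that fired; the rule table is
   a versioned CSV whose hash stamps every run).
2. **Isocaloric substitution.** A scenario replaces fraction *f* of the
   UPF aggregate with a substitute containing, per unit energy, 50% of the
   sodium, 20% of the added sugar and 150% of the fiber. In
   reduction-positive convention:

   Δsodium = (1 − 0.5)·f·UPF_sodium, Δsugar = (1 − 0.2)·f·UPF_sugar,
   Δfiber = (1.5 − 1)·f·UPF_fiber, Δenergy ≡ 0.

   Scenarios A/B/C use f = 0.25 / 0.50 / 1.00; deltas are exactly linear in f.
3. **Usual intake.** Per participant and nutrient, 10,000 Monte Carlo
   draws around the observed value with a 20% within-person coefficient of
   variation (moment-matched lognormal; per-participant random substreams).
4. **Health impacts.** Dose-response slopes map deltas to outcomes:
   2.5 mm Hg systolic blood pressure per 1000 mg/d sodium reduction, and
   percent relative risk reductions for type-2 diabetes (per g added sugar)
   and cardiovascular disease (per g fiber). The slope scale for sugar and
   fiber is an explicit `scale_mode` choice — see `docs/methods.md` for why
   there are two defensible readings. Coefficient uncertainty is propagated
   by truncated-normal Monte Carlo (relative SD 0.10).
5. **Survey estimation.** All summaries are survey-weighted with
   Taylor-linearization variance honoring strata and PSUs
   (df = PSUs − strata).

A **synthetic population generator** calibrated to the published group
profiles (767 SNAP / 5563 non-SNAP participants; group means/SDs for
energy, sodium, added sugar, fiber and UPF energy share; demographic
category mixes) makes the whole pipeline runnable and testable without any
survey download.

## Worked example

```python
from upfsim import UPFRestrictionModel, synthetic

model = UPFRestrictionModel.from_synthetic(synthetic.PopulationConfig(seed=1))
results = model.fit(seed=1)
print(results.summary())
```

On the default calibrated population this prints (Scenario C = full
replacement; survey-weighted means, Monte Carlo 95% percentile intervals):

```
   snap scenario C: sodium -254.6 mg/d, sugar -30.9 g/d, fiber +1.14 g/d, energy +0.0 kcal/d
nonsnap scenario C: sodium -294.0 mg/d, sugar -31.6 g/d, fiber +1.26 g/d, energy +0.0 kcal/d

   snap scenario C: SBP -0.64 mm Hg [0.51, 0.76], T2D -0.25% [0.20, 0.30], CVD -1.03% [0.83, 1.23]
nonsnap scenario C: SBP -0.73 mm Hg [0.59, 0.88], T2D -0.25% [0.20, 0.30], CVD -1.14% [0.92, 1.36]
```

Read: removing all UPFs from SNAP participants' diets (and replacing them
isocalorically) cuts ~255 mg/d of sodium, which the sodium-SBP slope
translates into a 0.64 mm Hg systolic blood pressure reduction;
nonparticipants, whose UPF-attributable pools are slightly larger, improve
slightly more. Individually modest, such shifts scale to meaningful
population-level benefit across tens of millions of beneficiaries.

The same run is available from the shell:

```bash
upfsim run-all --synthetic --seed 1 --out results/run1
upfsim generate --seed 1 --out data/     # just the synthetic tables
upfsim classify --foods data/foods.csv --out results/cls
```

## Layout

- `src/upfsim/records.py` — record types, CSV I/O, aggregation, PIR and
  food-security categorization
- `src/upfsim/nova.py` — keyword NOVA classifier + audit log
- `src/upfsim/substitution.py` — scenario engine
- `src/upfsim/usual_intake.py` — usual-intake Monte Carlo
- `src/upfsim/health.py` — dose-response impacts and uncertainty
- `src/upfsim/survey.py` — design-based estimation
- `src/upfsim/synthetic.py` — calibrated population generator
- `src/upfsim/model.py` — `UPFRestrictionModel` / `UPFRestrictionResults`
- `src/upfsim/cli.py` — `upfsim` command-line interface
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
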