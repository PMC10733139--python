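# tra-consumer

Screening-level (Tier 1) consumer chemical exposure estimation for product
(PC) and article (AC) use scenarios, plus the mechanistic comparator models
used to benchmark such screening estimates.

Screening exposure tools of this family are built to *never under-predict*:
in the absence of specific use information they combine conservative
scenario defaults with deliberately simple, linear route algorithms, so that
substance–scenario combinations can be cleared quickly or flagged for
higher-tier refinement. This package implements those route algorithms as a
library and CLI, and pairs them with the independent models a reviewer would
use to probe their conservatism: a ventilated-box release model, an
evaporation-limited emission simulator, four article dermal-transfer models,
and a migration-rate oral model for mouthed articles.

## The model

For a substance with vapor pressure VP (Pa) and molecular weight MW (g/mol)
used in a scenario with product amount A (g/event), weight fraction WF, room
volume V (m³), dilution fraction f_dil, event duration t (h), frequency
n (1/day), skin contact area SA (cm²), thickness layer TL (cm), contact
density ρ (g/cm³), transfer factor TF, ingested amount Q (g/event) and body
weight BW (kg):

* **Inhalation** — a fraction f_rel of the substance is released
  instantaneously into the well-mixed room:

      C = A·WF·f_rel·f_dil / V            [mg/m³, event average]
      dose = C·IR·t·n / BW                [mg/kg bw/day]

  f_rel is set by four vapor-pressure bands — `[10 Pa, ∞) → 1`,
  `[1, 10) → 0.1`, `[0.1, 1) → 0.01`, `(0, 0.1) → 0.001` — i.e. a factor-10
  reduction per decade of VP below the 10 Pa complete-release cutoff, with a
  floor of 0.1%. Aerosols always release 100%. Non-aerosol concentrations
  are capped at the saturated vapor concentration SVC = VP·MW/(R·T).

* **Dermal** — a uniform layer of thickness TL covers the contacted skin and
  its entire substance content is external dose:

      dose = SA·(TL·ρ·WF·TF)·n / BW      [mg/kg bw/day]

  TL is 0.01 cm for liquids (implying a 10 mg/cm² dermal load at unit
  density) and 0.001 cm for most articles.

* **Oral** — complete ingestion of the substance in the mouthed/ingested
  mass: `dose = Q·WF·TF·n / BW`.

* **Total** — the routes are summed *without* conserving mass: the same
  substance can be counted as fully airborne and fully on skin. The package
  reports (never corrects) this mass-balance exceedance.

## Worked example

```python
from tra_consumer import Substance, default_registry
from tra_consumer.tra import assess_scenario, total_exposure

registry = default_registry()            # bundled non-authoritative fixtures
flooring = registry.get("AC13-plastic-flooring")
plasticizer = Substance(name="plasticizer", molecular_weight=390.0,
                        vapor_pressure=3.4e-5)

for r in assess_scenario(flooring, plasticizer):
    print(f"{r.route:12s} {r.daily_dose:8.2f} mg/kg/day  caps={list(r.caps_applied)}")
print(f"{'total':12s} {total_exposure(assess_scenario(flooring, plasticizer)).daily_dose:8.2f} mg/kg/day")
```

prints

```
inhalation       0.00 mg/kg/day  caps=['svc_cap']
dermal         145.83 mg/kg/day  caps=[]
total          145.83 mg/kg/day
```

The dermal estimate dominates: 8750 cm² of contacted flooring carrying a
0.01 cm layer at 10% weight fraction is 8750 mg/day, i.e. ≈146 mg/kg/day for
a 60 kg adult. The semi-volatile's inhalation estimate is cut to its
saturated vapor concentration (`svc_cap`), illustrating the one nonlinearity
in the tool.

The same computations are available from a shell:

```sh
tra-consumer bands
tra-consumer run --scenario AC13-plastic-flooring --substance subs.csv --out reports
tra-consumer mouthing-time --rate 33 --target 0.1 --target 0.43 --target 4.3
tra-consumer sweep-vp --substance subs.csv --grid-points 25 --out sweep
tra-consumer compare-dermal --scenario AC13-plastic-flooring --substance subs.csv
```

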