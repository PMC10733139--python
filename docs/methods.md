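# Methods

This note documents the models implemented in `tra_consumer`, the unit and
parameter conventions, the numerical choices, what the bundled fixtures do
and do not represent, and the known limitations.

## Screening route algorithms

The screening estimator is deliberately simple and linear. For each
scenario–substance pair it produces up to three independent route estimates
(mg/kg body weight/day) and their sum.

**Inhalation.** The substance fraction f_rel assigned by the volatility
band (or 1 for aerosols) is released instantaneously into a well-mixed room
of volume V with no ventilation during the event, so the event-average
concentration equals the peak, C = A·WF·f_rel·f_dil/V. The dilution
fraction f_dil models unventilated air flow between residential rooms and
multiplies the concentration (rather than enlarging the effective volume);
it defaults to 1. Band boundaries are lower-inclusive/upper-exclusive:
exactly 10 Pa receives fraction 1 and exactly 0.1 Pa falls in the 0.01 band
(0.1 Pa is the cutoff *for* the lowest band, not part of it). One source
text states the lowest-band cutoff as 0.01 Pa in a single passage while
using 0.1 Pa everywhere else; this package implements the 0.1 Pa cutoff and
records the discrepancy here rather than resolving it. Non-aerosol
concentrations are capped at the saturated vapor concentration
SVC = VP·MW/(R·T) with R = 8.314 J/(mol·K) and T defaulting to 298.15 K
(the source material states no temperature; T is configurable). The daily
dose adds inhalation rate IR, duration t, frequency n and body weight BW:
C·IR·t·n/BW.

**Dermal.** A uniform thickness layer TL of product/article material covers
the contacted skin; all of its substance content is external dose. The
areal load is TL·ρ·WF·TF (mg/cm²). Standard TL values are 0.01 cm (liquids
and prolonged/moist article contact) and 0.001 cm (other articles, for the
reduced substance mobility in a solid matrix); other values are accepted
but recorded as a provenance warning rather than an error, since refined
assessments legitimately override TL. The contact density ρ defaults to
1 g/cm³, which is the choice that makes the standard 0.01 cm liquid layer
carry the canonical 10 mg/cm² load; registry entries may override it.

**Oral.** Complete ingestion of the substance in the mouthed/ingested mass:
Q·WF·TF·n/BW. No dust-ingestion pathway exists; the conservatism of the
direct routes is intended to cover it, and the mouthing-inversion analysis
(below) is the tool for probing that claim.

**Total and mass balance.** Route estimates are summed without conserving
mass. Each result carries the substance mass its route equation implicitly
assigns (emitted, transferred to skin, ingested) and the mass actually
present in the product (A·WF); when the routes together exceed the
available mass the total is flagged `mass_balance_exceeded` but never
corrected — over-assignment is part of the screening design. Results built
from bare printed doses lack mass bookkeeping and report the flag as
indeterminate (None).

**Rescaling.** All route equations are linear in WF, so results can be
rescaled to a refined weight fraction by the ratio new/old. Rescaling an
SVC-capped result is refused (the cap breaks linearity); the caller must
recompute the scenario.

**Rounding.** Reports round to 3 significant figures; mouthing times round
to one decimal below 1 h and to the nearest hour above. Internal values
keep full precision.

## Comparator models

**Ventilated box.** Instantaneous release of mass m into a box with air
exchange q gives the exact event average m/(V·q·T)·(1−e^(−qT)), with the
q→0 limit m/V. This is the mechanistic counterpart of the screening
inhalation equation with ventilation restored.

**Evaporation simulator.** A thin applied film of substance mass m₀ over
area A_s loses mass at the Langmuir-type rate k_m·A_s·(SVC − C) into the
ventilated box; C evolves by the same flux minus q·C·V. The mechanistic
release fraction is (m₀ − m_film(T))/m₀, clipped to [0, 1]; the film-
exhausted state is a terminal integration event mapped to fraction 1.
Integration uses LSODA with rtol 1e-8 and atol 1e-8·m₀; tests cross-check
against a fixed-step RK4 integrator (0.5% agreement) and verify
conservation of film + airborne + vented mass to 1e-6 relative. The
defaults (A_s 2 m², m₀ 500 g, k_m 1 m/h, V 20 m³, q 0.5/h, T 2 h) sketch a
wall-painting-like application at an indoor-scale mass-transfer
coefficient; they are declared fixtures, not authoritative scenario
parameters, and every sweep accepts explicit specs. Under these settings
the banded fraction bounds the mechanistic fraction across the whole
1e-3–1e3 Pa sweep grid (25 log-spaced points by default), and the log10 gap
grows monotonically as VP falls below the lowest-band cutoff — the widening
conservatism the band floor of 0.001 creates. The magnitude of the gap
depends on the evaporation fixtures and is reported, not asserted, by the
sweep.

**Article dermal models.** Four alternatives to the thickness layer, all
reported per contact area and as doses through the same population record
so ratios are unit-safe:

- *diffusion-layer*: emission = C0·d(t) with the mean 1-D diffusion travel
  distance d(t) = √(4Dt/π), capped at the article thickness L. The √(4/π)
  coefficient is chosen as the mean absolute displacement of 1-D Brownian
  motion, which makes the formula coincide exactly with the semi-infinite
  perfect-sink surface-flux integral 2C0√(Dt/π) — tested against a
  numerical slab-diffusion solution (1% agreement in the semi-infinite
  regime d < L/4). All emitted substance is assumed to transfer to skin.
  The model is flagged inapplicable above 2% weight fraction, where the
  substance itself alters matrix diffusivity. An optional `deplete_cap`
  bounds emission by the total content C0·L (redundant with the distance
  cap for a uniform slab; kept as an explicit guard). An absorption
  fraction is deliberately *not* applied by default: estimates are external
  exposure.
- *mass-balance*: the whole contacted slab's content C0·L·area, on either
  a skin-area or article-area basis.
- *migration-fraction*: C·L·(fraction migrating per time)·t in SI units,
  with a validity flag at fraction·time ≥ 0.1 and a hard error at ≥ 1 (the
  linearisation requires fraction·time ≪ 1).
- *transfer-efficiency*: areal material weight · WF · daily transfer
  efficiency · skin area. The 0.08 default efficiency is the literature
  carpet value; the default areal weight is ρ·L when not given.

`compare_models` needs an explicit diffusion travel time (defaulting to the
event duration) rather than guessing per-scenario defaults, because
published diffusion-layer results depend strongly on that choice and no
authoritative per-scenario values are available.

**Mouthing migration model.** Observed saliva-migration rates span
1.7×10⁻⁶–33 µg/10 cm²/min across substance–material pairs; rates are
stored per 10 cm² exactly as reported (the per-cm² conversion happens
inside the operations) to avoid a silent ×10 error. dose =
r·(area/10)·time/BW and its exact inversion give the daily mouthing time
needed to reach a screening estimate: at the highest observed rate, the
0.1/0.43/4.3 mg/kg/day article estimates require 0.5/≈2/22 h/day of
mouthing, and at the lowest rate even the smallest estimate requires far
more than 24 h/day — the quantitative sense in which the complete-ingestion
assumption is conservative. `implied_uptake_thickness` converts ingested
volumes to equivalent surface-layer thicknesses (0.01–0.3 cm³ over 10 cm²
↔ 0.001–0.03 cm).

## Units, populations, registry

One internal unit per quantity (g, mg, cm², cm, m³, h, kg, Pa, g/mol;
doses mg/kg bw/day, concentrations mg/m³); conversions happen only at I/O
boundaries. Default populations are 60 kg adults and 10 kg children;
inhalation rates (1.0 / 0.5 m³/h, light-activity scale) are fixture values
with no authoritative anchor and are flagged as such in the registry.
Frequency defaults to one event per day (daily use); no
frequency/duration-adjustment factor beyond n is implemented.

The bundled registry (`data/scenario_defaults.yaml`) is a synthetic,
editable fixture: authoritative scenario-default tables are deliberately
not reproduced. Every entry is tagged `fixture-nonauthoritative`; the only
`printed-in-paper` tags sit on individual field values that are anchored to
openly printed numbers (flooring WF 0.1 and TL 0.01 with 8750 cm² contact
area closing the 8750 mg/day estimate; in-room substance masses of 594 g
and 37 g closing the 29700 and 1850 mg/m³ top-band event averages at
V = 20 m³; ingested amounts closing the 0.1–4.3 mg/kg/day oral range for a
10 kg child). Tests and the acceptance script rely only on those anchored
values. Per-scenario dilution fractions are not anchored anywhere, so the
registry keeps the default of 1 with per-entry override. SCED-style
refinements go through `OverrideSet`: replacements are validated against
the scenario invariants, recorded field-by-field with their source label,
idempotent, and carried into result provenance.

## What the fixtures do and do not show

The synthetic substance generator draws vapor pressures log-uniformly over
1e-6–1e5 Pa (exercising all four bands), molecular weights over 50–500
g/mol, densities 0.8–1.5 g/cm³ and matrix diffusion coefficients
1e-14–1e-6 cm²/s — spans typical of product ingredients and article
additives, not any measured chemical inventory. Passing tests therefore
demonstrate the algebraic and ordering properties of the models (linearity,
caps, conservatism of the band floor relative to the evaporation
mechanism, exactness of inversions) under realistic parameter magnitudes;
they say nothing about agreement with measured human exposures, which
requires external data the package does not ship.

## Numerical choices and degenerate inputs

- Band assignment is a pure table lookup; VP ≤ 0 is a domain error
  (banding is undefined without volatility).
- The box-model closed form switches to the m/V limit for q·T < 1e-12 to
  avoid 0/0; the expression uses expm1 for small-q accuracy.
- CSV round-trips write floats with %.17g and parse with pandas'
  round-trip parser so registries and substance files reload bit-exactly.
- Zero migration rates make any positive target dose unreachable and raise
  rather than returning infinity.
- Unknown scenario codes raise with the closest registry codes (difflib)
  to keep CLI errors actionable; CLI exit codes are 0/2/3 for
  success/validation/numerical failures.

## Problem sizes

Tests and the acceptance script run on deliberately small inputs: sweep
grids of 9–25 vapor pressures, PDE oracle grids of 600 spatial nodes, and
hypothesis suites of 40–100 examples — sizes chosen so the whole
verification cycle stays interactive while still covering all bands,
regimes and cap branches.

## Known limitations

- Respirable-fraction physics for sprays is absent by design (aerosols are
  simply 100% released); spray scenarios carry no dermal route.
- Skin permeation/uptake is out of scope everywhere: all dermal quantities
  are external loads.
- The equilibrium surface-film dermal model is not implemented (no
  published closed form to implement, only a summary ratio).
- The evaporation comparator is this package's own mechanistic reference
  model, not a reimplementation of any external tool; cross-tool gap
  magnitudes quoted in the literature are context for its sweeps, not
  assertions.
- The mouthing analysis treats migration rates as constants over time and
  ignores depletion of the mouthed article.
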