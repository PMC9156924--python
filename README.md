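# broilerland

Steady-state demographics and land-use accounting for US broiler chicken
production, for environmental-systems and animal-welfare researchers who
want country-scale consequences of switching breeds or management systems.

## The model

The national flock is a two-box steady-state model: a breeding flock of hens
and a fattening flock of broilers. At steady state each box's standing
population is its residence time times its throughput,

    p = τ · f,

so 9.25 × 10⁹ birds yr⁻¹ slaughtered after a 47-day grow-out implies a
standing population of 9.25 × 10⁹ × 47/365 ≈ 1.19 × 10⁹ birds, and
98.0 × 10⁶ pullet placements yr⁻¹ with a 0.767-yr laying cycle imply
≈ 75.1 × 10⁶ breeding hens.

Replacing the conventional fast-growing breed (Ross 308, 2.93 kg live,
dressing 74%) with a slower-growing breed at **equal dressed production**
raises the slaughter rate by the breed's slaughter multiplier m and the
standing population by m · τ_breed/47. Land use has two parts:

* **direct** — housing or pasture area of the standing flock: 0.0743 m²/bird
  in CAFO housing, plus an outdoor area equal to 75% of the indoor floor
  space for outdoor access, or 10.12 m²/bird on pasture;
* **indirect** — maize and soy cropland growing the flock's feed: annual
  feed (slaughter rate × kg feed per bird) split by the national composition
  (60.3% maize, 26.8% soy, 12.9% other, the "other" share carrying no
  cropland), each crop mass divided by its yield (4.802 and 1.403
  tonnes/acre) to give land.

Because every component is linear in flock size, holding total land at the
conventional CAFO baseline L₀ caps a scenario's production at

    W(scenario) = L₀ / L(scenario) × W(conventional),

and consumption, slaughter rate and population all scale by the same factor.

A calibration module derives breed parameters from breeder performance-
objective tables (age-by-age live weight and cumulative feed) via two
top-down corrections against national statistics — a weight scale factor
(USDA mean slaughter weight ÷ table weight at 47 days) and a performance
scale factor (national feed per bird ÷ table cumulative feed at 47 days,
≈ 1.35) — and a synthetic-data module generates such tables with known
ground truth so the whole pipeline is testable offline.

## Worked example

```python
>>> import broilerland as bl
>>> params = bl.load_parameters()          # national defaults
>>> for r in bl.run_parameter_set(params):
...     print(f"{r.breed:8s} {r.management.value:8s} "
...           f"cap={r.max_consumption:5.1f} MMT  "
...           f"slaughter={r.slaughter_rate_at_cap/1e9:5.2f}e9  "
...           f"decrease={r.consumption_decrease_pct:5.1f}%")
Ross308  cafo     cap= 20.1 MMT  slaughter= 9.25e9  decrease=  0.0%
Ross308  outdoor  cap= 20.0 MMT  slaughter= 9.24e9  decrease=  0.1%
Ross308  pasture  cap= 17.3 MMT  slaughter= 7.99e9  decrease= 13.7%
RC       cafo     cap= 16.6 MMT  slaughter= 9.12e9  decrease= 17.3%
RC       outdoor  cap= 16.6 MMT  slaughter= 9.11e9  decrease= 17.4%
RC       pasture  cap= 13.9 MMT  slaughter= 7.67e9  decrease= 30.4%
RG       cafo     cap= 16.7 MMT  slaughter=10.42e9  decrease= 16.6%
RG       outdoor  cap= 16.7 MMT  slaughter=10.41e9  decrease= 16.7%
RG       pasture  cap= 13.8 MMT  slaughter= 8.57e9  decrease= 31.4%
RR       cafo     cap= 15.4 MMT  slaughter= 9.01e9  decrease= 23.4%
RR       outdoor  cap= 15.3 MMT  slaughter= 9.00e9  decrease= 23.5%
RR       pasture  cap= 12.5 MMT  slaughter= 7.35e9  decrease= 37.6%
```

Each row answers: if total land use (direct housing/pasture plus feed
cropland) must not exceed the conventional Ross-in-CAFO footprint of
≈ 75 577 km², how much chicken meat can that breed × management combination
produce, at what slaughter rate, and how much must national consumption
fall? E.g. slow-growing Rowan Ranger (RR) birds on pasture cap production at
12.5 MMT yr⁻¹ — a 37.6% cut from today's ≈ 20 MMT.

The same grid is available from a shell:

```sh
broilerland run --out report/            # scenarios.csv, footprints.csv, run log
broilerland synth --seed 1 --out synth/  # synthetic performance tables + truth
```

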