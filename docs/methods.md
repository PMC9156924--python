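# Methods

## Model

The national broiler system is modelled as two well-mixed compartments at
steady state. For a compartment with residence time τ and placement rate f,
the standing population is p = τ·f, and placements equal removals
(slaughters for the fattening flock, hen retirements for the breeding
flock). No age structure, grow-out mortality or carcass condemnation is
represented: placements and slaughters are identified with the single
national rate, and every bird placed is assumed slaughtered at the breed's
market age.

When a different breed supplies the whole market, its slaughter rate is set
to hold **annual dressed production** constant. Two equivalent
parameterizations are supported: a slaughter multiplier m (rate = m × the
conventional rate), or a scaled live slaughter weight w (rate = annual
dressed production ÷ (w × dressing fraction)). The multiplier form is
canonical for the default breeds because the published multipliers
(1.1922, 1.35, 1.272 for RC, RG, RR) are the mutually consistent set; the
published per-breed live-weight deltas do not reproduce them under the
production-conservation identity and are used only as synthetic-generator
anchors. The breeding flock scales proportionally to the fattening
population, and hen placements follow from the 0.767-yr laying cycle.

Land use has a direct and an indirect part. Direct land is the standing
fattening population times a stocking rate: 0.0743 m²/bird for CAFO housing
(20 000 birds per 1486 m² house), CAFO × 1.75 for outdoor access (the
outdoor run must be ≥ 75% of indoor floor area and is *added*, never
substituted), and 10.12 m²/bird on pasture. No land is charged to the
breeding flock's housing or feed. Indirect land converts the flock's annual
feed (slaughter rate × kg feed/bird) through the national composition
(60.3% maize / 26.8% soy / 12.9% other) and yields (4.802 and 1.403
tonnes/acre, 1 acre = 4046.8564 m², international acre); the "other" share
is conservatively assigned zero cropland. Management never changes feed
demand.

The constant-land question is solved in closed form. All land components
are linear in flock size, so capping total land at the conventional
Ross-in-CAFO total L₀ scales a scenario's consumption, slaughter rate and
population by s = L₀ / L(scenario); decreases are 1 − s (percent) and
(1 − s)·W (mass). No iteration is involved, and the fixed point — rebuilding
the capped flock's footprint returns L₀ — is property-tested.

## Parameters and defaults

| Parameter | Default | Units | Note |
|---|---|---|---|
| slaughter_rate | 9.25 × 10⁹ | birds/yr | 2018 national rate |
| broiler_residence | 47 (Ross), 57 (RC, RG), 69 (RR) | days | grow-out |
| hen_placement_rate | 98.0 × 10⁶ | hens/yr | pullet placements |
| hen_residence | 0.767 | yr | 40-week laying cycle |
| mean_live_weight | 2.93 | kg | dressing 0.74 → 2.17 kg dressed |
| feed_total / maize / soy | 58.1 / 35.56 / 15.78 | MMT/yr | national feed bill |
| cafo / pasture stocking | 0.0743 / 10.12 | m²/bird | outdoor adds 75% of CAFO |

A year is 365 days everywhere; quoted roundings (0.129 yr ≈ 47/365,
0.767 yr) are accepted as such. The slow breed's 69-day grow-out is the
value consistent with its published population increase (1.272 × 69/47 ≈
1.87); chained published percentages carry ~0.1 pp rounding noise (e.g. the
RR population increase computes to 86.7% against a published 86.8%), so
golden comparisons use 0.2–0.5% relative tolerances rather than printed
rounding. The dressing fraction is 0.74 for the conventional breed and 0.76
for the slower breeds.

Two deliberate asymmetries:

* **Baseline indirect land** uses the reported crop masses (35.56/15.78
  MMT) directly rather than composition × 58.1 MMT; the two disagree by
  ~1.4% and the reported masses are authoritative for the conventional
  system. Scenario flocks for other breeds use composition × total feed.
* **Effective feed per bird** for the slower breeds (6.457, 5.653, 6.536
  kg) is fixed by inverting each breed's national indirect-cropland
  requirement through the feed→cropland chain; the calibration module
  recomputes comparable values whenever performance tables are supplied.
  The conventional figure is the top-down 58.1 × 10⁹ kg / 9.25 × 10⁹ birds
  = 6.281 kg.

## Calibration

Breeder performance objectives overstate average commercial performance, so
two top-down factors rescale them: weight scale = national mean slaughter
weight ÷ table Ross weight at day 47, and performance scale = national feed
per bird ÷ table Ross cumulative feed at day 47 (≈ 1.35 for tables
anchored at 3.35 kg and 4.653 kg). Tables are linearly interpolated between
rows; at daily resolution the interpolation choice is benign (weekly
thinning moves the factors by < 0.5%, tested). Calibrating the Ross table
against itself reproduces the national per-bird figures exactly — a fixed
point the tests assert.

## Synthetic data

The generator emulates breeder performance booklets: per breed, a Gompertz
live-weight curve w(t) = A·exp(−exp(−k(t−T))) anchored to pass exactly
through a target weight at the slaughter age, and cumulative feed as a
power function of weight anchored the same way, sampled daily from day 0.
Anchors: Ross 3.35 kg / 4.653 kg at day 47 (so the true scale factors are
2.93/3.35 and 1.35); slower breeds anchored so their scaled weights sit
0.409/0.661/0.499 kg below 2.93 kg and their scaled feed equals the
effective defaults. Optional multiplicative Gaussian noise is applied
pointwise and monotonicity restored by a running maximum; all randomness
flows from one integer seed through per-breed `numpy` child generators.

The generator reproduces smooth, monotone, exactly-anchored tables — not
real breeder data: it has no sex split, no week-level feed-phase structure,
and its national statistics are constructed to be self-consistent. Passing
recovery tests therefore demonstrates that the calibration arithmetic is
correct and stable, not that real booklet data would yield these
parameters.

## Numerical choices and limitations

All quantities are closed-form products and ratios in float64; no
optimization or iteration occurs, so results are bit-reproducible and the
full 12-scenario grid runs in milliseconds. Degenerate inputs raise
`ValueError` (negative rates, zero scenario land, dressing fraction outside
(0,1)) or `ConfigurationError` (malformed config, unknown fields).
Zero-population flocks are valid and yield zero feed and land.

Out of scope by design: grow-out mortality and carcass rejection, mixed
breed portfolios or partial transitions, pasture forage intake offsetting
feed, cropland for the "other" feed share, breeding-flock land, and any
economic, greenhouse-gas or biodiversity accounting. The published
slow-intermediate-breed pasture slaughter rate has one internal
inconsistency (it does not match its own consumption row); the model
reports the self-consistent value.
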