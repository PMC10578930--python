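# spiketime

Time-series objects and foundational analyses for systems neuroscience.

Electrophysiology and imaging sessions mix heterogeneous time-resolved
streams — spike times, behavioral tracking, stimulus epochs, fluorescence
traces — that must stay aligned on one time base while being repeatedly
subset to wake/sleep periods, trials, or detected events. `spiketime`
provides five core objects that make this bookkeeping automatic:

- **`EpochSet`** — a normalized set of closed `[start, end]` intervals in
  seconds: "when data is valid / when a condition holds", with full interval
  algebra (`intersect`, `union`, `set_diff`, `drop_short_intervals`,
  `drop_long_intervals`, `merge_close_intervals`).
- **`TimestampSeries`** — discrete event times (spikes, licks, TTLs) with an
  attached `EpochSet` *time support*.
- **`ValuedSeries` / `MultiValuedSeries`** — sampled scalar / multi-channel
  signals with a time support.
- **`EventGroup`** — an id-keyed population of spike trains sharing one time
  support, with a per-unit metadata table (firing `rate` always present and
  auto-recomputed) and `getby_category` / `getby_threshold` /
  `getby_intervals` filters.

Every operation that subsets data in time (`restrict`, `threshold`,
`value_from`, `count`) propagates the time support by set intersection, so
"no events observed" is never confused with "period excluded".

On top of the containers, the package implements the foundational analyses:

- occupancy-normalized **tuning curves** (per-condition, 1D, 2D, and the
  mean of a continuous signal vs. a feature),
- **Bayesian population decoding** under independent Poisson spiking
  (Zhang et al. 1998): log P(x|n) = log P(x) + Σᵢ [nᵢ log fᵢ(x) − τ fᵢ(x)] + C,
- **auto/cross-correlograms** expressed as conditional rates,
- **peri-event alignment** (PSTH and event-triggered averages),
- CSV epoch/tracking loaders, an HDF5 session container with bit-exact
  round-trip, and a loader registry for custom formats,
- a synthetic-data module (wrapped random-walk head direction, von
  Mises-tuned Poisson units, calcium-like traces) so every analysis is
  testable against known ground truth.

## Worked example: head-direction cells, from simulation to decoding

```python
import numpy as np
from spiketime import (make_hd_population, tuning_1d, preferred_direction,
                       decode_bayes_1d, circular_distance, TimestampSeries)

# 20 simulated head-direction cells driving Poisson spikes for 300 s
group, angle, truth = make_hd_population(n_units=20, duration=300.0,
                                         dt=0.05, seed=42)
print(group)
print(group.metadata.head(3).round(2))

# 24-bin circular tuning curves, occupancy normalized
tc = tuning_1d(group, angle, nb_bins=24, circular=True)
pref = preferred_direction(tc)
err = np.degrees([float(circular_distance(pref[i], truth[i].mu))
                  for i in group.unit_ids])
print(f"max preferred-direction error: {err.max():.2f} deg")

# Bayesian decoding of the angle from population counts in 0.2 s windows
dec = decode_bayes_1d(tc, group, bin_size=0.2, ep=angle.time_support)
true_angle = TimestampSeries(dec.times,
                             time_support=angle.time_support).value_from(angle)
med = np.degrees(np.median(circular_distance(dec.map_estimate,
                                             true_angle.values)))
print(f"median decoding error: {med:.2f} deg  (chance: 90 deg)")
```

Output:

```
EventGroup(20 units, support=EpochSet(1 intervals, total_duration=300 s))
         rate
unit_id
0        3.94
1        2.89
2        3.03
max preferred-direction error: 3.82 deg
median decoding error: 9.16 deg  (chance: 90 deg)
```

The `rate` column is each unit's mean firing rate over the shared support
(a few Hz: sharply tuned cells are silent most of the time). Preferred
directions are recovered to within a few degrees of the simulated ground
truth — well inside one 15° tuning-curve bin — and the decoder tracks the
head direction with ~9° median error against a 90° chance level.

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
spiketime synth hd-session --units 20 --duration 300 --seed 1 --out hd.h5
spiketime info hd.h5
spiketime tuning hd.h5 --bins 24 --out tuning.csv
spiketime xcorr hd.h5 --ref 0 --target 1 --out xcorr.csv
spiketime decode hd.h5 --bins 24 --bin-size 0.2 --out decoded.csv
```

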