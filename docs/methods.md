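# Methods

This note documents the models, conventions and numerical choices behind
`spiketime` — what each analysis computes, which decisions were genuinely
open, and what the synthetic fixtures do and do not emulate.

## Time base and interval conventions

All times are stored as 64-bit floating seconds; other units ('ms', 'us')
exist only at ingest (`time_units=`) and display (`as_units`). Comparisons
are exact float comparisons with no epsilon — endpoints must therefore be
produced consistently by the library itself (e.g. bin edges are always
computed as `start + k*b`, never accumulated).

Intervals are closed on both ends, `[start, end]`. At construction an
`EpochSet` is sorted and overlapping *or abutting* intervals are merged, so
a shared endpoint is never ambiguous; a merged interval inherits the label
of its earliest constituent. Consequences:

- `set_diff` retains the boundary points of removed regions as closed
  endpoints (`[0,10] \ [3,5] → [0,3] ∪ [5,10]`). This differs from strict
  set difference on a measure-zero set only; the mask-oracle tests compare
  occupancy of 1 ms lattice cells, which cannot see it.
- Degenerate point intervals produced by set operations (e.g.
  `[0,5] ∩ [5,8]`) are dropped, again a measure-zero choice.
- `merge_close_intervals` compares `next.start <= current.end + max_gap`
  rather than `start − end <= max_gap`: the subtraction form can inflate a
  gap by one ulp (in binary floats `2.6 − 2.0 > 0.6`) and spuriously refuse
  a merge. Merging is applied transitively in a single left-to-right pass,
  which reaches the fixed point because intervals are sorted.

Sampled/event series require non-decreasing times (duplicates allowed —
simultaneous events are real); decreasing input is rejected rather than
silently sorted, so ordering bugs surface at the call site.

## Core methods

- **restrict** keeps samples with closed-interval membership and intersects
  the time support. It is idempotent, and restricting to the series' own
  support is the identity.
- **value_from** reads the *nearest-in-time* source sample, with ties
  broken toward the earlier sample (deterministic, unbiased in
  expectation). There is no maximum-gap cutoff: with quasi-regular
  sampling a cutoff adds a parameter without changing results, and gaps
  are better handled explicitly by restricting to epochs. Target times are
  restricted to the intersection of the two supports, but the lookup table
  is the unrestricted source: a surviving target time near a support
  boundary may be nearest to a sample just outside the intersection.
- **count** tiles half-open bins `[start + k·b, start + (k+1)·b)` from each
  epoch interval's start and drops the trailing partial bin — a rate
  computed from a partial bin would be biased. Output times are bin
  centers; the output support is the binning epoch, so Σcounts ≤ n_events,
  with equality when epoch boundaries align to bin multiples.
- **threshold** keeps samples strictly above/below the level and builds the
  new support from maximal runs of consecutive qualifying samples (first to
  last sample time of each run). No interpolation of crossing times is
  attempted: run-based supports are exact on the stored samples and make
  `threshold` invertible by `restrict`.
- **rate** is n_events / support duration; a zero-duration support is an
  error for a single series, while an `EventGroup` restricted to an empty
  epoch sets all rates to 0 with a warning (a group-level analysis should
  survive an empty condition; a direct rate query should not silently
  return garbage).

## EventGroup

The metadata table always carries `rate`, recomputed whenever the support
changes and never user-writable. The default support is the single interval
spanning all members' first and last events — a convenience for quick
interactive use; explicit supports are recommended because the spanning
default ignores recording gaps. Filters (`getby_*`) change membership only,
never member data, and preserve unit ids. `getby_intervals` bins are
half-open `[eᵢ, eᵢ₊₁)`; values outside the edges fall in no bin.

## Tuning curves

Occupancy per feature bin is `(#feature samples in bin) × Δt` with `Δt` the
median feature sampling interval (an `occupancy_dt` override exists for
irregular sampling). Spikes are assigned the feature value of their nearest
feature sample via `value_from` — no interpolation, consistent with the
core convention. Rate per bin is spike count / occupancy; **unvisited bins
are NaN, not 0**, because an unvisited bin carries no rate information.
Circular features are wrapped to [0, 2π), binned over the full circle by
default, and compared with circular distance.

`preferred_direction` estimates each unit's preferred angle as the
rate-weighted circular mean of the bin centers, `arg Σ_b r_b e^{iθ_b}`.
This pools the whole curve and is considerably more accurate than the raw
argmax bin (whose error is bounded below by half a bin width); with 300 s
of simulated data it recovers preferred directions to ~2–4°.

## Bayesian decoder

Independent-Poisson population decoding over the tuning-curve bins:
`log P(x|n) = log prior(x) + Σᵢ [nᵢ log fᵢ(x) − τ fᵢ(x)] + C`, normalized
per time window with `logsumexp`. Numerical choices:

- computation in log space throughout;
- tuning rates floored at 1e-12 events/s so a unit that was silent in a
  visited bin contributes a finite, near-zero likelihood rather than −∞;
- bins with zero occupancy (undefined tuning) are removed from the state
  space entirely — they are unknowns, not impossibilities;
- the default prior is uniform, with an `'occupancy'` option; the uniform
  default avoids coupling the decoder's output to how the animal happened
  to sample the feature during tuning-curve estimation.

2-D decoding is out of scope for this version.

## Correlograms

Lag bins are half-open with an odd count and the central bin centered on
lag 0, spanning `±(K+½)·b` with `K = ceil(window/b)`; this layout makes the
autocorrelogram's symmetry exact. 'rate' normalization divides pooled
counts by `n_ref × bin_size`, giving the conditional rate of the target in
events/s; `'count'` returns raw histograms. The autocorrelogram excludes
identical-index (zero-lag self) pairs and is computed from unordered-pair
|lags| then mirrored, so `value(−lag) == value(+lag)` bit-exactly; this
agrees with the literal ordered-pair histogram except for lags falling
exactly on a bin edge (measure zero for continuous spike times). Both
trains are restricted to the analysis epoch first; pairs spanning an epoch
gap are still counted if both members survive restriction — no boundary
(border-triangle) correction is applied.

## Peri-event alignment

Point events: per reference r, aligned times are `{t − r}` within the
closed window `[−before, +after]`; with a bin size, half-open lag bins tile
from `−before` and the pooled rate is counts / (n_ref × bin_size).
Continuous signals: values are sampled by nearest neighbor on the relative
grid `−before … +after` step `dt`; references outside the target's time
support are dropped and counted in `n_dropped`.

## Synthetic data

The generator emulates the statistical structure of a head-direction
recording so analyses can be scored against ground truth:

- **Trajectory**: wrapped Gaussian random walk,
  θ_{k+1} = wrap(θ_k + N(0, σ²·dt)), default σ = 1.2 rad/√s and dt = 50 ms —
  an angular diffusion that explores the full circle many times in a few
  minutes, like a foraging rodent's heading. It has no drift, no pauses,
  and no angular-velocity autocorrelation beyond the walk itself.
- **Tuning**: von Mises-shaped curves
  f(θ) = r_base + (r_max − r_base)·exp(κ(cos(θ−μ)−1)), defaults κ ∈ [2, 6],
  r_max ∈ [8, 25] Hz, r_base = 0.5 Hz — widths and peak rates typical of
  thalamic head-direction cells. Preferred directions are evenly spaced
  with a random rotation, so population coverage is guaranteed.
- **Spiking**: inhomogeneous Poisson by thinning against the peak rate,
  with the rate held piecewise constant at the left sample — exact for a
  piecewise-constant rate, with no refractoriness, bursting, or spike-count
  overdispersion. A single `SeedSequence` spawns per-unit child seeds, so
  multi-unit simulations are reproducible unit by unit.
- **Calcium traces**: unit-amplitude single-exponential transients on a
  regular grid plus optional Gaussian noise — no saturation, rise time, or
  indicator nonlinearity.

Passing the recovery tests therefore demonstrates correctness of the
estimators under their own model assumptions (Poisson spiking, stationary
tuning, accurate tracking), not robustness to the non-Poisson statistics,
tracking noise, or nonstationarity of real recordings.

Default problem sizes for the end-to-end checks — 20 units × 300 s for
tuning/decoding recovery, 1000 s of 10 Hz Poisson for correlogram
flatness, 500 references for peri-event recovery, 20 randomized sessions
for persistence — are large enough that the stochastic checks sit far from
their thresholds (e.g. preferred-direction errors of ~3° against a 15°
bound) while the whole suite runs in seconds.

## Persistence

One HDF5 file per session: `/epochs/<name>`, `/series/<name>` (kind
attribute `ts`/`tsd`/`tsdframe`), `/groups/<name>/unit_<id>`, with supports
stored alongside each object, group metadata as native per-column datasets,
and session metadata as a JSON attribute. Floats are written as raw
float64, so round trips are bit-exact. This layout is an original,
documented on-disk contract of this package (it is not an NWB file); NWB or
lab-specific formats can be plugged in through `register_loader`, and every
loader's output passes the shared object validators so corruption fails
loudly, naming the offending object. Built-in loaders assume all streams
already share time zero — cross-clock synchronization is the custom
loader's responsibility.

## Known limitations

- No smoothing/kernel options for tuning curves or correlograms; no
  spectral analysis; no 2-D decoding.
- Correlograms lack epoch-boundary corrections (documented above).
- `value_from` has no maximum-gap cutoff; with very sparse sources distant
  samples will be propagated silently.
- The calcium model is a deliberately minimal single-exponential surrogate.
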