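"""Foundational analyses: tuning curves, Bayesian decoding, correlograms,
and peri-event alignment.

Tuning curves
    Firing rate (or mean signal value) as a function of a behavioral or
    stimulus feature, normalized by occupancy — the time spent in each
    feature bin. Occupancy is estimated as (number of feature samples per
    bin) × (median feature sampling interval); an ``occupancy_dt`` override
    is available for irregularly sampled features. Bins that were never
    visited are NaN (undefined), never 0: an unvisited bin carries no rate
    information.

Bayesian decoding
    Population decoding under independent-Poisson spiking (Zhang et al.
    1998 style): for spike counts :math:`n_i` in a window of length
    :math:`\\tau` and tuning rates :math:`f_i(x)`,

    .. math:: \\log P(x \\mid n) = \\log P(x) +
        \\sum_i [\\, n_i \\log f_i(x) - \\tau f_i(x) \\,] + C.

    Computation is in log space; tuning rates are floored at 1e-12 events/s
    so bins where a unit is silent keep a finite (near-zero) likelihood,
    and feature bins with undefined tuning (zero occupancy) are removed
    from the state space entirely.

Correlograms
    Conditional rate of a target train around each reference event. Lag
    bins are half-open, an odd count with the central bin centered at lag
    0; 'rate' normalization divides counts by (n_ref × bin_size), giving
    events/s. The autocorrelogram excludes zero-lag self pairs and is
    symmetric about 0 by construction.

Peri-event alignment
    Event times (or signal snippets) collected in a window around reference
    timestamps — the classical PSTH / event-triggered average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import EpochSet, MultiValuedSeries, TimestampSeries, ValuedSeries
from .group import EventGroup

__all__ = [
    "TuningCurve",
    "Correlogram",
    "PeriEventEnsemble",
    "DecodedTrajectory",
    "tuning_discrete",
    "tuning_1d",
    "tuning_2d",
    "tuning_continuous",
    "decode_bayes_1d",
    "cross_correlogram",
    "auto_correlogram",
    "peri_event",
    "peri_event_continuous",
    "circular_distance",
    "preferred_direction",
]

TWO_PI = 2.0 * np.pi


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class TuningCurve:
    """Feature-binned rates (1D: DataFrame bins × units; 2D: dict of arrays).

    ``occupancy`` is in seconds per bin; NaN rates mark unvisited bins.
    """
    bin_centers: object            # ndarray (1D) or (ndarray, ndarray) (2D)
    rates: object                  # DataFrame (1D) or {unit_id: 2-D ndarray}
    occupancy: np.ndarray
    unit_ids: list
    circular: bool = False

    def to_csv(self, path) -> None:
        if isinstance(self.rates, pd.DataFrame):
            df = self.rates.copy()
            df.insert(0, "occupancy", self.occupancy)
            df.to_csv(path, index_label="bin_center")
        else:
            raise NotImplementedError("CSV export is for 1-D tuning curves")


@dataclass
class Correlogram:
    """Lag histogram of a target train around reference events."""
    lags: np.ndarray               # bin centers, symmetric about 0
    values: np.ndarray             # rate (events/s) or raw counts per lag bin
    n_reference: int
    bin_size: float
    norm: str = "rate"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "value": self.values})


@dataclass
class PeriEventEnsemble:
    """Trial-aligned events or traces around reference timestamps."""
    window: tuple                  # (before, after), both >= 0, seconds
    reference_times: np.ndarray
    trials: object                 # list of aligned-time arrays, or 2-D values
    bin_centers: np.ndarray | None = None   # lag grid (point) / rel. grid (cont.)
    mean_rate: np.ndarray | None = None     # pooled rate (point-event variant)
    mean_trace: np.ndarray | None = None    # trial mean (continuous variant)
    n_dropped: int = 0                      # references outside target support


@dataclass
class DecodedTrajectory:
    """Posterior over feature bins per time window, plus the MAP estimate."""
    times: np.ndarray
    posterior: pd.DataFrame        # index: times, columns: feature bin centers
    map_estimate: np.ndarray
    circular: bool = False


# --------------------------------------------------------------------------
# tuning curves
# --------------------------------------------------------------------------

def tuning_discrete(g: EventGroup,
                    conditions: Mapping[object, EpochSet]) -> pd.DataFrame:
    """Firing rate of every unit during each labeled condition epoch.

    Returns a DataFrame indexed by condition label with one column per unit.
    """
    rows = {}
    for label, ep in conditions.items():
        sub = g.restrict(ep)
        if sub.time_support.total_duration <= 0:
            raise ValueError(f"condition {label!r} has zero duration")
        rows[label] = sub.metadata["rate"]
    return pd.DataFrame(rows).T.rename_axis("condition")


def _feature_bins(vals, nb_bins, rng, circular):
    if circular:
        lo, hi = (0.0, TWO_PI) if rng is None else rng
    elif rng is None:
        lo, hi = float(np.min(vals)), float(np.max(vals))
        if lo == hi:
            hi = lo + 1.0  # single value: give the bin nonzero width
    else:
        lo, hi = rng
    edges = np.linspace(lo, hi, nb_bins + 1)
    centers = edges[:-1] + np.diff(edges) / 2.0
    return edges, centers


def _occupancy(feat_vals, feat_times, edges, occupancy_dt):
    if occupancy_dt is None:
        if feat_times.size < 2:
            raise ValueError("cannot infer sampling interval from < 2 samples")
        occupancy_dt = float(np.median(np.diff(feat_times)))
    counts, _ = np.histogram(feat_vals, bins=edges)
    return counts * occupancy_dt


def tuning_1d(g: EventGroup, feature: ValuedSeries, nb_bins: int,
              range: tuple | None = None, ep: EpochSet | None = None,
              circular: bool = False,
              occupancy_dt: float | None = None) -> TuningCurve:
    """Occupancy-normalized 1-D tuning curve for every unit in ``g``.

    Each spike is assigned the feature value at the nearest feature sample
    (no interpolation); rate per bin = spike count / occupancy. ``circular``
    wraps the feature to [0, 2π) and defaults the range to the full circle —
    the head-direction case.
    """
    if nb_bins < 1:
        raise ValueError("nb_bins must be >= 1")
    if ep is None:
        ep = feature.time_support.intersect(g.time_support)
    feat = feature.restrict(ep)
    if len(feat) == 0:
        raise ValueError("feature is empty after restriction to ep")
    fvals = np.mod(feat.values, TWO_PI) if circular else feat.values
    edges, centers = _feature_bins(fvals, nb_bins, range, circular)
    occ = _occupancy(fvals, feat.times, edges, occupancy_dt)
    if not np.any(occ > 0):
        raise ValueError("zero occupancy in every bin")
    rates = {}
    for i in g.unit_ids:
        sv = g[i].value_from(feature, ep)
        v = np.mod(sv.values, TWO_PI) if circular else sv.values
        cnt, _ = np.histogram(v, bins=edges)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(occ > 0, cnt / np.where(occ > 0, occ, np.nan), np.nan)
        rates[i] = r
    df = pd.DataFrame(rates, index=pd.Index(centers, name="bin_center"))
    return TuningCurve(centers, df, occ, g.unit_ids, circular)


def tuning_2d(g: EventGroup, features: MultiValuedSeries, nb_bins,
              ranges: tuple | None = None, ep: EpochSet | None = None,
              occupancy_dt: float | None = None) -> TuningCurve:
    """Occupancy-normalized 2-D rate map (product binning over two channels)."""
    if features.values.shape[1] != 2:
        raise ValueError("tuning_2d requires exactly 2 feature columns")
    nbx, nby = (nb_bins, nb_bins) if np.isscalar(nb_bins) else nb_bins
    if ep is None:
        ep = features.time_support.intersect(g.time_support)
    feat = features.restrict(ep)
    if len(feat) == 0:
        raise ValueError("features are empty after restriction to ep")
    rx = None if ranges is None else ranges[0]
    ry = None if ranges is None else ranges[1]
    ex, cx = _feature_bins(feat.values[:, 0], nbx, rx, False)
    ey, cy = _feature_bins(feat.values[:, 1], nby, ry, False)
    if occupancy_dt is None:
        if len(feat) < 2:
            raise ValueError("cannot infer sampling interval from < 2 samples")
        occupancy_dt = float(np.median(np.diff(feat.times)))
    h, _, _ = np.histogram2d(feat.values[:, 0], feat.values[:, 1], bins=(ex, ey))
    occ = h * occupancy_dt
    if not np.any(occ > 0):
        raise ValueError("zero occupancy in every bin")
    rates = {}
    for i in g.unit_ids:
        sv = g[i].value_from(features, ep)
        cnt, _, _ = np.histogram2d(sv.values[:, 0], sv.values[:, 1],
                                   bins=(ex, ey))
        with np.errstate(invalid="ignore", divide="ignore"):
            rates[i] = np.where(occ > 0, cnt / np.where(occ > 0, occ, np.nan),
                                np.nan)
    return TuningCurve((cx, cy), rates, occ, g.unit_ids, False)


def tuning_continuous(values, feature: ValuedSeries, nb_bins: int,
                      range: tuple | None = None,
                      ep: EpochSet | None = None,
                      circular: bool = False) -> TuningCurve:
    """Mean of a sampled signal per feature bin (e.g. fluorescence vs speed).

    Each value sample is assigned to the feature bin of its nearest feature
    sample in time; the bin entry is the mean of assigned values, NaN where
    no sample was assigned. ``occupancy`` counts assigned samples × median
    feature dt, for symmetry with the spiking variant.
    """
    if ep is None:
        ep = values.time_support.intersect(feature.time_support)
    sv = values.value_from(feature, ep)  # feature value at each value sample
    if len(sv) == 0:
        raise ValueError("values and feature have no temporal overlap")
    fv = np.mod(sv.values, TWO_PI) if circular else sv.values
    if isinstance(sv, MultiValuedSeries):
        fv = fv[:, 0]
    edges, centers = _feature_bins(fv, nb_bins, range, circular)
    val = values.restrict(sv.time_support)
    vmat = val.values if val.values.ndim == 2 else val.values[:, None]
    names = getattr(values, "column_names", [0])
    which = np.digitize(fv, edges) - 1
    which = np.clip(which, 0, nb_bins - 1)
    inside = (fv >= edges[0]) & (fv <= edges[-1])
    means = np.full((nb_bins, vmat.shape[1]), np.nan)
    counts = np.zeros(nb_bins)
    for b in np.arange(nb_bins):
        m = inside & (which == b)
        counts[b] = m.sum()
        if counts[b]:
            means[b] = vmat[m].mean(axis=0)
    feat_t = feature.restrict(ep).times
    dt = float(np.median(np.diff(feat_t))) if feat_t.size > 1 else np.nan
    df = pd.DataFrame(means, index=pd.Index(centers, name="bin_center"),
                      columns=names)
    return TuningCurve(centers, df, counts * dt, list(names), circular)


# --------------------------------------------------------------------------
# Bayesian decoding
# --------------------------------------------------------------------------

RATE_FLOOR = 1e-12  # events/s; keeps log-likelihood finite for silent bins


def decode_bayes_1d(tc: TuningCurve, g: EventGroup, bin_size: float,
                    ep: EpochSet, prior: str = "uniform") -> DecodedTrajectory:
    """Decode a 1-D feature from population spike counts.

    The state space is the set of tuning-curve bins with defined rates
    (positive occupancy); the likelihood is independent Poisson per unit.
    ``prior`` is 'uniform' (default) or 'occupancy' (proportional to time
    spent per bin during tuning-curve estimation).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not isinstance(tc.rates, pd.DataFrame):
        raise ValueError("decode_bayes_1d requires a 1-D tuning curve")
    missing = [u for u in tc.unit_ids if u not in g]
    if missing:
        raise ValueError(f"tuning-curve units missing from group: {missing}")
    rates = tc.rates[tc.unit_ids].to_numpy()          # (n_bins, n_units)
    valid = ~np.any(np.isnan(rates), axis=1) & (tc.occupancy > 0)
    if not np.any(valid):
        raise ValueError("all tuning-curve bins are undefined")
    F = np.maximum(rates[valid], RATE_FLOOR)          # (n_states, n_units)
    states = np.asarray(tc.bin_centers)[valid]
    if prior == "uniform":
        log_prior = np.zeros(F.shape[0])
    elif prior == "occupancy":
        p = tc.occupancy[valid] / tc.occupancy[valid].sum()
        log_prior = np.log(p)
    else:
        raise ValueError(f"prior must be 'uniform' or 'occupancy', got {prior!r}")

    sub = EventGroup._from_members(
        {i: g[i] for i in tc.unit_ids}, g.time_support,
        g.metadata.loc[tc.unit_ids].drop(columns=["rate"]))
    counts = sub.count(bin_size, ep)                  # (n_t, n_units)
    n = counts.values
    logF = np.log(F)
    # log P(x|n) ∝ log prior + n·log f − τ Σ f
    ll = n @ logF.T - bin_size * F.sum(axis=1)
    ll = ll + log_prior
    post = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
    map_est = states[np.argmax(post, axis=1)]
    df = pd.DataFrame(post, index=pd.Index(counts.times, name="time"),
                      columns=states)
    return DecodedTrajectory(counts.times, df, map_est, tc.circular)


# --------------------------------------------------------------------------
# correlograms
# --------------------------------------------------------------------------

def _lag_bins(bin_size: float, window: float):
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if window < bin_size:
        raise ValueError("window must be >= bin_size")
    K = int(np.ceil(window / bin_size))
    edges = (np.arange(-K, K + 2) - 0.5) * bin_size
    centers = np.arange(-K, K + 1) * bin_size
    return K, edges, centers


def cross_correlogram(ref: TimestampSeries, target: TimestampSeries,
                      bin_size: float, window: float,
                      ep: EpochSet | None = None,
                      norm: str = "rate") -> Correlogram:
    """Rate of ``target`` events at each lag relative to ``ref`` events.

    Both trains are restricted to ``ep`` first; pairs spanning an epoch gap
    are still counted if both events survive restriction (no boundary
    correction). 'rate' normalization divides the pooled histogram by
    (n_ref × bin_size); 'count' returns raw counts.
    """
    if norm not in ("rate", "count"):
        raise ValueError(f"norm must be 'rate' or 'count', got {norm!r}")
    K, edges, centers = _lag_bins(bin_size, window)
    if ep is not None:
        ref = ref.restrict(ep)
        target = target.restrict(ep)
    if len(ref) == 0:
        raise ValueError("reference train is empty after restriction")
    counts = np.zeros(centers.size)
    tt = target.times
    lo_all = np.searchsorted(tt, ref.times + edges[0], side="left")
    hi_all = np.searchsorted(tt, ref.times + edges[-1], side="left")
    for r, lo, hi in zip(ref.times, lo_all, hi_all):
        if hi > lo:
            counts += np.histogram(tt[lo:hi] - r, bins=edges)[0]
    values = counts / (len(ref) * bin_size) if norm == "rate" else counts
    return Correlogram(centers, values, len(ref), bin_size, norm)


def auto_correlogram(x: TimestampSeries, bin_size: float, window: float,
                     ep: EpochSet | None = None,
                     norm: str = "rate") -> Correlogram:
    """Autocorrelogram: cross-correlogram of a train with itself, with
    identical-index (zero-lag self) pairs excluded.

    Computed from unordered-pair absolute lags and mirrored, so the result
    is symmetric about lag 0 bit-exactly.
    """
    if norm not in ("rate", "count"):
        raise ValueError(f"norm must be 'rate' or 'count', got {norm!r}")
    K, edges, centers = _lag_bins(bin_size, window)
    if ep is not None:
        x = x.restrict(ep)
    if len(x) == 0:
        raise ValueError("train is empty after restriction")
    pos_edges = (np.arange(K + 2) - 0.5) * bin_size   # |lag| bins
    t = x.times
    half = np.zeros(K + 1)
    hi_all = np.searchsorted(t, t + pos_edges[-1], side="left")
    for i, hi in enumerate(hi_all):
        if hi > i + 1:
            half += np.histogram(t[i + 1:hi] - t[i], bins=pos_edges)[0]
    counts = np.concatenate([half[:0:-1], [2.0 * half[0]], half[1:]])
    values = counts / (len(x) * bin_size) if norm == "rate" else counts
    return Correlogram(centers, values, len(x), bin_size, norm)


# --------------------------------------------------------------------------
# peri-event alignment
# --------------------------------------------------------------------------

def peri_event(target, ref: TimestampSeries, before: float, after: float,
               bin_size: float | None = None):
    """Align events to reference timestamps (the PSTH).

    For a :class:`TimestampSeries` target, returns a
    :class:`PeriEventEnsemble` whose ``trials[k]`` holds the target event
    times relative to ``ref[k]`` within ``[-before, +after]`` (closed). With
    ``bin_size``, half-open lag bins tile from ``-before`` and ``mean_rate``
    is the pooled count divided by (n_ref × bin_size) — events/s.

    For an :class:`EventGroup` target, returns ``{unit_id: ensemble}``.
    """
    if before < 0 or after < 0:
        raise ValueError("before and after must be >= 0")
    if before == 0 and after == 0:
        raise ValueError("window has zero width")
    if len(ref) == 0:
        raise ValueError("empty reference train")
    if isinstance(target, EventGroup):
        return {i: peri_event(target[i], ref, before, after, bin_size)
                for i in target.unit_ids}
    tt = target.times
    lo = np.searchsorted(tt, ref.times - before, side="left")
    hi = np.searchsorted(tt, ref.times + after, side="right")
    trials = [tt[a:b] - r for r, a, b in zip(ref.times, lo, hi)]
    centers = mean_rate = None
    if bin_size is not None:
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        nb = int(np.floor((before + after) / bin_size + 1e-12))
        edges = -before + bin_size * np.arange(nb + 1)
        centers = edges[:-1] + bin_size / 2.0
        pooled = np.concatenate(trials) if trials else np.array([])
        cnt, _ = np.histogram(pooled, bins=edges)
        mean_rate = cnt / (len(ref) * bin_size)
    return PeriEventEnsemble((before, after), ref.times.copy(), trials,
                             centers, mean_rate)


def peri_event_continuous(target, ref: TimestampSeries, before: float,
                          after: float, dt: float) -> PeriEventEnsemble:
    """Event-triggered average of a sampled signal.

    Values are sampled by nearest neighbor on a relative-time grid
    ``-before … +after`` with step ``dt``; references falling outside the
    target's time support are dropped (their count is reported in
    ``n_dropped``). ``mean_trace`` is the across-trial mean.
    """
    if before < 0 or after < 0 or (before == 0 and after == 0):
        raise ValueError("invalid window")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(ref) == 0:
        raise ValueError("empty reference train")
    inside = target.time_support.contains(ref.times)
    n_dropped = int((~inside).sum())
    refs = ref.times[inside]
    if refs.size == 0:
        raise ValueError("no reference events inside the target time support")
    grid = np.arange(0, np.floor((before + after) / dt + 1e-9) + 1) * dt - before
    tt = target.times
    vals = target.values if target.values.ndim == 2 else target.values[:, None]
    snippets = np.empty((refs.size, grid.size, vals.shape[1]))
    for k, r in enumerate(refs):
        q = r + grid
        idx = np.searchsorted(tt, q, side="left")
        idx = np.clip(idx, 1, tt.size - 1) if tt.size > 1 else \
            np.zeros(q.size, int)
        if tt.size > 1:
            use_left = (q - tt[idx - 1]) <= (tt[idx] - q)
            idx = np.where(use_left, idx - 1, idx)
        snippets[k] = vals[idx]
    trials = snippets[:, :, 0] if vals.shape[1] == 1 else snippets
    mean_trace = trials.mean(axis=0)
    return PeriEventEnsemble((before, after), refs, trials, grid,
                             mean_trace=mean_trace, n_dropped=n_dropped)


# --------------------------------------------------------------------------
# circular helpers (shared by tests/CLI)
# --------------------------------------------------------------------------

def circular_distance(a, b) -> np.ndarray:
    """Absolute angular distance on the circle, in radians, in [0, π]."""
    d = np.mod(np.asarray(a) - np.asarray(b) + np.pi, TWO_PI) - np.pi
    return np.abs(d)


def preferred_direction(tc: TuningCurve) -> pd.Series:
    """Preferred direction per unit from a circular 1-D tuning curve.

    The rate-weighted circular mean of the bin centers,
    :math:`\\arg \\sum_b r_b e^{i\\theta_b}` — more accurate than the raw
    argmax bin because it pools the whole curve. NaN (unvisited) bins
    contribute nothing.
    """
    if not tc.circular or not isinstance(tc.rates, pd.DataFrame):
        raise ValueError("preferred_direction needs a circular 1-D tuning curve")
    th = np.asarray(tc.bin_centers)
    out = {}
    for u in tc.unit_ids:
        r = np.nan_to_num(tc.rates[u].to_numpy())
        out[u] = float(np.mod(np.angle(np.sum(r * np.exp(1j * th))), TWO_PI))
    return pd.Series(out, name="preferred_direction")
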