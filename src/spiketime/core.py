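"""Core time-series objects for neural data analysis.

All objects store time in 64-bit floating seconds. An :class:`EpochSet`
describes *when* data are valid (the "time support"); the series classes
(:class:`TimestampSeries`, :class:`ValuedSeries`, :class:`MultiValuedSeries`)
carry an EpochSet alongside their samples, and every operation that subsets
data in time propagates the support by set intersection. This lets analyses
distinguish "no events observed here" from "this period was excluded".

Interval convention: intervals are closed on both ends, ``[start, end]``.
Overlapping or abutting intervals are merged at construction, so a shared
endpoint is never ambiguous. Comparisons use exact float comparison — no
epsilon — so endpoints must be produced consistently by the library itself.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TIME_UNITS",
    "EpochSet",
    "TimestampSeries",
    "ValuedSeries",
    "MultiValuedSeries",
    "validate",
]

#: Supported time units and their scale relative to seconds (internal base).
TIME_UNITS = {"s": 1.0, "ms": 1e-3, "us": 1e-6}


def _unit_scale(unit: str) -> float:
    try:
        return TIME_UNITS[unit]
    except KeyError:
        raise ValueError(
            f"unknown time unit {unit!r}; expected one of {sorted(TIME_UNITS)}"
        ) from None


def _to_seconds(times, unit: str) -> np.ndarray:
    t = np.asarray(times, dtype=np.float64)
    scale = _unit_scale(unit)
    return t if scale == 1.0 else t * scale


class EpochSet:
    """A normalized set of closed time intervals ``[start, end]`` in seconds.

    After construction intervals are sorted by start, pairwise non-overlapping
    and non-abutting (strictly positive gap between consecutive intervals).
    Overlapping or abutting input intervals are merged; a merged interval
    inherits the label of its earliest constituent.

    Parameters
    ----------
    starts, ends
        Interval bounds in `time_units`. Must have equal length and satisfy
        ``ends[i] >= starts[i]``.
    labels
        Optional per-interval labels (one per input interval).
    time_units
        Unit of the inputs; storage is always seconds.
    """

    def __init__(self, starts, ends, labels=None, time_units: str = "s"):
        starts = np.atleast_1d(_to_seconds(starts, time_units))
        ends = np.atleast_1d(_to_seconds(ends, time_units))
        if starts.shape != ends.shape or starts.ndim != 1:
            raise ValueError(
                f"starts and ends must be 1-D of equal length, "
                f"got {starts.shape} and {ends.shape}"
            )
        bad = np.nonzero(ends < starts)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"interval {i} has end < start ({ends[i]} < {starts[i]})"
            )
        if labels is not None:
            labels = list(labels)
            if len(labels) != len(starts):
                raise ValueError(
                    f"labels length {len(labels)} != number of intervals {len(starts)}"
                )
        self.starts, self.ends, self.labels = self._normalize(starts, ends, labels)

    @staticmethod
    def _normalize(starts, ends, labels):
        if starts.size == 0:
            return starts.copy(), ends.copy(), ([] if labels is not None else None)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        if labels is not None:
            labels = [labels[i] for i in order]
        out_s, out_e, out_l = [starts[0]], [ends[0]], []
        if labels is not None:
            out_l.append(labels[0])
        for i in range(1, starts.size):
            if starts[i] <= out_e[-1]:  # overlap or abutting -> merge
                out_e[-1] = max(out_e[-1], ends[i])
            else:
                out_s.append(starts[i])
                out_e.append(ends[i])
                if labels is not None:
                    out_l.append(labels[i])
        return (
            np.asarray(out_s, dtype=np.float64),
            np.asarray(out_e, dtype=np.float64),
            out_l if labels is not None else None,
        )

    @classmethod
    def _raw(cls, starts, ends, labels=None):
        """Build from already-normalized arrays without re-validation."""
        obj = cls.__new__(cls)
        obj.starts = np.asarray(starts, dtype=np.float64)
        obj.ends = np.asarray(ends, dtype=np.float64)
        obj.labels = labels
        return obj

    # ---- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return int(self.starts.size)

    def __iter__(self):
        return iter(zip(self.starts, self.ends))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
            and self.labels == other.labels
        )

    def __repr__(self) -> str:
        return (
            f"EpochSet({len(self)} intervals, "
            f"total_duration={self.total_duration:g} s)"
        )

    @property
    def total_duration(self) -> float:
        """Summed interval durations in seconds."""
        return float(np.sum(self.ends - self.starts))

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"start": self.starts, "end": self.ends})
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def contains(self, times) -> np.ndarray:
        """Boolean closed-interval membership for each time (seconds)."""
        t = np.asarray(times, dtype=np.float64)
        if len(self) == 0:
            return np.zeros(t.shape, dtype=bool)
        idx = np.searchsorted(self.starts, t, side="right") - 1
        ok = idx >= 0
        out = np.zeros(t.shape, dtype=bool)
        out[ok] = t[ok] <= self.ends[idx[ok]]
        return out

    # ---- set algebra ----------------------------------------------------
    def intersect(self, other: "EpochSet") -> "EpochSet":
        """Set intersection; degenerate point overlaps are dropped."""
        i = j = 0
        out_s, out_e = [], []
        a_s, a_e, b_s, b_e = self.starts, self.ends, other.starts, other.ends
        while i < len(a_s) and j < len(b_s):
            s = max(a_s[i], b_s[j])
            e = min(a_e[i], b_e[j])
            if s < e:
                out_s.append(s)
                out_e.append(e)
            if a_e[i] <= b_e[j]:
                i += 1
            else:
                j += 1
        return EpochSet._raw(out_s, out_e)

    def union(self, other: "EpochSet") -> "EpochSet":
        """Normalized cover of times in either input."""
        return EpochSet(
            np.concatenate([self.starts, other.starts]),
            np.concatenate([self.ends, other.ends]),
        )

    def set_diff(self, other: "EpochSet") -> "EpochSet":
        """Times in self not interior to other.

        Endpoints of removed regions are retained as closed endpoints:
        ``[0,10] \\ [3,5] -> [0,3] ∪ [5,10]``. This differs from strict set
        difference only on a measure-zero set.
        """
        out_s, out_e = [], []
        b_s, b_e = other.starts, other.ends
        for s, e in self:
            cur = s
            k = np.searchsorted(b_e, cur, side="left")
            while k < len(b_s) and b_s[k] < e:
                if b_s[k] > cur:
                    out_s.append(cur)
                    out_e.append(b_s[k])
                cur = max(cur, b_e[k])
                if cur >= e:
                    break
                k += 1
            if cur < e:
                out_s.append(cur)
                out_e.append(e)
        return EpochSet._raw(out_s, out_e)

    def drop_short_intervals(self, min_dur: float) -> "EpochSet":
        """Keep intervals with duration >= ``min_dur`` seconds."""
        if min_dur < 0:
            raise ValueError(f"min_dur must be non-negative, got {min_dur}")
        keep = (self.ends - self.starts) >= min_dur
        return self._filtered(keep)

    def drop_long_intervals(self, max_dur: float) -> "EpochSet":
        """Keep intervals with duration <= ``max_dur`` seconds."""
        if max_dur < 0:
            raise ValueError(f"max_dur must be non-negative, got {max_dur}")
        keep = (self.ends - self.starts) <= max_dur
        return self._filtered(keep)

    def _filtered(self, keep: np.ndarray) -> "EpochSet":
        labels = None
        if self.labels is not None:
            labels = [l for l, k in zip(self.labels, keep) if k]
        return EpochSet._raw(self.starts[keep], self.ends[keep], labels)

    def merge_close_intervals(self, max_gap: float) -> "EpochSet":
        """Merge consecutive intervals separated by a gap <= ``max_gap``.

        Applied transitively: a chain of intervals each within ``max_gap``
        of the next collapses into one.
        """
        if max_gap < 0:
            raise ValueError(f"max_gap must be non-negative, got {max_gap}")
        if len(self) == 0:
            return EpochSet._raw([], [], self.labels)
        out_s, out_e = [self.starts[0]], [self.ends[0]]
        out_l = [self.labels[0]] if self.labels is not None else None
        for i in range(1, len(self)):
            # compare as start <= end + gap: subtraction can inflate the
            # gap by one ulp (e.g. 2.6 - 2.0 > 0.6)
            if self.starts[i] <= out_e[-1] + max_gap:
                out_e[-1] = max(out_e[-1], self.ends[i])
            else:
                out_s.append(self.starts[i])
                out_e.append(self.ends[i])
                if out_l is not None:
                    out_l.append(self.labels[i])
        return EpochSet._raw(out_s, out_e, out_l)


def _check_sorted_times(times: np.ndarray) -> None:
    if times.size > 1 and np.any(np.diff(times) < 0):
        i = int(np.nonzero(np.diff(times) < 0)[0][0])
        raise ValueError(
            f"times must be non-decreasing; times[{i + 1}]={times[i + 1]} "
            f"< times[{i}]={times[i]} (sort your input explicitly)"
        )


class _SeriesBase:
    """Shared behavior of the three series classes.

    Subclasses define ``times`` (1-D float64 seconds, non-decreasing) and a
    ``time_support`` :class:`EpochSet`; samples always lie inside the support
    (closed-interval membership). Duplicate timestamps are allowed
    (simultaneous events); decreasing input times are rejected, never
    silently sorted.
    """

    time_support: EpochSet
    times: np.ndarray

    def _init_times(self, times, time_units: str, time_support) -> np.ndarray:
        t = np.atleast_1d(_to_seconds(times, time_units))
        if t.ndim != 1:
            raise ValueError("times must be 1-D")
        _check_sorted_times(t)
        if time_support is None:
            if t.size:
                time_support = EpochSet._raw([t[0]], [t[-1]])
            else:
                time_support = EpochSet._raw([], [])
        keep = time_support.contains(t)
        self.time_support = time_support
        return t, keep

    def __len__(self) -> int:
        return int(self.times.size)

    def restrict(self, ep: EpochSet):
        """Keep samples inside ``ep``; support becomes the intersection."""
        keep = ep.contains(self.times)
        return self._subset(keep, self.time_support.intersect(ep))

    def _subset(self, keep, support):  # pragma: no cover - abstract
        raise NotImplementedError

    def as_units(self, unit: str):
        """Times expressed in ``unit`` ('s', 'ms' or 'us'); values unchanged."""
        scale = _unit_scale(unit)
        return self._as_units(self.times / scale)

    def start_time(self) -> float | None:
        return float(self.times[0]) if len(self) else None

    def end_time(self) -> float | None:
        return float(self.times[-1]) if len(self) else None


class TimestampSeries(_SeriesBase):
    """Discrete event times (e.g. spikes) in seconds with a time support."""

    def __init__(self, times, time_support: EpochSet | None = None,
                 time_units: str = "s"):
        t, keep = self._init_times(times, time_units, time_support)
        self.times = t[keep] if not keep.all() else t

    def __repr__(self) -> str:
        return f"TimestampSeries({len(self)} events, rate={self.rate():.3g} Hz)" \
            if self.time_support.total_duration > 0 else \
            f"TimestampSeries({len(self)} events)"

    def _subset(self, keep, support):
        obj = TimestampSeries.__new__(TimestampSeries)
        obj.times = self.times[keep]
        obj.time_support = support
        return obj

    def _as_units(self, scaled_times):
        return np.asarray(scaled_times)

    def rate(self, ep: EpochSet | None = None) -> float:
        """Event rate (events/s) over the (restricted) time support."""
        x = self if ep is None else self.restrict(ep)
        dur = x.time_support.total_duration
        if dur <= 0:
            raise ValueError("rate undefined: time support has zero duration")
        return len(x) / dur

    def count(self, bin_size: float, ep: EpochSet | None = None) -> "ValuedSeries":
        """Event counts in regular bins tiling each epoch interval.

        Bins are half-open ``[start + k*b, start + (k+1)*b)`` anchored at each
        interval start; trailing partial bins are dropped (rates computed from
        partial bins would be biased). Output times are bin centers and the
        output support is ``ep``.
        """
        if bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {bin_size}")
        if ep is None:
            ep = self.time_support
        x = self.restrict(ep)
        centers, counts = [], []
        for s, e in ep:
            nb = int(np.floor((e - s) / bin_size + 1e-12))
            if nb < 1:
                continue
            edges = s + bin_size * np.arange(nb + 1)
            lo = np.searchsorted(x.times, edges[:-1], side="left")
            hi = np.searchsorted(x.times, edges[1:], side="left")
            centers.append(edges[:-1] + bin_size / 2.0)
            counts.append((hi - lo).astype(np.float64))
        if centers:
            t = np.concatenate(centers)
            v = np.concatenate(counts)
        else:
            t = np.array([], dtype=np.float64)
            v = np.array([], dtype=np.float64)
        out = ValuedSeries.__new__(ValuedSeries)
        out.times = t
        out.values = v
        out.time_support = ep
        return out

    def value_from(self, source, ep: EpochSet | None = None):
        """Value of ``source`` at the nearest source time to each event.

        Both series are first restricted to the intersection of their time
        supports (and ``ep`` if given); ties between two equidistant source
        samples go to the earlier one. There is no maximum-gap cutoff.
        """
        return _value_from(self, source, ep)


def _value_from(target, source, ep):
    support = target.time_support.intersect(source.time_support)
    if ep is not None:
        support = support.intersect(ep)
    tgt = target.restrict(support)
    # the lookup table is the source restricted to ep only: a surviving
    # target time near the support boundary may still be nearest to a
    # source sample just outside the intersection
    src = source if ep is None else source.restrict(ep)
    if len(src) == 0:
        raise ValueError("value_from: source is empty after restriction")
    idx = np.searchsorted(src.times, tgt.times, side="left")
    idx = np.clip(idx, 1, len(src) - 1) if len(src) > 1 else np.zeros(len(tgt), int)
    if len(src) > 1:
        left, right = src.times[idx - 1], src.times[idx]
        # tie (equidistant) goes to the earlier sample: strict '<' on the right
        use_left = (tgt.times - left) <= (right - tgt.times)
        idx = np.where(use_left, idx - 1, idx)
    vals = src.values[idx] if len(tgt) else src.values[:0]
    if isinstance(source, MultiValuedSeries):
        out = MultiValuedSeries.__new__(MultiValuedSeries)
        out.times = tgt.times
        out.values = np.atleast_2d(vals).reshape(len(tgt), -1)
        out.column_names = list(src.column_names)
        out.time_support = support
        return out
    out = ValuedSeries.__new__(ValuedSeries)
    out.times = tgt.times
    out.values = np.asarray(vals, dtype=np.float64)
    out.time_support = support
    return out


class ValuedSeries(_SeriesBase):
    """A sampled scalar signal: one value per (non-decreasing) timestamp."""

    def __init__(self, times, values, time_support: EpochSet | None = None,
                 time_units: str = "s"):
        t, keep = self._init_times(times, time_units, time_support)
        v = np.asarray(values, dtype=np.float64)
        if v.shape != t.shape:
            raise ValueError(
                f"values shape {v.shape} does not match times shape {t.shape}"
            )
        self.times = t[keep] if not keep.all() else t
        self.values = v[keep] if not keep.all() else v

    def __repr__(self) -> str:
        return f"ValuedSeries({len(self)} samples)"

    def _subset(self, keep, support):
        obj = ValuedSeries.__new__(ValuedSeries)
        obj.times = self.times[keep]
        obj.values = self.values[keep]
        obj.time_support = support
        return obj

    def _as_units(self, scaled_times):
        return pd.Series(self.values, index=scaled_times)

    def value_from(self, source, ep: EpochSet | None = None):
        return _value_from(self, source, ep)

    def threshold(self, level: float, mode: str = "above") -> "ValuedSeries":
        """Samples strictly above (or below) ``level``.

        The new time support spans each maximal run of consecutive qualifying
        samples (closed interval from the first to the last sample time of
        the run); no interpolation of crossing times is attempted.
        """
        if len(self) == 0:
            raise ValueError("threshold on an empty series")
        if mode == "above":
            keep = self.values > level
        elif mode == "below":
            keep = self.values < level
        else:
            raise ValueError(f"mode must be 'above' or 'below', got {mode!r}")
        t = self.times[keep]
        v = self.values[keep]
        if t.size == 0:
            out = ValuedSeries.__new__(ValuedSeries)
            out.times = t
            out.values = v
            out.time_support = EpochSet._raw([], [])
            return out
        # runs of consecutive qualifying sample indices
        idx = np.nonzero(keep)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        run_starts = np.r_[0, breaks + 1]
        run_ends = np.r_[breaks, idx.size - 1]
        support = EpochSet(self.times[idx[run_starts]], self.times[idx[run_ends]])
        out = ValuedSeries.__new__(ValuedSeries)
        out.times = t
        out.values = v
        out.time_support = support
        return out


class MultiValuedSeries(_SeriesBase):
    """A multi-channel sampled signal: common timestamps, one row per time."""

    def __init__(self, times, values, column_names: Sequence | None = None,
                 time_support: EpochSet | None = None, time_units: str = "s"):
        t, keep = self._init_times(times, time_units, time_support)
        v = np.asarray(values, dtype=np.float64)
        if v.ndim == 1:
            v = v[:, None]
        if v.shape[0] != t.size:
            raise ValueError(
                f"values has {v.shape[0]} rows but there are {t.size} times"
            )
        if column_names is None:
            column_names = list(range(v.shape[1]))
        column_names = list(column_names)
        if len(column_names) != v.shape[1]:
            raise ValueError(
                f"{len(column_names)} column names for {v.shape[1]} columns"
            )
        if len(set(column_names)) != len(column_names):
            raise ValueError("column names must be unique")
        self.times = t[keep] if not keep.all() else t
        self.values = v[keep] if not keep.all() else v
        self.column_names = column_names

    def __repr__(self) -> str:
        return (
            f"MultiValuedSeries({len(self)} samples × "
            f"{self.values.shape[1]} columns)"
        )

    def _subset(self, keep, support):
        obj = MultiValuedSeries.__new__(MultiValuedSeries)
        obj.times = self.times[keep]
        obj.values = self.values[keep]
        obj.column_names = list(self.column_names)
        obj.time_support = support
        return obj

    def _as_units(self, scaled_times):
        return pd.DataFrame(self.values, index=scaled_times,
                            columns=self.column_names)

    def __getitem__(self, name) -> ValuedSeries:
        """Extract one channel as a :class:`ValuedSeries`."""
        j = self.column_names.index(name)
        out = ValuedSeries.__new__(ValuedSeries)
        out.times = self.times
        out.values = self.values[:, j]
        out.time_support = self.time_support
        return out

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.times,
                            columns=self.column_names)


def validate(obj) -> None:
    """Assert the type invariants of any core object; raise ValueError if violated.

    Used by loaders and tests so every constructed or deserialized object is
    checked against the same contract.
    """
    if isinstance(obj, EpochSet):
        if np.any(obj.ends < obj.starts):
            raise ValueError("EpochSet: end < start")
        if len(obj) > 1 and np.any(obj.starts[1:] <= obj.ends[:-1]):
            raise ValueError("EpochSet: intervals overlap or abut")
        if obj.labels is not None and len(obj.labels) != len(obj):
            raise ValueError("EpochSet: labels length mismatch")
        return
    if isinstance(obj, (TimestampSeries, ValuedSeries, MultiValuedSeries)):
        validate(obj.time_support)
        _check_sorted_times(obj.times)
        if not np.all(obj.time_support.contains(obj.times)):
            raise ValueError(f"{type(obj).__name__}: times outside time support")
        if isinstance(obj, ValuedSeries) and obj.values.shape != obj.times.shape:
            raise ValueError("ValuedSeries: values/times length mismatch")
        if isinstance(obj, MultiValuedSeries):
            if obj.values.shape[0] != obj.times.size:
                raise ValueError("MultiValuedSeries: row count mismatch")
            if len(obj.column_names) != obj.values.shape[1]:
                raise ValueError("MultiValuedSeries: column names mismatch")
        return
    raise TypeError(f"no validator for {type(obj).__name__}")
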