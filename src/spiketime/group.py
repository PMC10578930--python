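"""EventGroup: an id-keyed population of spike trains with shared time support.

Each unit keeps its own timestamps but all members share one
:class:`~spiketime.core.EpochSet` time support, and a per-unit metadata table
travels with the group. The 'rate' column (events/s over the group support)
is always present, recomputed automatically whenever the support changes,
and never user-writable. Unit ids are preserved — never renumbered — through
filtering, so units can be tracked across analyses.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .core import EpochSet, MultiValuedSeries, TimestampSeries

__all__ = ["EventGroup"]


class EventGroup:
    """Mapping from integer unit id to :class:`TimestampSeries`.

    Parameters
    ----------
    units
        ``{unit_id: TimestampSeries}`` with unique non-negative integer keys.
    time_support
        Shared support. If omitted, the single interval spanning the first
        and last event over all members is used (explicit supports are
        recommended: the spanning default ignores gaps in the recording).
    """

    def __init__(self, units: Mapping[int, TimestampSeries],
                 time_support: EpochSet | None = None):
        if len(units) == 0:
            raise ValueError("EventGroup requires at least one unit")
        ids = list(units.keys())
        if any((not isinstance(i, (int, np.integer))) or i < 0 for i in ids):
            raise ValueError("unit ids must be non-negative integers")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate unit ids")
        if time_support is None:
            firsts = [u.start_time() for u in units.values() if len(u)]
            lasts = [u.end_time() for u in units.values() if len(u)]
            if not firsts:
                raise ValueError(
                    "cannot infer a time support from all-empty units; "
                    "pass time_support explicitly"
                )
            time_support = EpochSet([min(firsts)], [max(lasts)])
        self._init_members(
            {int(i): units[i].restrict(time_support) for i in sorted(ids)},
            time_support, None)

    @classmethod
    def _from_members(cls, units, time_support, metadata):
        """Internal constructor: members already restricted; may be empty."""
        obj = cls.__new__(cls)
        obj._init_members(units, time_support, metadata)
        return obj

    def _init_members(self, units, time_support, metadata):
        self.units = units
        self.time_support = time_support
        rates = {}
        dur = time_support.total_duration
        for i, u in units.items():
            if dur > 0:
                rates[i] = len(u) / dur
            else:
                rates[i] = 0.0
        if dur <= 0 and units:
            warnings.warn(
                "EventGroup time support has zero duration; rates set to 0",
                RuntimeWarning, stacklevel=3)
        idx = pd.Index(sorted(units), name="unit_id")
        if metadata is None:
            metadata = pd.DataFrame(index=idx)
        else:
            metadata = metadata.loc[idx].drop(columns=["rate"], errors="ignore")
        metadata.insert(0, "rate", pd.Series(rates, dtype=float))
        self.metadata = metadata

    # ---- mapping protocol ----------------------------------------------
    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def __getitem__(self, unit_id: int) -> TimestampSeries:
        return self.units[unit_id]

    def __contains__(self, unit_id) -> bool:
        return unit_id in self.units

    def keys(self):
        return self.units.keys()

    def __repr__(self) -> str:
        return f"EventGroup({len(self)} units, support={self.time_support!r})"

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.units)

    # ---- metadata -------------------------------------------------------
    def set_metadata(self, name: str, values: Mapping[int, object]) -> "EventGroup":
        """Return a copy with metadata column ``name`` added or replaced.

        ``values`` must cover every unit id; 'rate' is reserved.
        """
        if name == "rate":
            raise ValueError("'rate' is computed automatically and read-only")
        missing = set(self.units) - set(values)
        if missing:
            raise ValueError(f"missing metadata for unit ids {sorted(missing)}")
        meta = self.metadata.copy()
        meta[name] = pd.Series({int(k): v for k, v in values.items()})
        return EventGroup._from_members(dict(self.units), self.time_support, meta)

    # ---- filters (membership only; member data is never altered) -------
    def _subgroup(self, ids) -> "EventGroup":
        return EventGroup._from_members(
            {i: self.units[i] for i in ids}, self.time_support,
            self.metadata.loc[list(ids)] if len(ids) else
            self.metadata.iloc[:0])

    def _column(self, column, numeric=False) -> pd.Series:
        if column not in self.metadata.columns:
            raise KeyError(f"unknown metadata column {column!r}")
        col = self.metadata[column]
        if numeric and not pd.api.types.is_numeric_dtype(col):
            raise TypeError(f"column {column!r} is not numeric")
        return col

    def getby_category(self, column: str) -> dict:
        """Split into subgroups by the distinct values of a metadata column.

        The returned subgroups partition the parent's unit set.
        """
        col = self._column(column)
        return {label: self._subgroup(sorted(sub.index))
                for label, sub in self.metadata.groupby(col, sort=True)}

    def getby_threshold(self, column: str, level: float,
                        op: str = ">") -> "EventGroup":
        """Units whose numeric metadata value satisfies ``value <op> level``."""
        col = self._column(column, numeric=True)
        ops = {">": col > level, "<": col < level,
               ">=": col >= level, "<=": col <= level}
        if op not in ops:
            raise ValueError(f"op must be one of {sorted(ops)}, got {op!r}")
        return self._subgroup(sorted(col.index[ops[op]]))

    def getby_intervals(self, column: str, edges) -> list:
        """One subgroup per half-open bin ``[edges[k], edges[k+1])``.

        Units whose value falls outside the edges belong to no bin.
        """
        col = self._column(column, numeric=True)
        edges = np.asarray(edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 values")
        which = np.digitize(col.to_numpy(), edges) - 1
        out = []
        for b in range(edges.size - 1):
            ids = sorted(col.index[(which == b)])
            out.append(self._subgroup(ids))
        return out

    # ---- member-wise core methods ---------------------------------------
    def restrict(self, ep: EpochSet) -> "EventGroup":
        """Restrict every member to ``ep``; rates are recomputed."""
        support = self.time_support.intersect(ep)
        units = {i: u.restrict(support) for i, u in self.units.items()}
        meta = self.metadata.drop(columns=["rate"])
        return EventGroup._from_members(units, support, meta)

    def count(self, bin_size: float, ep: EpochSet | None = None) -> MultiValuedSeries:
        """Bin all spike trains on shared bin centers.

        Columns are ordered by unit id; column j equals
        ``self[unit_ids[j]].count(bin_size, ep)``.
        """
        if ep is None:
            ep = self.time_support
        ids = self.unit_ids
        per_unit = [self.units[i].count(bin_size, ep) for i in ids]
        t = per_unit[0].times
        mat = np.column_stack([c.values for c in per_unit]) if len(t) else \
            np.zeros((0, len(ids)))
        out = MultiValuedSeries.__new__(MultiValuedSeries)
        out.times = t
        out.values = mat
        out.column_names = ids
        out.time_support = ep
        return out

    def value_from(self, source, ep: EpochSet | None = None) -> dict:
        """Member-wise :meth:`TimestampSeries.value_from`."""
        return {i: u.value_from(source, ep) for i, u in self.units.items()}
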