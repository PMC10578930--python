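"""Session persistence and tabular loaders.

A :class:`Session` bundles named core objects (epochs, series, event groups)
with free-form metadata, mirroring how an experimental recording session is
organized. Sessions round-trip through a documented HDF5 layout:

    /epochs/<name>           starts, ends [, labels]
    /series/<name>           times [, values, columns], support_starts/ends,
                             attr kind in {'ts', 'tsd', 'tsdframe'}
    /groups/<name>/unit_<id> times          (per-unit spike times)
    /groups/<name>           support_starts/ends; /_metadata holds unit_ids
                             and one col_<name> dataset per metadata column
    root attrs               name, metadata_json

All times are stored as 64-bit float seconds, so `load(save(s))` reproduces
every object bit-exactly. Every loaded object is passed through the shared
core validator, so a corrupt container fails loudly, naming the object.

Built-in loaders assume all input streams already share time zero: aligning
data acquired on different clocks to one absolute time base is the caller's
(or a custom loader's) responsibility.

Custom formats plug in through :func:`register_loader`; ``load_session(path,
format=...)`` dispatches on the registered name. The built-in formats are
``'hdf5'`` (the container above) and ``'csv_session'`` (a directory of
``<name>.epochs.csv`` and ``<name>.tracking.csv`` files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import h5py
import numpy as np
import pandas as pd

from .core import (EpochSet, MultiValuedSeries, TimestampSeries, ValuedSeries,
                   validate)
from .group import EventGroup

__all__ = [
    "Session",
    "read_epochs_csv",
    "read_tracking_csv",
    "save_session",
    "load_session",
    "register_loader",
    "registered_formats",
]

logger = logging.getLogger(__name__)


@dataclass
class Session:
    """A named collection of core objects plus free-form metadata."""
    name: str
    objects: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, name: str, obj) -> None:
        if name in self.objects:
            raise ValueError(f"object name {name!r} already in session")
        self.objects[name] = obj

    def __getitem__(self, name):
        return self.objects[name]

    def __repr__(self) -> str:
        kinds = {k: type(v).__name__ for k, v in self.objects.items()}
        return f"Session({self.name!r}, objects={kinds})"


# --------------------------------------------------------------------------
# CSV loaders
# --------------------------------------------------------------------------

def read_epochs_csv(path) -> EpochSet:
    """Load an epoch table: header ``start,end[,label]``, seconds, '.' decimal."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:2] != ["start", "end"] or cols not in (["start", "end"],
                                                    ["start", "end", "label"]):
        raise ValueError(
            f"expected header 'start,end' or 'start,end,label', got {cols} "
            f"in {path}"
        )
    for c in ("start", "end"):
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValueError(f"column {c!r} contains non-numeric entries in {path}")
    bad = df.index[df["end"] < df["start"]]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"end < start at CSV row {bad[0] + 2} in {path}")
    labels = df["label"].tolist() if "label" in df.columns else None
    return EpochSet(df["start"].to_numpy(), df["end"].to_numpy(), labels)


def write_epochs_csv(ep: EpochSet, path) -> None:
    ep.as_dataframe().to_csv(path, index=False)


def read_tracking_csv(path, time_column: str = "time",
                      value_columns=None) -> MultiValuedSeries:
    """Load behavioral tracking: one time column plus value columns.

    Rows with any missing value are dropped (the count is logged); the time
    column must be strictly increasing after NaN removal. The support is the
    single interval spanning the retained samples.
    """
    df = pd.read_csv(path)
    if time_column not in df.columns:
        raise ValueError(f"time column {time_column!r} absent from {path}")
    if value_columns is None:
        value_columns = [c for c in df.columns if c != time_column]
    missing = [c for c in value_columns if c not in df.columns]
    if missing:
        raise ValueError(f"columns {missing} absent from {path}")
    sub = df[[time_column] + list(value_columns)]
    clean = sub.dropna()
    n_dropped = len(sub) - len(clean)
    if n_dropped:
        logger.info("read_tracking_csv(%s): dropped %d rows with missing values",
                    path, n_dropped)
    t = clean[time_column].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"time column {time_column!r} not strictly increasing "
                         f"in {path}")
    return MultiValuedSeries(t, clean[list(value_columns)].to_numpy(dtype=float),
                             column_names=list(value_columns))


# --------------------------------------------------------------------------
# HDF5 container
# --------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def _write_support(grp, ep: EpochSet) -> None:
    grp.create_dataset("support_starts", data=ep.starts)
    grp.create_dataset("support_ends", data=ep.ends)


def _read_support(grp) -> EpochSet:
    return EpochSet._raw(np.asarray(grp["support_starts"], dtype=np.float64),
                         np.asarray(grp["support_ends"], dtype=np.float64))


def save_session(s: Session, path) -> None:
    """Write the session to one HDF5 file (layout documented in the module)."""
    with h5py.File(path, "w") as f:
        f.attrs["name"] = s.name
        f.attrs["metadata_json"] = json.dumps(s.metadata)
        for name, obj in s.objects.items():
            if isinstance(obj, EpochSet):
                g = f.create_group(f"epochs/{name}")
                g.create_dataset("starts", data=obj.starts)
                g.create_dataset("ends", data=obj.ends)
                if obj.labels is not None:
                    g.create_dataset("labels",
                                     data=[str(l) for l in obj.labels],
                                     dtype=_STR)
            elif isinstance(obj, MultiValuedSeries):
                g = f.create_group(f"series/{name}")
                g.attrs["kind"] = "tsdframe"
                g.create_dataset("times", data=obj.times)
                g.create_dataset("values", data=obj.values)
                g.create_dataset("columns",
                                 data=[str(c) for c in obj.column_names],
                                 dtype=_STR)
                g.attrs["columns_are_int"] = all(
                    isinstance(c, (int, np.integer)) for c in obj.column_names)
                _write_support(g, obj.time_support)
            elif isinstance(obj, ValuedSeries):
                g = f.create_group(f"series/{name}")
                g.attrs["kind"] = "tsd"
                g.create_dataset("times", data=obj.times)
                g.create_dataset("values", data=obj.values)
                _write_support(g, obj.time_support)
            elif isinstance(obj, TimestampSeries):
                g = f.create_group(f"series/{name}")
                g.attrs["kind"] = "ts"
                g.create_dataset("times", data=obj.times)
                _write_support(g, obj.time_support)
            elif isinstance(obj, EventGroup):
                g = f.create_group(f"groups/{name}")
                _write_support(g, obj.time_support)
                meta = obj.metadata.drop(columns=["rate"])
                mg = g.create_group("_metadata")
                mg.create_dataset("unit_ids",
                                  data=np.asarray(meta.index, dtype=np.int64))
                mg.attrs["columns_json"] = json.dumps(list(meta.columns))
                for col in meta.columns:
                    v = meta[col].to_numpy()
                    if v.dtype.kind in "if":
                        mg.create_dataset(f"col_{col}", data=v)
                    else:
                        mg.create_dataset(f"col_{col}",
                                          data=[str(x) for x in v], dtype=_STR)
                for i in obj.unit_ids:
                    g.create_dataset(f"unit_{i}", data=obj[i].times)
            else:
                raise TypeError(
                    f"cannot save object {name!r} of type {type(obj).__name__}")


def _load_hdf5(path) -> Session:
    with h5py.File(path, "r") as f:
        s = Session(str(f.attrs.get("name", Path(path).stem)),
                    metadata=json.loads(f.attrs.get("metadata_json", "{}")))
        for name, g in f.get("epochs", {}).items():
            _require(g, ("starts", "ends"), f"epochs/{name}")
            labels = ([l.decode() if isinstance(l, bytes) else str(l)
                       for l in g["labels"]] if "labels" in g else None)
            obj = EpochSet._raw(np.asarray(g["starts"], dtype=np.float64),
                                np.asarray(g["ends"], dtype=np.float64), labels)
            _validated(s, name, obj)
        for name, g in f.get("series", {}).items():
            kind = g.attrs.get("kind")
            _require(g, ("times", "support_starts", "support_ends"),
                     f"series/{name}")
            t = np.asarray(g["times"], dtype=np.float64)
            support = _read_support(g)
            if kind == "ts":
                obj = TimestampSeries.__new__(TimestampSeries)
                obj.times, obj.time_support = t, support
            elif kind == "tsd":
                _require(g, ("values",), f"series/{name}")
                obj = ValuedSeries.__new__(ValuedSeries)
                obj.times = t
                obj.values = np.asarray(g["values"], dtype=np.float64)
                obj.time_support = support
            elif kind == "tsdframe":
                _require(g, ("values", "columns"), f"series/{name}")
                obj = MultiValuedSeries.__new__(MultiValuedSeries)
                obj.times = t
                obj.values = np.asarray(g["values"], dtype=np.float64)
                cols = [c.decode() if isinstance(c, bytes) else str(c)
                        for c in g["columns"]]
                if g.attrs.get("columns_are_int", False):
                    cols = [int(c) for c in cols]
                obj.column_names = cols
                obj.time_support = support
            else:
                raise ValueError(f"series/{name}: unknown kind {kind!r}")
            _validated(s, name, obj)
        for name, g in f.get("groups", {}).items():
            _require(g, ("support_starts", "support_ends"), f"groups/{name}")
            support = _read_support(g)
            units = {}
            for key in g:
                if key.startswith("unit_"):
                    u = TimestampSeries.__new__(TimestampSeries)
                    u.times = np.asarray(g[key], dtype=np.float64)
                    u.time_support = support
                    _validate_named(u, f"groups/{name}/{key}")
                    units[int(key[5:])] = u
            if not units:
                raise ValueError(f"groups/{name}: no units found")
            _require(g, ("_metadata",), f"groups/{name}")
            mg = g["_metadata"]
            idx = pd.Index(np.asarray(mg["unit_ids"], dtype=np.int64),
                           name="unit_id")
            meta = pd.DataFrame(index=idx)
            for col in json.loads(mg.attrs["columns_json"]):
                v = np.asarray(mg[f"col_{col}"])
                if v.dtype.kind == "O" or v.dtype.kind == "S":
                    v = [x.decode() if isinstance(x, bytes) else str(x)
                         for x in v]
                meta[col] = v
            obj = EventGroup._from_members(units, support, meta)
            s.add(name, obj)
    return s


def _require(g, keys, where: str) -> None:
    for k in keys:
        if k not in g:
            raise ValueError(f"corrupt container: {where} is missing "
                             f"dataset {k!r}")


def _validate_named(obj, name: str) -> None:
    try:
        validate(obj)
    except ValueError as e:
        raise ValueError(f"object {name!r} failed validation: {e}") from e


def _validated(s: Session, name: str, obj) -> None:
    _validate_named(obj, name)
    s.add(name, obj)


def _load_csv_session(path) -> Session:
    """Directory of ``<name>.epochs.csv`` / ``<name>.tracking.csv`` files."""
    p = Path(path)
    if not p.is_dir():
        raise ValueError(f"csv_session expects a directory, got {path}")
    s = Session(p.name)
    for fp in sorted(p.glob("*.epochs.csv")):
        _validated(s, fp.name[:-len(".epochs.csv")], read_epochs_csv(fp))
    for fp in sorted(p.glob("*.tracking.csv")):
        _validated(s, fp.name[:-len(".tracking.csv")], read_tracking_csv(fp))
    return s


# --------------------------------------------------------------------------
# loader registry
# --------------------------------------------------------------------------

_REGISTRY: dict[str, Callable] = {
    "hdf5": _load_hdf5,
    "csv_session": _load_csv_session,
}


def register_loader(name: str, fn: Callable) -> None:
    """Register a custom ``path -> Session`` loader under ``name``.

    Re-registration of an existing name is rejected.
    """
    if name in _REGISTRY:
        raise ValueError(f"loader {name!r} already registered")
    _REGISTRY[name] = fn


def registered_formats() -> list[str]:
    return sorted(_REGISTRY)


def load_session(path, format: str = "hdf5") -> Session:
    """Load a session via a registered loader (built-ins: 'hdf5', 'csv_session')."""
    if format not in _REGISTRY:
        raise ValueError(
            f"unknown format {format!r}; registered formats: "
            f"{registered_formats()}"
        )
    return _REGISTRY[format](path)
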