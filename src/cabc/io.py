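"""Readers and writers for item sets, partitions and recursion traces.

Items come in as CSV/TSV (a ``label``/``value`` pair of columns, or a
single numeric column whose rows are auto-labelled) or as a JSON object
``{label: value}``.  Partitions and traces go out as versioned JSON
(machine interface) or CSV (human tables); both round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ABCPartition, ItemSet
from .errors import NegativeValueError, SchemaError
from .recursion import RecursionLevel, RecursionTrace, UniformityResult

__all__ = ["read_items", "write_partition", "read_partition",
           "write_trace", "read_trace"]

SCHEMA_VERSION = 1


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_items(path) -> ItemSet:
    """Read an item set from CSV/TSV or JSON.

    Raises :class:`SchemaError` naming the offending row for malformed or
    negative values.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            obj = json.load(fh)
        if not isinstance(obj, dict) or not obj:
            raise SchemaError(f"{path}: expected a non-empty JSON object "
                              "{label: value}")
        try:
            return ItemSet.from_dict(obj)
        except NegativeValueError as exc:
            raise SchemaError(f"{path}: {exc}") from exc

    try:
        frame = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse as CSV/TSV ({exc})") from exc
    if frame.shape[1] == 1:
        col = frame.columns[0]
        labels = [f"row{i + 1}" for i in range(len(frame))]
        values = frame[col]
    elif "label" in frame.columns and "value" in frame.columns:
        labels = frame["label"].astype(str).tolist()
        values = frame["value"]
    else:
        raise SchemaError(
            f"{path}: expected a single value column or columns "
            f"'label' and 'value'; got {list(frame.columns)}")
    values = pd.to_numeric(values, errors="coerce")
    bad = np.flatnonzero(values.isna().to_numpy())
    if bad.size:
        raise SchemaError(f"{path}: non-numeric value in data row {bad[0] + 1}")
    neg = np.flatnonzero((values < 0).to_numpy())
    if neg.size:
        raise SchemaError(f"{path}: negative value in data row {neg[0] + 1} "
                          f"(item {labels[neg[0]]!r})")
    return ItemSet(labels, values.to_numpy(dtype=float))


def write_partition(part: ABCPartition, path, items: ItemSet | None = None) -> None:
    """Write a partition as JSON (``.json``) or as a label/value/rank/subset
    CSV (anything else; requires ``items`` for the values)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"schema_version": SCHEMA_VERSION, **part.to_dict()}
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    if items is None:
        raise ValueError("CSV partition output needs the original items")
    value_of = dict(zip(items.labels, items.values))
    rows = []
    rank = 0
    for subset, labels in (("A", part.set_a), ("B", part.set_b),
                           ("C", part.set_c)):
        for lab in labels:
            rank += 1
            rows.append({"label": lab, "value": value_of[lab],
                         "rank": rank, "subset": subset})
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_partition(path) -> ABCPartition:
    path = Path(path)
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported partition schema "
                          f"{obj.get('schema_version')!r}")
    try:
        return ABCPartition(
            juran=tuple(obj["juran"]), break_even=tuple(obj["break_even"]),
            degenerate_flat=bool(obj["degenerate_flat"]),
            set_a=tuple(obj["a"]), set_b=tuple(obj["b"]),
            set_c=tuple(obj["c"]), a_fraction=float(obj["a_fraction"]),
            n=int(obj["n"]))
    except KeyError as exc:
        raise SchemaError(f"{path}: missing partition field {exc}") from exc


def write_trace(trace: RecursionTrace, path) -> None:
    Path(path).write_text(json.dumps(trace.to_dict(), indent=2) + "\n")


def _partition_from_dict(obj: dict) -> ABCPartition:
    return ABCPartition(
        juran=tuple(obj["juran"]), break_even=tuple(obj["break_even"]),
        degenerate_flat=bool(obj["degenerate_flat"]),
        set_a=tuple(obj["a"]), set_b=tuple(obj["b"]), set_c=tuple(obj["c"]),
        a_fraction=float(obj["a_fraction"]), n=int(obj["n"]))


def read_trace(path) -> RecursionTrace:
    path = Path(path)
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported trace schema "
                          f"{obj.get('schema_version')!r}")

    def _uni(u):
        if u is None:
            return None
        return UniformityResult(u["statistic"], u["p_value"], u["identical"])

    try:
        levels = tuple(
            RecursionLevel(name=lvl["name"],
                           input_labels=tuple(lvl["input_labels"]),
                           uniformity=_uni(lvl["uniformity"]),
                           partition=_partition_from_dict(lvl["partition"]))
            for lvl in obj["levels"]
        )
        return RecursionTrace(levels=levels, stop_reason=obj["stop_reason"],
                              final_set=tuple(obj["final_set"]),
                              final_name=obj["final_name"],
                              final_uniformity=_uni(obj["final_uniformity"]),
                              alpha=float(obj["alpha"]))
    except KeyError as exc:
        raise SchemaError(f"{path}: missing trace field {exc}") from exc
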