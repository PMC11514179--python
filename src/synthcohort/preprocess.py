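"""Encoding (min-max + one-hot) and 80:20 splitting.

The encoded matrix — every entry in [0, 1], one column per continuous
variable, one indicator column per category — is the common currency of the
neural generators and all distance-based metrics.  The outcome pair can be
folded in as ordinary columns (time min-max scaled, event one-hot), matching
how the generators treat the full table.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import Cohort, CohortSchema


@dataclass
class ColumnInfo:
    name: str          # encoded column name
    source: str        # source variable (or outcome) name
    role: str          # continuous | onehot | binary
    category: str | None = None


@dataclass
class EncodedMatrix:
    values: np.ndarray
    columns: list[str]
    layout: list[ColumnInfo]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)

    def block_slices(self) -> dict[str, slice]:
        """Contiguous column slice per source variable (one-hot blocks intact)."""
        out: dict[str, slice] = {}
        start = 0
        cur = None
        for j, info in enumerate(self.layout):
            if info.source != cur:
                if cur is not None:
                    out[cur] = slice(start, j)
                cur, start = info.source, j
        out[cur] = slice(start, len(self.layout))
        return out


class Encoder:
    """Invertible min-max + one-hot encoder with a JSON-serializable spec."""

    def __init__(self, schema: CohortSchema, ranges: dict[str, tuple[float, float]],
                 include_outcome: bool = False,
                 time_range: tuple[float, float] | None = None):
        self.schema = schema
        self.ranges = dict(ranges)
        self.include_outcome = include_outcome
        self.time_range = time_range
        self.layout: list[ColumnInfo] = []
        for v in schema.variables:
            if v.vtype in ("continuous", "derived"):
                self.layout.append(ColumnInfo(v.name, v.name, "continuous"))
            elif v.vtype == "binary":
                self.layout.append(ColumnInfo(v.name, v.name, "binary"))
            else:
                for c in v.categories:
                    self.layout.append(ColumnInfo(f"{v.name}={c}", v.name, "onehot", c))
        if include_outcome:
            self.layout.append(ColumnInfo(schema.outcome_time_name,
                                          schema.outcome_time_name, "continuous"))
            for c in ("0", "1"):
                self.layout.append(ColumnInfo(f"{schema.outcome_event_name}={c}",
                                              schema.outcome_event_name, "onehot", c))
        self.columns = [ci.name for ci in self.layout]

    # ---- construction -------------------------------------------------------
    @classmethod
    def from_cohort(cls, cohort: Cohort, include_outcome: bool = False) -> "Encoder":
        """Fit min-max ranges from the data (training portion in eval loops)."""
        ranges = {}
        for v in cohort.schema.variables:
            if v.vtype in ("continuous", "derived"):
                col = cohort.data[v.name].to_numpy(float)
                lo, hi = float(col.min()), float(col.max())
                if hi <= lo:
                    raise ValueError(f"constant continuous column {v.name!r} (zero range)")
                ranges[v.name] = (lo, hi)
        time_range = None
        if include_outcome:
            if not cohort.has_outcome:
                raise ValueError("cohort has no outcome to encode")
            t = cohort.time
            lo, hi = float(t.min()), float(t.max())
            if hi <= lo:
                raise ValueError("constant follow-up time (zero range)")
            time_range = (lo, hi)
        return cls(cohort.schema, ranges, include_outcome, time_range)

    @classmethod
    def from_schema(cls, schema: CohortSchema) -> "Encoder":
        """Use the schema's fixed native-unit bounds (the ground-truth scale)."""
        ranges = {v.name: v.bounds for v in schema.variables
                  if v.vtype in ("continuous", "derived")}
        return cls(schema, ranges, include_outcome=False)

    # ---- transform ----------------------------------------------------------
    def transform(self, cohort: Cohort) -> EncodedMatrix:
        n = cohort.n
        out = np.empty((n, len(self.layout)))
        for j, info in enumerate(self.layout):
            if info.source == self.schema.outcome_time_name and self.include_outcome:
                lo, hi = self.time_range
                out[:, j] = np.clip((cohort.time - lo) / (hi - lo), 0.0, 1.0)
            elif info.source == self.schema.outcome_event_name and self.include_outcome:
                out[:, j] = (cohort.event == int(info.category)).astype(float)
            elif info.role == "continuous":
                lo, hi = self.ranges[info.source]
                col = cohort.data[info.source].to_numpy(float)
                out[:, j] = np.clip((col - lo) / (hi - lo), 0.0, 1.0)
            elif info.role == "binary":
                out[:, j] = cohort.data[info.source].to_numpy(float)
            else:
                out[:, j] = (cohort.data[info.source].to_numpy(str) == info.category).astype(float)
        return EncodedMatrix(out, list(self.columns), list(self.layout))

    def inverse_transform(self, matrix: EncodedMatrix | np.ndarray) -> Cohort:
        vals = matrix.values if isinstance(matrix, EncodedMatrix) else np.asarray(matrix, float)
        if vals.shape[1] != len(self.layout):
            raise ValueError("layout mismatch: wrong number of encoded columns")
        cols: dict[str, np.ndarray] = {}
        j = 0
        for v in self.schema.variables:
            if v.vtype in ("continuous", "derived"):
                lo, hi = self.ranges[v.name]
                cols[v.name] = lo + np.clip(vals[:, j], 0.0, 1.0) * (hi - lo)
                j += 1
            elif v.vtype == "binary":
                cols[v.name] = (vals[:, j] >= 0.5).astype(int)
                j += 1
            else:
                k = len(v.categories)
                idx = np.argmax(vals[:, j:j + k], axis=1)
                cols[v.name] = np.asarray(v.categories)[idx]
                j += k
        if self.include_outcome:
            lo, hi = self.time_range
            cols[self.schema.outcome_time_name] = lo + np.clip(vals[:, j], 0.0, 1.0) * (hi - lo)
            cols[self.schema.outcome_event_name] = np.argmax(vals[:, j + 1:j + 3], axis=1)
            j += 3
        order = list(self.schema.names)
        if self.include_outcome:
            order += [self.schema.outcome_time_name, self.schema.outcome_event_name]
        return Cohort(self.schema, pd.DataFrame(cols, columns=order))

    # ---- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "schema": self.schema.to_dict(),
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "include_outcome": self.include_outcome,
            "time_range": list(self.time_range) if self.time_range else None,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Encoder":
        d = json.loads(Path(path).read_text())
        return cls(CohortSchema.from_dict(d["schema"]),
                   {k: tuple(v) for k, v in d["ranges"].items()},
                   d["include_outcome"],
                   tuple(d["time_range"]) if d["time_range"] else None)


def onehot_block_slices(encoder: Encoder) -> list[slice]:
    """Slices of the categorical (one-hot) blocks in the encoded layout."""
    blocks: list[slice] = []
    start = None
    src = None
    for j, info in enumerate(encoder.layout + [ColumnInfo("_end", "_end", "continuous")]):
        if info.role == "onehot" and src == info.source:
            continue
        if start is not None:
            blocks.append(slice(start, j))
            start, src = None, None
        if info.role == "onehot":
            start, src = j, info.source
    return blocks


@dataclass(frozen=True)
class Split:
    """An 80:20 train/test partition of row indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train_indices": self.train_indices.tolist(),
            "test_indices": self.test_indices.tolist(),
            "seed": self.seed,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "Split":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["train_indices"]), np.asarray(d["test_indices"]), d["seed"])


def split_80_20(n: int, seed: int, train_frac: float = 0.8) -> Split:
    """Uniformly random split; train size = round(0.8 n), ties toward train."""
    if n < 5:
        raise ValueError("n must be >= 5")
    n_train = int(np.floor(train_frac * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    return Split(np.sort(perm[:n_train]), np.sort(perm[n_train:]), seed)
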