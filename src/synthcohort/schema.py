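"""Core data structures: variable specs, cohort schema, the generating survival model.

A :class:`Cohort` couples a mixed-type participant table with a right-censored
time-to-event outcome.  The :class:`TrueModel` records the Cox model that drives
the simulated outcomes; it is the ground truth every downstream evaluation is
scored against.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VTYPES = ("continuous", "categorical", "derived", "binary")


@dataclass(frozen=True)
class VariableSpec:
    """Description of one cohort variable in native units."""

    name: str
    vtype: str
    categories: tuple[str, ...] | None = None
    bounds: tuple[float, float] | None = None
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise ValueError(f"unknown vtype {self.vtype!r}")
        if self.vtype == "categorical":
            if self.categories is None or len(self.categories) < 2:
                raise ValueError(f"{self.name}: categorical needs >=2 categories")
        if self.vtype in ("continuous", "derived"):
            if self.bounds is None or not self.bounds[0] < self.bounds[1]:
                raise ValueError(f"{self.name}: continuous needs bounds min < max")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "vtype": self.vtype,
            "categories": list(self.categories) if self.categories else None,
            "bounds": list(self.bounds) if self.bounds else None,
            "generator_params": _jsonable(self.generator_params),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableSpec":
        return cls(
            name=d["name"],
            vtype=d["vtype"],
            categories=tuple(d["categories"]) if d.get("categories") else None,
            bounds=tuple(d["bounds"]) if d.get("bounds") else None,
            generator_params=dict(d.get("generator_params") or {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass(frozen=True)
class CohortSchema:
    """Ordered inventory of candidate predictors plus the outcome column names."""

    variables: tuple[VariableSpec, ...]
    outcome_time_name: str = "time"
    outcome_event_name: str = "event"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if self.outcome_time_name in names or self.outcome_event_name in names:
            raise ValueError("outcome columns must not appear among predictors")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "variables": [v.to_dict() for v in self.variables],
            "outcome_time_name": self.outcome_time_name,
            "outcome_event_name": self.outcome_event_name,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSchema":
        return cls(
            variables=tuple(VariableSpec.from_dict(v) for v in d["variables"]),
            outcome_time_name=d.get("outcome_time_name", "time"),
            outcome_event_name=d.get("outcome_event_name", "event"),
        )


@dataclass(frozen=True)
class TrueModel:
    """Generating proportional-hazards model with a Weibull baseline.

    ``beta`` maps *encoded* feature names (min-max-scaled continuous variables,
    ``var=Category`` one-hot indicators) to log hazard ratios.  Features absent
    from ``beta`` or mapped to 0 are the designated noise features.
    Times are in years.  Censoring is the minimum of an administrative cutoff
    and an exponential dropout time.
    """

    beta: Mapping[str, float]
    baseline_shape: float = 1.3
    baseline_scale: float = 80.0
    admin_censor_time: float = 11.0
    dropout_censor_rate: float = 0.02

    def nonzero_features(self) -> set[str]:
        return {k for k, v in self.beta.items() if v != 0.0}

    def to_dict(self) -> dict:
        return {
            "beta": dict(self.beta),
            "baseline_shape": self.baseline_shape,
            "baseline_scale": self.baseline_scale,
            "admin_censor_time": self.admin_censor_time,
            "dropout_censor_rate": self.dropout_censor_rate,
        }


@dataclass
class Cohort:
    """Participant table in native units, optionally with (time, event) outcome."""

    schema: CohortSchema
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [n for n in self.schema.names if n not in self.data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        if self.data.isna().any().any():
            raise ValueError("cohort contains missing values")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def has_outcome(self) -> bool:
        return (
            self.schema.outcome_time_name in self.data.columns
            and self.schema.outcome_event_name in self.data.columns
        )

    @property
    def time(self) -> np.ndarray:
        return self.data[self.schema.outcome_time_name].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data[self.schema.outcome_event_name].to_numpy(int)

    def covariates(self) -> pd.DataFrame:
        return self.data[self.schema.names]

    def subset(self, idx) -> "Cohort":
        return Cohort(self.schema, self.data.iloc[np.asarray(idx)].reset_index(drop=True))

    # ---- CSV + JSON side-car round trip -------------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        cols = list(self.data.columns)
        self.data.to_csv(path, index=False, float_format="%.12g", columns=cols)
        sidecar = path.with_suffix(path.suffix + ".schema.json")
        sidecar.write_text(json.dumps(self.schema.to_dict(), indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, schema: CohortSchema | None = None) -> "Cohort":
        path = Path(path)
        if schema is None:
            sidecar = path.with_suffix(path.suffix + ".schema.json")
            schema = CohortSchema.from_dict(json.loads(sidecar.read_text()))
        # keep_default_na: the literal category label "None" must survive
        df = pd.read_csv(path, keep_default_na=False, na_values=[""])
        for v in schema.variables:
            if v.vtype == "categorical":
                df[v.name] = df[v.name].astype(str)
        return cls(schema, df)

    def validate(self) -> None:
        """Check native-unit invariants (derived identities, category membership)."""
        for v in self.schema.variables:
            col = self.data[v.name]
            if v.vtype == "categorical":
                bad = set(col.unique()) - set(v.categories)
                if bad:
                    raise ValueError(f"{v.name}: unknown categories {bad}")
            elif v.vtype == "binary":
                if not col.isin([0, 1]).all():
                    raise ValueError(f"{v.name}: binary column must be 0/1")
        if self.has_outcome:
            if (self.time <= 0).any():
                raise ValueError("follow-up times must be positive")
            if not self.data[self.schema.outcome_event_name].isin([0, 1]).all():
                raise ValueError("event indicator must be 0/1")


def outcome_frame(cohort: Cohort) -> pd.DataFrame:
    """(time, event) as a two-column frame; raises if the cohort has no outcome."""
    if not cohort.has_outcome:
        raise ValueError("cohort has no outcome columns")
    s = cohort.schema
    return cohort.data[[s.outcome_time_name, s.outcome_event_name]].copy()
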