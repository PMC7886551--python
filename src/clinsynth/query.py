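"""Cohort identification and feature construction from longitudinal events.

Event tables are long-format records (patient_id, event_type, timestamp,
attr_name, attr_value) — one row per attribute of a clinical event.  A cohort
query is a conjunction of existential predicates over those events (a patient
is in the cohort when, for every filter, at least one of their events
satisfies it), optionally with an index-event rule anchoring time zero.
Feature construction slices each patient's timeline to a window relative to
index time and reduces attribute values with one of the enumerated
aggregators; composites combine already-built features arithmetically.
"""

from __future__ import annotations

import ast
import logging
import math
import operator
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .errors import ConfigError, SamplingError, SchemaError

__all__ = [
    "EventRecord",
    "Predicate",
    "CohortQuery",
    "FeatureDefinition",
    "AGGREGATORS",
    "load_events",
    "select_cohort",
    "nonsepsis_index_time",
    "window_slice",
    "aggregate_feature",
    "derive_composite",
    "one_hot_encode",
    "abnormal_flags",
    "sample_controls",
]

logger = logging.getLogger(__name__)

AGGREGATORS = ("max", "median", "variance", "count", "sum", "mean", "sd", "first", "last")

_OPS = {
    "==": operator.eq,
    "!=": operator.ne,
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}


@dataclass(frozen=True)
class EventRecord:
    """One clinical event on a patient timeline."""

    patient_id: str
    event_type: str
    timestamp: datetime
    attributes: dict

    def __post_init__(self):
        if not self.patient_id:
            raise ConfigError("patient_id must be non-empty")
        if not self.attributes:
            raise ConfigError("attributes must be non-empty")


@dataclass(frozen=True)
class Predicate:
    """Existential predicate: some event of ``event_type`` (any type when
    None) has ``attribute`` standing in relation ``op`` to ``value``.
    ``attribute`` may be the literal ``"timestamp"``."""

    attribute: str
    op: str
    value: object
    event_type: str | None = None

    def __post_init__(self):
        if self.op not in _OPS:
            raise ConfigError(f"unknown predicate op {self.op!r}")


@dataclass(frozen=True)
class CohortQuery:
    filters: tuple[Predicate, ...] = ()
    index_event_rule: Predicate | None = None

    def __post_init__(self):
        object.__setattr__(self, "filters", tuple(self.filters))


@dataclass(frozen=True)
class FeatureDefinition:
    """Declarative feature: aggregate one event attribute over a window
    (hours before index time, closed endpoints), or a composite formula over
    previously built features.  Variance uses the n-1 (sample) denominator."""

    name: str
    source_event: str | None = None
    source_attr: str | None = None
    window_hours: tuple[float, float] = (0.0, float("inf"))
    aggregator: str = "last"
    formula: str | None = None

    def __post_init__(self):
        lo, hi = self.window_hours
        if not lo <= hi:
            raise ConfigError(f"window start must be <= end for {self.name!r}")
        if self.aggregator not in AGGREGATORS:
            raise ConfigError(f"aggregator {self.aggregator!r} not in {AGGREGATORS}")


def load_events(path) -> pd.DataFrame:
    """Read a long-format event CSV (patient_id,event_type,timestamp,attr_name,attr_value)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "attr_value": str})
    required = {"patient_id", "event_type", "timestamp", "attr_name", "attr_value"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"event table lacks columns {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def _coerce(series: pd.Series, value) -> pd.Series:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return pd.to_numeric(series, errors="coerce")
    return series


def _predicate_mask(events: pd.DataFrame, pred: Predicate) -> tuple[pd.DataFrame, pd.Series]:
    sub = events
    if pred.event_type is not None:
        sub = sub[sub["event_type"] == pred.event_type]
    if pred.attribute == "timestamp":
        return sub, _OPS[pred.op](sub["timestamp"], pd.Timestamp(pred.value))
    known = set(events["attr_name"].unique())
    if pred.attribute not in known:
        raise SchemaError(f"predicate references unknown attribute {pred.attribute!r}")
    sub = sub[sub["attr_name"] == pred.attribute]
    lhs = _coerce(sub["attr_value"], pred.value)
    return sub, _OPS[pred.op](lhs, pred.value)


def select_cohort(events: pd.DataFrame, query: CohortQuery) -> set[str]:
    """Patients whose timeline satisfies every filter (set semantics,
    order-insensitive).  An empty filter list is vacuously true."""
    ids = set(events["patient_id"].unique())
    for pred in query.filters:
        sub, mask = _predicate_mask(events, pred)
        matched = set(sub.loc[mask, "patient_id"])
        ids &= matched
    return ids


def nonsepsis_index_time(admit: datetime, discharge: datetime) -> datetime:
    """Index time for a non-case stay: the admission/discharge midpoint for
    stays longer than 24 h, otherwise 12 h into the admission (stays of
    exactly 24 h take the 12-h rule)."""
    admit = pd.Timestamp(admit)
    discharge = pd.Timestamp(discharge)
    if discharge < admit:
        raise ConfigError("discharge precedes admission")
    stay = discharge - admit
    if stay > timedelta(hours=24):
        return admit + stay / 2
    return admit + timedelta(hours=12)


def window_slice(
    events: pd.DataFrame, index_time: datetime, window_hours: tuple[float, float]
) -> pd.DataFrame:
    """Events whose lead time (index_time - t) lies in [lower, upper] hours,
    closed on both ends."""
    lo, hi = window_hours
    index_time = pd.Timestamp(index_time)
    lead_h = (index_time - events["timestamp"]).dt.total_seconds() / 3600.0
    return events[(lead_h >= lo) & (lead_h <= hi)]


def aggregate_feature(values, aggregator: str) -> float:
    """Reduce a numeric sequence with one of the enumerated aggregators.

    ``count`` of an empty sequence is 0; every other aggregator on an empty
    sequence yields missing (NaN).  Variance and sd use the n-1 denominator.
    """
    if aggregator not in AGGREGATORS:
        raise ConfigError(f"aggregator {aggregator!r} not in {AGGREGATORS}")
    vals = list(values)
    if aggregator == "count":
        return float(len(vals))
    if len(vals) == 0:
        return float("nan")
    x = np.asarray(vals, dtype=float)
    if aggregator == "max":
        return float(x.max())
    if aggregator == "median":
        return float(np.median(x))
    if aggregator == "variance":
        return float(x.var(ddof=1)) if x.size > 1 else float("nan")
    if aggregator == "sd":
        return float(x.std(ddof=1)) if x.size > 1 else float("nan")
    if aggregator == "sum":
        return float(x.sum())
    if aggregator == "mean":
        return float(x.mean())
    if aggregator == "first":
        return float(x[0])
    return float(x[-1])  # last


_ALLOWED_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
    ast.Pow: operator.pow,
    ast.Mod: operator.mod,
}
_ALLOWED_UNARY = {ast.UAdd: operator.pos, ast.USub: operator.neg}


def _eval_arith(node: ast.AST, env: dict) -> float:
    """Recursive evaluator for the arithmetic-only formula grammar
    (names, numeric literals, + - * / ** %, unary sign, parentheses)."""
    if isinstance(node, ast.Expression):
        return _eval_arith(node.body, env)
    if isinstance(node, ast.Constant):
        if isinstance(node.value, (int, float)):
            return float(node.value)
        raise ConfigError(f"non-numeric literal {node.value!r} in formula")
    if isinstance(node, ast.Name):
        if node.id not in env:
            raise SchemaError(f"formula references an unknown feature {node.id!r}")
        return env[node.id]
    if isinstance(node, ast.BinOp) and type(node.op) in _ALLOWED_BINOPS:
        return _ALLOWED_BINOPS[type(node.op)](
            _eval_arith(node.left, env), _eval_arith(node.right, env)
        )
    if isinstance(node, ast.UnaryOp) and type(node.op) in _ALLOWED_UNARY:
        return _ALLOWED_UNARY[type(node.op)](_eval_arith(node.operand, env))
    raise ConfigError(f"disallowed construct {type(node).__name__} in formula")


def derive_composite(features: dict, formula: str) -> float:
    """Evaluate an arithmetic formula over named feature values.

    The formula grammar is names, numeric literals and + - * / ** % only
    (parsed, not executed as code).  A missing operand (None or NaN)
    propagates a missing result and logs one entry rather than raising —
    composites over sparse windows are expected to have gaps.
    """
    env: dict[str, float] = {}
    for name, val in features.items():
        if val is None or (isinstance(val, float) and math.isnan(val)):
            logger.info("composite operand %r missing; result set missing", name)
            return float("nan")
        env[name] = float(val)
    try:
        tree = ast.parse(formula, mode="eval")
    except SyntaxError as exc:
        raise ConfigError(f"malformed composite formula {formula!r}") from exc
    return float(_eval_arith(tree, env))


def one_hot_encode(column: pd.Series, levels=None) -> pd.DataFrame:
    """One-hot encode a categorical column.

    Cardinality-2 columns stay a single 0/1 indicator (of the
    lexicographically larger level); higher cardinality yields one binary
    column per level, so each row's level columns sum to 1.  A value outside
    the declared levels is a schema error.
    """
    name = column.name or "level"
    if levels is None:
        levels = sorted(column.dropna().unique().tolist())
    else:
        levels = list(levels)
        unseen = set(column.dropna().unique()) - set(levels)
        if unseen:
            raise SchemaError(f"unseen level(s) {sorted(map(str, unseen))} in {name!r}")
    if len(levels) < 2:
        raise ConfigError(f"one-hot encoding needs cardinality >= 2 ({name!r})")
    if len(levels) == 2:
        positive = levels[1]
        return pd.DataFrame({f"{name}_{positive}": (column == positive).astype(int)})
    return pd.DataFrame(
        {f"{name}_{lvl}": (column == lvl).astype(int) for lvl in levels}
    )


def abnormal_flags(
    value: float,
    low: float | None = None,
    high: float | None = None,
    critical: float | None = None,
) -> dict[str, int]:
    """Binary abnormal flags for a lab value against reference thresholds.

    Comparisons are inclusive: low flags value <= low, high flags value >=
    high, critical flags value >= critical; a critical value is also high
    (nested upper-tail flags).  Thresholds must satisfy low < high <= critical
    where present.
    """
    if low is not None and high is not None and not low < high:
        raise ConfigError(f"thresholds unordered: low={low} !< high={high}")
    if high is not None and critical is not None and not high <= critical:
        raise ConfigError(f"thresholds unordered: high={high} !<= critical={critical}")
    flags: dict[str, int] = {}
    if low is not None:
        flags["low"] = int(value <= low)
    if critical is not None:
        flags["critical"] = int(value >= critical)
    if high is not None:
        flags["high"] = int(value >= high or flags.get("critical", 0) == 1)
    return flags


def sample_controls(case_ids, pool_ids, ratio: int, seed: int) -> list:
    """Draw ratio-per-case controls uniformly without replacement.

    Returns exactly ``ratio * len(case_ids)`` distinct ids from the pool
    (cases excluded); an insufficient pool is a sampling error.  Identical
    seeds give identical selections.
    """
    cases = set(case_ids)
    pool = sorted(set(pool_ids) - cases)
    n_needed = ratio * len(cases)
    if len(pool) < n_needed:
        raise SamplingError(f"control pool has {len(pool)} candidates, need {n_needed}")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pool), size=n_needed, replace=False)
    return [pool[i] for i in picks]
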