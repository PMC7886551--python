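"""Population rates per 100,000 by year and zip, with census denominators.

Event tables are patient-level rows (year, zip, age, sex, ...); denominators
are census population counts per zip.  Rates are unadjusted counts per
100,000 persons, reported to one decimal.  Real-vs-synthetic rate
differences are signed synthetic − real with a Wald 95% confidence interval
using the Poisson variance rate²/count per arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

__all__ = [
    "RateDifference",
    "event_rate",
    "aggregate_rates",
    "rate_difference",
    "export_geo_csv",
]

GEO_COLUMNS = ("zip", "year", "count", "population", "rate", "mean_age", "pct_female")


@dataclass(frozen=True)
class RateDifference:
    """Synthetic − real rate difference per 100,000 with a 95% CI."""

    key: object
    difference: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not self.ci_low <= self.difference <= self.ci_high:
            raise ConfigError("confidence interval does not bracket the difference")


def event_rate(count: int, population: int) -> float:
    """Unadjusted rate per 100,000 persons (full precision; round on report)."""
    if population <= 0:
        raise ConfigError("population must be positive")
    if count < 0:
        raise ConfigError("count must be nonnegative")
    return count / population * 1e5


def aggregate_rates(
    events: pd.DataFrame,
    denominators: pd.DataFrame,
    keys: tuple[str, ...] = ("year", "zip"),
) -> pd.DataFrame:
    """Tally events per key combination and attach rates per 100,000.

    ``events`` needs the key columns plus optional ``age`` and ``sex``
    (female share is computed when present); ``denominators`` needs ``zip``
    and ``population``.  Every event zip must have a denominator.
    """
    missing_cols = [k for k in keys if k not in events.columns]
    if missing_cols:
        raise SchemaError(f"event table lacks key columns {missing_cols}")
    denom = denominators.set_index("zip")["population"]
    known = set(denom.index)
    event_zips = set(events["zip"].unique()) if "zip" in keys else known
    orphans = sorted(event_zips - known)
    if orphans:
        raise SchemaError(f"zip(s) without census denominator: {orphans}")

    grouped = events.groupby(list(keys))
    rows = []
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        rec["count"] = len(sub)
        if "zip" in keys:
            rec["population"] = int(denom.loc[rec["zip"]])
        else:
            rec["population"] = int(denom.sum())
        rec["rate"] = event_rate(rec["count"], rec["population"])
        rec["mean_age"] = float(sub["age"].mean()) if "age" in sub else float("nan")
        rec["pct_female"] = (
            float((sub["sex"] == "F").mean() * 100) if "sex" in sub else float("nan")
        )
        rows.append(rec)
    return pd.DataFrame(rows).sort_values(list(keys)).reset_index(drop=True)


def rate_difference(
    rate_real: float, count_real: int, rate_synth: float, count_synth: int, key=None
) -> RateDifference:
    """Synthetic − real difference (per 100,000) with a Poisson-variance
    Wald 95% CI: difference ± 1.96·sqrt(rate_r²/n_r + rate_s²/n_s).

    Differences and bounds are reported to one decimal.
    """
    if count_real <= 0 or count_synth <= 0:
        raise ConfigError("counts must be positive for a defined CI")
    diff = rate_synth - rate_real
    se = np.sqrt(rate_real**2 / count_real + rate_synth**2 / count_synth)
    return RateDifference(
        key=key,
        difference=round(diff, 1),
        ci_low=round(diff - 1.96 * se, 1),
        ci_high=round(diff + 1.96 * se, 1),
    )


def export_geo_csv(table: pd.DataFrame, path) -> None:
    """Write the choropleth-ready CSV (zip,year,count,population,rate,
    mean_age,pct_female) with 5-character zero-padded zips and 1-decimal
    rates."""
    if len(table) == 0:
        raise ConfigError("cannot export an empty rate table")
    out = table.copy()
    out["zip"] = out["zip"].astype(str).str.zfill(5)
    out["rate"] = out["rate"].round(1)
    out["mean_age"] = out["mean_age"].round(2)
    out["pct_female"] = out["pct_female"].round(2)
    out[list(GEO_COLUMNS)].to_csv(path, index=False)
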