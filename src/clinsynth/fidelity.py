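"""Summary analysis and report: distributional fidelity of a synthetic table.

Compares a real feature matrix against its synthetic derivative feature by
feature (five-figure quantile panels, Wilcoxon rank-sum and two-sample
Kolmogorov–Smirnov for numeric features, Pearson chi-squared on level counts
for categorical/binary ones) and across features (all pairwise correlations,
Pearson or Spearman, with absolute deltas).  Per-feature p-values are
reported unadjusted; the report flags how many fall below alpha instead of
applying a multiplicity correction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import FeatureSpec, infer_spec
from .errors import ConfigError, SchemaError

__all__ = [
    "TestResult",
    "FeatureComparison",
    "CorrelationComparison",
    "FidelityReport",
    "summary_quantiles",
    "wilcoxon_ranksum",
    "ks_two_sample",
    "chi_squared_independence",
    "spearman_rho",
    "correlation_delta",
    "build_report",
]

QUANTILE_PROBS = (0.0, 0.25, 0.5, 0.75, 0.9, 1.0)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


@dataclass
class FeatureComparison:
    """Per-feature comparison: quantile panels plus the applicable tests
    (wilcoxon + ks for numeric kinds, chi-squared for categorical/binary)."""

    feature: str
    kind: str
    real_quantiles: tuple | None
    synth_quantiles: tuple | None
    tests: dict[str, TestResult] = field(default_factory=dict)

    @property
    def min_pvalue(self) -> float:
        return min(t.pvalue for t in self.tests.values())


@dataclass(frozen=True)
class CorrelationComparison:
    pair: tuple[str, str]
    real: float
    synth: float
    delta: float
    method: str


@dataclass
class FidelityReport:
    comparisons: list[FeatureComparison]
    correlations: list[CorrelationComparison]
    alpha: float

    @property
    def n_below_alpha(self) -> int:
        return sum(
            1 for c in self.comparisons for t in c.tests.values() if t.pvalue < self.alpha
        )

    @property
    def max_correlation_delta(self) -> float:
        return max((c.delta for c in self.correlations), default=0.0)

    def min_pvalue(self, test: str | None = None) -> float:
        ps = [
            t.pvalue
            for c in self.comparisons
            for name, t in c.tests.items()
            if test is None or name == test
        ]
        if not ps:
            raise ConfigError("report holds no test of that name")
        return min(ps)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_below_alpha": self.n_below_alpha,
            "max_correlation_delta": self.max_correlation_delta,
            "features": [
                {
                    "feature": c.feature,
                    "kind": c.kind,
                    "real_quantiles": list(c.real_quantiles) if c.real_quantiles else None,
                    "synth_quantiles": list(c.synth_quantiles) if c.synth_quantiles else None,
                    "tests": {
                        name: {
                            "statistic": t.statistic,
                            "pvalue": t.pvalue,
                            "degenerate": t.degenerate,
                        }
                        for name, t in c.tests.items()
                    },
                }
                for c in self.comparisons
            ],
            "correlations": [
                {
                    "pair": list(c.pair),
                    "real": c.real,
                    "synth": c.synth,
                    "delta": c.delta,
                    "method": c.method,
                }
                for c in self.correlations
            ],
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def to_frame(self) -> pd.DataFrame:
        """Flat table, one row per (feature, test), for spreadsheet use."""
        rows = []
        for c in self.comparisons:
            for name, t in c.tests.items():
                rows.append(
                    {
                        "feature": c.feature,
                        "kind": c.kind,
                        "test": name,
                        "statistic": t.statistic,
                        "pvalue": t.pvalue,
                        "degenerate": t.degenerate,
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def summary_quantiles(values) -> tuple:
    """Five-figure panel (min, 25th, 50th, 75th, 90th, max), linear interpolation."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ConfigError("summary_quantiles needs non-empty input")
    return tuple(float(q) for q in np.quantile(x, QUANTILE_PROBS))


def wilcoxon_ranksum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration when the combined sample is small (< 20) and tie-free;
    otherwise the tie-corrected normal approximation without continuity
    correction.  When every value across both samples is identical the test
    is degenerate and reports p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=float(a.size * b.size / 2), pvalue=1.0, degenerate=True)
    n = a.size + b.size
    has_ties = np.unique(pooled).size < n
    method = "exact" if (n < 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov–Smirnov: D = sup |ECDF_a - ECDF_b|, asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return TestResult(statistic=float(res.statistic), pvalue=float(min(res.pvalue, 1.0)))


def chi_squared_independence(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    Returns (chi2, df, p).  A zero row or column margin is an error naming
    the offending margin.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ConfigError("table must be two-dimensional")
    if (t < 0).any():
        raise ConfigError("counts must be nonnegative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    zero_rows = np.flatnonzero(row_sums == 0)
    zero_cols = np.flatnonzero(col_sums == 0)
    if zero_rows.size or zero_cols.size:
        raise ConfigError(
            f"zero margin: rows {zero_rows.tolist()}, columns {zero_cols.tolist()}"
        )
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(dof), float(p)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks, tie-safe)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigError("inputs must share length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConfigError("spearman_rho undefined for a constant input vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _numeric_features(specs: Sequence[FeatureSpec]) -> list[str]:
    return [s.name for s in specs if s.kind in ("continuous", "count", "binary")]


def correlation_delta(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    method: str = "pearson",
    specs: Sequence[FeatureSpec] | None = None,
) -> list[CorrelationComparison]:
    """All p(p-1)/2 pairwise correlations in both tables with absolute deltas."""
    if method not in ("pearson", "spearman"):
        raise ConfigError(f"unknown correlation method {method!r}")
    if specs is None:
        names = [c for c in real.columns if c in synth.columns
                 and pd.api.types.is_numeric_dtype(real[c])]
    else:
        names = [n for n in _numeric_features(specs) if n in real.columns and n in synth.columns]
    if len(names) < 2:
        raise ConfigError("need at least 2 shared numeric features")
    r_corr = real[names].corr(method=method)
    s_corr = synth[names].corr(method=method)
    out = []
    for f1, f2 in itertools.combinations(names, 2):
        rv = float(r_corr.loc[f1, f2])
        sv = float(s_corr.loc[f1, f2])
        out.append(
            CorrelationComparison(
                pair=(f1, f2), real=rv, synth=sv, delta=abs(sv - rv), method=method
            )
        )
    return out


def build_report(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    specs: Sequence[FeatureSpec] | None = None,
    alpha: float = 0.05,
    correlation_method: str = "pearson",
) -> FidelityReport:
    """End-of-pipeline comparison of a real table and its synthetic derivative.

    Numeric features get a five-figure quantile panel plus Wilcoxon and K-S
    tests; categorical and binary features get a chi-squared test on level
    counts.  The feature sets must coincide; a mismatch is an error listing
    the difference.
    """
    if specs is None:
        specs = infer_spec(real)
    real_only = set(real.columns) - set(synth.columns)
    synth_only = set(synth.columns) - set(real.columns)
    if real_only or synth_only:
        raise SchemaError(
            f"feature-set mismatch: only in real {sorted(real_only)}, "
            f"only in synthetic {sorted(synth_only)}"
        )
    comparisons = []
    for s in specs:
        a = real[s.name]
        b = synth[s.name]
        if s.kind in ("continuous", "count"):
            av = a.to_numpy(dtype=float)
            bv = b.to_numpy(dtype=float)
            comp = FeatureComparison(
                feature=s.name,
                kind=s.kind,
                real_quantiles=summary_quantiles(av),
                synth_quantiles=summary_quantiles(bv),
                tests={
                    "wilcoxon": wilcoxon_ranksum(av, bv),
                    "ks": ks_two_sample(av, bv),
                },
            )
        else:
            levels = s.levels if s.levels is not None else sorted(
                set(a.unique()) | set(b.unique())
            )
            counts = np.array(
                [
                    [int((a == lvl).sum()) for lvl in levels],
                    [int((b == lvl).sum()) for lvl in levels],
                ],
                dtype=float,
            )
            keep = counts.sum(axis=0) > 0
            counts = counts[:, keep]
            if counts.shape[1] < 2:
                test = TestResult(statistic=0.0, pvalue=1.0, degenerate=True)
            else:
                chi2, _, p = chi_squared_independence(counts)
                test = TestResult(statistic=chi2, pvalue=p)
            comp = FeatureComparison(
                feature=s.name,
                kind=s.kind,
                real_quantiles=None,
                synth_quantiles=None,
                tests={"chi-squared": test},
            )
        comparisons.append(comp)
    if len(_numeric_features(specs)) >= 2:
        correlations = correlation_delta(real, synth, method=correlation_method, specs=specs)
    else:
        correlations = []
    return FidelityReport(comparisons=comparisons, correlations=correlations, alpha=alpha)
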