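"""Distribution tests, correlation panels and the fidelity report.

Each statistical routine is checked against an independent oracle: exact
rank-assignment enumeration for the Wilcoxon test, ECDF step enumeration for
Kolmogorov–Smirnov, the 2x2 closed form for chi-squared, and the d² formula
for Spearman.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinsynth.engine import FeatureSpec
from clinsynth.errors import ConfigError, SchemaError
from clinsynth.fidelity import (
    build_report,
    chi_squared_independence,
    correlation_delta,
    ks_two_sample,
    spearman_rho,
    summary_quantiles,
    wilcoxon_ranksum,
)


# ------------------------------------------------------------------ oracles

def exact_wilcoxon_p(a, b):
    """Enumerate every assignment of pooled ranks to group A; two-sided p
    as the probability of a rank-sum at least as extreme as observed."""
    pooled = sorted(a) + sorted(b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in a)
    n_a = len(a)
    mean_w = n_a * (len(pooled) + 1) / 2
    dev_obs = abs(w_obs - mean_w)
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n_a):
        total += 1
        if abs(sum(combo) - mean_w) >= dev_obs - 1e-12:
            count += 1
    return count / total


def ecdf_ks_d(a, b):
    """D = sup |ECDF_a - ECDF_b| evaluated at every pooled point."""
    a, b = np.sort(a), np.sort(b)
    points = np.concatenate([a, b])
    d = 0.0
    for p in points:
        fa = np.mean(a <= p)
        fb = np.mean(b <= p)
        d = max(d, abs(fa - fb))
    return d


def chi2_2x2_closed_form(t):
    (a, b), (c, d) = t
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def spearman_d2(x, y):
    """1 - 6 sum d^2 / (n(n^2-1)); valid without ties."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    return 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))


# -------------------------------------------------------------------- tests

class TestSummaryQuantiles:
    def test_exact_grid_points(self):
        q = summary_quantiles([0, 1, 2, 3, 4])
        assert q[0] == 0 and q[1] == 1 and q[2] == 2 and q[3] == 3 and q[5] == 4

    def test_q90_linear_interpolation(self):
        assert summary_quantiles(range(1, 11))[4] == pytest.approx(9.1)

    def test_single_value_all_equal(self):
        assert summary_quantiles([7.0]) == (7.0,) * 6

    def test_nondecreasing(self):
        q = summary_quantiles(np.random.default_rng(0).normal(size=100))
        assert list(q) == sorted(q)

    def test_empty_errors(self):
        with pytest.raises(ConfigError):
            summary_quantiles([])


class TestWilcoxon:
    def test_identical_samples_p_near_one(self):
        r = wilcoxon_ranksum(np.arange(30.0), np.arange(30.0))
        assert r.pvalue > 0.99

    def test_small_sample_exact_p_one_third(self):
        r = wilcoxon_ranksum([1.0, 2.0], [3.0, 4.0])
        assert r.pvalue == pytest.approx(1 / 3, abs=1e-9)

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1.0, 2.0], [3.0, 4.0]),
            ([1.0, 5.0, 9.0], [2.0, 3.0, 4.0]),
            ([10.0, 1.0], [2.0, 3.0, 7.0]),
            ([1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0]),
        ],
    )
    def test_exact_method_matches_enumeration(self, a, b):
        assert wilcoxon_ranksum(a, b).pvalue == pytest.approx(exact_wilcoxon_p(a, b), abs=1e-9)

    def test_large_shifted_samples_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 400)
        b = rng.normal(1, 1, 400)
        assert wilcoxon_ranksum(a, b).pvalue < 0.001

    def test_all_tied_degenerate(self):
        r = wilcoxon_ranksum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert r.pvalue == 1.0 and r.degenerate


class TestKS:
    def test_identical_samples_d_zero(self):
        assert ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).statistic == 0.0

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [4, 5, 6], 1.0),
            ([1, 3], [2, 4], 0.5),
        ],
    )
    def test_separated_and_interleaved(self, a, b, expected):
        r = ks_two_sample(a, b)
        assert r.statistic == pytest.approx(expected, abs=1e-9)
        assert r.statistic == pytest.approx(ecdf_ks_d(a, b), abs=1e-9)

    def test_matches_ecdf_enumeration_on_random_input(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=23), rng.normal(0.4, 1.2, size=17)
        assert ks_two_sample(a, b).statistic == pytest.approx(ecdf_ks_d(a, b), abs=1e-9)

    @settings(max_examples=30, derandomize=True)
    @given(
        a=st.lists(st.floats(-50, 50), min_size=3, max_size=15, unique=True),
        b=st.lists(st.floats(-50, 50), min_size=3, max_size=15, unique=True),
    )
    def test_invariant_under_monotone_transform(self, a, b):
        d_raw = ks_two_sample(a, b).statistic
        f = lambda v: [math.atan(x / 10) * 3 + x / 100 for x in v]  # strictly monotone
        assert ks_two_sample(f(a), f(b)).statistic == pytest.approx(d_raw, abs=1e-12)


class TestChiSquared:
    def test_2x2_matches_closed_form(self):
        t = [[10, 20], [20, 10]]
        chi2, df, p = chi_squared_independence(t)
        assert chi2 == pytest.approx(chi2_2x2_closed_form(t), abs=1e-9)
        assert chi2 == pytest.approx(20 / 3, abs=1e-9)
        assert df == 1

    def test_proportional_rows_give_zero(self):
        chi2, _, p = chi_squared_independence([[10, 20, 30], [20, 40, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_error_names_margin(self):
        with pytest.raises(ConfigError, match="zero margin"):
            chi_squared_independence([[5, 0], [0, 0]])


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_d_squared_formula(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 3, 5, 4]
        assert spearman_rho(x, y) == pytest.approx(0.8, abs=1e-9)
        assert spearman_rho(x, y) == pytest.approx(spearman_d2(x, y), abs=1e-9)

    def test_constant_vector_flagged(self):
        with pytest.raises(ConfigError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestCorrelationDelta:
    def _toys(self):
        rng = np.random.default_rng(2)
        real = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        synth = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        return real, synth

    def test_identical_matrices_zero_delta(self):
        real, _ = self._toys()
        comps = correlation_delta(real, real.copy())
        assert max(c.delta for c in comps) == 0.0

    def test_pair_count_and_brute_force(self):
        real, synth = self._toys()
        comps = correlation_delta(real, synth)
        assert len(comps) == 3  # p(p-1)/2 with p=3
        for c in comps:  # oracle: direct per-pair corrcoef
            f1, f2 = c.pair
            rv = np.corrcoef(real[f1], real[f2])[0, 1]
            sv = np.corrcoef(synth[f1], synth[f2])[0, 1]
            assert c.delta == pytest.approx(abs(sv - rv), abs=1e-12)

    def test_too_few_numeric_features(self):
        with pytest.raises(ConfigError):
            correlation_delta(pd.DataFrame({"a": [1.0, 2.0]}), pd.DataFrame({"a": [1.0, 2.0]}))


class TestBuildReport:
    def _tables(self, n=80):
        rng = np.random.default_rng(8)
        real = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "k": rng.integers(0, 5, size=n),
                "grp": rng.choice(["u", "v"], size=n),
            }
        )
        synth = real.copy()
        synth["x"] = rng.normal(size=n)
        spec = [
            FeatureSpec("x", "continuous"),
            FeatureSpec("k", "count"),
            FeatureSpec("grp", "categorical", levels=("u", "v")),
        ]
        return real, synth, spec

    def test_every_feature_appears_once(self):
        real, synth, spec = self._tables()
        report = build_report(real, synth, spec)
        assert [c.feature for c in report.comparisons] == ["x", "k", "grp"]
        assert set(report.comparisons[0].tests) == {"wilcoxon", "ks"}
        assert set(report.comparisons[2].tests) == {"chi-squared"}

    def test_missing_column_is_mismatch_error(self):
        real, synth, spec = self._tables()
        with pytest.raises(SchemaError, match="x"):
            build_report(real, synth.drop(columns=["x"]), spec)

    def test_json_tsv_roundtrip(self, tmp_path):
        real, synth, spec = self._tables()
        report = build_report(real, synth, spec)
        report.write_json(tmp_path / "r.json")
        report.write_tsv(tmp_path / "r.tsv")
        flat = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        assert len(flat) == 5  # 2 numeric features x 2 tests + 1 chi-squared
        assert ((flat["pvalue"] >= 0) & (flat["pvalue"] <= 1)).all()
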