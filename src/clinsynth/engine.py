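"""Synthetic-cohort generation by grouped kernel-density resampling.

The generator models a rectangular feature matrix as a mixture over "groups of
similar patients": rows are stratified on declared grouping features (joint
categorical levels crossed with quantile bins of continuous anchors), a
per-group model is fit (per-dimension Gaussian-kernel bandwidths for numeric
features, empirical level frequencies for categorical ones, and the observed
within-group envelope), and synthetic rows are drawn by resampling a donor row
per draw and jittering each numeric dimension with kernel noise.  Strata with
fewer than ``min_group_size`` members are censored outright, and jittered
values falling outside the group envelope are redrawn and finally clipped, so
outlying individuals cannot be reproduced and no synthetic row corresponds to
a real one.

The public surface is the :class:`KDESynthesizer` estimator (sklearn
conventions: parameters in ``__init__``, fitted state in trailing-underscore
attributes, ``fit``/``sample``) plus the thin functional wrappers
:func:`partition_similar`, :func:`fit_group_model`, :func:`sample_group`,
:func:`censor_envelope` and :func:`synthesize`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigError, EmptyModelError, SchemaError

__all__ = [
    "FeatureSpec",
    "SynthesisConfig",
    "GroupModel",
    "SyntheticCohort",
    "infer_spec",
    "load_spec",
    "spec_to_json",
    "silverman_bandwidth",
    "partition_similar",
    "fit_group_model",
    "sample_group",
    "censor_envelope",
    "synthesize",
    "KDESynthesizer",
]

_KINDS = ("continuous", "count", "binary", "categorical")
_NUMERIC_KINDS = ("continuous", "count")


@dataclass(frozen=True)
class FeatureSpec:
    """Declared semantics of one feature-matrix column.

    Parameters
    ----------
    name : column name.
    kind : one of ``continuous``, ``count``, ``binary``, ``categorical``.
    bounds : optional ``(lower, upper)`` hard support for numeric kinds.
    levels : level list for categorical kinds (cardinality >= 2).
    grouping : whether this feature defines "similar patient" strata.
    """

    name: str
    kind: str
    bounds: tuple[float, float] | None = None
    levels: tuple | None = None
    grouping: bool = False

    def __post_init__(self):
        if not self.name:
            raise ConfigError("feature name must be non-empty")
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.bounds is not None:
            lo, hi = self.bounds
            if not lo <= hi:
                raise ConfigError(f"bounds for {self.name!r} are not ordered: {self.bounds}")
            object.__setattr__(self, "bounds", (float(lo), float(hi)))
        if self.kind == "categorical":
            if self.levels is None or len(self.levels) < 2:
                raise ConfigError(f"categorical {self.name!r} needs >= 2 declared levels")
            object.__setattr__(self, "levels", tuple(self.levels))
        elif self.levels is not None:
            raise ConfigError(f"levels only apply to categorical features ({self.name!r})")


@dataclass(frozen=True)
class SynthesisConfig:
    """Knobs of the synthesis engine.

    min_group_size is the privacy threshold k: strata with fewer members are
    censored in full.  n_quantile_bins controls how continuous grouping
    anchors are discretised into strata.  Envelope policy is
    reject-then-clip: out-of-envelope kernel noise is redrawn up to
    ``max_rejects`` times, then clipped.
    """

    min_group_size: int = 10
    n_quantile_bins: int = 4
    bandwidth_rule: str = "silverman"
    envelope_policy: str = "reject-then-clip"
    max_rejects: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.min_group_size < 2:
            raise ConfigError("min_group_size must be >= 2")
        if self.n_quantile_bins < 1:
            raise ConfigError("n_quantile_bins must be >= 1")
        if self.max_rejects < 1:
            raise ConfigError("max_rejects must be >= 1")
        if self.bandwidth_rule != "silverman":
            raise ConfigError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if self.envelope_policy != "reject-then-clip":
            raise ConfigError(f"unknown envelope policy {self.envelope_policy!r}")


@dataclass
class GroupModel:
    """Per-stratum synthesis model: donors, bandwidths, frequencies, envelope.

    ``scales`` records, per numeric dimension, whether kernel noise acts on
    the linear or the log scale; strictly positive dimensions with strong
    right skew are jittered multiplicatively (noise added to log values) so
    that a bandwidth sized for the bulk does not swamp the lower tail.  The
    bandwidth is computed by the configured rule within group on whichever
    scale the dimension uses.

    ``atoms`` records, per numeric dimension, the values shared by at least
    ``min_group_size`` group members.  Such point masses (zero-inflation,
    heaped scores) are non-identifying for the same reason censored strata
    are — at least k patients carry them — so sampling emits them exactly
    rather than smoothing the atom away; only sparsely held values receive
    kernel noise.
    """

    group_key: tuple
    member_count: int
    bandwidths: dict[str, float]
    scales: dict[str, str]
    atoms: dict[str, frozenset]
    frequencies: dict[str, dict]
    envelope: dict[str, tuple[float, float]]
    donors: pd.DataFrame = field(repr=False)


@dataclass
class SyntheticCohort:
    """A synthetic derivative plus its generation audit trail.

    Rows carry no identifier linking them to source rows; ``censored_count``
    is the number of real rows withheld because their stratum fell below the
    privacy threshold, and ``clip_count`` the number of sampled values clipped
    to the group envelope after exhausting rejection redraws.
    """

    matrix: pd.DataFrame
    censored_count: int
    clip_count: int
    config: SynthesisConfig
    seed: int

    def sidecar(self) -> dict:
        return {
            "censored_count": int(self.censored_count),
            "clip_count": int(self.clip_count),
            "seed": int(self.seed),
            "n_rows": int(len(self.matrix)),
            "config": asdict(self.config),
        }

    def write(self, csv_path, sidecar_path=None) -> None:
        self.matrix.to_csv(csv_path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.sidecar(), fh, indent=2)
                fh.write("\n")


def infer_spec(matrix: pd.DataFrame) -> list[FeatureSpec]:
    """Infer a plain spec from dtypes: floats are continuous, integers count,
    everything else categorical; no grouping features (a single stratum)."""
    specs = []
    for name in matrix.columns:
        col = matrix[name]
        if pd.api.types.is_float_dtype(col):
            specs.append(FeatureSpec(name, "continuous"))
        elif pd.api.types.is_integer_dtype(col):
            uniq = set(col.dropna().unique().tolist())
            if uniq <= {0, 1}:
                specs.append(FeatureSpec(name, "binary"))
            else:
                specs.append(FeatureSpec(name, "count"))
        else:
            levels = tuple(sorted(col.dropna().unique().tolist()))
            specs.append(FeatureSpec(name, "categorical", levels=levels))
    return specs


def load_spec(path) -> list[FeatureSpec]:
    """Read a feature-spec JSON document (a list of column declarations)."""
    with open(path) as fh:
        doc = json.load(fh)
    specs = []
    for entry in doc:
        specs.append(
            FeatureSpec(
                name=entry["name"],
                kind=entry["kind"],
                bounds=tuple(entry["bounds"]) if entry.get("bounds") else None,
                levels=tuple(entry["levels"]) if entry.get("levels") else None,
                grouping=bool(entry.get("grouping", False)),
            )
        )
    return specs


def spec_to_json(specs: Sequence[FeatureSpec], path) -> None:
    doc = []
    for s in specs:
        doc.append(
            {
                "name": s.name,
                "kind": s.kind,
                "bounds": list(s.bounds) if s.bounds else None,
                "levels": list(s.levels) if s.levels else None,
                "grouping": s.grouping,
            }
        )
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def _check_matrix(matrix: pd.DataFrame, specs: Sequence[FeatureSpec]) -> None:
    missing = [s.name for s in specs if s.name not in matrix.columns]
    if missing:
        raise SchemaError(f"matrix lacks declared columns: {missing}")
    na_cols = [s.name for s in specs if matrix[s.name].isna().any()]
    if na_cols:
        raise ConfigError(f"missing values in columns {na_cols}; drop or impute first")


def silverman_bandwidth(values: np.ndarray) -> float:
    """Per-dimension Gaussian-kernel bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    Zero-dispersion input yields bandwidth 0, so constant columns are
    reproduced exactly rather than erroring.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        return 0.0
    sd = x.std(ddof=1)
    q75, q25 = np.quantile(x, [0.75, 0.25])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread <= 0:
        return 0.0
    return 0.9 * spread * n ** (-0.2)


_LOG_SKEW_THRESHOLD = 1.0


def _jitter_scale(x: np.ndarray) -> str:
    """Pick the kernel-noise scale for one numeric dimension.

    Strictly positive samples with sample skewness above 1 are jittered on
    the log scale (multiplicative noise), which keeps a bandwidth sized for
    the bulk from swamping the lower tail of heavy-tailed clinical
    quantities (alarm counts, length of stay); everything else uses the
    linear scale.
    """
    if x.size < 2 or x.min() <= 0:
        return "linear"
    sd = x.std(ddof=1)
    if sd == 0:
        return "linear"
    skew = float(np.mean(((x - x.mean()) / sd) ** 3))
    return "log" if skew > _LOG_SKEW_THRESHOLD else "linear"


def partition_similar(
    matrix: pd.DataFrame, specs: Sequence[FeatureSpec], config: SynthesisConfig
) -> tuple[dict[tuple, np.ndarray], np.ndarray]:
    """Stratify rows on the grouping features and censor small strata.

    Strata are the joint levels of grouping categoricals crossed with
    quantile bins of grouping continuous features.  Returns ``(groups,
    censored)`` where ``groups`` maps stratum key -> positional row indices
    (each stratum >= k members) and ``censored`` holds the positional indices
    of rows in strata below k.  With no grouping features every row lands in
    a single stratum.
    """
    if len(matrix) == 0:
        raise ConfigError("cannot partition an empty matrix")
    _check_matrix(matrix, specs)

    n = len(matrix)
    keys: list[np.ndarray] = []
    for s in specs:
        if not s.grouping:
            continue
        col = matrix[s.name].to_numpy()
        if s.kind in ("categorical", "binary"):
            keys.append(col.astype(object))
        else:
            binned = pd.qcut(
                matrix[s.name], q=config.n_quantile_bins, labels=False, duplicates="drop"
            ).to_numpy()
            keys.append(binned.astype(object))
    if not keys:
        key_tuples = [("all",)] * n
    else:
        key_tuples = list(zip(*keys))

    by_key: dict[tuple, list[int]] = {}
    for i, k in enumerate(key_tuples):
        by_key.setdefault(tuple(k), []).append(i)

    groups, censored = {}, []
    for k in sorted(by_key, key=repr):
        idx = np.asarray(by_key[k], dtype=int)
        if idx.size >= config.min_group_size:
            groups[k] = idx
        else:
            censored.extend(idx.tolist())
    if not groups:
        sizes = {k: len(v) for k, v in by_key.items()}
        raise EmptyModelError(
            f"every stratum falls below min_group_size={config.min_group_size}: {sizes}"
        )
    return groups, np.asarray(sorted(censored), dtype=int)


def fit_group_model(
    rows: pd.DataFrame,
    specs: Sequence[FeatureSpec],
    config: SynthesisConfig,
    group_key: tuple = ("all",),
) -> GroupModel:
    """Fit the per-group model: bandwidths, categorical frequencies, envelope."""
    if len(rows) < config.min_group_size:
        raise ConfigError(
            f"group {group_key} has {len(rows)} rows < min_group_size={config.min_group_size}"
        )
    bandwidths: dict[str, float] = {}
    scales: dict[str, str] = {}
    atoms: dict[str, frozenset] = {}
    frequencies: dict[str, dict] = {}
    envelope: dict[str, tuple[float, float]] = {}
    for s in specs:
        col = rows[s.name]
        if s.kind in _NUMERIC_KINDS:
            x = col.to_numpy(dtype=float)
            scales[s.name] = _jitter_scale(x)
            if scales[s.name] == "log":
                bandwidths[s.name] = silverman_bandwidth(np.log(x))
            else:
                bandwidths[s.name] = silverman_bandwidth(x)
            vals, counts = np.unique(x, return_counts=True)
            atoms[s.name] = frozenset(vals[counts >= config.min_group_size])
            envelope[s.name] = (float(x.min()), float(x.max()))
        else:
            counts = col.value_counts(normalize=True)
            frequencies[s.name] = {lvl: float(p) for lvl, p in counts.items()}
    donors = rows.reset_index(drop=True)
    return GroupModel(
        group_key=tuple(group_key),
        member_count=len(rows),
        bandwidths=bandwidths,
        scales=scales,
        atoms=atoms,
        frequencies=frequencies,
        envelope=envelope,
        donors=donors,
    )


def censor_envelope(
    proposals: np.ndarray,
    envelope: tuple[float, float],
    redraw,
    max_rejects: int = 10,
) -> tuple[np.ndarray, int]:
    """Reject-then-clip envelope censoring for one numeric dimension.

    ``proposals`` are candidate values; entries outside ``envelope`` are
    replaced by fresh proposals from ``redraw(flagged_indices)`` up to
    ``max_rejects`` rounds, after which survivors are clipped.  Returns the
    censored values and the number of clip events.
    """
    lo, hi = envelope
    vals = np.asarray(proposals, dtype=float).copy()
    for _ in range(max_rejects):
        bad = np.flatnonzero((vals < lo) | (vals > hi))
        if bad.size == 0:
            break
        vals[bad] = redraw(bad)
    bad = (vals < lo) | (vals > hi)
    clip_count = int(bad.sum())
    if clip_count:
        vals = np.clip(vals, lo, hi)
    return vals, clip_count


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def sample_group(
    model: GroupModel,
    n: int,
    rng: np.random.Generator,
    specs: Sequence[FeatureSpec],
    config: SynthesisConfig,
) -> tuple[pd.DataFrame, int]:
    """Draw ``n`` synthetic rows from one group model.

    Each draw picks a donor row uniformly (with replacement) so cross-feature
    dependence is inherited, then jitters every numeric dimension
    independently with Gaussian kernel noise and envelope censoring;
    categorical and binary dimensions are drawn from the group's empirical
    level frequencies.  Count kinds round half away from zero and respect
    declared bounds.  Returns the rows and the clip-event count.
    """
    if n < 0:
        raise ConfigError("n must be >= 0")
    cols: dict[str, np.ndarray] = {}
    clip_total = 0
    if n == 0:
        empty = {s.name: np.array([]) for s in specs}
        return pd.DataFrame(empty), 0
    donor_idx = rng.integers(0, model.member_count, size=n)
    for s in specs:
        if s.kind in _NUMERIC_KINDS:
            base = model.donors[s.name].to_numpy(dtype=float)[donor_idx]
            h = model.bandwidths[s.name]
            log_scale = model.scales.get(s.name) == "log"
            atom_set = model.atoms.get(s.name, frozenset())
            vals = base.copy()
            jitter = (
                ~np.isin(base, np.asarray(sorted(atom_set)))
                if atom_set
                else np.ones(n, dtype=bool)
            )
            if h > 0 and jitter.any():
                jbase = base[jitter]
                m = jbase.size
                if log_scale:
                    log_base = np.log(jbase)
                    proposals = np.exp(log_base + rng.normal(0.0, h, size=m))
                    redraw = lambda idx, b=log_base, h=h: np.exp(
                        b[idx] + rng.normal(0.0, h, size=idx.size)
                    )
                else:
                    proposals = jbase + rng.normal(0.0, h, size=m)
                    redraw = lambda idx, b=jbase, h=h: b[idx] + rng.normal(
                        0.0, h, size=idx.size
                    )
                jvals, clipped = censor_envelope(
                    proposals, model.envelope[s.name], redraw, config.max_rejects
                )
                vals[jitter] = jvals
                clip_total += clipped
            if s.kind == "count":
                vals = _round_half_away(vals)
                lo, hi = model.envelope[s.name]
                vals = np.clip(vals, np.ceil(lo), np.floor(hi))
            if s.bounds is not None:
                vals = np.clip(vals, s.bounds[0], s.bounds[1])
            cols[s.name] = vals
        else:
            # The donor's level: marginally identical to drawing from the
            # group's empirical frequency table (no smoothing noise is ever
            # added to categorical dims), but inheriting the donor keeps the
            # joint structure with the numeric dims intact.
            cols[s.name] = model.donors[s.name].to_numpy()[donor_idx]
    out = pd.DataFrame(cols)
    for s in specs:  # preserve integer dtype for counts/binaries
        if s.kind in ("count", "binary"):
            out[s.name] = out[s.name].astype(np.int64)
    return out[[s.name for s in specs]], clip_total


class KDESynthesizer(BaseEstimator):
    """Grouped kernel-density synthesizer for rectangular clinical tables.

    Parameters
    ----------
    spec : list of :class:`FeatureSpec` or None
        Column declarations; inferred from dtypes when None.
    min_group_size : int, default 10
        Privacy threshold k; strata with fewer members are censored in full.
    n_quantile_bins : int, default 4
        Quantile bins used to discretise continuous grouping anchors.
    bandwidth_rule : str, default "silverman"
        Per-dimension kernel bandwidth rule, computed within group.
    max_rejects : int, default 10
        Envelope rejection redraws before clipping.
    random_state : int or None
        Seed for the single generator stream driving all sampling.

    Attributes (after ``fit``)
    --------------------------
    spec_ : resolved feature spec.
    groups_ : dict mapping stratum key -> positional row indices.
    models_ : dict mapping stratum key -> :class:`GroupModel`.
    censored_ids_ : positional indices of rows censored for privacy.
    n_features_in_ : number of declared features.
    """

    def __init__(
        self,
        spec=None,
        min_group_size: int = 10,
        n_quantile_bins: int = 4,
        bandwidth_rule: str = "silverman",
        max_rejects: int = 10,
        random_state: int | None = None,
    ):
        self.spec = spec
        self.min_group_size = min_group_size
        self.n_quantile_bins = n_quantile_bins
        self.bandwidth_rule = bandwidth_rule
        self.max_rejects = max_rejects
        self.random_state = random_state

    def _config(self) -> SynthesisConfig:
        return SynthesisConfig(
            min_group_size=self.min_group_size,
            n_quantile_bins=self.n_quantile_bins,
            bandwidth_rule=self.bandwidth_rule,
            max_rejects=self.max_rejects,
            seed=0 if self.random_state is None else int(self.random_state),
        )

    def fit(self, X: pd.DataFrame, y=None) -> "KDESynthesizer":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [f"x{i}" for i in range(X.shape[1])]
        if len(X) == 0:
            raise ConfigError("cannot fit on an empty matrix")
        specs = self.spec if self.spec is not None else infer_spec(X)
        config = self._config()
        _check_matrix(X, specs)
        groups, censored = partition_similar(X, specs, config)
        models = {}
        for key, idx in groups.items():
            models[key] = fit_group_model(X.iloc[idx], specs, config, group_key=key)
        self.spec_ = list(specs)
        self.groups_ = groups
        self.models_ = models
        self.censored_ids_ = censored
        self.n_input_rows_ = len(X)
        self.n_features_in_ = len(specs)
        return self

    def sample(self, n_samples: int | None = None, random_state: int | None = None) -> SyntheticCohort:
        """Generate a synthetic cohort.

        With ``n_samples`` None the requested draw count equals the original
        row count and per-group draws equal group sizes, so censored strata
        shrink the output (the emitted count need not match the input count).
        """
        if not hasattr(self, "models_"):
            raise ConfigError("synthesizer is not fitted")
        config = self._config()
        seed = config.seed if random_state is None else int(random_state)
        rng = np.random.default_rng(seed)
        total_requested = self.n_input_rows_ if n_samples is None else int(n_samples)
        noncensored = self.n_input_rows_ - len(self.censored_ids_)
        frames, clip_total = [], 0
        for key in sorted(self.models_, key=repr):
            model = self.models_[key]
            n_g = int(round(total_requested * model.member_count / self.n_input_rows_))
            rows, clipped = sample_group(model, n_g, rng, self.spec_, config)
            clip_total += clipped
            if len(rows):
                frames.append(rows)
        matrix = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=[s.name for s in self.spec_]
        )
        if len(matrix):
            matrix = matrix.iloc[rng.permutation(len(matrix))].reset_index(drop=True)
        return SyntheticCohort(
            matrix=matrix,
            censored_count=int(len(self.censored_ids_)),
            clip_count=clip_total,
            config=config,
            seed=seed,
        )


def synthesize(
    matrix: pd.DataFrame,
    specs: Sequence[FeatureSpec] | None = None,
    config: SynthesisConfig | None = None,
) -> SyntheticCohort:
    """One-shot synthesis: fit the grouped KDE model and draw a derivative
    whose requested size equals the input row count."""
    config = config or SynthesisConfig()
    synth = KDESynthesizer(
        spec=list(specs) if specs is not None else None,
        min_group_size=config.min_group_size,
        n_quantile_bins=config.n_quantile_bins,
        bandwidth_rule=config.bandwidth_rule,
        max_rejects=config.max_rejects,
        random_state=config.seed,
    )
    synth.fit(matrix)
    return synth.sample()
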