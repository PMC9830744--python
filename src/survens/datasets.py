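"""Survival dataset container, I/O, normalization, CV splits and resampling.

All dataset-level conventions live here: feature kinds (continuous,
boolean, categorical), the categorical level-code encoding, train-fitted
z-score normalization of continuous columns, event-stratified repeated
k-fold splits and bootstrap resampling with hierarchical seeding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

CONTINUOUS = "continuous"
BOOLEAN = "boolean"
CATEGORICAL = "categorical"
KINDS = (CONTINUOUS, BOOLEAN, CATEGORICAL)


class SchemaError(ValueError):
    """Input table does not match the declared schema."""


class ParseError(ValueError):
    """A cell value could not be interpreted under its declared kind."""


class ImputationRequiredError(ValueError):
    """Missing values present but no imputation hook configured."""


@dataclass(frozen=True)
class FeatureMeta:
    """Per-feature metadata.

    ``levels`` is the ordered list of category labels for categorical
    features (values are stored as integer codes into this list).
    Probe features record the original feature they were permuted from.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    is_probe: bool = False
    probe_source: str | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if (self.kind == CATEGORICAL) != bool(self.levels):
            raise ValueError(
                f"feature {self.name!r}: levels must be given iff kind is categorical"
            )
        if self.is_probe and not self.probe_source:
            raise ValueError(f"probe {self.name!r} must name its source feature")


@dataclass
class SurvivalDataset:
    """m samples x p features plus a right-censored outcome.

    ``features`` stores continuous values as floats, booleans as {0,1}
    and categoricals as non-negative level codes.  ``time`` is positive
    (units carried verbatim from input); ``event`` is 1 when the event
    was observed and 0 when censored.
    """

    features: pd.DataFrame
    meta: list[FeatureMeta]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        names = [f.name for f in self.meta]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names")
        if list(self.features.columns) != names:
            raise SchemaError("feature columns do not match metadata order")
        if self.features.shape[0] != self.time.shape[0] or self.time.shape != self.event.shape:
            raise SchemaError("features, time and event have inconsistent lengths")
        if self.features.shape[0] < 2:
            raise SchemaError("need at least 2 samples")
        if np.any(self.time <= 0):
            bad = int(np.argmax(self.time <= 0))
            raise SchemaError(f"non-positive time at row {bad}")
        if not np.isin(self.event, (0, 1)).all():
            bad = int(np.argmax(~np.isin(self.event, (0, 1))))
            raise SchemaError(f"event must be 0/1; offending row {bad}")
        for fm in self.meta:
            col = self.features[fm.name]
            vals = col.dropna().to_numpy()
            if fm.kind == BOOLEAN and not np.isin(vals, (0, 1)).all():
                raise SchemaError(f"boolean feature {fm.name!r} has values outside {{0,1}}")
            if fm.kind == CATEGORICAL:
                if vals.size and (vals.min() < 0 or vals.max() >= len(fm.levels)):
                    raise SchemaError(f"categorical feature {fm.name!r} has out-of-range codes")

    @property
    def m(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def censoring_rate(self) -> float:
        return 1.0 - float(self.event.mean())

    def subset_rows(self, rows) -> "SurvivalDataset":
        rows = np.asarray(rows)
        return SurvivalDataset(
            self.features.iloc[rows].reset_index(drop=True),
            list(self.meta),
            self.time[rows],
            self.event[rows],
        )

    def select_features(self, names: list[str]) -> "SurvivalDataset":
        name_set = set(names)
        meta = [f for f in self.meta if f.name in name_set]
        keep = [f.name for f in meta]
        return SurvivalDataset(self.features[keep].copy(), meta, self.time.copy(), self.event.copy())

    def has_missing(self) -> bool:
        return bool(self.features.isna().to_numpy().any())


@dataclass(frozen=True)
class FoldSplit:
    repeat_index: int  # 1-based
    fold_index: int  # 1..k
    train_rows: np.ndarray
    test_rows: np.ndarray


@dataclass
class NormalizationParams:
    """Train-fitted mean/sd per continuous feature (sample sd, ddof=1).

    Features whose training sd is zero are flagged degenerate and map
    to all-zeros.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    degenerate: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# seeding

def child_seed_sequence(master_seed: int, *path: int) -> np.random.SeedSequence:
    """Deterministic sub-seed derivation: master seed plus an integer
    path such as (repeat, fold, bootstrap), so any single bootstrap is
    reproducible in isolation."""
    return np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(x) for x in path))


def child_rng(master_seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(child_seed_sequence(master_seed, *path))


# ---------------------------------------------------------------------------
# reading / writing

def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        text = fh.read()
    if str(config).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_dataset(path, config) -> SurvivalDataset:
    """Read a CSV/TSV table into a validated :class:`SurvivalDataset`.

    ``config`` (dict or YAML/JSON path) must provide ``time_col``,
    ``event_col`` and ``feature_kinds`` (name -> kind).  ``na_policy``
    may be ``"error"`` (default) or ``"keep"`` (defer to an imputation
    hook downstream).
    """
    cfg = _load_config(config)
    for key in ("time_col", "event_col", "feature_kinds"):
        if key not in cfg:
            raise SchemaError(f"config missing required key {key!r}")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep)
    time_col, event_col = cfg["time_col"], cfg["event_col"]
    kinds: dict[str, str] = cfg["feature_kinds"]
    missing = [c for c in (time_col, event_col, *kinds) if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")

    time = pd.to_numeric(raw[time_col], errors="coerce").to_numpy(dtype=float)
    if np.isnan(time).any():
        row = int(np.argmax(np.isnan(time)))
        raise ParseError(f"unparseable time at row {row}, column {time_col!r}")
    event_raw = pd.to_numeric(raw[event_col], errors="coerce").to_numpy()
    if np.isnan(event_raw).any():
        row = int(np.argmax(np.isnan(event_raw)))
        raise ParseError(f"unparseable event at row {row}, column {event_col!r}")
    if not np.isin(event_raw, (0, 1)).all():
        row = int(np.argmax(~np.isin(event_raw, (0, 1))))
        raise ParseError(
            f"event must be 0/1; offending cell row {row}, column {event_col!r} "
            f"(value {event_raw[row]!r})"
        )
    keep = time > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} rows with non-positive time")

    cols = {}
    meta: list[FeatureMeta] = []
    for name, kind in kinds.items():
        col = raw[name]
        if kind == CONTINUOUS:
            vals = pd.to_numeric(col, errors="coerce")
            bad = vals.isna() & col.notna()
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise ParseError(f"unparseable value at row {row}, column {name!r}")
            cols[name] = vals.astype(float)
            meta.append(FeatureMeta(name, CONTINUOUS))
        elif kind == BOOLEAN:
            mapped = col.map(
                {True: 1, False: 0, "True": 1, "False": 0, "TRUE": 1, "FALSE": 0,
                 1: 1, 0: 0, "1": 1, "0": 0, 1.0: 1, 0.0: 0}
            )
            bad = mapped.isna() & col.notna()
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise ParseError(f"unparseable boolean at row {row}, column {name!r}")
            cols[name] = mapped.astype(float)
            meta.append(FeatureMeta(name, BOOLEAN))
        elif kind == CATEGORICAL:
            # levels in first-appearance order of the non-missing labels
            labels = [str(v) for v in col.dropna()]
            levels = tuple(dict.fromkeys(labels))
            if not levels:
                raise ParseError(f"categorical column {name!r} has no observed levels")
            lut = {lv: i for i, lv in enumerate(levels)}
            cols[name] = col.map(lambda v: np.nan if pd.isna(v) else lut[str(v)]).astype(float)
            meta.append(FeatureMeta(name, CATEGORICAL, levels=levels))
        else:
            raise SchemaError(f"unknown kind {kind!r} for feature {name!r}")

    feats = pd.DataFrame(cols)[ [f.name for f in meta] ].loc[keep].reset_index(drop=True)
    ds = SurvivalDataset(feats, meta, time[keep], event_raw[keep].astype(int))
    na_policy = cfg.get("na_policy", "error")
    if ds.has_missing() and na_policy == "error":
        raise ImputationRequiredError(
            "dataset contains missing values and no imputation hook is configured "
            "(set na_policy: keep and pass an imputer to the harness)"
        )
    return ds


def write_dataset(ds: SurvivalDataset, path, time_col="time", event_col="event") -> None:
    """Canonical CSV writer (categoricals written as their labels)."""
    out = {}
    for fm in ds.meta:
        col = ds.features[fm.name]
        if fm.kind == CATEGORICAL:
            out[fm.name] = col.map(
                lambda c: "" if pd.isna(c) else fm.levels[int(c)]
            )
        elif fm.kind == BOOLEAN:
            out[fm.name] = col.astype("Int64")
        else:
            out[fm.name] = col
    out[time_col] = ds.time
    out[event_col] = ds.event
    pd.DataFrame(out).to_csv(path, index=False)


def dataset_config(ds: SurvivalDataset, time_col="time", event_col="event") -> dict:
    """Run-config dict matching :func:`write_dataset` output."""
    return {
        "time_col": time_col,
        "event_col": event_col,
        "feature_kinds": {f.name: f.kind for f in ds.meta},
        "na_policy": "keep" if ds.has_missing() else "error",
    }


# ---------------------------------------------------------------------------
# normalization

def fit_normalization(ds: SurvivalDataset, rows=None) -> NormalizationParams:
    """Estimate per-continuous-feature mean/sd on the given training rows."""
    if rows is None:
        rows = np.arange(ds.m)
    rows = np.asarray(rows)
    if rows.size == 0:
        raise ValueError("rows must be non-empty")
    mean, sd, degenerate = {}, {}, set()
    for fm in ds.meta:
        if fm.kind != CONTINUOUS:
            continue
        vals = ds.features[fm.name].iloc[rows].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        mu = float(vals.mean()) if vals.size else 0.0
        s = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        if s == 0.0:
            degenerate.add(fm.name)
        mean[fm.name], sd[fm.name] = mu, s
    return NormalizationParams(mean, sd, degenerate)


def apply_normalization(ds: SurvivalDataset, params: NormalizationParams) -> SurvivalDataset:
    """z-score continuous columns with train-fitted parameters.

    Boolean and categorical columns are unchanged; degenerate
    (zero-sd) features map to all-zeros.
    """
    feats = ds.features.copy()
    for fm in ds.meta:
        if fm.kind != CONTINUOUS or fm.name not in params.mean:
            continue
        if fm.name in params.degenerate:
            feats[fm.name] = np.where(feats[fm.name].isna(), np.nan, 0.0)
        else:
            feats[fm.name] = (feats[fm.name] - params.mean[fm.name]) / params.sd[fm.name]
    return SurvivalDataset(feats, list(ds.meta), ds.time.copy(), ds.event.copy())


# ---------------------------------------------------------------------------
# imputation hook (default: median/mode fit on training rows)

class MedianModeImputer:
    """Median (continuous) / mode (boolean, categorical) imputation.

    Parameters are fit on training rows only and applied to any rows,
    so no information leaks from test folds.  Stands in for heavier
    schemes such as chained-equation multiple imputation, which can be
    plugged in through the same fit/transform contract.
    """

    def __init__(self):
        self.fill_: dict[str, float] = {}

    def fit(self, ds: SurvivalDataset, rows=None) -> "MedianModeImputer":
        if rows is None:
            rows = np.arange(ds.m)
        for fm in ds.meta:
            col = ds.features[fm.name].iloc[np.asarray(rows)].dropna()
            if col.empty:
                self.fill_[fm.name] = 0.0
            elif fm.kind == CONTINUOUS:
                self.fill_[fm.name] = float(col.median())
            else:
                self.fill_[fm.name] = float(col.mode().iloc[0])
        return self

    def transform(self, ds: SurvivalDataset) -> SurvivalDataset:
        feats = ds.features.fillna(self.fill_)
        return SurvivalDataset(feats, list(ds.meta), ds.time.copy(), ds.event.copy())


# ---------------------------------------------------------------------------
# CV splits and bootstrap

def make_cv_splits(m: int, events, k: int = 5, repeats: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Event-stratified repeated k-fold splits, reproducible from seed.

    Stratification keeps the censored/event mix similar across folds,
    which matters under heavy censoring where unstratified folds may
    contain no events at all.  Falls back to unstratified folds (with a
    warning) when there are fewer events than folds.
    """
    events = np.asarray(events, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if m < k:
        raise ValueError("m must be >= k")
    stratified = events.sum() >= k
    if not stratified:
        warnings.warn("fewer events than folds: falling back to unstratified CV")
    splits: list[FoldSplit] = []
    for rep in range(1, repeats + 1):
        rng = child_rng(seed, rep)
        assignment = np.empty(m, dtype=int)
        if stratified:
            for grp in (np.flatnonzero(events == 1), np.flatnonzero(events == 0)):
                perm = grp[rng.permutation(grp.size)]
                assignment[perm] = np.arange(perm.size) % k
        else:
            perm = rng.permutation(m)
            assignment[perm] = np.arange(m) % k
        for fold in range(1, k + 1):
            test = np.flatnonzero(assignment == fold - 1)
            train = np.flatnonzero(assignment != fold - 1)
            splits.append(FoldSplit(rep, fold, train, test))
    return splits


def bootstrap_sample(ds: SurvivalDataset, seed) -> tuple[SurvivalDataset, np.ndarray]:
    """Draw m rows with replacement; returns the drawn indices for audit.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    """
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ds.m, size=ds.m)
    return ds.subset_rows(idx), idx


# ---------------------------------------------------------------------------
# design matrix (dummy expansion for model fitting)

def design_matrix(ds: SurvivalDataset) -> tuple[np.ndarray, list[str]]:
    """Expand categoricals to one-hot dummies; returns (X, column->feature map).

    Importance scores computed on dummy columns are mapped back to the
    original feature as the maximum absolute score over its dummies.
    """
    blocks, owners = [], []
    for fm in ds.meta:
        col = ds.features[fm.name].to_numpy(dtype=float)
        if fm.kind == CATEGORICAL:
            for code in range(len(fm.levels)):
                blocks.append((col == code).astype(float))
                owners.append(fm.name)
        else:
            blocks.append(col)
            owners.append(fm.name)
    X = np.column_stack(blocks) if blocks else np.empty((ds.m, 0))
    return X, owners


def collapse_scores(column_scores: np.ndarray, owners: list[str]) -> dict[str, float]:
    """Max |score| over each original feature's design columns."""
    out: dict[str, float] = {}
    for s, name in zip(column_scores, owners):
        v = abs(float(s))
        if name not in out or v > out[name]:
            out[name] = v
    return out
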