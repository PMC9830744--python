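"""The experiment harness: per-fold ensemble -> aggregate -> threshold ->
ridge-Cox fit -> concordance, plus stability over the final subsets,
combined Euclidean scoring and consensus features across models.

Every run is reproducible end to end from one master seed: CV folds,
bootstrap draws and probe permutations each derive their own sub-seed
from (repeat, fold, bootstrap) paths.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .aggregation import (
    AggregatedRanking,
    EnsembleRun,
    RankedList,
    mean_rank,
    mean_weight,
    medrank,
    ranked_list_from_result,
    rra_select,
    threshold_algorithm,
)
from .datasets import (
    MedianModeImputer,
    SurvivalDataset,
    apply_normalization,
    bootstrap_sample,
    child_seed_sequence,
    design_matrix,
    fit_normalization,
    make_cv_splits,
)
from .metrics import concordance_index, euclidean_score
from .probes import inject_probes, is_probe_name, strip_probes
from .selectors import apply_selector, get_selector
from .stability import SubsetSystem, cw_rel
from .thresholding import best_probe_threshold, fixed_fraction, kde_threshold, quantile75

SELF_THRESHOLDING = ("RRA", "TA", "MA")


@dataclass
class ExperimentResult:
    """Everything one configuration produced over the repeated CV."""

    selector_id: str
    aggregator_id: str | None
    threshold_id: str | None
    seed: int
    folds: int
    repeats: int
    B: int | None
    probes: bool
    subsets: list[list[str]]  # folds*repeats final feature subsets (sorted)
    c_indexes: list[float]
    mean_c_index: float
    stability: float  # CW_rel over the final subsets
    score: float  # Euclidean distance from origin
    k_values: list[int | None] = field(default_factory=list)
    warnings_log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selector": self.selector_id,
            "aggregator": self.aggregator_id,
            "threshold": self.threshold_id,
            "seed": self.seed,
            "folds": self.folds,
            "repeats": self.repeats,
            "bootstraps": self.B,
            "probes": self.probes,
            "subsets": self.subsets,
            "c_indexes": self.c_indexes,
            "mean_c_index": self.mean_c_index,
            "stability": self.stability,
            "euclidean_score": self.score,
            "k_values": self.k_values,
            "warnings": self.warnings_log,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, **kw)


# ---------------------------------------------------------------------------
# ridge survival model

def fit_ridge_cox(train: SurvivalDataset, selected, alpha: float = 1.0):
    """L2-penalized Cox fit on the selected (normalized) features.

    Returns a callable mapping a dataset to per-sample risk scores
    (higher = higher hazard).  The fixed default penalty keeps fits
    deterministic; pass a different ``alpha`` to change shrinkage.
    """
    selected = sorted(selected)
    if not selected:
        raise ValueError("selected feature set must be non-empty")
    if train.event.sum() < 1:
        raise ValueError("need at least one event to fit the ridge model")
    sub = train.select_features(selected)
    X, _ = design_matrix(sub)
    y = Surv.from_arrays(train.event.astype(bool), train.time)
    model = CoxPHSurvivalAnalysis(alpha=alpha)
    try:
        model.fit(X, y)
    except Exception as exc:
        raise RuntimeError(
            f"ridge Cox fit failed on {len(selected)} features "
            f"(m={train.m}, events={int(train.event.sum())}): {exc}"
        ) from exc

    def score(ds: SurvivalDataset) -> np.ndarray:
        Xs, _ = design_matrix(ds.select_features(selected))
        return model.predict(Xs)

    return score


# ---------------------------------------------------------------------------
# identifiers

def parse_aggregator(aggregator_id: str):
    """Return (kind, param) for an aggregator identifier.

    Accepted: ``MR``, ``MW``, ``TA``, ``MA``, ``RRA:<p>`` and the
    presets ``RRA05`` ... ``RRA25``.
    """
    a = aggregator_id.upper()
    if a in ("MR", "MW", "TA", "MA"):
        return a, None
    if a.startswith("RRA"):
        if ":" in a:
            p = float(a.split(":", 1)[1])
        elif len(a) > 3:
            p = int(a[3:]) / 100.0
        else:
            raise ValueError("RRA needs a p-value, e.g. RRA:0.15 or RRA15")
        if not (0 < p < 1):
            raise ValueError("RRA p-value must be in (0, 1)")
        return "RRA", p
    raise ValueError(f"unknown aggregator {aggregator_id!r}")


def parse_threshold(threshold_id: str | None):
    if threshold_id in (None, "none", "None"):
        return None, None
    t = threshold_id.lower()
    if t.startswith("fixed:"):
        return "fixed", float(t.split(":", 1)[1])
    if t in ("q75", "kde", "probe"):
        return t, None
    raise ValueError(f"unknown threshold {threshold_id!r}")


def _apply_score_threshold(kind, param, agg: AggregatedRanking, run: EnsembleRun | None):
    if kind == "fixed":
        return fixed_fraction(agg, param)
    if kind == "q75":
        return quantile75(agg)
    if kind == "kde":
        return kde_threshold(agg)
    if kind == "probe":
        sparse_no_probe = False
        if run is not None and all(rl.partial for rl in run.lists):
            listed = set().union(*(rl.ordering for rl in run.lists)) if run.lists else set()
            if not any(is_probe_name(n) for n in listed):
                # no probe was ever selected by the sparse selector: keep
                # everything the ensemble selected
                agg.selected = listed
                return best_probe_threshold(agg, sparse_no_probe=True)
        return best_probe_threshold(agg)
    raise ValueError(f"unknown threshold kind {kind!r}")


# ---------------------------------------------------------------------------
# experiment loops

def _prepare_fold(ds, split, imputer_factory):
    """Imputation and normalization, both fit on training rows only."""
    imputer = imputer_factory().fit(ds, split.train_rows)
    full = imputer.transform(ds)
    train = full.subset_rows(split.train_rows)
    test = full.subset_rows(split.test_rows)
    params = fit_normalization(train)
    return apply_normalization(train, params), apply_normalization(test, params)


def _finalize(subsets, cindexes, ds, res_kw) -> ExperimentResult:
    universe = set(ds.feature_names)
    system = SubsetSystem(subsets, universe)
    stability = cw_rel(system)
    mean_c = float(np.mean(cindexes))
    return ExperimentResult(
        subsets=[sorted(s) for s in subsets],
        c_indexes=[float(c) for c in cindexes],
        mean_c_index=mean_c,
        stability=float(stability),
        score=euclidean_score(stability, mean_c),
        **res_kw,
    )


def run_experiment(
    ds: SurvivalDataset,
    selector_id: str,
    aggregator_id: str,
    threshold_id: str | None = None,
    B: int = 50,
    folds: int = 5,
    repeats: int = 5,
    probes: bool = True,
    seed: int = 0,
    ridge_alpha: float = 1.0,
    imputer_factory=MedianModeImputer,
    selector_params: dict | None = None,
) -> ExperimentResult:
    """Full ensemble pipeline over repeated cross-validation.

    For every training fold: normalize and impute (train-fitted), draw B
    bootstrap samples, re-permute probes per bootstrap, fit the base
    selector on each, aggregate the B ranked lists, threshold, strip
    probes, fit the ridge Cox model on the final subset and score
    concordance on the held-out fold.  Stability (CW_rel) is computed
    over all folds*repeats final subsets.
    """
    get_selector(selector_id)  # fail fast on unknown ids
    agg_kind, agg_param = parse_aggregator(aggregator_id)
    thr_kind, thr_param = parse_threshold(threshold_id)
    if agg_kind in SELF_THRESHOLDING and thr_kind is not None:
        raise ValueError(
            f"{agg_kind} performs its own thresholding; no separate threshold applies"
        )
    if agg_kind not in SELF_THRESHOLDING and thr_kind is None:
        raise ValueError(f"{agg_kind} needs an explicit threshold")
    if thr_kind == "probe" and not probes:
        raise ValueError("the probe threshold requires probe injection (probes=True)")
    selector_params = selector_params or {}

    splits = make_cv_splits(ds.m, ds.event, k=folds, repeats=repeats, seed=seed)
    log: list[str] = []
    subsets, cindexes, k_values = [], [], []
    for split in splits:
        train, test = _prepare_fold(ds, split, imputer_factory)
        universe = list(train.feature_names)
        if probes:
            probe_template = inject_probes(train, child_seed_sequence(seed, split.repeat_index, split.fold_index, 0, 1))
            universe = list(probe_template.feature_names)
        lists = []
        for b in range(1, B + 1):
            boot, _ = bootstrap_sample(
                train, child_seed_sequence(seed, split.repeat_index, split.fold_index, b, 0)
            )
            if probes:
                boot = inject_probes(
                    boot, child_seed_sequence(seed, split.repeat_index, split.fold_index, b, 1)
                )
            sub_seed = int(
                child_seed_sequence(seed, split.repeat_index, split.fold_index, b, 2)
                .generate_state(1)[0] % (2**31)
            )
            try:
                result = apply_selector(selector_id, boot, seed=sub_seed, **selector_params)
                lists.append(ranked_list_from_result(result))
            except Exception as exc:
                log.append(
                    f"rep{split.repeat_index} fold{split.fold_index} boot{b}: "
                    f"selector failed ({exc}); empty list"
                )
                lists.append(RankedList([], {}, partial=True))
        run = EnsembleRun(lists, tuple(universe), selector_id)

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if agg_kind == "MR":
                agg = mean_rank(run)
            elif agg_kind == "MW":
                agg = mean_weight(run)
            elif agg_kind == "RRA":
                agg = rra_select(run, agg_param)
            elif agg_kind == "TA":
                agg = threshold_algorithm(run)
            else:  # MA
                agg = medrank(run)
            if agg_kind in SELF_THRESHOLDING:
                selected = set(agg.selected)
            else:
                selected = _apply_score_threshold(thr_kind, thr_param, agg, run)
        for w in caught:
            log.append(f"rep{split.repeat_index} fold{split.fold_index}: {w.message}")

        selected = strip_probes(selected)
        if not selected:
            log.append(
                f"rep{split.repeat_index} fold{split.fold_index}: empty selection; "
                "falling back to all features"
            )
            selected = set(train.feature_names)
        k_values.append(agg.k)
        subsets.append(selected)
        scorer = fit_ridge_cox(train, selected, alpha=ridge_alpha)
        cindexes.append(concordance_index(test.time, test.event, scorer(test)))

    return _finalize(
        subsets,
        cindexes,
        ds,
        dict(
            selector_id=selector_id,
            aggregator_id=aggregator_id,
            threshold_id=threshold_id,
            seed=seed,
            folds=folds,
            repeats=repeats,
            B=B,
            probes=probes,
            k_values=k_values,
            warnings_log=log,
        ),
    )


def run_individual(
    ds: SurvivalDataset,
    selector_id: str,
    threshold_id: str | None = None,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    ridge_alpha: float = 1.0,
    imputer_factory=MedianModeImputer,
    selector_params: dict | None = None,
) -> ExperimentResult:
    """Non-ensemble baseline: one selector fit per training fold.

    Sparse selectors provide their own subset, so they reject an
    explicit threshold; filters require one (fixed fraction, 75%
    quantile or KDE).
    """
    get_selector(selector_id)
    thr_kind, thr_param = parse_threshold(threshold_id)
    if thr_kind == "probe":
        raise ValueError("the probe threshold applies to ensembles, not individual runs")
    selector_params = selector_params or {}

    splits = make_cv_splits(ds.m, ds.event, k=folds, repeats=repeats, seed=seed)
    log: list[str] = []
    subsets, cindexes = [], []
    for split in splits:
        train, test = _prepare_fold(ds, split, imputer_factory)
        sub_seed = int(
            child_seed_sequence(seed, split.repeat_index, split.fold_index, 0, 2)
            .generate_state(1)[0] % (2**31)
        )
        result = apply_selector(selector_id, train, seed=sub_seed, **selector_params)
        if result.is_sparse:
            if thr_kind is not None:
                raise ValueError(
                    f"sparse selector {selector_id!r} selects its own subset; "
                    "no threshold applies"
                )
            selected = set(result.selected)
        else:
            if thr_kind is None:
                raise ValueError(
                    f"filter selector {selector_id!r} requires a threshold, "
                    "even in individual form"
                )
            agg = AggregatedRanking(
                sorted(result.scores, key=lambda n: (-result.scores[n], n)),
                dict(result.scores),
                "IND",
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                selected = _apply_score_threshold(thr_kind, thr_param, agg, None)
            for w in caught:
                log.append(f"rep{split.repeat_index} fold{split.fold_index}: {w.message}")
        if not selected:
            log.append(
                f"rep{split.repeat_index} fold{split.fold_index}: empty selection; "
                "falling back to all features"
            )
            selected = set(train.feature_names)
        subsets.append(selected)
        scorer = fit_ridge_cox(train, selected, alpha=ridge_alpha)
        cindexes.append(concordance_index(test.time, test.event, scorer(test)))

    return _finalize(
        subsets,
        cindexes,
        ds,
        dict(
            selector_id=selector_id,
            aggregator_id=None,
            threshold_id=threshold_id,
            seed=seed,
            folds=folds,
            repeats=repeats,
            B=None,
            probes=False,
            k_values=[],
            warnings_log=log,
        ),
    )


# ---------------------------------------------------------------------------
# consensus across models

def consensus_features(
    results: list[ExperimentResult], top_n: int = 10, min_fraction: float = 0.5
) -> list[tuple[str, float]]:
    """Features agreed on by the best-scoring models.

    Models are ranked by their Euclidean (stability, accuracy) score; a
    feature counts as selected by a model when it appears in more than
    half of that model's fold subsets.  Returned are the features
    selected by at least ``min_fraction`` of the top ``top_n`` models,
    with their selection fractions, most frequent first.
    """
    if not results:
        raise ValueError("no results given")
    if len(results) < top_n:
        warnings.warn(f"only {len(results)} results available; using all")
        top_n = len(results)
    ranked = sorted(results, key=lambda r: -r.score)[:top_n]
    counts: dict[str, int] = {}
    for res in ranked:
        half = len(res.subsets) / 2
        freq: dict[str, int] = {}
        for s in res.subsets:
            for f in s:
                freq[f] = freq.get(f, 0) + 1
        for f, c in freq.items():
            if c > half:
                counts[f] = counts.get(f, 0) + 1
    out = [
        (f, c / top_n) for f, c in counts.items() if c / top_n >= min_fraction
    ]
    return sorted(out, key=lambda t: (-t[1], t[0]))
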