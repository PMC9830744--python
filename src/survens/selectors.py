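"""Base feature selectors behind a uniform contract.

Two families are distinguished throughout the ensemble machinery:

* *filters* return a nonnegative importance score for every feature and
  no subset (thresholding is a separate, later step);
* *sparse* selectors return both scores (absolute coefficients — which
  are comparable because continuous features are normalized first) and
  the subset of features with nonzero coefficients.

Concrete selectors: a univariate Cox concordance filter (``unicox``),
L1/elastic-net penalized Cox (``lasso``/``enet``), componentwise
gradient-boosted Cox (``glmboost``) and a random survival forest with
permutation importance (``rsf``).  Anything that produces a valid
:class:`SelectorResult` can be registered alongside them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.inspection import permutation_importance
from sksurv.ensemble import (
    ComponentwiseGradientBoostingSurvivalAnalysis,
    RandomSurvivalForest,
)
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .datasets import SurvivalDataset, collapse_scores, design_matrix
from .metrics import concordance_index


class SelectorContractError(ValueError):
    """A selector produced output violating the SelectorResult contract."""


class SelectorUnavailableError(KeyError):
    """Requested selector id is not registered."""


@dataclass
class SelectorResult:
    """Importance scores (all features) plus, for sparse selectors, the
    selected subset."""

    scores: dict[str, float]
    selected: set[str] | None
    is_sparse: bool
    selector_id: str

    def validate(self) -> "SelectorResult":
        for name, s in self.scores.items():
            if not np.isfinite(s) or s < 0:
                raise SelectorContractError(
                    f"{self.selector_id}: score for {name!r} must be finite and >= 0"
                )
        if self.is_sparse:
            if self.selected is None:
                raise SelectorContractError(f"{self.selector_id}: sparse selector must report a subset")
            extra = self.selected - set(self.scores)
            if extra:
                raise SelectorContractError(f"{self.selector_id}: selected names outside scores: {extra}")
            for name in self.selected:
                if self.scores[name] <= 0:
                    raise SelectorContractError(
                        f"{self.selector_id}: selected feature {name!r} has non-positive score"
                    )
        elif self.selected is not None:
            raise SelectorContractError(f"{self.selector_id}: filters must not report a subset")
        return self


def _surv_y(ds: SurvivalDataset):
    return Surv.from_arrays(ds.event.astype(bool), ds.time)


# ---------------------------------------------------------------------------
# penalty policies for penalized Cox

class PenaltyPolicy:
    """Chooses the regularization strength for penalized Cox fits."""

    def coefficients(self, X, y, l1_ratio: float) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class PathFractionPenalty(PenaltyPolicy):
    """Deterministic alternative: fit a short regularization path and use
    the coefficients at the alpha closest to ``ratio * alpha_max``.

    One path fit per call, no internal resampling, bit-reproducible.
    """

    ratio: float = 0.25
    n_alphas: int = 8
    alpha_min_ratio: float = 0.05

    def coefficients(self, X, y, l1_ratio):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio, n_alphas=self.n_alphas, alpha_min_ratio=self.alpha_min_ratio
        )
        model.fit(X, y)
        target = self.ratio * model.alphas_[0]
        j = int(np.argmin(np.abs(np.asarray(model.alphas_) - target)))
        return model.coef_[:, j]


@dataclass
class FixedPenalty(PenaltyPolicy):
    """Fit at one user-supplied alpha (deterministic tests, strong-penalty
    boundary cases)."""

    alpha: float

    def coefficients(self, X, y, l1_ratio):
        model = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=[self.alpha])
        model.fit(X, y)
        return model.coef_[:, 0]


def _cox_partial_loglik(X, time, event, coef) -> float:
    """Breslow partial log-likelihood of fixed coefficients on a sample."""
    eta = X @ coef
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o, t_o, e_o = eta[order], time[order], event[order]
    log_risk = np.logaddexp.accumulate(eta_o)  # log sum over risk set {t_j >= t_i}
    # tied times share the full risk set: propagate the last index of each tie block
    for i in range(len(t_o) - 2, -1, -1):
        if t_o[i] == t_o[i + 1]:
            log_risk[i] = log_risk[i + 1]
    mask = e_o == 1
    return float(np.sum(eta_o[mask] - log_risk[mask]))


@dataclass
class CVPenalty(PenaltyPolicy):
    """Pick alpha by internal k-fold cross-validated partial likelihood.

    The default policy: mirrors the usual penalized-Cox practice of
    choosing the regularization strength that maximizes the held-out Cox
    partial log-likelihood over a short alpha path.  The internal splits
    are seeded, so any single fit is reproducible.
    """

    n_splits: int = 3
    n_alphas: int = 10
    alpha_min_ratio: float = 0.05
    seed: int = 0

    def coefficients(self, X, y, l1_ratio):
        from sklearn.model_selection import KFold

        path = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio, n_alphas=self.n_alphas, alpha_min_ratio=self.alpha_min_ratio
        )
        path.fit(X, y)
        alphas = list(path.alphas_)
        time = y[y.dtype.names[1]]
        event = y[y.dtype.names[0]].astype(int)
        scores = np.zeros(len(alphas))
        kf = KFold(n_splits=self.n_splits, shuffle=True, random_state=self.seed)
        for tr, te in kf.split(X):
            if event[tr].sum() == 0 or event[te].sum() == 0:
                continue
            m = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas)
            m.fit(X[tr], y[tr])
            for j in range(m.coef_.shape[1]):
                scores[j] += _cox_partial_loglik(X[te], time[te], event[te], m.coef_[:, j])
        best = int(np.argmax(scores))
        return path.coef_[:, best]


# ---------------------------------------------------------------------------
# selectors

def univariate_cox_filter(ds: SurvivalDataset) -> SelectorResult:
    """Score every feature by the concordance of its own Cox model.

    Each (dummy-expanded) column gets a single-covariate proportional
    hazards fit; the score is Harrell's C of that model's risk score on
    the same data, so scores live on [0.5, ~1] for informative features
    and near 0.5 for noise.  Non-convergent fits score 0.5 (uninformative).
    """
    if ds.event.sum() < 1:
        raise ValueError("need at least one observed event")
    X, owners = design_matrix(ds)
    y = _surv_y(ds)
    col_scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        xj = X[:, j : j + 1]
        if np.all(xj == xj[0]):  # constant column carries no ordering
            col_scores[j] = 0.5
            continue
        try:
            model = CoxPHSurvivalAnalysis(alpha=0.01)
            model.fit(xj, y)
            risk = model.predict(xj)
            col_scores[j] = concordance_index(ds.time, ds.event, risk)
        except Exception as exc:  # non-convergence -> uninformative
            warnings.warn(f"univariate Cox fit failed for column {j}: {exc}")
            col_scores[j] = 0.5
    scores = collapse_scores(col_scores, owners)
    return SelectorResult(scores, None, False, "unicox").validate()


def sparse_cox_selector(
    ds: SurvivalDataset,
    penalty: str = "lasso",
    mixing: float = 0.5,
    policy: PenaltyPolicy | None = None,
) -> SelectorResult:
    """L1 or elastic-net penalized Cox; selected = nonzero coefficients.

    Continuous features must be normalized beforehand so the absolute
    coefficients are comparable importance scores.
    """
    if ds.event.sum() < 1:
        raise ValueError("all-censored data: penalized Cox cannot be fit")
    if penalty not in ("lasso", "elastic_net"):
        raise ValueError(f"unknown penalty {penalty!r}")
    l1_ratio = 1.0 if penalty == "lasso" else float(mixing)
    if not (0 < l1_ratio <= 1):
        raise ValueError("mixing must be in (0, 1]")
    policy = policy or CVPenalty()
    X, owners = design_matrix(ds)
    coef = policy.coefficients(X, _surv_y(ds), l1_ratio)
    scores = collapse_scores(np.abs(coef), owners)
    selected = {name for name, s in scores.items() if s > 0}
    sid = "lasso" if penalty == "lasso" else "enet"
    return SelectorResult(scores, selected, True, sid).validate()


def boosted_cox_selector(
    ds: SurvivalDataset,
    flavour: str = "gradient",
    n_estimators: int = 100,
    learning_rate: float = 0.1,
    seed: int = 0,
) -> SelectorResult:
    """Componentwise gradient-boosted Cox: coefficient magnitudes as
    scores, nonzero coefficients as the selected subset.

    Only the gradient flavour has a reference adapter here; a
    likelihood-based boosting implementation can be registered through
    the same contract.
    """
    if flavour != "gradient":
        raise SelectorUnavailableError(
            f"no adapter for boosting flavour {flavour!r}; available: gradient"
        )
    X, owners = design_matrix(ds)
    if n_estimators == 0:
        scores = dict.fromkeys(dict.fromkeys(owners), 0.0)
        return SelectorResult(scores, set(), True, "glmboost").validate()
    model = ComponentwiseGradientBoostingSurvivalAnalysis(
        n_estimators=n_estimators, learning_rate=learning_rate, random_state=seed
    )
    model.fit(X, _surv_y(ds))
    coef = np.asarray(model.coef_)[1:]  # drop intercept
    scores = collapse_scores(np.abs(coef), owners)
    selected = {name for name, s in scores.items() if s > 0}
    return SelectorResult(scores, selected, True, "glmboost").validate()


def survival_forest_selector(
    ds: SurvivalDataset,
    n_estimators: int = 50,
    n_repeats: int = 5,
    max_depth: int | None = 6,
    seed: int = 0,
) -> SelectorResult:
    """Random survival forest filter scored by permutation importance.

    Negative importances are clipped to zero so the scores can enter
    weight-based aggregation.
    """
    X, owners = design_matrix(ds)
    y = _surv_y(ds)
    model = RandomSurvivalForest(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    imp = permutation_importance(model, X, y, n_repeats=n_repeats, random_state=seed)
    scores = collapse_scores(np.clip(imp.importances_mean, 0, None), owners)
    return SelectorResult(scores, None, False, "rsf").validate()


# ---------------------------------------------------------------------------
# registry

_REGISTRY: dict[str, callable] = {}


def register_selector(selector_id: str, fn) -> None:
    """Register a callable (ds, seed, **params) -> SelectorResult."""
    _REGISTRY[selector_id] = fn


def available_selectors() -> list[str]:
    return sorted(_REGISTRY)


def get_selector(selector_id: str):
    try:
        return _REGISTRY[selector_id]
    except KeyError:
        raise SelectorUnavailableError(
            f"unknown selector {selector_id!r}; available: {available_selectors()}"
        ) from None


def apply_selector(selector_id: str, ds: SurvivalDataset, seed: int = 0, **params) -> SelectorResult:
    result = get_selector(selector_id)(ds, seed, **params)
    if not isinstance(result, SelectorResult):
        raise SelectorContractError(f"{selector_id} did not return a SelectorResult")
    return result.validate()


register_selector("unicox", lambda ds, seed, **kw: univariate_cox_filter(ds))
register_selector("lasso", lambda ds, seed, **kw: sparse_cox_selector(ds, "lasso", **kw))
register_selector(
    "enet", lambda ds, seed, **kw: sparse_cox_selector(ds, "elastic_net", **kw)
)
register_selector("glmboost", lambda ds, seed, **kw: boosted_cox_selector(ds, seed=seed, **kw))
register_selector("rsf", lambda ds, seed, **kw: survival_forest_selector(ds, seed=seed, **kw))
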