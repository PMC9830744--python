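"""Rank/score aggregation of bootstrap selector ensembles.

An ensemble run holds B ranked lists over a fixed universe of feature
names (real features plus any injected probes).  Five aggregators
combine them:

* ``mean_rank`` / ``mean_weight`` — arithmetic mean of per-list ranks or
  importance scores (a ranking; thresholding is a separate step);
* ``rra_select`` — Robust Rank Aggregation: each feature's sorted
  normalized ranks are compared with uniform order statistics through
  binomial tail probabilities, and the minimum tail probability over
  the order index is the feature's score rho; features with
  rho < p are selected (aggregation and thresholding in one step);
* ``threshold_algorithm`` — the top-k early-stopping algorithm over
  score-sorted lists with a sum aggregate;
* ``medrank`` — sequential access that outputs a feature once it has
  appeared in more than a given fraction of the lists.

Tie-breaking everywhere is deterministic: stable sorts with the feature
name as secondary key.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .probes import is_probe_name
from .selectors import SelectorResult


@dataclass
class RankedList:
    """One bootstrap's ranking: names best-to-worst with their scores.

    ``partial`` marks sparse-selector lists that contain only the
    selected features; unlisted universe members are treated downstream
    as worst-ranked with score 0.
    """

    ordering: list[str]
    scores: dict[str, float]
    partial: bool = False

    def __post_init__(self):
        if len(set(self.ordering)) != len(self.ordering):
            raise ValueError("duplicate names in ranked list")
        missing = [n for n in self.ordering if n not in self.scores]
        if missing:
            raise ValueError(f"ordering names missing scores: {missing[:3]}")


def ranked_list_from_result(result: SelectorResult) -> RankedList:
    """Order a selector's output by score (descending, name tiebreak).

    Sparse selectors contribute only their selected subset (a partial
    list); filters contribute every scored feature.
    """
    names = sorted(result.selected) if result.is_sparse else sorted(result.scores)
    ordering = sorted(names, key=lambda n: (-result.scores[n], n))
    return RankedList(ordering, {n: result.scores[n] for n in ordering}, result.is_sparse)


@dataclass
class EnsembleRun:
    """B ranked lists over one fixed feature-plus-probe universe."""

    lists: list[RankedList]
    universe: tuple[str, ...]
    selector_id: str = ""
    seeds: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.lists) < 2:
            raise ValueError("an ensemble needs at least 2 lists")
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("duplicate names in universe")
        for rl in self.lists:
            extra = set(rl.ordering) - uni
            if extra:
                raise ValueError(f"list names outside universe: {sorted(extra)[:3]}")

    @property
    def B(self) -> int:
        return len(self.lists)

    @property
    def n_original(self) -> int:
        return sum(not is_probe_name(n) for n in self.universe)

    def subset_sizes(self) -> list[int] | None:
        """Per-list selected-subset sizes, or None for filter ensembles."""
        if all(rl.partial for rl in self.lists):
            return [len(rl.ordering) for rl in self.lists]
        return None

    def default_k(self) -> int:
        """Target size for the top-k aggregators: round-half-up mean
        subset size, falling back to 25% of the real features for
        filter ensembles (which have no natural subset length)."""
        sizes = self.subset_sizes()
        if sizes is not None:
            return max(1, math.floor(np.mean(sizes) + 0.5))
        warnings.warn(
            "filter ensemble has no subset sizes; defaulting k to 25% of features"
        )
        return max(1, math.ceil(0.25 * self.n_original))


@dataclass
class AggregatedRanking:
    """Final aggregated ordering with per-feature scores.

    ``scores`` follow the method's own direction (``higher_is_better``);
    ``selected`` is set by the self-thresholding aggregators (RRA, TA,
    MedRank).  RRA additionally exposes per-feature rho in ``extras``.
    """

    ordering: list[str]
    scores: dict[str, float]
    method: str
    higher_is_better: bool = True
    selected: set[str] | None = None
    k: int | None = None
    extras: dict = field(default_factory=dict)

    def score_array(self, names=None) -> np.ndarray:
        names = list(names) if names is not None else self.ordering
        return np.array([self.scores[n] for n in names])


def _order(scores: dict[str, float], higher_is_better: bool) -> list[str]:
    sign = -1.0 if higher_is_better else 1.0
    return sorted(scores, key=lambda n: (sign * scores[n], n))


# ---------------------------------------------------------------------------
# mean rank / mean weight

def _integer_ranks(rl: RankedList, universe) -> dict[str, int]:
    ranks = {n: len(universe) for n in universe}  # unlisted -> worst
    for pos, n in enumerate(rl.ordering, start=1):
        ranks[n] = pos
    return ranks


def mean_rank(run: EnsembleRun) -> AggregatedRanking:
    """Mean of per-list ranks (unlisted features take the worst rank).

    Equivalent to a Borda count; the reported score is
    ``|universe| + 1 - mean rank`` so that higher is uniformly better
    for the downstream score-based thresholds.
    """
    total = dict.fromkeys(run.universe, 0.0)
    for rl in run.lists:
        for n, r in _integer_ranks(rl, run.universe).items():
            total[n] += r
    means = {n: t / run.B for n, t in total.items()}
    scores = {n: len(run.universe) + 1 - m for n, m in means.items()}
    return AggregatedRanking(
        _order(scores, True), scores, "MR", extras={"mean_rank": means}
    )


def mean_weight(run: EnsembleRun) -> AggregatedRanking:
    """Mean importance score per feature (absent from a sparse list = 0)."""
    total = dict.fromkeys(run.universe, 0.0)
    for rl in run.lists:
        for n, s in rl.scores.items():
            total[n] += s
    scores = {n: t / run.B for n, t in total.items()}
    return AggregatedRanking(_order(scores, True), scores, "MW")


# ---------------------------------------------------------------------------
# Robust Rank Aggregation

def rra_beta(k: int, n: int, x: float) -> float:
    """P(at least k of n uniform ranks are <= x): the binomial tail
    sum_{l=k}^{n} C(n,l) x^l (1-x)^{n-l}, via the stable survival form."""
    if not (1 <= k <= n):
        raise ValueError("need 1 <= k <= n")
    if not (0.0 <= x <= 1.0):
        raise ValueError("x must be in [0, 1]")
    return float(binom.sf(k - 1, n, x))


def rra_score(ranks, bonferroni: bool = False) -> float:
    """rho for one feature: min over k of beta_{k,n}(r(k)).

    ``ranks`` must be the feature's normalized ranks sorted ascending,
    each in (0, 1].  With ``bonferroni`` the minimum is multiplied by n
    (capped at 1), matching the original RRA significance correction;
    the default reports the uncorrected minimum.
    """
    r = np.asarray(ranks, dtype=float)
    if np.any(np.diff(r) < 0):
        raise ValueError("ranks must be sorted ascending")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    n = r.size
    rho = float(min(rra_beta(k, n, r[k - 1]) for k in range(1, n + 1)))
    if bonferroni:
        rho = min(1.0, rho * n)
    return rho


def _normalized_ranks(run: EnsembleRun) -> dict[str, np.ndarray]:
    U = len(run.universe)
    cols = {n: np.ones(run.B) for n in run.universe}  # unlisted -> 1.0
    for b, rl in enumerate(run.lists):
        for pos, n in enumerate(rl.ordering, start=1):
            cols[n][b] = pos / U
    return cols

def rra_select(
    run: EnsembleRun, p_threshold: float, bonferroni: bool = False
) -> AggregatedRanking:
    """Aggregate by rho and select features with rho < p_threshold.

    This aggregator both ranks and thresholds; no separate threshold
    step applies.  An empty selection is valid (the harness falls back
    to all features so a model can still be fit).
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    norm = _normalized_ranks(run)
    rho = {n: rra_score(np.sort(v), bonferroni=bonferroni) for n, v in norm.items()}
    selected = {n for n, r in rho.items() if r < p_threshold}
    return AggregatedRanking(
        _order(rho, False),
        rho,
        f"RRA:{p_threshold}",
        higher_is_better=False,
        selected=selected,
        extras={"rho": rho, "p_threshold": p_threshold, "bonferroni": bonferroni},
    )


# ---------------------------------------------------------------------------
# Threshold Algorithm (top-k with early stopping)

def threshold_algorithm(run: EnsembleRun, k: int | None = None) -> AggregatedRanking:
    """Fagin-style TA over the B score-sorted lists with a sum aggregate.

    Sequential access proceeds depth by depth; the stopping threshold at
    depth d is the sum over lists of their d-th score.  A feature first
    seen at any depth gets its full aggregate (sum of its scores across
    all lists, missing = 0) by random access.  The algorithm stops when
    the current k-th best aggregate is >= the threshold, and returns
    exactly k features.  k defaults to the ensemble's mean subset size.
    """
    if k is None:
        k = run.default_k()
    if k < 1:
        raise ValueError("k must be >= 1")
    U = len(run.universe)
    if k > U:
        warnings.warn(f"k={k} exceeds universe size {U}; clamping")
        k = U

    aggregate = dict.fromkeys(run.universe, 0.0)
    for rl in run.lists:
        for n, s in rl.scores.items():
            aggregate[n] += s

    seen: set[str] = set()
    max_depth = max(len(rl.ordering) for rl in run.lists)
    stopped_at = max_depth
    for depth in range(1, max_depth + 1):
        threshold = sum(
            rl.scores[rl.ordering[depth - 1]]
            for rl in run.lists
            if len(rl.ordering) >= depth
        )
        for rl in run.lists:
            if len(rl.ordering) >= depth:
                seen.add(rl.ordering[depth - 1])
        best = sorted(seen, key=lambda n: (-aggregate[n], n))[:k]
        if len(best) == k and all(aggregate[n] >= threshold for n in best):
            stopped_at = depth
            break

    # final answer: top-k among seen items (pad from the universe if the
    # lists were too short to surface k distinct names)
    pool = seen if len(seen) >= k else set(run.universe)
    top = sorted(pool, key=lambda n: (-aggregate[n], n))[:k]
    return AggregatedRanking(
        sorted(aggregate, key=lambda n: (-aggregate[n], n)),
        dict(aggregate),
        "TA",
        selected=set(top),
        k=k,
        extras={"stopped_at_depth": stopped_at},
    )


# ---------------------------------------------------------------------------
# MedRank

def medrank(run: EnsembleRun, k: int | None = None, fraction: float = 0.2) -> AggregatedRanking:
    """Sequential-access aggregation: output a feature the moment it has
    appeared in more than ``fraction`` of the B lists.

    Lists are visited in index order at each depth (a documented,
    deterministic convention).  Terminates early once k features are
    output; if the lists are exhausted first the shorter output is
    returned.  The default fraction 0.2 suits weak signals where few
    features appear in more than half the lists.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if k is None:
        k = run.default_k()
    if k < 1:
        raise ValueError("k must be >= 1")
    need = fraction * run.B  # output once count > need
    counts = dict.fromkeys(run.universe, 0)
    output: list[str] = []
    emitted: set[str] = set()
    max_depth = max(len(rl.ordering) for rl in run.lists)
    for depth in range(1, max_depth + 1):
        for rl in run.lists:
            if len(rl.ordering) < depth:
                continue
            name = rl.ordering[depth - 1]
            counts[name] += 1
            if name not in emitted and counts[name] > need:
                output.append(name)
                emitted.add(name)
                if len(output) == k:
                    scores = {n: float(len(output) - i) for i, n in enumerate(output)}
                    return AggregatedRanking(
                        output, scores, "MA", selected=set(output), k=k
                    )
    scores = {n: float(len(output) - i) for i, n in enumerate(output)}
    return AggregatedRanking(output, scores, "MA", selected=set(output), k=k)
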