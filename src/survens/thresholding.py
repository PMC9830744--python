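"""Cut an aggregated ranking into selected vs. discarded features.

Four families: fixed top-fraction cuts, the 75% quantile of the
aggregated scores, a kernel-density clustering of the 1-D score
distribution, and the best-random-probe rule.  All of them return a
subset of the *original* (non-probe) features; degenerate empty
selections fall back to all features with a warning so the downstream
survival model can always be fit.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .aggregation import AggregatedRanking
from .probes import is_probe_name


def _original_order(agg: AggregatedRanking) -> list[str]:
    return [n for n in agg.ordering if not is_probe_name(n)]


def fixed_fraction(agg: AggregatedRanking, fraction: float) -> set[str]:
    """Top round-half-up(fraction * number of real features) features.

    Probes are excluded both from the count and the result.  A fraction
    rounding to zero keeps the single best feature.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    originals = _original_order(agg)
    count = math.floor(fraction * len(originals) + 0.5)
    if count == 0:
        warnings.warn("fraction rounds to 0 features; keeping the top-1")
        count = 1
    return set(originals[:count])


def quantile75(agg: AggregatedRanking, q: float = 0.75) -> set[str]:
    """Features scoring strictly above the q-quantile of all scores.

    Quantile uses linear interpolation.  Ranking-only aggregations must
    provide a higher-is-better score (mean-rank does, via its reversed
    score).  All-equal scores select nothing; fall back to everything.
    """
    originals = _original_order(agg)
    scores = agg.score_array(originals)
    if not agg.higher_is_better:
        scores = -scores
    cut = np.quantile(scores, q)
    kept = {n for n, s in zip(originals, scores) if s > cut}
    if not kept:
        warnings.warn("quantile threshold selected nothing; keeping all features")
        return set(originals)
    return kept


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9 * sd * m^(-1/5).

    The sd-based form is used rather than the IQR-robust variant: when
    the bulk of the scores sit in one tight cluster (the typical
    feature-selection shape) the IQR collapses to the within-cluster
    spread and the estimate undersmooths, splitting the irrelevant
    cluster into spurious modes.
    """
    sd = x.std(ddof=1)
    if sd <= 0:
        sd = 1.0
    return 0.9 * sd * x.size ** (-0.2)


def _kde_grid(x: np.ndarray, h: float, grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    return grid, dens


def kde_cut_value(
    scores: np.ndarray, max_iter: int = 10, shrink: float = 0.75, grid_size: int = 512
) -> float | None:
    """Locate the score value separating the irrelevant-feature cluster.

    Gaussian KDE with Silverman's rule-of-thumb bandwidth on a 512-point
    grid; cluster centres are the local density maxima.  Assuming most
    features are irrelevant, the highest peak is the irrelevant cluster's
    centre; the cut is the first local minimum above it.  If the
    bandwidth is too wide to show more than one peak it is shrunk by
    0.75 and the estimate repeated, up to ``max_iter`` times; once the
    density is multimodal the estimate is final, and if no local minimum
    lies above the highest peak there is no valid cut.  Returns None
    when no valid cut exists.
    """
    x = np.asarray(scores, dtype=float)
    h = _silverman_bandwidth(x)
    for _ in range(max_iter):
        grid, dens = _kde_grid(x, h, grid_size)
        d = np.sign(np.diff(dens))
        # forward-fill zero slopes (density plateaus, incl. underflow to 0
        # between well-separated clusters) so extrema spanning a plateau
        # are still detected
        for i in range(1, d.size):
            if d[i] == 0:
                d[i] = d[i - 1]
        maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] < 0)) + 1
        minima = np.flatnonzero((d[:-1] < 0) & (d[1:] > 0)) + 1
        if maxima.size >= 2:
            top = maxima[np.argmax(dens[maxima])]
            above = minima[minima > top]
            if above.size:
                return float(grid[above[0]])
            return None  # multimodal but the top peak is the last cluster
        h *= shrink
    return None


def kde_threshold(agg: AggregatedRanking, max_iter: int = 10) -> set[str]:
    """Keep features whose score exceeds the KDE cluster boundary.

    Falls back to all features when fewer than 4 distinct scores exist
    or no valid cut is found (e.g. a unimodal score distribution).
    """
    originals = _original_order(agg)
    scores = agg.score_array(originals)
    if not agg.higher_is_better:
        scores = -scores
    if np.unique(scores).size < 4:
        warnings.warn("fewer than 4 distinct scores; KDE thresholding skipped")
        return set(originals)
    cut = kde_cut_value(scores, max_iter=max_iter)
    if cut is None:
        warnings.warn("no valid KDE cut found; keeping all features")
        return set(originals)
    kept = {n for n, s in zip(originals, scores) if s > cut}
    if not kept:
        warnings.warn("KDE cut above every score; keeping all features")
        return set(originals)
    return kept


def best_probe_threshold(
    agg: AggregatedRanking, probe_names: set[str] | None = None, sparse_no_probe: bool = False
) -> set[str]:
    """Keep the original features ranked strictly better than the best probe.

    A feature tying the best probe's aggregated position is discarded
    (conservative).  ``sparse_no_probe`` covers the sparse-selector
    special case: when no probe was ever selected in any bootstrap there
    is nothing to compare against, so the aggregation's own selected set
    is kept unchanged.
    """
    if sparse_no_probe:
        if agg.selected is not None:
            return {n for n in agg.selected if not is_probe_name(n)}
        return set(_original_order(agg))
    if probe_names is None:
        probe_names = {n for n in agg.ordering if is_probe_name(n)}
    if not probe_names:
        raise ValueError(
            "no probes in the aggregated universe: enable probe injection "
            "to use the best-probe threshold"
        )
    sign = 1.0 if agg.higher_is_better else -1.0
    best_probe = max(sign * agg.scores[n] for n in probe_names)
    kept = {
        n
        for n in agg.ordering
        if not is_probe_name(n) and sign * agg.scores[n] > best_probe
    }
    if not kept:
        warnings.warn("best probe outranks every feature; keeping all features")
        return set(_original_order(agg))
    return kept
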