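"""Concordance and combined performance/stability scoring."""

from __future__ import annotations

import math

import numpy as np


def concordance_index(time, event, risk) -> float:
    """Harrell's C-index for right-censored data.

    A pair (i, j) is comparable iff the subject with the earlier time
    had the event observed.  The pair is concordant when that subject
    also has the higher predicted risk; ties in risk count 1/2.  Tied
    times with both events observed are not comparable.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk, dtype=float)
    if not (time.shape == event.shape == risk.shape):
        raise ValueError("time, event and risk must have equal length")
    # comparable: t_i < t_j and e_i = 1; or t_i == t_j with exactly one event
    ti, tj = time[:, None], time[None, :]
    ei, ej = event[:, None], event[None, :]
    ri, rj = risk[:, None], risk[None, :]
    comparable = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    concordant = comparable & (ri > rj)
    tied = comparable & (ri == rj)
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def euclidean_score(stability: float, performance: float) -> float:
    """Distance from the origin in the (stability, accuracy) plane.

    Both coordinates live on [0, 1]; larger distance means a model that
    is simultaneously more stable and more accurate.
    """
    if not (math.isfinite(stability) and math.isfinite(performance)):
        raise ValueError("inputs must be finite")
    return math.hypot(stability, performance)
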