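"""Random permutation probes.

A probe is an independently permuted copy of a real feature: it keeps
the marginal distribution but has no association with the outcome, so
the rank the best probe attains in an aggregated ranking is a
data-driven cutoff between relevant and irrelevant features.

Probes are regenerated (re-permuted) on every bootstrap iteration.
Boolean features get no probe: with only two values a permutation
leaves many entries fixed, letting the probe inherit real signal.
Categorical probes are retained, their larger level sets permuting more
thoroughly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import BOOLEAN, FeatureMeta, SurvivalDataset, child_rng

PROBE_PREFIX = "__probe__"


def probe_name(source: str) -> str:
    return PROBE_PREFIX + source


def is_probe_name(name: str) -> bool:
    return name.startswith(PROBE_PREFIX)


def strip_probes(names) -> set[str]:
    """Drop probe names from a collection of feature names."""
    return {n for n in names if not is_probe_name(n)}


def inject_probes(ds: SurvivalDataset, seed) -> SurvivalDataset:
    """Append one permuted probe per continuous/categorical feature.

    ``seed`` may be an int or :class:`numpy.random.SeedSequence`; the
    same seed yields identical permutations.  Raises when the dataset
    has only boolean features (no probe could be built).
    """
    eligible = [fm for fm in ds.meta if fm.kind != BOOLEAN and not fm.is_probe]
    if not eligible:
        raise ValueError(
            "all features are boolean: probe thresholding unavailable "
            "(boolean-derived probes are excluded)"
        )
    rng = np.random.default_rng(seed)
    feats = ds.features.copy()
    meta = list(ds.meta)
    for fm in eligible:
        pname = probe_name(fm.name)
        perm = rng.permutation(ds.m)
        feats[pname] = ds.features[fm.name].to_numpy()[perm]
        meta.append(
            FeatureMeta(pname, fm.kind, levels=fm.levels, is_probe=True, probe_source=fm.name)
        )
    return SurvivalDataset(feats, meta, ds.time.copy(), ds.event.copy())
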