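import numpy as np
import pandas as pd
import pytest

from survens import (
    BOOLEAN,
    CATEGORICAL,
    CONTINUOUS,
    EnsembleRun,
    FeatureMeta,
    RankedList,
    SurvivalDataset,
)


def make_dataset(columns, time, event):
    """Build a SurvivalDataset from {name: (kind, values[, levels])}."""
    meta, data = [], {}
    for name, spec in columns.items():
        kind = spec[0]
        values = np.asarray(spec[1], dtype=float)
        levels = tuple(spec[2]) if kind == CATEGORICAL else None
        meta.append(FeatureMeta(name, kind, levels=levels))
        data[name] = values
    return SurvivalDataset(pd.DataFrame(data), meta, np.asarray(time, float), np.asarray(event, int))


def full_list(ordering):
    """RankedList over a full universe: scores decrease down the ordering."""
    n = len(ordering)
    return RankedList(list(ordering), {f: float(n - i) for i, f in enumerate(ordering)})


def sparse_list(scored: dict):
    ordering = sorted(scored, key=lambda f: (-scored[f], f))
    return RankedList(ordering, dict(scored), partial=True)


def make_run(lists, universe, selector_id="test"):
    return EnsembleRun(list(lists), tuple(universe), selector_id)


@pytest.fixture
def tiny_ds():
    """6 samples, one feature of each kind, no censoring ties."""
    return make_dataset(
        {
            "age": (CONTINUOUS, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
            "apoe4": (BOOLEAN, [0, 1, 0, 1, 1, 0]),
            "site": (CATEGORICAL, [0, 1, 2, 0, 1, 2], ["A", "B", "C"]),
        },
        time=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        event=[1, 0, 1, 1, 0, 1],
    )
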