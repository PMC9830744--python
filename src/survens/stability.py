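"""Stability of feature selection across resampled runs.

Three indices quantify how much the selected subsets agree:

* Kuncheva's consistency index for two equal-size subsets,
  I_c = (r*n - k^2) / (k*(n - k)) with r the intersection size, k the
  common subset size and n the universe size (chance-corrected; 1 for
  identical subsets, possibly negative for disjoint ones);
* Lustgarten's adjusted measure, which extends the chance correction to
  subsets of unequal size;
* Somol and Novovicova's relative weighted consistency CW_rel of a whole
  system of subsets, which handles varying sizes, lies in [0, 1] and
  does not over-reward low-frequency features.  It is the headline
  stability measure of the evaluation harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations


@dataclass
class SubsetSystem:
    """A system of feature subsets over a common universe Y."""

    subsets: list[set]
    universe: set

    def __post_init__(self):
        self.subsets = [set(s) for s in self.subsets]
        self.universe = set(self.universe)
        if len(self.subsets) < 2:
            raise ValueError("need at least 2 subsets")
        for s in self.subsets:
            if not s <= self.universe:
                raise ValueError(f"subset members outside universe: {sorted(s - self.universe)[:3]}")

    @property
    def n(self) -> int:
        return len(self.subsets)

    def occurrences(self) -> dict:
        occ = dict.fromkeys(self.universe, 0)
        for s in self.subsets:
            for f in s:
                occ[f] += 1
        return occ

    @property
    def N(self) -> int:
        return sum(len(s) for s in self.subsets)


def kuncheva(s1, s2, universe_size: int) -> float:
    """Kuncheva consistency index for two subsets of identical size."""
    s1, s2 = set(s1), set(s2)
    n = int(universe_size)
    k = len(s1)
    if len(s2) != k:
        raise ValueError("Kuncheva's index requires subsets of identical size")
    if k == 0 or k == n:
        raise ValueError("undefined for empty or full subsets (zero denominator)")
    r = len(s1 & s2)
    return (r * n - k * k) / (k * (n - k))


def lustgarten(si, sj, universe_size: int) -> float:
    """Lustgarten's adjusted stability measure (handles unequal sizes)."""
    si, sj = set(si), set(sj)
    n = int(universe_size)
    ki, kj = len(si), len(sj)
    if ki == 0 or kj == 0 or ki >= n or kj >= n:
        raise ValueError("subset sizes must lie strictly between 0 and n")
    denom = min(ki, kj) - max(0, ki + kj - n)
    if denom == 0:
        raise ValueError("zero denominator")
    r = len(si & sj)
    return (r - ki * kj / n) / denom


def cw_rel(system: SubsetSystem, d_convention: str = "N") -> float:
    """Relative weighted consistency of a subset system, in [0, 1].

    With |Y| the universe size, F_f the occurrence count of feature f,
    N the total number of occurrences, n the number of subsets,
    D = N mod |Y| and H = N mod n:

        CW_rel = (|Y| (N - D + sum_f F_f (F_f - 1)) - N^2 + D^2)
                 / (|Y| (H^2 + n (N - H) - D) - N^2 + D^2)

    ``d_convention`` selects the remainder in D: ``"N"`` (default, the
    original definition, D = N mod |Y|) or ``"n"`` (D = n mod |Y|, a
    variant seen in some renderings of the formula).  A degenerate zero
    denominator — e.g. every subset equal to the full universe — returns
    1.0 when all subsets are identical (perfectly consistent) and 0.0
    otherwise, with a warning.
    """
    if d_convention not in ("N", "n"):
        raise ValueError("d_convention must be 'N' or 'n'")
    Y = len(system.universe)
    n = system.n
    N = system.N
    if N == 0:
        warnings.warn("all subsets empty; CW_rel undefined, returning 0.0")
        return 0.0
    D = (N % Y) if d_convention == "N" else (n % Y)
    H = N % n
    sum_ff = sum(F * (F - 1) for F in system.occurrences().values())
    num = Y * (N - D + sum_ff) - N * N + D * D
    den = Y * (H * H + n * (N - H) - D) - N * N + D * D
    if den == 0:
        identical = all(s == system.subsets[0] for s in system.subsets)
        warnings.warn("degenerate CW_rel denominator; returning sentinel")
        return 1.0 if identical else 0.0
    return num / den


def mean_pairwise(metric, subsets, universe_size: int) -> tuple[float, int]:
    """Unweighted mean of a pairwise metric over all unordered pairs.

    Pairs the metric cannot score (e.g. Kuncheva with unequal sizes) are
    skipped with a warning; returns (mean, number of skipped pairs).
    """
    subsets = [set(s) for s in subsets]
    if len(subsets) < 2:
        raise ValueError("need at least 2 subsets")
    values, skipped = [], 0
    for a, b in combinations(subsets, 2):
        try:
            values.append(metric(a, b, universe_size))
        except ValueError:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} pair(s) skipped (metric inapplicable)")
    if not values:
        raise ValueError("metric applicable to no pair")
    return sum(values) / len(values), skipped
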