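"""Score the agreement of feature subsets selected across CV folds."""

import survens as sv

universe = {"age", "apoe4", "memory", "gait", "bmi", "smoking"}
subsets = [
    {"age", "apoe4", "memory"},
    {"age", "apoe4", "gait"},
    {"age", "apoe4", "memory", "bmi"},
]

system = sv.SubsetSystem(subsets, universe)
print(f"relative weighted consistency CW_rel: {sv.cw_rel(system):.4f}")
# CW_rel is 1 when every fold selects the same subset and 0 when the
# selections share nothing beyond what their sizes force.

mean_l, _ = sv.mean_pairwise(sv.lustgarten, subsets, len(universe))
print(f"mean pairwise Lustgarten: {mean_l:.4f}")

mean_k, skipped = sv.mean_pairwise(sv.kuncheva, subsets, len(universe))
print(f"mean pairwise Kuncheva: {mean_k:.4f} ({skipped} unequal-size pairs skipped)")
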