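"""Aggregate conflicting ranked lists with the five aggregators.

Three bootstrap 'selectors' disagree about features a-e; each aggregator
resolves the disagreement differently.
"""

from survens import (
    RankedList, EnsembleRun,
    mean_rank, mean_weight, rra_select, threshold_algorithm, medrank,
)

lists = [
    RankedList(["a", "b", "c", "d", "e"], {"a": .9, "b": .7, "c": .5, "d": .3, "e": .1}),
    RankedList(["b", "a", "d", "c", "e"], {"b": .8, "a": .75, "d": .4, "c": .35, "e": .05}),
    RankedList(["a", "c", "b", "e", "d"], {"a": .85, "c": .6, "b": .55, "e": .2, "d": .15}),
]
run = EnsembleRun(lists, ("a", "b", "c", "d", "e"), "demo")

mr = mean_rank(run)
print("mean rank ordering:   ", mr.ordering, "(Borda-equivalent)")
mw = mean_weight(run)
print("mean weight ordering: ", mw.ordering)

rra = rra_select(run, p_threshold=0.15)
print("RRA rho:", {f: round(r, 4) for f, r in rra.extras["rho"].items()})
print("RRA selected (rho < 0.15):", sorted(rra.selected))
# rho is the minimum binomial tail probability comparing a feature's
# sorted normalized ranks with uniform order statistics: small rho means
# the feature ranks consistently better than chance.

ta = threshold_algorithm(run, k=2)
print("Threshold Algorithm top-2:", sorted(ta.selected),
      f"(early stop at depth {ta.extras['stopped_at_depth']})")

ma = medrank(run, k=2, fraction=0.5)
print("MedRank top-2 (majority):", ma.ordering)
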