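"""Drought-vs-control fold-change screen and multi-period intersection.

Generates a water-stress/well-watered expression matrix with planted
differential structure, calls genes with |log2(WS/WW)| > 1 per timepoint,
and intersects the calls across timepoints.
"""

from ringkit import call_degs, log2_fold_change, multi_period_intersection
from ringkit.simulate import gen_expression

matrix, truth = gen_expression(200, deg_fraction=0.25, n_multi_period=8, seed=42)
fc = log2_fold_change(matrix, "M4")
degs = call_degs(fc, threshold=1.0)
for tp, s in sorted(degs.items()):
    print(f"{tp}: {len(s)} differential genes")
report = multi_period_intersection(degs, k=3)
print(f"genes differential in >= 3 of 4 periods: {len(report.at_least_k)}")
print("they are:", sorted(report.at_least_k))
print("matches planted truth:",
      report.at_least_k == set(truth['genotypes']['M4']['multi_period_genes']))
# Genes repeatedly differential across the time course are the screen's
# drought-response candidates.
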