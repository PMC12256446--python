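"""Normalized eye activity across stimulus bins, with Kruskal-Wallis + Dunn.

Runs five simulated larvae through the grating-spacing characterization
trial, tabulates the per-bin normalized eye activity (NEA), and tests
whether the blank bin differs from the stimulated bins.
"""

import pandas as pd

from okrloop import VirtualLarvaParams, build_schedule, nea, nea_stats, simulate_trace

schedule = build_schedule("spacing")
tables = []
for seed in range(5):
    trace = simulate_trace(VirtualLarvaParams(seed=seed), schedule)
    tables.append(nea(trace.series, schedule, larva_id=f"larva{seed}", trial_id="spacing"))
table = pd.concat(tables, ignore_index=True)

print(table.groupby("bin", sort=False)["NEA"].mean().round(3).to_string())
res = nea_stats(table)
print(f"\nKruskal-Wallis: H = {res.H:.2f}, p = {res.p:.2e}")
if res.pairwise is not None:
    sig = res.pairwise[res.pairwise["significant"]]
    print("significant Dunn contrasts (Bonferroni-adjusted):")
    print(sig[["group_a", "group_b", "p_adj"]].round(4).to_string(index=False))
print("-> the blank bin B carries far less eye activity than any grating bin,")
print("   and the rank tests flag exactly those blank-vs-stimulus contrasts.")
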