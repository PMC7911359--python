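"""Build a planted toy TCS world and score its specificity network.

Generates five histidine-kinase families with cognate response-regulator
families, fits cognate and scrambled Potts models by mean-field DCA, and
prints the H_TCSspecific matrix of the family representatives. The
diagonal (cognate pairs) should be strongly negative — encoded specificity
— while off-diagonal (non-cognate) cells sit near or above zero.
"""

from tcspec import make_toy_world, validation_metrics
from tcspec.benchmark import run_world

world = make_toy_world(n_hk_families=5, M_per_family=300, coupling_strength=3.0, seed=42)
recovery, calls, matrix, di = run_world(world, seed=42)

print("planted interface pairs recovered in top-DI ranking:", f"{recovery:.0%}")
print("\nH_TCSspecific (rows = HK families, columns = RR families):")
header = "        " + "  ".join(f"{r:>8}" for r in matrix.rr_ids)
print(header)
for h, hk_id in enumerate(matrix.hk_ids):
    print(f"{hk_id:>8}" + "  ".join(f"{v:8.2f}" for v in matrix.scores[h]))

summary = validation_metrics(calls)
print(f"\ncognate pairs detected (positive and/or negative selection): "
      f"{summary.tp}/{summary.tp + summary.fn} (sensitivity {summary.sensitivity:.2f})")
print("negative scores = encoded specificity; near zero = shared TCS attributes only.")
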