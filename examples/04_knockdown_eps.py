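"""Detect exacerbated pause sites (EPSs) in a simulated knockdown.

Depleting an editing factor stalls progression at specific sites: stop
sites whose renormalized counts increase significantly (Student's t
P < 0.05, BH q < 0.05, consistent in every induced replicate) are EPSs.
Pre-edited sequences are removed and the remainder renormalized first, so
only transcripts that entered the editing pathway are compared.
"""

from uindel import class_change_test, detect_eps
from uindel.simulate import (
    KnockdownEffect, SimulationParams, demo_gene, generate_knockdown_pair,
)

table = demo_gene()
base = SimulationParams(table=table, depth=100_000, n_replicates=5)
effect = KnockdownEffect(sites=(7, 21), multiplier=10.0, class_shift=(0.40, 0.15))
uninduced, induced, _ = generate_knockdown_pair(base, effect, seed=5)

ind = [s.to_population() for s in induced]
unind = [s.to_population() for s in uninduced]

stats = detect_eps(ind, unind)
for row in stats[stats["is_eps"]].itertuples():
    print(f"EPS at ES{row.site_label}: {row.mean_uninduced:.0f} -> "
          f"{row.mean_induced:.0f} renormalized counts, p={row.p:.2e}, q={row.q:.2e}")

print(class_change_test(ind, unind).to_string(index=False))
# The two designated pause sites are recovered; the class table shows the
# accompanying shift toward pre-edited transcripts upon knockdown.
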