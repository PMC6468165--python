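"""Explain an observed junction with candidate guide RNAs.

Guides pair the mRNA antiparallel (Watson-Crick plus G:U wobble), anchor
3' of the block they edit, and their purine runs template U insertions.
Given a junction's U counts, the search ranks a guide set by how many
editing sites each guide explains exactly.  The bulge mode shows how a
one-U misalignment of a cognate guide turns a 5-U block into 9 Us.
"""

import numpy as np

from uindel import predict_templated_block, search_grna_db
from uindel.simulate import JunctionModel, demo_gene, demo_guides

table = demo_gene()
jm = JunctionModel()

# an observed junction created by the alternative guide: canonical 3' of
# site 5, then the alternative editing pattern over sites 6..14
u = np.array(table.pre_U)
u[:jm.alt_ess] = table.full_U[:jm.alt_ess]
for site, count in jm.alt_pattern:
    u[site - 1] = count

for cand in search_grna_db(u, table, demo_guides())[:3]:
    print(f"{cand.guide_id}: explains {cand.n_explained} site(s) "
          f"{cand.sites[0]}..{cand.sites[-1]}, anchor mismatches "
          f"{cand.anchor.n_mismatch}, duplex score {cand.duplex_score:.0f}")
# The guide that actually generated the junction ranks first and explains
# every junction site, despite being annotated to another transcript.

g = next(x for x in demo_guides() if x.id == "gDemo-mis")
window = table.skeleton[:table.n_sites - 11][::-1]
canonical = predict_templated_block(g, window, start=8)
bulge = g.sequence.index("AAAAATAAAA") + 5
bulged = predict_templated_block(g, window, start=8, bulge=bulge)
print(f"canonical run at ES447: {canonical.u_counts[1]} Us; "
      f"with one guide U bulged: {bulged.u_counts[1]} Us")
# 5 -> 9: the misalignment mechanism behind the hybrid junctions.
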