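import numpy as np
import pandas as pd
import pytest

from uindel.quantify import SamplePopulation
from uindel.simulate import demo_gene
from uindel.templates import table_from_counts


@pytest.fixture(scope="session")
def toy():
    """4-site toy gene: skeleton ACG, single-base flanks (G...A)."""
    return table_from_counts("toy", "ACG", [0, 0, 0, 0], [2, 0, 1, 0],
                             flank5="G", flank3="A")


@pytest.fixture(scope="session")
def demo():
    """The packaged 30-site synthetic minimally-edited gene."""
    return demo_gene()


def make_population(table, rows, sample_id="s", scale=100_000.0):
    """Build a SamplePopulation from (u_counts, norm_count) style rows.

    ``rows`` is a list of dicts with keys u_counts (tuple), norm_count and
    optionally eclass/ess/jes; missing landmarks are derived.
    """
    from uindel.reads import classify_and_landmark

    recs = []
    for r in rows:
        lm = classify_and_landmark(r["u_counts"], table)
        recs.append({
            "count": r.get("count", 1),
            "norm_count": float(r["norm_count"]),
            "eclass": r.get("eclass", lm.eclass),
            "ess": r.get("ess", lm.ess),
            "jss": lm.jss,
            "jes": lm.jes,
            "jl": lm.jl,
            "u_counts": tuple(r["u_counts"]),
        })
    entries = pd.DataFrame(recs)
    qc = {"total": len(recs), "unique": len(recs),
          "standard": int(entries["count"].sum()), "non_standard": 0, "unanchored": 0}
    return SamplePopulation(sample_id, table, entries, scale, qc)
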