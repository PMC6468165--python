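"""Junction ranking, length distributions and pattern matching.

A *junction* is the variably edited region 5' of a transcript's editing
stop site that matches neither the pre-edited nor the fully edited
reference.  Junctions at a pause site are characterized by ranking unique
U-count vectors by their average normalized abundance across replicates
(zero-filled for replicates lacking the sequence) and by binning junction
lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import SamplePopulation
from .reads import PARTIALLY_EDITED, PRE_EDITED
from .templates import EditingSiteTable


def render_edited(u_counts, table: EditingSiteTable) -> str:
    """Display a U-count vector as the figures do: lowercase u = inserted U."""
    u = np.asarray(u_counts, dtype=int)
    m = table.n_sites
    parts = []
    for site in range(m, 0, -1):  # 5'->3' over the domain
        n, n_pre = int(u[site - 1]), int(table.pre_U[site - 1])
        parts.append("T" * min(n, n_pre) + "u" * max(0, n - n_pre))
        if site > 1:
            parts.append(table.skeleton[m - site])
    return "".join(parts)


def top_junctions(
    samples: list[SamplePopulation],
    ess: int,
    min_avg: float = 100.0,
    denominator: str = "ess",
) -> pd.DataFrame:
    """Most abundant junction sequences arising at one editing stop site.

    Unique U-count vectors of partially edited sequences with the given
    ESS are averaged across samples (a sequence absent from a replicate
    contributes zero) and those with average normalized count >= ``min_avg``
    are returned, most abundant first.  ``share_of_ess`` expresses each
    junction as a percentage of the chosen denominator: all sequences at
    that ESS (``"ess"``), all sequences that entered the editing pathway
    (``"pathway"``) or the whole population (``"total"``).
    """
    if not samples:
        raise ValueError("no samples given")
    table = samples[0].table
    if not 0 <= ess <= table.n_sites:
        raise ValueError(f"ess {ess} outside site domain 0..{table.n_sites}")
    n = len(samples)
    per_sample_totals = []
    sums: dict[tuple, float] = {}
    for pop in samples:
        ent = pop.entries
        if denominator == "ess":
            denom = ent.loc[(ent["eclass"] == PARTIALLY_EDITED) & (ent["ess"] == ess), "norm_count"].sum()
        elif denominator == "pathway":
            denom = ent.loc[ent["eclass"] != PRE_EDITED, "norm_count"].sum()
        elif denominator == "total":
            denom = ent["norm_count"].sum()
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        per_sample_totals.append(denom)
        sel = ent[(ent["eclass"] == PARTIALLY_EDITED) & (ent["ess"] == ess)]
        for u, c in zip(sel["u_counts"], sel["norm_count"]):
            sums[u] = sums.get(u, 0.0) + c
    denom_avg = float(np.mean(per_sample_totals))
    rows = []
    for u, total in sums.items():
        avg = total / n
        uv = np.asarray(u, dtype=int)
        jes = int(np.nonzero(uv != table.pre_U)[0][-1]) + 1 if (uv != table.pre_U).any() else 0
        rows.append({
            "u_counts": u,
            "rendered": render_edited(u, table),
            "ess": ess,
            "jl": max(0, jes - ess),
            "avg_norm_count": avg,
            "share_of_ess": 100.0 * avg / denom_avg if denom_avg > 0 else 0.0,
            "matched_sites": tuple(bool(b) for b in (uv == table.full_U)),
        })
    df = pd.DataFrame(rows, columns=[
        "u_counts", "rendered", "ess", "jl", "avg_norm_count", "share_of_ess", "matched_sites",
    ])
    df = df.sort_values(["avg_norm_count", "u_counts"], ascending=[False, True], ignore_index=True)
    return df[df["avg_norm_count"] >= min_avg].reset_index(drop=True)


DEFAULT_JL_BINS = ((0, 0), (1, 2), (11, 13))


def junction_length_distribution(
    groups: dict[str, list[SamplePopulation]],
    bins=DEFAULT_JL_BINS,
) -> pd.DataFrame:
    """Total normalized count per junction-length bin, averaged over replicates.

    ``bins`` is a sequence of inclusive (lo, hi) junction-length ranges;
    overlapping ranges are rejected.  Returns one row per bin with one
    column per sample group.
    """
    bins = [tuple(b) for b in bins]
    for i, (lo, hi) in enumerate(bins):
        if lo > hi:
            raise ValueError(f"bin {lo}-{hi} is inverted")
        for lo2, hi2 in bins[i + 1:]:
            if lo <= hi2 and lo2 <= hi:
                raise ValueError(f"bins {lo}-{hi} and {lo2}-{hi2} overlap")
    out = {"jl_bin": [f"{lo}" if lo == hi else f"{lo}-{hi}" for lo, hi in bins]}
    for name, pops in groups.items():
        totals = np.zeros(len(bins))
        for pop in pops:
            part = pop.entries[pop.entries["eclass"] == PARTIALLY_EDITED]
            jl = part["jl"].to_numpy(dtype=int)
            nc = part["norm_count"].to_numpy(dtype=float)
            for k, (lo, hi) in enumerate(bins):
                totals[k] += nc[(jl >= lo) & (jl <= hi)].sum()
        out[name] = totals / max(len(pops), 1)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class SitePredicate:
    """Constraint on the U count at one published editing-site label.

    ``kind`` is ``exact`` (count == value), ``canonical`` (count equals the
    fully edited reference), ``pre`` (count equals the pre-edited
    reference) or ``any``.
    """

    label: int
    kind: str
    value: int | None = None


def match_pattern(u_counts, pattern: list[SitePredicate], table: EditingSiteTable) -> bool:
    """True iff the U-count vector satisfies every site predicate.

    Used e.g. to count 'hybrid' sequences: an exact non-canonical count at
    one site with canonical editing both 3' and 5' of it.
    """
    u = np.asarray(u_counts, dtype=int)
    for pred in pattern:
        i = table.local_site(pred.label) - 1
        if pred.kind == "exact":
            ok = u[i] == pred.value
        elif pred.kind == "canonical":
            ok = u[i] == table.full_U[i]
        elif pred.kind == "pre":
            ok = u[i] == table.pre_U[i]
        elif pred.kind == "any":
            ok = True
        else:
            raise ValueError(f"unknown predicate kind {pred.kind!r}")
        if not ok:
            return False
    return True
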