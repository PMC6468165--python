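"""Sample normalization, class fractions and stop-site histograms.

Standard alignments of a sample are rescaled to a common total (100 000 by
default) so relative abundances can be compared across libraries of
different depth.  Normalized counts stay fractional; no rounding is
applied anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads import FULLY_EDITED, PARTIALLY_EDITED, PRE_EDITED
from .templates import EditingSiteTable

DEFAULT_SCALE = 100_000.0


class EmptySampleError(ValueError):
    """A sample retains no standard alignments to normalize."""


@dataclass
class SamplePopulation:
    """Normalized unique-sequence table for one sample.

    ``entries`` holds standard alignments only, one row per unique
    sequence: count (raw), norm_count, eclass, ess, jss, jes, jl and
    u_counts (tuple, 3'->5').  ``qc`` carries total/unique/standard/
    non_standard/unanchored read counts of the originating sample.
    """

    sample_id: str
    table: EditingSiteTable
    entries: pd.DataFrame
    scale: float = DEFAULT_SCALE
    qc: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.table.n_sites


def normalize_sample(
    aligned: pd.DataFrame,
    table: EditingSiteTable,
    sample_id: str = "sample",
    scale: float = DEFAULT_SCALE,
) -> SamplePopulation:
    """Build a normalized population from a ``process_reads`` table."""
    std = aligned[aligned["category"] == "standard"].copy()
    total_std = std["count"].sum()
    if total_std == 0:
        raise EmptySampleError(f"sample {sample_id!r} has no standard alignments")
    std["norm_count"] = std["count"] * (scale / total_std)
    std["u_counts"] = std["u_counts"].map(lambda s: tuple(int(x) for x in s.split(",")))
    cols = ["count", "norm_count", "eclass", "ess", "jss", "jes", "jl", "u_counts"]
    if "sequence" in std.columns:
        cols = ["sequence"] + cols
    qc = {
        "total": int(aligned["count"].sum()),
        "unique": int(len(aligned)),
        "standard": int(total_std),
        "non_standard": int(aligned.loc[aligned["category"] == "non_standard", "count"].sum()),
        "unanchored": int(aligned.loc[aligned["category"] == "unanchored", "count"].sum()),
    }
    return SamplePopulation(sample_id, table, std[cols].reset_index(drop=True), scale, qc)


def class_fractions(pop: SamplePopulation) -> dict[str, float]:
    """Percentage of the normalized population in each editing class."""
    by = pop.entries.groupby("eclass")["norm_count"].sum()
    total = pop.entries["norm_count"].sum()
    return {
        "pre": 100.0 * by.get(PRE_EDITED, 0.0) / total,
        "partial": 100.0 * by.get(PARTIALLY_EDITED, 0.0) / total,
        "full": 100.0 * by.get(FULLY_EDITED, 0.0) / total,
    }


def stop_site_histogram(
    pop: SamplePopulation,
    exclude: frozenset[str] | set[str] = frozenset({PRE_EDITED, FULLY_EDITED}),
) -> np.ndarray:
    """Normalized count of sequences sharing each editing stop site.

    Returns a dense vector over sites 0..m (zero-filled); pre-edited and
    fully edited transcripts are excluded by default so the histogram
    describes pausing of the partially edited population.
    """
    h = np.zeros(pop.n_sites + 1)
    kept = pop.entries[~pop.entries["eclass"].isin(exclude)]
    if len(kept):
        sums = kept.groupby("ess")["norm_count"].sum()
        h[sums.index.to_numpy(dtype=int)] = sums.to_numpy()
    return h


def renormalize_excluding(
    pop: SamplePopulation,
    drop: frozenset[str] | set[str] = frozenset({PRE_EDITED}),
) -> SamplePopulation:
    """Drop the given classes and rescale the remainder to ``pop.scale``.

    Used to compare transcripts that have entered the editing pathway
    while ignoring swings in the pre-edited pool; pairwise abundance
    ratios of retained sequences are preserved exactly.
    """
    kept = pop.entries[~pop.entries["eclass"].isin(drop)].copy()
    total = kept["norm_count"].sum()
    if total == 0:
        raise EmptySampleError(f"sample {pop.sample_id!r} retains no sequences after dropping {sorted(drop)}")
    kept["norm_count"] *= pop.scale / total
    return SamplePopulation(pop.sample_id, pop.table, kept.reset_index(drop=True), pop.scale, dict(pop.qc))


def qc_summary(pops: list[SamplePopulation], max_fold: float = 2.0) -> pd.DataFrame:
    """Per-sample library QC with a two-fold standard-depth comparison flag.

    A sample is flagged when its standard-alignment total differs from that
    of any other sample by more than ``max_fold``.
    """
    rows = [{"sample_id": p.sample_id, **p.qc} for p in pops]
    df = pd.DataFrame(rows)
    std = df["standard"].to_numpy(dtype=float)
    df["depth_flag"] = [
        any(max(a, b) > max_fold * min(a, b) for j, b in enumerate(std) if j != i)
        for i, a in enumerate(std)
    ]
    return df
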