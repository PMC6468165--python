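"""Read collapsing, template-anchored alignment and editing landmarks.

Amplicon reads are anchored by exact match of the never-edited flanks
(both orientations tried), the editing domain is extracted and converted
to per-site U counts, and each sequence is classified against the
pre-edited / fully edited references.  Reads whose domain skeleton carries
any non-T mismatch are *non-standard alignments* and are excluded from all
downstream quantification, mirroring the exclusion applied to the original
amplicon libraries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .templates import EditingSiteTable, _gap_scan, as_dna, revcomp

PRE_EDITED = "pre_edited"
FULLY_EDITED = "fully_edited"
PARTIALLY_EDITED = "partially_edited"


@dataclass(frozen=True)
class UniqueSequence:
    sequence: str
    count: int


@dataclass(frozen=True)
class AlignmentOutcome:
    """Result of anchoring one sequence to a gene's templates.

    ``category`` is ``standard`` (skeleton matches; ``u_counts`` present),
    ``non_standard`` (anchored but skeleton mismatch) or ``unanchored``.
    """

    category: str
    u_counts: np.ndarray | None = None
    orientation: str = "forward"

    @property
    def is_standard(self) -> bool:
        return self.category == "standard"


@dataclass(frozen=True)
class EditingLandmarks:
    """Table-1 landmarks of a standard alignment.

    ESS: 5'-most site up to which the sequence matches the fully edited
    reference (0 = no canonical progress); JSS = ESS + 1; JES: 5'-most site
    with any editing action (difference from pre-edited); JL = junction
    length in sites.
    """

    eclass: str
    ess: int
    jes: int

    @property
    def jss(self) -> int:
        return self.ess + 1

    @property
    def jl(self) -> int:
        return max(0, self.jes - self.ess)


def collapse_reads(reads: Iterable[str]) -> list[UniqueSequence]:
    """Collapse identical sequences, keeping multiplicities.

    Order is deterministic: count descending, then lexicographic.
    """
    counts = Counter(as_dna(r) for r in reads)
    return [
        UniqueSequence(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def _extract(seq: str, table: EditingSiteTable) -> np.ndarray | None:
    # flanks are primer-defined never-edited regions: the outermost exact
    # placements (first flank5, last flank3) delimit the editing domain
    i5 = seq.find(table.flank5)
    if i5 == -1:
        return None
    i3 = seq.rfind(table.flank3)
    if i3 == -1:
        return None
    if i3 < i5 + len(table.flank5):
        i3 = seq.find(table.flank3, i5 + len(table.flank5))
        if i3 == -1:
            return None
    domain = seq[i5 + len(table.flank5):i3]
    skeleton, gaps = _gap_scan(table.flank5[-1] + domain + table.flank3[0])
    if skeleton[1:-1] != table.skeleton:
        return np.array([])  # sentinel: anchored but non-standard
    return np.array(gaps[::-1], dtype=int)


def align_to_templates(seq: str, table: EditingSiteTable) -> AlignmentOutcome:
    """Anchor a read by its flanks and convert it to per-site U counts.

    Forward orientation is tried first, then the reverse complement; the
    accepted orientation is recorded and counts always refer to the cDNA
    sense of the templates.
    """
    seq = as_dna(seq)
    for orientation, s in (("forward", seq), ("reverse_complement", revcomp(seq))):
        if len(s) < len(table.flank5) + len(table.flank3):
            continue
        u = _extract(s, table)
        if u is None:
            continue
        if u.size == 0:
            return AlignmentOutcome("non_standard", None, orientation)
        return AlignmentOutcome("standard", u, orientation)
    return AlignmentOutcome("unanchored")


def classify_and_landmark(u_counts, table: EditingSiteTable) -> EditingLandmarks:
    """Classify a standard alignment and compute its Table-1 landmarks."""
    u = np.asarray(u_counts, dtype=int)
    m = table.n_sites
    if len(u) != m:
        raise ValueError(f"u_counts has length {len(u)}, expected {m}")
    if np.array_equal(u, table.pre_U):
        eclass = PRE_EDITED
    elif np.array_equal(u, table.full_U):
        eclass = FULLY_EDITED
    else:
        eclass = PARTIALLY_EDITED
    matches_full = u == table.full_U
    ess = m if matches_full.all() else int(np.argmin(matches_full))
    differs_pre = np.nonzero(u != table.pre_U)[0]
    jes = int(differs_pre[-1]) + 1 if differs_pre.size else 0
    return EditingLandmarks(eclass, ess, jes)


def process_reads(
    reads: Iterable[str] | Sequence[UniqueSequence],
    table: EditingSiteTable,
) -> pd.DataFrame:
    """Collapse, align and landmark a read set into a per-sequence table.

    Returns one row per unique sequence with columns: sequence, count,
    category, orientation, eclass, ess (local), ess_label, jss, jes, jl and
    u_counts (comma-joined, 3'->5').  Non-standard and unanchored sequences
    keep their category with empty landmark fields.
    """
    reads = list(reads)
    if reads and isinstance(reads[0], UniqueSequence):
        unique = reads
    else:
        unique = collapse_reads(reads)
    rows = []
    for us in unique:
        out = align_to_templates(us.sequence, table)
        row = {
            "sequence": us.sequence,
            "count": us.count,
            "category": out.category,
            "orientation": out.orientation if out.category != "unanchored" else "",
            "eclass": "",
            "ess": pd.NA,
            "ess_label": pd.NA,
            "jss": pd.NA,
            "jes": pd.NA,
            "jl": pd.NA,
            "u_counts": "",
        }
        if out.is_standard:
            lm = classify_and_landmark(out.u_counts, table)
            row.update(
                eclass=lm.eclass,
                ess=lm.ess,
                ess_label=table.site_label(lm.ess),
                jss=lm.jss,
                jes=lm.jes,
                jl=lm.jl,
                u_counts=",".join(map(str, out.u_counts)),
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("ess", "ess_label", "jss", "jes", "jl"):
        df[col] = df[col].astype("Int64")
    return df
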