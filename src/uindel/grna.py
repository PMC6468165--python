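"""Guide-RNA:mRNA duplex modelling and templated-editing prediction.

Guide RNAs direct U-indel editing through antiparallel duplexes with the
mRNA that allow both Watson-Crick and G:U wobble pairs.  A guide anchors
through its 5' region to mRNA 3' of the block it edits; moving 3'->5'
along the mRNA, each encoded (non-T) mRNA base must pair the next guide
base, and maximal runs of unconsumed guide purines (A/G) between those
pairings template that many Us at the intervening editing site.  A guide
base left without a pairing partner is a *bulge*; bulging a single
mRNA-pairing U out of register shifts the guide by one base and can merge
two purine runs -- the misalignment mechanism that converts a templated
run of 5 Us into 9.

All sequences are handled in the DNA alphabet (U == T on input); guide
sequences are given 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .templates import EditingSiteTable, as_dna

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "T"), ("T", "G")}  # G:U wobble, T == U internally


def pair_class(mrna_base: str, grna_base: str, allow_gu: bool = True) -> str:
    """Classify one antiparallel base pair: ``WC``, ``GU`` or ``mismatch``."""
    p = (mrna_base, grna_base)
    if p in WC_PAIRS:
        return "WC"
    if allow_gu and p in GU_PAIRS:
        return "GU"
    return "mismatch"


@dataclass(frozen=True)
class GuideRNA:
    id: str
    sequence: str  # 5'->3'
    annotation: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", as_dna(self.sequence))


@dataclass
class GuideAlignment:
    """Ungapped antiparallel duplex between an mRNA window and a guide.

    ``offset`` places the guide's 3'-most aligned base: mRNA position
    ``offset + len(grna) - 1`` pairs guide base 0 (the guide 5' end pairs
    the mRNA 3' end of the window).  ``pair_classes`` runs 5'->3' along
    the mRNA over the overlap.
    """

    guide_id: str
    offset: int
    mrna_start: int
    mrna_end: int  # exclusive
    pair_classes: list[str]
    score: float

    @property
    def n_wc(self) -> int:
        return self.pair_classes.count("WC")

    @property
    def n_gu(self) -> int:
        return self.pair_classes.count("GU")

    @property
    def n_mismatch(self) -> int:
        return self.pair_classes.count("mismatch")


def duplex_align(
    mrna: str,
    grna: GuideRNA | str,
    offsets=None,
    allow_gu: bool = True,
    score_wc: float = 2.0,
    score_gu: float = 1.0,
    score_mismatch: float = -2.0,
) -> GuideAlignment:
    """Best ungapped antiparallel alignment of a guide onto an mRNA segment.

    ``offsets`` restricts the mRNA position paired with the guide's 3'
    terminal base (default: every placement with at least one overlapping
    base).  Ties in score break toward the 3'-most mRNA placement.
    """
    mrna = as_dna(mrna)
    gid, gseq = (grna.id, grna.sequence) if isinstance(grna, GuideRNA) else ("guide", as_dna(grna))
    L = len(gseq)
    if not mrna or not L:
        raise ValueError("empty sequence")
    if offsets is None:
        offsets = range(-L + 1, len(mrna))
    offsets = list(offsets)
    if not offsets:
        raise ValueError("empty offset range")
    best = None
    for off in offsets:
        # mRNA position off + k pairs guide base L-1-k
        lo = max(0, off)
        hi = min(len(mrna), off + L)
        if hi <= lo:
            continue
        classes = [
            pair_class(mrna[pos], gseq[L - 1 - (pos - off)], allow_gu)
            for pos in range(lo, hi)
        ]
        score = sum(
            score_wc if c == "WC" else score_gu if c == "GU" else score_mismatch
            for c in classes
        )
        cand = GuideAlignment(gid, off, lo, hi, classes, score)
        if best is None or score > best.score or (score == best.score and off > best.offset):
            best = cand
    if best is None:
        raise ValueError("no overlapping placement in offset range")
    return best


@dataclass(frozen=True)
class AnchorPlacement:
    """A contiguous anchor duplex between a guide's 5' region and the mRNA.

    ``mrna_start``/``mrna_end`` delimit the paired mRNA span (end
    exclusive); guide base 0 pairs mRNA position ``mrna_end - 1``.
    """

    guide_id: str
    mrna_start: int
    mrna_end: int
    length: int
    n_mismatch: int
    n_gu: int


def find_anchor(
    mrna: str,
    grna: GuideRNA | str,
    min_len: int = 6,
    allow_gu: bool = True,
    max_mismatch: int = 1,
    max_len: int | None = None,
) -> list[AnchorPlacement]:
    """Anchor placements of a guide's 5' region on an mRNA.

    For every mRNA position pairing the guide's 5' terminal base, the
    anchor is extended 5' along the mRNA (3' along the guide) while the
    mismatch budget holds (anchors end on paired bases, never on a
    mismatch, and ``max_len`` caps the extension); placements of maximal
    length >= ``min_len`` are returned ranked by (mismatches ascending,
    length descending, then 3'-most mRNA position).
    """
    mrna = as_dna(mrna)
    gid, gseq = (grna.id, grna.sequence) if isinstance(grna, GuideRNA) else ("guide", as_dna(grna))
    placements = []
    cap = len(gseq) if max_len is None else min(max_len, len(gseq))
    for j in range(len(mrna) - 1, min_len - 2, -1):
        # guide base k pairs mRNA position j - k
        mism = gu = 0
        best = None
        for k in range(min(cap, j + 1)):
            c = pair_class(mrna[j - k], gseq[k], allow_gu)
            if c == "mismatch":
                mism += 1
                if mism > max_mismatch:
                    break
                continue
            if c == "GU":
                gu += 1
            if k + 1 >= min_len:
                best = (k + 1, mism, gu)
        if best:
            length, n_mis, n_gu = best
            placements.append(AnchorPlacement(gid, j - length + 1, j + 1, length, n_mis, n_gu))
    placements.sort(key=lambda a: (a.n_mismatch, -a.length, -a.mrna_end))
    return placements


@dataclass
class TemplatingResult:
    """Outcome of walking a guide 3'->5' across a skeleton window.

    ``u_counts[k]`` is the number of Us templated at the editing site
    immediately 3' of window base ``k`` (window given 3'->5').  When a
    skeleton base cannot pair any remaining guide base, ``failed_at``
    names that window index; Us templated 3' of the unpairable base
    before the register broke are still reported, so ``u_counts`` may be
    one longer than ``consumed``.  ``exhausted_at`` marks a guide that
    ran out of bases (a trailing purine run is likewise reported).
    ``pairs`` records (window index, guide index, class) for consumed
    skeleton pairings and (site index, guide index, 'U') for templated Us.
    """

    u_counts: np.ndarray
    consumed: int  # window bases successfully paired
    failed_at: int | None = None
    exhausted_at: int | None = None
    pairs: list[tuple] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.failed_at is None


def predict_templated_block(
    grna: GuideRNA | str,
    window: str,
    start: int = 0,
    allow_gu: bool = True,
    bulge: int | None = None,
) -> TemplatingResult:
    """Predict the per-site U counts a guide templates over a skeleton window.

    ``window`` is the sequence of encoded (non-T) mRNA bases to be paired,
    given 3'->5' (the direction of editing); ``start`` is the index of the
    first guide base 3' of the anchor (guide bases before it are the
    anchor and are not consumed here).  ``bulge`` names a guide base (by
    index in the full guide) bulged out of the duplex and skipped by the
    walk -- the single-base misalignment mode.

    A guide G is consumed by the next skeleton base when that base is C
    (Watson-Crick) or, with wobble enabled, when the walk needs it to pair
    a templated U; otherwise it joins the purine run templating U
    insertions.  The greedy register-following walk is deterministic.
    """
    gseq = grna.sequence if isinstance(grna, GuideRNA) else as_dna(grna)
    window = as_dna(window)
    counts = []
    pairs = []
    pos = start
    for k, base in enumerate(window):
        run = 0
        while True:
            if pos >= len(gseq):
                # guide ran out: a trailing purine run still templates Us
                if run:
                    counts.append(run)
                return TemplatingResult(np.array(counts, dtype=int), k, exhausted_at=k, pairs=pairs)
            if pos == bulge:
                pos += 1
                continue
            gb = gseq[pos]
            if pair_class(base, gb, allow_gu) != "mismatch":
                # greedy: a guide G pairs a skeleton C rather than extending the run
                counts.append(run)
                pairs.append((k, pos, pair_class(base, gb, allow_gu)))
                pos += 1
                break
            if gb in "AG":
                run += 1
                pos += 1
                continue
            # unpairable skeleton base: Us inserted 3' of it before the stall
            # are already templated, then the duplex register breaks
            counts.append(run)
            return TemplatingResult(
                np.array(counts, dtype=int), k, failed_at=k, pairs=pairs
            )
    return TemplatingResult(np.array(counts, dtype=int), len(window), pairs=pairs)


def templated_duplex_classes(
    grna: GuideRNA | str,
    window: str,
    result: TemplatingResult,
    start: int = 0,
    allow_gu: bool = True,
    bulge: int | None = None,
) -> list[str]:
    """Re-pair a templating result against its guide, base by base.

    Renders the edited mRNA implied by ``result`` (window bases with the
    templated Us between them, 3'->5') and classifies each base against
    the guide bases consumed by the walk, in walk order.  A correct
    templated block forms a duplex with WC and G:U pairs only.
    """
    gseq = grna.sequence if isinstance(grna, GuideRNA) else as_dna(grna)
    window = as_dna(window)
    classes = []
    pos = start
    for k in range(len(result.u_counts)):
        for _ in range(int(result.u_counts[k])):
            while pos == bulge:
                pos += 1
            classes.append(pair_class("T", gseq[pos], allow_gu))
            pos += 1
        if k < result.consumed:
            while pos == bulge:
                pos += 1
            classes.append(pair_class(window[k], gseq[pos], allow_gu))
            pos += 1
    return classes


@dataclass
class GuideCandidate:
    """A guide able to explain (part of) an observed junction."""

    guide_id: str
    anchor: AnchorPlacement
    sites: tuple  # local site indices covered by the walk, 3'->5'
    n_explained: int
    explained_mask: tuple
    predicted: tuple
    observed: tuple
    duplex_score: float


def search_grna_db(
    u_counts,
    table: EditingSiteTable,
    guides: list[GuideRNA],
    min_anchor: int = 6,
    max_mismatch: int = 1,
    allow_gu: bool = True,
    max_anchors_per_guide: int = 50,
) -> list[GuideCandidate]:
    """Rank guides by how many editing sites of an observed sequence they explain.

    The observed U-count vector is rendered to its mRNA sequence; each
    guide is anchored on it through a fixed-length ``min_anchor`` 5'
    anchor (so the templating register begins immediately 5' of the
    anchor), the templated block is predicted along the walk and compared
    site-by-site with the observed counts.  Candidates are ranked by
    number of exactly explained sites, then duplex score.  Guides
    annotated to other transcripts are searched all the same: promiscuous
    guide utilization is a real phenomenon.
    """
    u = np.asarray(u_counts, dtype=int)
    read = table.render_read(u)
    m = table.n_sites
    dom_start = len(table.flank5)
    dom = read[dom_start:len(read) - len(table.flank3)]
    skel_pos = [dom_start + i for i, b in enumerate(dom) if b != "T"]
    candidates = []
    for g in guides:
        anchors = find_anchor(read, g, min_anchor, allow_gu, max_mismatch,
                              max_len=min_anchor)[:max_anchors_per_guide]
        for anchor in anchors:
            inside = [j for j, p in enumerate(skel_pos) if p < anchor.mrna_start]
            if not inside:
                continue
            j_last = inside[-1]
            window = table.skeleton[:j_last + 1][::-1]  # 3'->5'
            first_site = m - 1 - j_last  # site 3' of strict[j_last]... see below
            # site 3'-adjacent to strict[j] is gap j+1 == site m-1-j
            res = predict_templated_block(g, window, start=anchor.length, allow_gu=allow_gu)
            n_pred = min(len(res.u_counts), m - first_site + 1)
            if n_pred == 0:
                continue
            sites = [first_site + k for k in range(n_pred)]
            pred = res.u_counts[:n_pred]
            obs = u[[s - 1 for s in sites]]
            explained = pred == obs
            dup = duplex_align(
                read[anchor.mrna_start:anchor.mrna_end], g.sequence[:anchor.length],
                offsets=[0], allow_gu=allow_gu,
            )
            candidates.append(GuideCandidate(
                g.id, anchor, tuple(sites), int(explained.sum()),
                tuple(bool(b) for b in explained),
                tuple(int(x) for x in pred), tuple(int(x) for x in obs),
                dup.score,
            ))
    candidates.sort(key=lambda c: (-c.n_explained, -c.duplex_score, c.guide_id))
    return candidates
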