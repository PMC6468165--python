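"""Synthetic amplicon populations with known editing ground truth.

The generator emulates the statistical structure of an edited-mRNA
amplicon library: a mixture of pre-edited, partially edited and fully
edited transcripts; a categorical distribution of editing stop sites with
optional spikes at designated pause sites; junction content produced by
several mechanisms (no junction, random per-site U perturbation,
misalignment of the cognate guide, templating by an alternative guide);
and a per-base substitution error on non-T positions, which by
construction produces non-standard or unanchored alignments only.

Draw order is part of the seed contract and is fixed per replicate:
class counts, then stop-site counts, then per-stop-site mechanism counts,
then perturbation details (in ascending stop-site order), then T-run
jitter reassignment, then error thinning.  Replicate ``k`` of a
population seeded with ``seed`` uses
``numpy.random.default_rng(SeedSequence(seed).spawn(n_replicates)[k])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quantify import DEFAULT_SCALE, SamplePopulation
from .reads import classify_and_landmark
from .templates import EditingSiteTable, table_from_counts

# ---------------------------------------------------------------------------
# demonstration gene

_DEMO_SKELETON = "GACGAGCAGAGCAGGCGAACGAGACGAGA"
_DEMO_PRE_U = (0, 0, 0, 0, 1, 0, 2, 0, 0, 1, 0, 0, 0, 2, 0,
               0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
_DEMO_FULL_U = (0, 0, 1, 2, 1, 3, 0, 1, 2, 3, 1, 5, 4, 1, 1,
                0, 2, 1, 0, 2, 1, 3, 1, 0, 2, 1, 1, 2, 1, 0)


def demo_gene() -> EditingSiteTable:
    """A synthetic minimally-edited gene used throughout examples and tests.

    30 editing sites; mostly U insertions with three deletion sites and a
    handful of never-edited sites.  Sites 12/13 carry canonical runs of
    5 and 4 Us separated by an encoded A, reproducing the configuration
    in which a one-U guide bulge merges two templated runs into 9 Us.
    ``es_offset=436`` so local sites 12/13 carry published labels
    ES447/ES448.  The gene is synthetic: it mimics the structure of a
    minimally edited mitochondrial transcript, not any real sequence.
    """
    return table_from_counts(
        "demo", _DEMO_SKELETON, _DEMO_PRE_U, _DEMO_FULL_U,
        flank5="GGCCAGTACC", flank3="CCATGGTTGG", es_offset=436,
    )


def guide_for(
    table: EditingSiteTable,
    u_counts,
    es_lo: int,
    es_hi: int,
    anchor_len: int = 10,
    gid: str = "guide",
    annotation: str = "",
):
    """Construct the guide RNA that would template the given editing.

    Returns the exact antiparallel complement of the rendered mRNA from
    the skeleton base 5' of site ``es_hi`` through ``anchor_len`` bases 3'
    of site ``es_lo``: its 5' region anchors 3' of the block and its
    purine runs template the ``u_counts`` at sites ``es_lo``..``es_hi``.
    """
    from .grna import GuideRNA
    from .templates import revcomp

    if not 1 <= es_lo <= es_hi <= table.n_sites - 1:
        raise ValueError("guide window must lie within sites 1..m-1")
    read = table.render_read(u_counts)
    m = table.n_sites
    dom_start = len(table.flank5)
    dom = read[dom_start:len(read) - len(table.flank3)]
    skel_pos = [dom_start + i for i, b in enumerate(dom) if b != "T"]
    j_lo, j_hi = m - es_lo, m - es_hi
    anchor_start = skel_pos[j_lo] if j_lo <= m - 2 else len(read) - len(table.flank3)
    segment = read[skel_pos[j_hi - 1]:anchor_start + anchor_len]
    return GuideRNA(gid, revcomp(segment), annotation)


def demo_guides() -> list:
    """Guide set for the demo gene: two cognate guides covering the domain,
    the alternative guide behind the generator's ``alt`` junction
    mechanism (annotated to another transcript: guide utilization can be
    promiscuous), and the misalignment-prone cognate guide spanning the
    5-U/4-U run pair."""
    table = demo_gene()
    jm = JunctionModel()
    alt_u = np.array(table.pre_U)
    alt_u[:jm.alt_ess] = table.full_U[:jm.alt_ess]
    for site, count in jm.alt_pattern:
        alt_u[site - 1] = count
    return [
        guide_for(table, table.full_U, 1, 10, 10, "gDemo-1", "cognate, initiating"),
        guide_for(table, table.full_U, 16, 29, 10, "gDemo-2", "cognate, second block"),
        guide_for(table, table.full_U, 11, 14, 8, "gDemo-mis", "cognate, covers ES446-449 run pair"),
        guide_for(table, alt_u, 6, 14, 10, "gDemo-alt", "identified on transcript CRx"),
    ]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class JunctionModel:
    """Mixture of junction-generating mechanisms for partially edited reads.

    ``p_none``: pause with pre-edited sequence 5' of the stop site (only
    available once some canonical editing has occurred, otherwise the read
    would simply be pre-edited); ``p_perturb``: random per-site U jitter
    around the canonical counts over a junction of random length;
    ``p_misalign``: cognate-guide misalignment placing a non-canonical run
    at the site 5' of ``misalign_ess`` (with probability ``hybrid_prob``
    followed by canonically edited sequence, a 'hybrid'); ``p_alt``:
    templating by an alternative guide, substituting ``alt_pattern`` 5' of
    ``alt_ess``.  Mechanisms whose preconditions fail at a drawn stop site
    fall back to perturbation.
    """

    p_none: float = 0.35
    p_perturb: float = 0.45
    p_misalign: float = 0.10
    p_alt: float = 0.10
    jl_weights: tuple = (0.30, 0.18, 0.10, 0.05, 0.03, 0.02, 0.02,
                         0.02, 0.03, 0.05, 0.08, 0.07, 0.05)  # JL = 1..13
    jitter: int = 2
    misalign_ess: int = 11
    misalign_count: int = 9
    hybrid_prob: float = 0.5
    hybrid_jes_sites: tuple = (22, 23)
    alt_ess: int = 5
    alt_pattern: tuple = ((6, 1), (7, 1), (8, 1), (9, 0), (10, 2),
                          (11, 0), (12, 5), (13, 4), (14, 1))

    @property
    def probs(self) -> np.ndarray:
        p = np.array([self.p_none, self.p_perturb, self.p_misalign, self.p_alt])
        if (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("junction mechanism probabilities must be a distribution")
        return p


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated sample group.

    Defaults reflect a wild-type amplicon study: 100 000 reads per
    replicate, five replicates, roughly a quarter each of pre-edited and
    fully edited transcripts with the partially edited majority in
    between, uniform pausing over the editable stop sites unless
    ``spikes`` multiplies designated sites, and a 0.2% per-base
    substitution error on non-T positions.
    """

    table: EditingSiteTable
    depth: int = 100_000
    n_replicates: int = 5
    p_pre: float = 0.25
    p_full: float = 0.25
    stop_site_weights: tuple | None = None  # over stop sites 0..m-1; None = uniform over eligible
    spikes: tuple = ()  # ((site, multiplier), ...)
    junctions: JunctionModel = field(default_factory=JunctionModel)
    epsilon: float = 0.002
    t_jitter_rate: float = 0.0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 <= self.p_pre <= 1 and 0 <= self.p_full <= 1 and self.p_pre + self.p_full <= 1):
            raise ValueError("class probabilities must be in [0,1] and sum to <= 1")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must be in [0,1)")
        self.junctions.probs  # validates

    @property
    def p_partial(self) -> float:
        return 1.0 - self.p_pre - self.p_full

    def stop_weights(self) -> np.ndarray:
        """Normalized stop-site distribution over eligible stop sites.

        A stop site s is eligible when site s+1 requires editing (so the
        intended stop is a genuine stop).  Spike multipliers apply on top
        of the base weights.
        """
        m = self.table.n_sites
        req = self.table.requires_editing
        eligible = np.array([s for s in range(m) if req[s]])  # req[s] <-> site s+1
        if self.stop_site_weights is not None:
            w = np.asarray(self.stop_site_weights, dtype=float)
            if len(w) != m:
                raise ValueError(f"stop_site_weights must have length {m}")
            w = w.copy()
            w[~np.isin(np.arange(m), eligible)] = 0.0
        else:
            w = np.zeros(m)
            w[eligible] = 1.0
        for site, mult in self.spikes:
            w[site] *= mult
        if w.sum() <= 0:
            raise ValueError("stop-site weights sum to zero")
        return w / w.sum()


@dataclass(frozen=True)
class KnockdownEffect:
    """Designated effect of an editing-factor depletion."""

    sites: tuple = ()
    multiplier: float = 1.0
    class_shift: tuple | None = None  # (p_pre, p_full)


# ---------------------------------------------------------------------------
# generation


@dataclass
class SimulatedSample:
    """One simulated replicate: unique-vector ground truth + lazy reads.

    ``truth`` has one row per (mechanism, U-count vector): u_counts,
    count (intended reads), standard_count (reads surviving the error
    process unmutated), mechanism, eclass, ess, jss, jes, jl.  Landmarks
    are derived from the true U-count vector, so at epsilon=0 they are by
    construction what a correct pipeline must recover from the emitted
    sequences.
    """

    sample_id: str
    params: SimulationParams
    truth: pd.DataFrame
    _error_seed: np.random.SeedSequence

    @property
    def table(self) -> EditingSiteTable:
        return self.params.table

    def reads(self) -> list[tuple[str, int]]:
        """Collapsed (sequence, count) list including substitution errors."""
        table = self.table
        out: dict[str, int] = {}
        rng = np.random.default_rng(self._error_seed)
        eps = self.params.epsilon
        cols = zip(self.truth["u_counts"], self.truth["count"], self.truth["standard_count"])
        for u, n, n_std in cols:
            seq = table.render_read(u)
            if n_std:
                out[seq] = out.get(seq, 0) + int(n_std)
            for _ in range(int(n - n_std)):
                out_seq = _mutate(seq, eps, rng)
                out[out_seq] = out.get(out_seq, 0) + 1
        return sorted(out.items(), key=lambda kv: (-kv[1], kv[0]))

    def expanded_reads(self) -> list[str]:
        return [s for s, n in self.reads() for _ in range(n)]

    def to_population(self, scale: float = DEFAULT_SCALE) -> SamplePopulation:
        """Normalized population of the standard (error-free) alignments.

        Equivalent to running the alignment pipeline on ``reads()`` and
        normalizing: mutated reads carry non-T mismatches and are excluded
        there, which is what ``standard_count`` already accounts for.
        """
        t = self.truth[self.truth["standard_count"] > 0]
        total = t["standard_count"].sum()
        if total == 0:
            raise ValueError("no standard reads in simulated sample")
        entries = pd.DataFrame({
            "count": t["standard_count"].to_numpy(),
            "norm_count": t["standard_count"].to_numpy() * (scale / total),
            "eclass": t["eclass"].to_numpy(),
            "ess": t["ess"].to_numpy(),
            "jss": t["jss"].to_numpy(),
            "jes": t["jes"].to_numpy(),
            "jl": t["jl"].to_numpy(),
            "u_counts": t["u_counts"].to_numpy(),
        })
        qc = {
            "total": int(self.truth["count"].sum()),
            "unique": int(len(t)),  # unique standard vectors; error reads not rendered here
            "standard": int(total),
            "non_standard": 0,
            "unanchored": 0,
        }
        return SamplePopulation(self.sample_id, self.params.table, entries, scale, qc)

    def write_fasta(self, path) -> None:
        from .io import write_reads_fasta
        write_reads_fasta(path, self.reads(), prefix=self.sample_id)

    def write_truth_tsv(self, path) -> None:
        df = self.truth.copy()
        df["u_counts"] = df["u_counts"].map(lambda u: ",".join(map(str, u)))
        df.to_csv(path, sep="\t", index=False)


def _n_non_t(table: EditingSiteTable) -> int:
    """Number of non-T positions of any read of this gene (U-count independent)."""
    return (sum(b != "T" for b in table.flank5)
            + sum(b != "T" for b in table.flank3)
            + len(table.skeleton))


def _mutate(seq: str, eps: float, rng: np.random.Generator) -> str:
    """Apply at least one substitution at non-T positions of one read."""
    positions = [i for i, b in enumerate(seq) if b != "T"]
    while True:
        hits = np.nonzero(rng.random(len(positions)) < eps)[0]
        if hits.size:
            break
    chars = list(seq)
    for h in hits:
        i = positions[int(h)]
        alternatives = [b for b in "ACG" if b != chars[i]]
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _perturb_vectors(
    table: EditingSiteTable, s: int, n: int, jm: JunctionModel, rng: np.random.Generator
) -> np.ndarray:
    """Random-perturbation junction vectors for n reads stopping at site s."""
    m = table.n_sites
    full, pre = table.full_U, table.pre_U
    max_jl = len(jm.jl_weights)
    jl = rng.choice(max_jl, size=n, p=np.asarray(jm.jl_weights) / np.sum(jm.jl_weights)) + 1
    jl = np.minimum(jl, m - s)
    width = int(min(max_jl, m - s))
    delta = rng.integers(-jm.jitter, jm.jitter + 1, size=(n, max_jl))
    v = np.clip(full[s:s + width][None, :] + delta[:, :width], 0, None)
    # the junction must start 5' of the stop site (u != full there) ...
    one = jl == 1
    while True:
        bad = (v[:, 0] == full[s]) | (one & (v[:, 0] == pre[s]))
        if not bad.any():
            break
        v[bad, 0] += 1
    # ... and its 5'-most site is its JES (u != pre there)
    rows = np.arange(n)
    jes_col = jl - 1
    jes_pre = pre[s + jes_col]
    jes_full_guard = np.where(one, full[s], -1)
    while True:
        vv = v[rows, jes_col]
        bad = (vv == jes_pre) | (vv == jes_full_guard)
        if not bad.any():
            break
        v[rows[bad], jes_col[bad]] += 1
    out = np.empty((n, m), dtype=np.int16)
    out[:, :] = pre[None, :]
    out[:, :s] = full[None, :s]
    cols_in_junction = np.arange(width)[None, :] < jl[:, None]
    block = out[:, s:s + width]
    block[cols_in_junction] = v[cols_in_junction]
    out[:, s:s + width] = block
    return out


def _misalign_vectors(
    table: EditingSiteTable, s: int, n: int, jm: JunctionModel, rng: np.random.Generator
) -> np.ndarray:
    m = table.n_sites
    full, pre = table.full_U, table.pre_U
    hybrid = rng.random(n) < jm.hybrid_prob
    jes_sites = np.array(jm.hybrid_jes_sites)
    h = jes_sites[rng.integers(len(jes_sites), size=n)]
    out = np.empty((n, m), dtype=np.int16)
    out[:, :] = pre[None, :]
    out[:, :s] = full[None, :s]
    out[:, s] = jm.misalign_count
    for i in range(n):
        if hybrid[i]:
            out[i, s + 1:h[i]] = full[s + 1:h[i]]
    return out


def _alt_vectors(table: EditingSiteTable, s: int, n: int, jm: JunctionModel) -> np.ndarray:
    m = table.n_sites
    full, pre = table.full_U, table.pre_U
    v = pre.copy().astype(np.int16)
    v[:s] = full[:s]
    for site, count in jm.alt_pattern:
        v[site - 1] = count
    return np.tile(v, (n, 1))


def _unique_rows(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row deduplication via lexsort (fast path for small-int matrices)."""
    if len(arr) == 0:
        return arr, np.array([], dtype=int)
    order = np.lexsort(arr.T[::-1])
    srt = arr[order]
    change = np.any(srt[1:] != srt[:-1], axis=1)
    starts = np.concatenate(([0], np.nonzero(change)[0] + 1))
    counts = np.diff(np.concatenate((starts, [len(arr)])))
    return srt[starts], counts


def _landmark_frame(uniq: np.ndarray, cnt: np.ndarray, mechanism, table: EditingSiteTable) -> pd.DataFrame:
    """Landmark unique U-count row vectors (vectorized over rows)."""
    uniq = np.asarray(uniq)
    n, m = uniq.shape
    full, pre = table.full_U, table.pre_U
    matches_full = uniq == full[None, :]
    all_full = matches_full.all(axis=1)
    ess = np.where(all_full, m, matches_full.argmin(axis=1))
    differs_pre = uniq != pre[None, :]
    any_diff = differs_pre.any(axis=1)
    jes = np.where(any_diff, m - differs_pre[:, ::-1].argmax(axis=1), 0)
    is_pre = ~any_diff
    eclass = np.where(is_pre, "pre_edited",
                      np.where(all_full, "fully_edited", "partially_edited"))
    jl = np.maximum(0, jes - ess)
    return pd.DataFrame({
        "u_counts": [tuple(v) for v in uniq.tolist()],
        "count": cnt,
        "mechanism": mechanism,
        "eclass": eclass,
        "ess": ess,
        "jss": ess + 1,
        "jes": jes,
        "jl": jl,
    })


def _generate_replicate(
    params: SimulationParams, seed: np.random.SeedSequence, sample_id: str
) -> SimulatedSample:
    table = params.table
    m = table.n_sites
    rng = np.random.default_rng(seed)
    jm = params.junctions
    req = table.requires_editing
    first_edit_site = int(np.argmax(req)) + 1  # 'none' needs canonical progress
    # 1. class counts
    n_pre, n_partial, n_full = rng.multinomial(
        params.depth, [params.p_pre, params.p_partial, params.p_full]
    )
    # 2. stop-site counts
    w = params.stop_weights()
    ess_counts = rng.multinomial(n_partial, w)
    # 3. mechanism counts per stop site (ascending), with fallbacks to perturb
    mech_plan: list[tuple[int, str, int]] = []
    base_probs = jm.probs
    for s in np.nonzero(ess_counts)[0]:
        p = base_probs.copy()
        if s < first_edit_site:
            p[1] += p[0]; p[0] = 0.0
        if s != jm.misalign_ess:
            p[1] += p[2]; p[2] = 0.0
        if s != jm.alt_ess:
            p[1] += p[3]; p[3] = 0.0
        counts = rng.multinomial(int(ess_counts[s]), p)
        for mech, c in zip(("none", "perturb", "misalign", "alt"), counts):
            if c:
                mech_plan.append((int(s), mech, int(c)))
    # 4. build vectors; per-read random vectors are deduplicated in one pass
    frames = []
    full, pre = table.full_U, table.pre_U
    mech_codes = {"none": 0, "perturb": 1, "misalign": 2, "alt": 3}
    mech_names = np.array(["none", "perturb", "misalign", "alt"])
    if n_pre:
        frames.append(_landmark_frame(pre[None, :], np.array([n_pre]), "pre", table))
    if n_full:
        frames.append(_landmark_frame(full[None, :], np.array([n_full]), "full", table))
    per_read_blocks = []
    for s, mech, c in mech_plan:
        if mech == "none":
            v = pre.copy().astype(np.int16)
            v[:s] = full[:s]
            frames.append(_landmark_frame(v[None, :], np.array([c]), mech, table))
        elif mech == "alt":
            frames.append(_landmark_frame(_alt_vectors(table, s, 1, jm), np.array([c]), mech, table))
        else:
            vec = (_perturb_vectors if mech == "perturb" else _misalign_vectors)(
                table, s, c, jm, rng)
            tagged = np.empty((c, m + 1), dtype=np.int16)
            tagged[:, 0] = mech_codes[mech]
            tagged[:, 1:] = vec
            per_read_blocks.append(tagged)
    if per_read_blocks:
        allv = np.vstack(per_read_blocks)
        uniq, cnt = _unique_rows(allv)
        frames.append(_landmark_frame(uniq[:, 1:], cnt, mech_names[uniq[:, 0]], table))
    truth = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["u_counts", "count", "mechanism", "eclass", "ess", "jss", "jes", "jl"])
    # 5. optional T-run jitter (plausible-looking mis-edits, still standard)
    if params.t_jitter_rate > 0:
        truth = _apply_t_jitter(truth, table, params.t_jitter_rate, rng)
    # 6. substitution-error thinning (number of reads per row that mutate)
    if params.epsilon > 0:
        p_err = 1.0 - (1.0 - params.epsilon) ** _n_non_t(table)
        n_err = rng.binomial(truth["count"].to_numpy(), p_err)
        truth["standard_count"] = truth["count"].to_numpy() - n_err
    else:
        truth["standard_count"] = truth["count"]
    return SimulatedSample(sample_id, params, truth, seed.spawn(1)[0])


def _apply_t_jitter(truth, table, rate, rng):
    m = table.n_sites
    rows = truth.to_dict("records")
    extra = []
    for row in rows:
        k = rng.binomial(row["count"], rate)
        if not k:
            continue
        row["count"] -= int(k)
        sites = rng.integers(m, size=int(k))
        deltas = rng.choice([-1, 1], size=int(k))
        for site, d in zip(sites, deltas):
            v = np.array(row["u_counts"], dtype=int)
            v[site] = max(0, v[site] + d)
            lm = classify_and_landmark(v, table)
            extra.append({
                "u_counts": tuple(int(x) for x in v), "count": 1,
                "mechanism": row["mechanism"] + "+tjitter",
                "eclass": lm.eclass, "ess": lm.ess, "jss": lm.jss,
                "jes": lm.jes, "jl": lm.jl,
            })
    out = pd.DataFrame([r for r in rows if r["count"] > 0] + extra)
    return out.groupby(
        ["u_counts", "mechanism", "eclass", "ess", "jss", "jes", "jl"], as_index=False, sort=False
    )["count"].sum()[["u_counts", "count", "mechanism", "eclass", "ess", "jss", "jes", "jl"]]


def generate_population(
    params: SimulationParams, seed: int | np.random.SeedSequence, id_prefix: str = "rep"
) -> list[SimulatedSample]:
    """Generate ``params.n_replicates`` replicate samples.

    Deterministic: identical params and seed give byte-identical reads
    and truth tables.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(params.n_replicates)
    return [
        _generate_replicate(params, child, f"{id_prefix}{k + 1}")
        for k, child in enumerate(children)
    ]


def generate_knockdown_pair(
    params: SimulationParams,
    effect: KnockdownEffect,
    seed: int | np.random.SeedSequence,
    n_induced: int = 2,
    n_uninduced: int = 8,
):
    """Uninduced and induced replicate sets for a knockdown comparison.

    Uninduced replicates follow ``params``; induced replicates multiply
    the stop-site weights at ``effect.sites`` by ``effect.multiplier``
    and/or shift the class mixture to ``effect.class_shift``.  Returns
    ``(uninduced, induced, effect)``; the effect records the designated
    exacerbated pause sites.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    c_unind, c_ind = ss.spawn(2)
    unind_params = replace(params, n_replicates=n_uninduced)
    spikes = tuple(params.spikes) + tuple((s, effect.multiplier) for s in effect.sites)
    kwargs = {"n_replicates": n_induced, "spikes": spikes}
    if effect.class_shift is not None:
        kwargs["p_pre"], kwargs["p_full"] = effect.class_shift
    ind_params = replace(params, **kwargs)
    uninduced = generate_population(unind_params, c_unind, id_prefix="uninduced")
    induced = generate_population(ind_params, c_ind, id_prefix="induced")
    return uninduced, induced, effect
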