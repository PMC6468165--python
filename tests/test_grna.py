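import numpy as np
import pytest

from uindel.grna import (
    GuideRNA,
    duplex_align,
    find_anchor,
    pair_class,
    predict_templated_block,
    search_grna_db,
    templated_duplex_classes,
)
from uindel.simulate import JunctionModel, demo_guides, guide_for
from uindel.templates import revcomp


def _guide(name):
    return next(g for g in demo_guides() if g.id == name)


class TestDuplexAlign:
    def test_perfect_complement(self):
        mrna = "ACGTACGGACGT"
        out = duplex_align(mrna, revcomp(mrna), offsets=[0])
        assert out.n_wc == 12 and out.n_mismatch == 0

    def test_single_gu_wobble(self):
        mrna = "ACGTACGGACGT"
        g = list(revcomp(mrna))
        i = next(k for k, b in enumerate(g) if b == "C")  # pairs an mRNA G
        g[i] = "T"  # G:U instead of G:C
        out = duplex_align(mrna, "".join(g), offsets=[0])
        assert (out.n_wc, out.n_gu, out.n_mismatch) == (11, 1, 0)

    def test_best_offset_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        mrna = "".join(rng.choice(list("ACGT"), 60))
        guide = revcomp(mrna[30:45])
        best = duplex_align(mrna, guide)
        # independent enumeration of every placement
        def score_at(off):
            L = len(guide)
            s = 0.0
            for pos in range(max(0, off), min(len(mrna), off + L)):
                c = pair_class(mrna[pos], guide[L - 1 - (pos - off)])
                s += {"WC": 2.0, "GU": 1.0, "mismatch": -2.0}[c]
            return s
        scores = {off: score_at(off) for off in range(-14, 60)}
        assert best.score == max(scores.values())
        assert best.offset == 30

    def test_strand_role_swap_invariance(self):
        """The duplex is symmetric: aligning the mRNA onto the guide at the
        mirrored offset scores identically (pair classes are unordered)."""
        rng = np.random.default_rng(1)
        mrna = "".join(rng.choice(list("ACGT"), 30))
        guide = "".join(rng.choice(list("ACGT"), 12))
        a = duplex_align(mrna, guide, offsets=[5])
        b = duplex_align(guide, mrna, offsets=[5 + len(guide) - len(mrna)])
        assert a.score == pytest.approx(b.score)
        assert a.n_gu == b.n_gu and a.n_mismatch == b.n_mismatch

    def test_empty_offsets_rejected(self):
        with pytest.raises(ValueError):
            duplex_align("ACGT", "ACGT", offsets=[])


class TestFindAnchor:
    def test_cognate_guide_anchors_at_construction_site(self, demo):
        read = demo.render_read(demo.full_U)
        g = _guide("gDemo-2")
        anchors = find_anchor(read, g, min_len=8, max_mismatch=0)
        assert anchors
        best = anchors[0]
        # guide built with a 10-base anchor region: 5' end pairs edited mRNA
        assert best.n_mismatch == 0 and best.length >= 10

    def test_mismatch_budget(self):
        mrna = "AAAAGGGCCCTTT"
        anchor = revcomp(mrna[4:12])
        broken = "X"
        g = anchor[:3] + ("A" if anchor[3] != "A" else "C") + anchor[4:]
        # ensure we actually broke a pair
        assert g != anchor
        assert find_anchor(mrna, g, min_len=8, max_mismatch=0) == []
        found = find_anchor(mrna, g, min_len=7, max_mismatch=1)
        assert found and found[0].n_mismatch <= 1

    def test_gu_plus_one_mismatch_tolerated(self):
        mrna = "CCCCAGAGAGACCCC"
        anchor = revcomp(mrna[4:12])  # pairs AGAGAGAC region
        g = list(anchor)
        # turn one C (pairing mRNA G) into T -> G:U pair
        i = next(k for k, b in enumerate(g) if b == "C")
        g[i] = "T"
        # and break one other pair outright
        j = next(k for k, b in enumerate(g) if b == "T" and k != i)
        g[j] = "C"
        found = find_anchor(mrna, "".join(g), min_len=6, allow_gu=True, max_mismatch=1)
        assert found
        assert found[0].n_gu >= 1 and found[0].n_mismatch <= 1
        assert find_anchor(mrna, "".join(g), min_len=8, allow_gu=False, max_mismatch=0) == []


class TestTemplating:
    @pytest.mark.parametrize("k", [0, 1, 5])
    def test_purine_run_templates_that_many_us(self, k):
        # window: two As; guide: anchorless walk pairing T, then k purines, then T
        guide = "T" + "A" * k + "T"
        res = predict_templated_block(guide, "AA", start=0)
        assert res.ok and res.consumed == 2
        assert res.u_counts.tolist() == [0, k]

    def test_canonical_five_u_block_at_es447(self, demo):
        g = _guide("gDemo-mis")
        window = demo.skeleton[:demo.n_sites - 11][::-1]
        res = predict_templated_block(g, window, start=8)
        # sites 11..14 in editing order: canonical counts, 5 Us at ES447
        assert res.u_counts.tolist() == demo.full_U[10:14].tolist()
        assert res.u_counts[1] == 5

    def test_single_u_bulge_converts_5_to_9(self, demo):
        g = _guide("gDemo-mis")
        window = demo.skeleton[:demo.n_sites - 11][::-1]
        bulge = g.sequence.index("AAAAATAAAA") + 5
        res = predict_templated_block(g, window, start=8, bulge=bulge)
        assert res.u_counts.tolist()[:2] == [1, 9]
        assert res.failed_at is not None  # register broken 5' of the run

    def test_deletion_sites_templated_to_zero(self, demo):
        # site 7 encodes 2 Us in the pre-edited mRNA and 0 in the edited one;
        # the cognate guide simply templates no Us there
        g = _guide("gDemo-1")
        window = demo.skeleton[:demo.n_sites - 1][::-1]
        res = predict_templated_block(g, window, start=10)
        assert res.u_counts[6] == 0
        assert res.u_counts.tolist() == demo.full_U[:len(res.u_counts)].tolist()

    def test_unpairable_base_reports_position(self):
        res = predict_templated_block("TC", "AA", start=0)
        assert not res.ok and res.failed_at == 1

    @pytest.mark.parametrize("name", ["gDemo-1", "gDemo-2", "gDemo-mis", "gDemo-alt"])
    def test_repair_property_no_mismatches(self, demo, name):
        """Rendered templated blocks re-pair against their guide WC/GU only."""
        g = _guide(name)
        window = demo.skeleton[::-1]
        for start in (8, 10):
            res = predict_templated_block(g, window[:20], start=start)
            classes = templated_duplex_classes(g, window[:20], res, start=start)
            assert "mismatch" not in classes


class TestSearch:
    def _alt_junction(self, demo):
        jm = JunctionModel()
        u = np.array(demo.pre_U)
        u[:jm.alt_ess] = demo.full_U[:jm.alt_ess]
        for site, c in jm.alt_pattern:
            u[site - 1] = c
        return u, jm

    def test_planted_guide_ranks_first_and_explains_junction(self, demo):
        u, jm = self._alt_junction(demo)
        cands = search_grna_db(u, demo, demo_guides())
        assert cands[0].guide_id == "gDemo-alt"
        explained = {s for s, ok in zip(cands[0].sites, cands[0].explained_mask) if ok}
        junction_sites = {site for site, _ in jm.alt_pattern}
        assert junction_sites <= explained

    def test_promiscuous_guide_still_reported(self, demo):
        # the alternative guide is annotated to a different transcript
        u, _ = self._alt_junction(demo)
        alt = next(g for g in demo_guides() if g.id == "gDemo-alt")
        assert "CRx" in alt.annotation
        assert any(c.guide_id == "gDemo-alt" for c in search_grna_db(u, demo, demo_guides()))

    def test_random_guides_no_better_than_bruteforce_best(self, demo):
        rng = np.random.default_rng(6)
        guides = [GuideRNA(f"rand{i}", "".join(rng.choice(list("ACGT"), 40)))
                  for i in range(12)]
        u = np.array(demo.pre_U)
        u[:9] = demo.full_U[:9]
        u[9] = demo.full_U[9] + 2
        cands = search_grna_db(u, demo, guides)
        if not cands:
            return
        # independent exhaustive enumeration over guides x anchor placements
        best = 0
        read = None
        from uindel.grna import find_anchor as fa
        read = demo.render_read(u)
        dom_start = len(demo.flank5)
        skel_pos = [dom_start + i for i, b in
                    enumerate(read[dom_start:len(read) - len(demo.flank3)]) if b != "T"]
        m = demo.n_sites
        for g in guides:
            for a in fa(read, g, 6, True, 1, max_len=6):
                inside = [j for j, p in enumerate(skel_pos) if p < a.mrna_start]
                if not inside:
                    continue
                j_last = inside[-1]
                res = predict_templated_block(g, demo.skeleton[:j_last + 1][::-1], start=a.length)
                first = m - 1 - j_last
                n_pred = min(len(res.u_counts), m - first + 1)
                obs = u[[first + k - 1 for k in range(n_pred)]]
                best = max(best, int((res.u_counts[:n_pred] == obs).sum()))
        assert cands[0].n_explained == best


def test_guide_for_window_bounds(demo):
    with pytest.raises(ValueError):
        guide_for(demo, demo.full_U, 0, 5)
    with pytest.raises(ValueError):
        guide_for(demo, demo.full_U, 5, demo.n_sites)
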