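import numpy as np
import pytest

from uindel.quantify import class_fractions, normalize_sample
from uindel.reads import process_reads
from uindel.simulate import (
    JunctionModel,
    KnockdownEffect,
    SimulationParams,
    generate_knockdown_pair,
    generate_population,
)


class TestDeterminism:
    def test_same_seed_byte_identical(self, demo):
        params = SimulationParams(table=demo, depth=2000, n_replicates=2, epsilon=0.01)
        a = generate_population(params, 123)
        b = generate_population(params, 123)
        for sa, sb in zip(a, b):
            assert sa.truth.equals(sb.truth)
            assert sa.reads() == sb.reads()

    def test_different_seeds_differ(self, demo):
        params = SimulationParams(table=demo, depth=2000, n_replicates=1, epsilon=0.0)
        a = generate_population(params, 1)[0]
        b = generate_population(params, 2)[0]
        assert not a.truth.equals(b.truth)

    def test_seed_contract_class_counts(self, demo):
        """Replicate k draws its class counts first from the spawned stream."""
        params = SimulationParams(table=demo, depth=50_000, n_replicates=3, epsilon=0.0)
        pops = generate_population(params, 77)
        children = np.random.SeedSequence(77).spawn(3)
        for k, sample in enumerate(pops):
            rng = np.random.default_rng(children[k])
            expected = rng.multinomial(
                params.depth, [params.p_pre, params.p_partial, params.p_full])
            by_mech = sample.truth.groupby("mechanism")["count"].sum()
            got = np.array([
                by_mech.get("pre", 0),
                sample.truth["count"].sum() - by_mech.get("pre", 0) - by_mech.get("full", 0),
                by_mech.get("full", 0),
            ])
            assert np.array_equal(got, expected)


class TestPopulationContent:
    def test_p_full_one_emits_only_the_edited_template(self, demo):
        params = SimulationParams(table=demo, depth=500, n_replicates=1,
                                  p_pre=0.0, p_full=1.0, epsilon=0.0)
        sample = generate_population(params, 3)[0]
        reads = sample.reads()
        assert reads == [(demo.render_read(demo.full_U), 500)]

    def test_epsilon_zero_roundtrip_matches_truth(self, demo):
        params = SimulationParams(table=demo, depth=5000, n_replicates=1, epsilon=0.0)
        sample = generate_population(params, 4)[0]
        truth = sample.truth.set_index("u_counts")
        for seq, n in sample.reads():
            df = process_reads([seq], demo)
            assert df["category"].iloc[0] == "standard"
            u = tuple(int(x) for x in df["u_counts"].iloc[0].split(","))
            rows = sample.truth[sample.truth["u_counts"] == u]
            assert len(rows) >= 1
            assert (rows["eclass"] == df["eclass"].iloc[0]).all()
            assert (rows["ess"] == df["ess"].iloc[0]).all()
            assert (rows["jl"] == df["jl"].iloc[0]).all()

    def test_epsilon_errors_are_never_standard(self, demo):
        params = SimulationParams(table=demo, depth=2000, n_replicates=1, epsilon=0.01)
        sample = generate_population(params, 5)[0]
        n_err = int((sample.truth["count"] - sample.truth["standard_count"]).sum())
        assert n_err > 0
        df = process_reads([s for s, n in sample.reads() for _ in range(n)], demo)
        bad = df.loc[df["category"] != "standard", "count"].sum()
        assert bad == n_err
        pop = normalize_sample(df, demo)
        assert pop.qc["standard"] == int(sample.truth["standard_count"].sum())

    def test_class_fractions_within_three_se(self, demo):
        depth = 100_000
        params = SimulationParams(table=demo, depth=depth, n_replicates=1, epsilon=0.0)
        pop = generate_population(params, 6)[0].to_population()
        fr = class_fractions(pop)
        for cls, p in (("pre", 0.25), ("partial", 0.5), ("full", 0.25)):
            se = 100 * np.sqrt(p * (1 - p) / depth)
            assert abs(fr[cls] - 100 * p) <= 3 * se

    def test_stop_sites_follow_weights(self, demo):
        params = SimulationParams(table=demo, depth=50_000, n_replicates=1,
                                  spikes=((7, 30.0),), epsilon=0.0)
        sample = generate_population(params, 8)[0]
        partial = sample.truth[sample.truth["eclass"] == "partially_edited"]
        by_ess = partial.groupby("ess")["count"].sum()
        assert by_ess.idxmax() == 7

    def test_mechanism_truth_consistent_with_landmarks(self, demo):
        params = SimulationParams(table=demo, depth=20_000, n_replicates=1, epsilon=0.0)
        truth = generate_population(params, 9)[0].truth
        none_rows = truth[truth["mechanism"] == "none"]
        assert (none_rows["jl"] == 0).all()
        mis = truth[truth["mechanism"] == "misalign"]
        jm = JunctionModel()
        assert (mis["ess"] == jm.misalign_ess).all()
        assert all(u[jm.misalign_ess] == jm.misalign_count for u in mis["u_counts"])
        alt = truth[truth["mechanism"] == "alt"]
        assert (alt["ess"] == jm.alt_ess).all()

    def test_t_jitter_mode_keeps_reads_standard(self, demo):
        params = SimulationParams(table=demo, depth=2000, n_replicates=1,
                                  epsilon=0.0, t_jitter_rate=0.05)
        sample = generate_population(params, 10)[0]
        assert (sample.truth["mechanism"].str.endswith("+tjitter")).any()
        df = process_reads([s for s, n in sample.reads() for _ in range(n)], demo)
        assert (df["category"] == "standard").all()

    def test_invalid_mixture_rejected(self, demo):
        with pytest.raises(ValueError):
            SimulationParams(table=demo, p_pre=0.7, p_full=0.5)
        with pytest.raises(ValueError):
            SimulationParams(table=demo, depth=0)


class TestKnockdown:
    def test_null_effect_matches_base_distribution(self, demo):
        params = SimulationParams(table=demo, depth=5000, n_replicates=2, epsilon=0.0)
        unind, ind, _ = generate_knockdown_pair(
            params, KnockdownEffect(sites=(), multiplier=1.0), 11,
            n_induced=2, n_uninduced=2)
        # same params; only the seed stream differs
        assert ind[0].params.stop_weights().tolist() == unind[0].params.stop_weights().tolist()
        assert ind[0].params.p_pre == unind[0].params.p_pre

    def test_multiplier_shifts_designated_sites(self, demo):
        params = SimulationParams(table=demo, depth=50_000, n_replicates=2, epsilon=0.0)
        unind, ind, eff = generate_knockdown_pair(
            params, KnockdownEffect(sites=(7, 21), multiplier=10.0), 12)
        w_u = unind[0].params.stop_weights()
        w_i = ind[0].params.stop_weights()
        assert w_i[7] / w_u[7] > 5
        assert eff.sites == (7, 21)

    def test_class_shift_reproduces_knockdown_profile(self, demo):
        """A depleted factor can leave 94% of transcripts pre-edited."""
        params = SimulationParams(table=demo, depth=50_000, n_replicates=2, epsilon=0.0)
        _, ind, _ = generate_knockdown_pair(
            params, KnockdownEffect(class_shift=(0.94, 0.02)), 13)
        fr = class_fractions(ind[0].to_population())
        assert fr["pre"] == pytest.approx(94.0, abs=1.0)
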