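import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sigconnect as sc
from sigconnect.enrichment import (
    _es_from_positions,
    _hit_weights,
    format_p,
)

from _oracles import es_oracle, ks_oracle


def assert_es_matches(engine_es, oracle_es, running, tol=1e-12):
    """Engine ES equals the oracle's up to the positive-wins tie rule: when
    the max and min deviations have (numerically) equal magnitude either
    extreme is a valid ES."""
    hi, lo = max(running), min(running)
    if abs(abs(hi) - abs(lo)) < 1e-9:
        assert min(abs(engine_es - hi), abs(engine_es - lo)) < tol
    else:
        assert engine_es == pytest.approx(oracle_es, abs=tol)


class TestEnrichmentScore:
    def test_spec_instance_matches_enumeration_oracle(self, ten_gene_ranking):
        rk = ten_gene_ranking
        members = [rk.genes[0], rk.genes[2], rk.genes[9]]  # ranks 1, 3, 10
        res = sc.enrichment_score(rk, sc.GeneSet("s", members))
        es, running = es_oracle(rk.genes, rk.scores, members, p=1.0)
        assert res.es == pytest.approx(es, abs=1e-12)
        assert np.allclose(res.running_sum, running, atol=1e-12)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_top_k_set_scores_plus_one(self, make_ranking, k):
        rk = make_ranking(40)
        res = sc.enrichment_score(rk, sc.GeneSet("top", rk.genes[:k]))
        assert res.es == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_bottom_k_set_scores_minus_one(self, make_ranking, k):
        rk = make_ranking(40)
        res = sc.enrichment_score(rk, sc.GeneSet("bot", rk.genes[-k:]))
        assert res.es == pytest.approx(-1.0, abs=1e-12)

    def test_exhaustive_oracle_equivalence_small_universes(self):
        # every subset of size <= 4 on fixed score grids
        for n, grid in [(5, [3.0, 1.5, 0.2, -0.7, -2.2]),
                        (8, [5, 4, 3, 2, -1, -2, -3, -4]),
                        (10, [9.1, 4.2, 3.3, 1.1, 0.4, -0.6, -1.8, -2.2, -5.5, -7.0])]:
            genes = [f"g{i}" for i in range(n)]
            rk = sc.RankedList(genes, [float(s) for s in grid])
            for k in range(1, min(4, n - 1) + 1):
                for members in itertools.combinations(genes, k):
                    res = sc.enrichment_score(rk, sc.GeneSet("s", members))
                    es, running = es_oracle(genes, rk.scores, members)
                    assert_es_matches(res.es, es, running)

    def test_sampled_oracle_equivalence_up_to_n20(self, rng):
        for _ in range(400):
            n = int(rng.integers(6, 21))
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            rk = sc.RankedList(genes, scores)
            k = int(rng.integers(1, min(5, n - 1) + 1))
            members = list(rng.choice(genes, size=k, replace=False))
            res = sc.enrichment_score(rk, sc.GeneSet("s", members))
            es, running = es_oracle(genes, scores, members)
            assert_es_matches(res.es, es, running)

    def test_running_sum_has_n_steps_and_returns_to_zero(self, make_ranking, rng):
        rk = make_ranking(200)
        members = rng.choice(rk.genes, size=17, replace=False)
        res = sc.enrichment_score(rk, sc.GeneSet("s", members))
        assert res.running_sum.size == rk.n
        assert abs(res.running_sum[-1]) < 1e-9

    def test_antisymmetry_under_score_negation(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 80))
            scores = rng.normal(0, 2, n)
            rk = sc.build_ranked_list({f"g{i}": s for i, s in enumerate(scores)})
            neg = sc.build_ranked_list({f"g{i}": -s for i, s in enumerate(scores)})
            k = int(rng.integers(1, n // 2 + 1))
            members = rng.choice(rk.genes, size=k, replace=False)
            gs = sc.GeneSet("s", members)
            assert sc.enrichment_score(neg, gs).es == pytest.approx(
                -sc.enrichment_score(rk, gs).es, abs=1e-12
            )

    def test_invariant_to_positive_rescaling(self, make_ranking, rng):
        rk = make_ranking(60)
        members = rng.choice(rk.genes, size=8, replace=False)
        gs = sc.GeneSet("s", members)
        base = sc.enrichment_score(rk, gs).es
        for c in (0.01, 3.7, 250.0):
            scaled = sc.RankedList(rk.genes, rk.scores * c)
            assert sc.enrichment_score(scaled, gs).es == pytest.approx(
                base, abs=1e-12
            )

    def test_weight_zero_reduces_to_classical_ks(self, rng):
        cfg = sc.EnrichmentConfig(weight_exponent=0.0, n_perm=1)
        for _ in range(40):
            n = int(rng.integers(6, 51))
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            rk = sc.RankedList(genes, scores)
            k = int(rng.integers(1, n))
            members = list(rng.choice(genes, size=k, replace=False))
            res = sc.enrichment_score(rk, sc.GeneSet("s", members), cfg)
            assert res.es == pytest.approx(ks_oracle(genes, scores, members),
                                           abs=1e-12)

    def test_agrees_with_external_prerank_implementation(self, rng):
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        scores = np.sort(rng.normal(0, 2, 60))[::-1]
        genes = [f"g{i:03d}" for i in range(60)]
        rk = sc.RankedList(genes, scores)
        for idx in ([0, 3, 7, 20, 44], [50, 55, 59], [10, 30, 58]):
            members = [genes[i] for i in idx]
            ours = sc.enrichment_score(rk, sc.GeneSet("s", members)).es
            ext = gseapy.prerank(
                rnk=pd.DataFrame({"gene": genes, "score": scores}),
                gene_sets={"s": members}, permutation_num=4, min_size=1,
                max_size=100, seed=0, outdir=None, no_plot=True, threads=1,
            )
            assert ours == pytest.approx(float(ext.res2d["ES"].iloc[0]),
                                         abs=1e-9)

    def test_leading_edge_members_lie_at_the_enriched_extreme(self, ten_gene_ranking):
        rk = ten_gene_ranking
        res = sc.enrichment_score(rk, sc.GeneSet("s", ["g0", "g1", "g8"]))
        assert res.es > 0
        assert all(rk._index[g] <= res.peak_index
                   for g in res.leading_edge.members)

    def test_no_overlap_and_full_universe_rejected(self, ten_gene_ranking):
        with pytest.raises(ValueError, match="no overlap"):
            sc.enrichment_score(ten_gene_ranking, sc.GeneSet("s", ["absent"]))
        with pytest.raises(ValueError, match="entire universe"):
            sc.enrichment_score(ten_gene_ranking,
                                sc.GeneSet("s", ten_gene_ranking.genes))

    def test_members_outside_universe_dropped_and_counted(self, ten_gene_ranking):
        res = sc.enrichment_score(
            ten_gene_ranking, sc.GeneSet("s", ["g0", "g3", "zzz", "yyy"])
        )
        assert res.size == 2
        assert res.n_dropped == 2

    @given(st.integers(0, 2**31 - 1))
    def test_property_es_bounded_and_sum_closes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.normal(0, 1, n)
        rk = sc.build_ranked_list({f"g{i}": s for i, s in enumerate(scores)})
        k = int(rng.integers(1, n))
        members = rng.choice(rk.genes, size=k, replace=False)
        res = sc.enrichment_score(rk, sc.GeneSet("s", members))
        assert -1.0 - 1e-12 <= res.es <= 1.0 + 1e-12
        assert abs(res.running_sum[-1]) < 1e-9


class TestNullDistribution:
    def test_sample_count_and_bounds(self, make_ranking):
        rk = make_ranking(100)
        cfg = sc.EnrichmentConfig(n_perm=2000, seed=5)
        null = sc.null_distribution(rk, 7, cfg)
        assert null.es_samples.size == 2000
        assert null.es_samples.min() >= -1 and null.es_samples.max() <= 1

    def test_same_seed_reproduces_sample_sequence(self, make_ranking):
        rk = make_ranking(50)
        cfg = sc.EnrichmentConfig(n_perm=500, seed=11)
        a = sc.null_distribution(rk, 5, cfg)
        b = sc.null_distribution(rk, 5, cfg)
        assert np.array_equal(a.es_samples, b.es_samples)

    def test_near_full_sets_match_enumerated_values(self, rng):
        # at set_size = N-1 only N distinct sets exist; every sample must be
        # one of their brute-force scores, all bounded away from 0
        n = 7
        scores = np.sort(rng.normal(0, 2, n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        rk = sc.RankedList(genes, scores)
        enumerated = []
        for left_out in genes:
            members = [g for g in genes if g != left_out]
            enumerated.append(es_oracle(genes, scores, members)[0])
        null = sc.null_distribution(rk, n - 1,
                                    sc.EnrichmentConfig(n_perm=300, seed=2))
        for s in null.es_samples:
            assert min(abs(s - e) for e in enumerated) < 1e-12
        assert np.all(np.abs(null.es_samples) > 0)

    def test_positional_fast_path_equals_profile_path(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 120))
            scores = rng.normal(0, 2, n)
            rk = sc.build_ranked_list({f"g{i:03d}": s
                                       for i, s in enumerate(scores)})
            k = int(rng.integers(1, n))
            members = rng.choice(rk.genes, size=k, replace=False)
            prof = sc.enrichment_score(rk, sc.GeneSet("s", members))
            pos, _ = rk.positions_of(members)
            fast = _es_from_positions(pos[None, :],
                                      _hit_weights(rk.scores, 1.0), n)[0]
            assert_es_matches(fast, prof.es, prof.running_sum)

    def test_set_size_out_of_range_rejected(self, make_ranking):
        rk = make_ranking(10)
        for bad in (0, 10, 11):
            with pytest.raises(ValueError):
                sc.null_distribution(rk, bad)


class TestNesAndP:
    def _null(self, samples):
        samples = np.asarray(samples, dtype=float)
        return sc.NullDistribution(es_samples=samples, n_perm=samples.size,
                                   set_size=3)

    def test_nes_zero_for_zero_es(self):
        assert sc.normalize_es(0.0, self._null([0.5, -0.5])) == 0.0

    def test_nes_is_es_over_same_sign_mean(self):
        null = self._null([0.4, 0.4, -0.9])
        assert sc.normalize_es(0.8, null) == pytest.approx(2.0)
        assert sc.normalize_es(-0.45, null) == pytest.approx(-0.5)

    def test_nes_unset_with_warning_when_no_same_sign_samples(self):
        with pytest.warns(RuntimeWarning, match="NES"):
            assert sc.normalize_es(0.8, self._null([-0.1, -0.2])) is None

    def test_p_floor_reported_below_simulation_resolution(self):
        null = self._null(np.concatenate([np.full(9999, 0.01), [-0.5]]))
        p = sc.nominal_p(0.9, null)
        assert p == pytest.approx(1 / 10000)
        assert format_p(p, 10000) == "<0.0001"

    def test_p_near_half_at_null_median(self, make_ranking):
        rk = make_ranking(100)
        null = sc.null_distribution(rk, 5, sc.EnrichmentConfig(n_perm=2000,
                                                               seed=3))
        positives = null.es_samples[null.es_samples > 0]
        med = float(np.median(positives))
        assert sc.nominal_p(med, null) == pytest.approx(0.5, abs=0.05)

    def test_p_uses_add_one_smoothing(self):
        null = self._null([0.1, 0.2, 0.3])
        assert sc.nominal_p(0.9, null) == pytest.approx(1 / 4)


class TestGseaBatch:
    def test_single_set_fdr_equals_p(self, make_ranking, rng):
        rk = make_ranking(80)
        members = rng.choice(rk.genes, size=6, replace=False)
        table = sc.gsea_batch(rk, [sc.GeneSet("only", members)],
                              sc.EnrichmentConfig(n_perm=300, seed=1))
        assert table["fdr"].iloc[0] == pytest.approx(table["p"].iloc[0])

    def test_extreme_sets_hit_both_floors(self, make_ranking):
        rk = make_ranking(200)
        cfg = sc.EnrichmentConfig(n_perm=500, seed=4)
        table = sc.gsea_batch(
            rk,
            [sc.GeneSet("top50", rk.genes[:50]),
             sc.GeneSet("bottom50", rk.genes[-50:])],
            cfg,
        ).set_index("name")
        assert table.loc["top50", "es"] == pytest.approx(1.0, abs=1e-12)
        assert table.loc["bottom50", "es"] == pytest.approx(-1.0, abs=1e-12)
        for res in table.attrs["results"]:
            assert res.p_at_floor  # nothing in the null is as extreme
            assert res.p_display.startswith("<")

    def test_non_overlapping_sets_skipped_with_warning(self, make_ranking, rng):
        rk = make_ranking(50)
        ok = sc.GeneSet("ok", rng.choice(rk.genes, size=5, replace=False))
        with pytest.warns(RuntimeWarning, match="skipping"):
            table = sc.gsea_batch(rk, [ok, sc.GeneSet("ghost", ["nope"])],
                                  sc.EnrichmentConfig(n_perm=100, seed=1))
        assert list(table["name"]) == ["ok"]

    def test_type_i_error_controlled_on_random_collections(self, rng):
        # random sets vs random rankings: on average at most 5% of 20 sets
        # reach FDR < 0.05
        n_reps, n_sets = 40, 20
        hits = 0
        cfg = sc.EnrichmentConfig(n_perm=250, seed=9)
        for rep in range(n_reps):
            scores = rng.normal(0, 1, 250)
            rk = sc.build_ranked_list({f"g{i}": s for i, s in enumerate(scores)})
            sets = [
                sc.GeneSet(f"s{j}", rng.choice(rk.genes, size=15, replace=False))
                for j in range(n_sets)
            ]
            table = sc.gsea_batch(rk, sets, cfg)
            hits += int((table["fdr"] < 0.05).sum())
        assert hits / n_reps <= 1.0


class TestModelSurface:
    def test_preranked_gsea_fit_and_summary(self, make_ranking, rng):
        rk = make_ranking(120)
        sets = [sc.GeneSet("top", rk.genes[:10]),
                sc.GeneSet("rand", rng.choice(rk.genes, 10, replace=False))]
        res = sc.PrerankedGSEA(rk, sets,
                               sc.EnrichmentConfig(n_perm=200, seed=0)).fit()
        text = res.summary()
        assert "top" in text and "simulations: 200" in text
        assert len(res.table) == 2


class TestSamplePermutationNull:
    def _matrix(self, rng, n_features=150, n_pairs=6):
        import pandas as pd

        base = rng.normal(7, 1, n_features)
        cols, pairs = {}, []
        for i in range(n_pairs):
            non = base + rng.normal(0, 1, n_features)
            les = non + rng.normal(0, 1, n_features)
            cols[f"p{i}_LS"], cols[f"p{i}_NL"] = les, non
            pairs.append((f"p{i}", f"p{i}_LS", f"p{i}_NL"))
        values = pd.DataFrame(cols, index=[f"g{j:03d}" for j in range(n_features)])
        return sc.PairedExpressionMatrix(values, pairs)

    def test_samples_bounded_seeded_and_centred(self, rng):
        m = self._matrix(rng)
        gs = sc.GeneSet("s", [f"g{j:03d}" for j in range(0, 150, 15)])
        cfg = sc.EnrichmentConfig(n_perm=200, seed=6)
        null = sc.sample_permutation_null(m, gs, cfg)
        again = sc.sample_permutation_null(m, gs, cfg)
        assert null.mode == "sample-permutation"
        assert np.array_equal(null.es_samples, again.es_samples)
        assert np.all(np.abs(null.es_samples) <= 1.0)
        se = null.es_samples.std(ddof=1) / np.sqrt(null.n_perm)
        assert abs(null.es_samples.mean()) < 4 * se + 0.02

    def test_no_overlap_rejected(self, rng):
        m = self._matrix(rng)
        with pytest.raises(ValueError, match="no overlap"):
            sc.sample_permutation_null(m, sc.GeneSet("s", ["zzz"]))


def test_running_sum_plot_smoke(make_ranking):
    import matplotlib

    matplotlib.use("Agg")
    from sigconnect.plotting import plot_enrichment

    rk = make_ranking(50)
    res = sc.enrichment_score(rk, sc.GeneSet("s", rk.genes[:5]))
    ax = plot_enrichment(res)
    assert ax.get_xlabel() == "rank in ordered list"
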