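import numpy as np
import pytest

from miipa import IpaOptions, build_ca, run_ipa
from miipa.evaluation import (
    SpeciesSharedStats,
    excess_shared,
    expected_random_tp,
    mi_spectrum,
    random_pairing_tp,
    rank_candidate_partners,
    replication_fractions,
    scramble_columns,
    shared_prediction_stats,
    top_m_tp,
    tp_fraction,
)
from miipa.scoring import build_score_model, pairwise_mi
from miipa.statistics import frequencies
from miipa.synthetic_data import SyntheticSpec, generate


class TestTpFraction:
    def test_perfect_and_disjoint(self):
        gold = {"a1": "b1", "a2": "b2"}
        assert tp_fraction(gold, gold) == 1.0
        assert tp_fraction({"a1": "b2", "a2": "b1"}, gold) == 0.0

    def test_exclusion_of_training_pairs(self):
        gold = {"a1": "b1", "a2": "b2"}
        pred = {"a1": "b1", "a2": "b1"}
        assert tp_fraction(pred, gold, exclude=["a1"]) == 0.0

    def test_empty_prediction_is_error(self):
        with pytest.raises(ValueError):
            tp_fraction({}, {"a": "b"})

    def test_monte_carlo_matches_fixed_point_expectation(self):
        spec = SyntheticSpec(n_species=30, pairs_per_species=(2, 9), L_a=4, L_b=4,
                             n_coupled=0, epsilon=0.0, rng_seed=0)
        aln = generate(spec)
        tps = random_pairing_tp(aln, n_draws=1000, rng=1)
        expect = expected_random_tp(aln)
        se = tps.std() / np.sqrt(len(tps))
        assert abs(tps.mean() - expect) < 3 * se + 1e-3


class TestExcessShared:
    def test_identical_predictions_give_one(self):
        stats = [SpeciesSharedStats("s1", 5, 3, 3, 3),
                 SpeciesSharedStats("s2", 4, 2, 2, 2)]
        assert excess_shared(stats) == pytest.approx(1.0)

    def test_hand_computed_single_species(self):
        # m=4, p=q=2, k_obs=1: <k> = 1, numerator 0 -> E = 0
        assert excess_shared([SpeciesSharedStats("s", 4, 2, 2, 1)]) == pytest.approx(0.0)

    def test_degenerate_denominator_reported_as_nan(self):
        # p=q=m: <k> = m = min(p, q), denominator 0
        assert np.isnan(excess_shared([SpeciesSharedStats("s", 3, 3, 3, 3)]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            SpeciesSharedStats("s", 3, 2, 2, 3)

    def test_independent_predictors_center_on_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(2000):
            stats = []
            for i in range(20):
                m = 5
                g = np.arange(m)
                c1 = rng.permutation(m) == g
                c2 = rng.permutation(m) == g
                stats.append(SpeciesSharedStats(
                    str(i), m, int(c1.sum()), int(c2.sum()), int((c1 & c2).sum())
                ))
            vals.append(excess_shared(stats))
        vals = np.array(vals)
        vals = vals[~np.isnan(vals)]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_builder_counts_overlap_correctly(self):
        gold = {"a1": "b1", "a2": "b2", "a3": "b3"}
        species_of = {"a1": "s", "a2": "s", "a3": "s"}
        p1 = {"a1": "b1", "a2": "b2", "a3": "b1"}  # 2 correct
        p2 = {"a1": "b1", "a2": "b3", "a3": "b3"}  # 2 correct, shares a1
        (st,) = shared_prediction_stats(p1, p2, gold, species_of)
        assert (st.m, st.p, st.q, st.k_obs) == (3, 2, 2, 1)


class TestReplication:
    def _results(self, aln, seeds, n_increment=10):
        return [run_ipa(aln, IpaOptions(n_increment=n_increment, seed=s)) for s in seeds]

    def test_identical_replicates_give_binary_fractions(self, strong_aln, strong_run):
        rt = replication_fractions([strong_run, strong_run])
        assert set(rt["fraction"]) <= {1.0}

    def test_disagreement_halves_the_fraction(self):
        class FakeRes:
            def __init__(self, pairs):
                self.final_pairs = pairs

        from miipa.ipa import PredictedPair

        p1 = [PredictedPair("s", "a1", "b1", 1.0, 2.0)]
        p2 = [PredictedPair("s", "a1", "b2", 1.0, 2.0)]
        rt = replication_fractions([FakeRes(p1), FakeRes(p2)])
        assert sorted(rt["fraction"]) == [0.5, 0.5]

    def test_bimodal_for_interacting_unimodal_for_scrambled(self, strong_aln):
        results = self._results(strong_aln, range(12))
        rt = replication_fractions(results)
        f = rt["fraction"].to_numpy()
        assert np.mean(f >= 0.9) > 0.2  # a heavy near-1 mode
        assert np.mean(f <= 0.1) > 0.05  # and a near-0 mode
        scr = scramble_columns(strong_aln, rng=3)
        rs = replication_fractions(
            [run_ipa(scr, IpaOptions(n_increment=50, seed=s)) for s in range(12)]
        )
        fs = rs["fraction"].to_numpy()
        assert np.mean(fs >= 0.9) < 0.05  # no stable consensus without signal

    def test_consensus_ranking_beats_mean_replicate(self):
        spec = SyntheticSpec(n_species=40, pairs_per_species=4, L_a=25, L_b=25,
                             n_coupled=10, epsilon=0.55, rng_seed=42)
        aln = generate(spec)
        results = [run_ipa(aln, IpaOptions(n_increment=6, seed=s)) for s in range(10)]
        tps = [tp_fraction(r.predicted(), aln.gold) for r in results]
        rt = replication_fractions(results)
        assert top_m_tp(rt, aln.M, aln.gold) >= np.mean(tps)


class TestScramble:
    def test_single_row_unchanged(self):
        spec = SyntheticSpec(n_species=1, pairs_per_species=1, L_a=5, L_b=5,
                             n_coupled=0, epsilon=0.0, rng_seed=0)
        # min_pairs filter not applied here; a 1-pair alignment is legal input
        aln = generate(spec)
        scr = scramble_columns(aln, rng=0)
        assert np.array_equal(scr.X_a, aln.X_a) and np.array_equal(scr.X_b, aln.X_b)

    def test_column_marginals_preserved_exactly(self, strong_aln):
        scr = scramble_columns(strong_aln, rng=1)
        for X0, X1 in ((strong_aln.X_a, scr.X_a), (strong_aln.X_b, scr.X_b)):
            for j in range(X0.shape[1]):
                assert np.array_equal(np.bincount(X0[:, j], minlength=21),
                                      np.bincount(X1[:, j], minlength=21))
        assert scr.gold == strong_aln.gold

    def test_scrambled_mi_drops_to_iid_null_level(self):
        """Scrambling removes the planted signal entirely: the residual
        pairwise MI is pure finite-size bias, matching a fresh iid null to
        within a few percent (permutation nulls sit very slightly below iid
        ones because their column marginals are fixed rather than sampled)."""
        spec = SyntheticSpec(n_species=60, pairs_per_species=4, L_a=4, L_b=4,
                             n_coupled=4, epsilon=0.9, rng_seed=5)
        aln = generate(spec)
        ia, ib = aln.index_a, aln.index_b
        gold_pairs = [(ia[a], ib[b]) for a, b in aln.gold.items()]
        signal = pairwise_mi(build_ca(aln, gold_pairs))
        scrambled = [
            pairwise_mi(build_ca(scramble_columns(aln, rng=s), gold_pairs))
            for s in range(20)
        ]
        iid = []
        for s in range(20):
            null_spec = SyntheticSpec(n_species=60, pairs_per_species=4, L_a=4,
                                      L_b=4, n_coupled=0, epsilon=0.0,
                                      rng_seed=100 + s)
            null = generate(null_spec)
            ja, jb = null.index_a, null.index_b
            iid.append(pairwise_mi(build_ca(null, [(ja[a], jb[b]) for a, b in null.gold.items()])))
        assert np.mean(scrambled) == pytest.approx(np.mean(iid), rel=0.05)
        # and far below the unscrambled signal
        assert signal - np.mean(scrambled) > 10 * np.std(iid)


class TestMiSpectrum:
    def test_planted_pairs_occupy_top_ranks(self, strong_aln):
        ia, ib = strong_aln.index_a, strong_aln.index_b
        ca = build_ca(strong_aln, [(ia[a], ib[b]) for a, b in strong_aln.gold.items()])
        sm = build_score_model(frequencies(ca, lam=0.15))
        top = mi_spectrum(sm, top_k=8)
        assert set(zip(top["i"] - 1, top["j"] - 1)) == {(k, k) for k in range(8)}

    def test_averaging_and_concatenated_coordinates(self):
        m1 = np.array([[1.0, 0.0]])
        m2 = np.array([[0.0, 2.0]])
        df = mi_spectrum([m1, m2])
        assert df.iloc[0]["mi"] == pytest.approx(1.0)
        assert df.iloc[0]["j_concat"] == df.iloc[0]["j"] + 1  # L_a = 1

    def test_invariant_under_row_permutation(self, strong_aln):
        ia, ib = strong_aln.index_a, strong_aln.index_b
        pairs = [(ia[a], ib[b]) for a, b in strong_aln.gold.items()]
        ca1 = build_ca(strong_aln, pairs)
        ca2 = build_ca(strong_aln, pairs[::-1])
        sm1 = build_score_model(frequencies(ca1, lam=0.15))
        sm2 = build_score_model(frequencies(ca2, lam=0.15))
        assert np.allclose(sm1.mi, sm2.mi, atol=1e-12)


class TestCandidateRanking:
    def test_true_partner_ranks_first_under_strong_coupling(self, strong_aln):
        ia, ib = strong_aln.index_a, strong_aln.index_b
        ca = build_ca(strong_aln, [(ia[a], ib[b]) for a, b in strong_aln.gold.items()])
        sm = build_score_model(frequencies(ca, lam=0.15))
        hits = 0
        checked = 0
        for sp, (a_idx, b_idx) in sorted(strong_aln.species_index.items())[:10]:
            focal = a_idx[0]
            cands = [(strong_aln.ids_b[i], strong_aln.X_b[i]) for i in b_idx]
            ranked = rank_candidate_partners(strong_aln.X_a[focal], cands, sm)
            hits += ranked[0][0] == strong_aln.gold[strong_aln.ids_a[focal]]
            checked += 1
        assert hits >= 0.8 * checked

    def test_zero_table_keeps_stable_id_order(self):
        from miipa.scoring import ScoreModel

        sm = ScoreModel(mode="pmi", table=np.zeros((2, 2, 21, 21)), mi=np.zeros((2, 2)))
        cands = [("b2", np.array([0, 0])), ("b1", np.array([1, 1]))]
        ranked = rank_candidate_partners(np.array([0, 0]), cands, sm)
        assert [r[0] for r in ranked] == ["b1", "b2"]
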