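"""Query strategies against hand computations and exhaustive oracles."""

import numpy as np
import pytest

from alstim.query import (
    AL_STRATEGY_NAMES,
    STRATEGY_NAMES,
    QueryState,
    StrategyConfig,
    emcm_scores,
    gs_scores,
    qbc_scores,
    representative_init,
    select_emcm,
    select_gs,
    select_next,
    select_qbc,
    select_random,
    select_rd,
)
from alstim.regressors import RegressorSpec, bootstrap_committee, fit, predict

RIDGE = RegressorSpec(family="ridge", ridge_lambda=0.1)


def make_state(features, labeled, targets, seed=0):
    n = np.atleast_2d(features).shape[0]
    unlabeled = sorted(set(range(n)) - set(labeled))
    return QueryState(
        pool_features=features, labeled=list(labeled), unlabeled=unlabeled,
        labeled_targets=np.asarray(targets, dtype=float), rng_seed=seed,
    )


class TestScores:
    def test_qbc_variance_hand_example(self):
        # candidate A: committee predictions {1,2,3} -> population var 2/3;
        # candidate B: {2,2,2} -> 0
        preds = np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]])
        np.testing.assert_allclose(qbc_scores(preds), [2.0 / 3.0, 0.0])

    def test_emcm_hand_example(self):
        # yhat = 0; A residuals {1,-1} with unit feature norm -> g = 1;
        # B residuals {0.1,0.1} with unit norm -> g = 0.1
        preds = np.array([[1.0, -1.0], [0.1, 0.1]])
        yhat = np.zeros(2)
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(emcm_scores(preds, yhat, U), [1.0, 0.1])

    def test_emcm_is_homogeneous_in_the_feature_vector(self):
        preds = np.array([[0.4, -0.2]])
        yhat = np.array([0.1])
        u = np.array([[1.0, 2.0]])
        base = emcm_scores(preds, yhat, u)[0]
        assert emcm_scores(preds, yhat, 2 * u)[0] == pytest.approx(2 * base)

    def test_gs_hand_example_interior_point_wins(self):
        # labeled at 0 and 4 on a line; candidates 1,2,3 have min-distances 1,2,1
        labeled = np.array([[0.0], [4.0]])
        cands = np.array([[1.0], [2.0], [3.0]])
        np.testing.assert_allclose(gs_scores(cands, labeled), [1.0, 2.0, 1.0])

    def test_gs_max_max_variant_reproduces_literal_formula(self):
        labeled = np.array([[0.0], [4.0]])
        cands = np.array([[1.0], [2.0], [3.0]])
        np.testing.assert_allclose(gs_scores(cands, labeled, "max_max"), [3.0, 2.0, 3.0])


class TestSelection:
    def test_random_single_candidate_is_forced(self):
        state = make_state(np.arange(6.0)[:, None], [0, 1, 2, 3, 4], np.zeros(5))
        assert select_random(state) == 5

    def test_random_is_reproducible_and_uniform(self):
        feats = np.arange(8.0)[:, None]
        state = make_state(feats, [0, 1, 2, 3], np.zeros(4), seed=9)
        assert select_random(state) == select_random(state)
        counts = np.zeros(8)
        for s in range(10_000):
            st = make_state(feats, [0, 1, 2, 3], np.zeros(4), seed=s)
            counts[select_random(st)] += 1
        freqs = counts[4:] / 10_000
        # binomial 3-sigma band around 1/4
        assert np.abs(freqs - 0.25).max() < 3 * np.sqrt(0.25 * 0.75 / 10_000)

    def test_gs_farther_point_wins_and_coincident_never_selected(self):
        feats = np.array([[0.0], [1.0], [3.0], [0.0]])
        state = make_state(feats, [0], [1.0])
        assert select_gs(state) == 2
        # index 3 coincides with the labeled point: zero distance
        scores = gs_scores(feats[[1, 2, 3]], feats[[0]])
        assert scores[2] == 0.0

    def test_qbc_zero_disagreement_falls_back_to_lowest_index(self):
        # all labeled targets identical -> every committee member predicts the
        # same function -> ties everywhere -> lowest unlabeled index
        feats = np.tile(np.array([[1.0, 0.0]]), (5, 1))
        state = make_state(feats, [3, 4], [2.0, 2.0], seed=1)
        assert select_qbc(state, RIDGE, StrategyConfig(name="qbc")) == 0

    def test_qbc_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(10)
        for trial in range(100):
            feats = rng.normal(size=(6, 2))
            labeled = [0, 1, 2]
            targets = rng.normal(size=3)
            state = make_state(feats, labeled, targets, seed=trial)
            config = StrategyConfig(name="qbc", committee_size=5)
            chosen = select_qbc(state, RIDGE, config)
            committee = bootstrap_committee(RIDGE, feats[labeled], targets, 5, seed=trial)
            cands = state.unlabeled
            sigma = np.array(
                [np.var([predict(m, feats[[c]])[0] for m in committee.members]) for c in cands]
            )
            assert chosen == cands[int(np.argmax(sigma))]

    def test_emcm_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(20)
        for trial in range(100):
            feats = rng.normal(size=(6, 3))
            labeled = [1, 4]
            targets = rng.normal(size=2)
            state = make_state(feats, labeled, targets, seed=trial)
            config = StrategyConfig(name="emcm", committee_size=4)
            chosen = select_emcm(state, RIDGE, config)
            main = fit(RIDGE, feats[labeled], np.asarray(targets))
            committee = bootstrap_committee(RIDGE, feats[labeled], np.asarray(targets), 4, seed=trial)
            cands = state.unlabeled
            g = []
            for c in cands:
                yhat = predict(main, feats[[c]])[0]
                member_preds = [predict(m, feats[[c]])[0] for m in committee.members]
                g.append(np.mean(np.abs(np.array(member_preds) - yhat)) * np.linalg.norm(feats[c]))
            assert chosen == cands[int(np.argmax(g))]

    def test_gs_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(30)
        for trial in range(100):
            feats = rng.normal(size=(6, 2))
            labeled = [0, 3]
            state = make_state(feats, labeled, rng.normal(size=2), seed=trial)
            chosen = select_gs(state)
            cands = state.unlabeled
            d = [min(np.linalg.norm(feats[c] - feats[m]) for m in labeled) for c in cands]
            assert chosen == cands[int(np.argmax(d))]


def two_blobs(n1=5, n2=5, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.3, size=(n1, 2))
    b = rng.normal(sep, 0.3, size=(n2, 2))
    return np.vstack([a, b])


class TestRD:
    def test_naive_rd_picks_unlabeled_blob_centroid_member(self):
        feats = two_blobs()
        # one labeled point in blob 1 -> k=2 clustering; blob 2 is labeled-free
        state = make_state(feats, [0], [1.0], seed=3)
        chosen = select_rd(state)
        blob2 = feats[5:]
        nearest = 5 + int(np.argmin(np.linalg.norm(blob2 - blob2.mean(axis=0), axis=1)))
        assert chosen == nearest

    def test_largest_labeled_free_cluster_is_preferred(self):
        feats = two_blobs(n1=5, n2=3, sep=12.0, seed=1)
        # label a far-away singleton so both blobs are labeled-free
        feats = np.vstack([feats, [[30.0, 30.0]]])
        state = make_state(feats, [8], [0.5], seed=4)
        chosen = select_rd(state)
        assert chosen in range(0, 5)  # the size-5 blob

    def test_identical_unlabeled_rows_select_that_point(self):
        feats = np.vstack([np.tile([[2.0, 2.0]], (4, 1)), [[0.0, 0.0]]])
        state = make_state(feats, [4], [1.0], seed=5)
        assert select_rd(state) in (0, 1, 2, 3)

    def test_integrated_rd_restricts_base_to_cluster(self):
        feats = two_blobs(seed=2)
        state = make_state(feats, [0], [1.0], seed=6)
        chosen = select_rd(state, base="gs", spec=RIDGE, config=StrategyConfig(name="rd_gs"))
        assert chosen >= 5  # must come from the labeled-free blob
        # within the cluster, gs picks the member farthest from labeled point 0
        cluster = list(range(5, 10))
        d = [np.linalg.norm(feats[c] - feats[0]) for c in cluster]
        assert chosen == cluster[int(np.argmax(d))]


class TestEnhancedInit:
    def test_one_representative_per_separated_blob(self):
        rng = np.random.default_rng(8)
        blobs = [rng.normal(c, 0.2, size=(6, 2)) for c in ((0, 0), (10, 0), (0, 10))]
        feats = np.vstack(blobs)
        chosen = representative_init(feats, n_init=3, seed=1)
        assert len(chosen) == 3
        owners = {min(2, c // 6) for c in chosen}
        assert owners == {0, 1, 2}
        for c in chosen:
            blob = feats[(c // 6) * 6 : (c // 6) * 6 + 6]
            dist = np.linalg.norm(blob - blob.mean(axis=0), axis=1)
            assert c % 6 == int(np.argmin(dist))

    def test_gross_outlier_is_not_an_initial_sample(self):
        rng = np.random.default_rng(9)
        feats = np.vstack([rng.normal(0, 1, size=(20, 2)), [[50.0, 50.0]]])
        chosen = representative_init(feats, n_init=3, seed=2)
        assert 20 not in chosen

    def test_enhanced_queries_equal_base_strategy_given_same_state(self):
        rng = np.random.default_rng(12)
        feats = rng.normal(size=(10, 2))
        state = make_state(feats, [0, 1, 2], rng.normal(size=3), seed=7)
        eq = select_next(state, StrategyConfig(name="eqbc"), RIDGE)
        base = select_next(state, StrategyConfig(name="qbc"), RIDGE)
        assert eq == base


class TestContracts:
    @pytest.mark.parametrize("name", STRATEGY_NAMES)
    def test_every_strategy_returns_an_unlabeled_index(self, name):
        rng = np.random.default_rng(13)
        feats = rng.normal(size=(9, 3))
        state = make_state(feats, [0, 4, 8], rng.normal(size=3), seed=11)
        chosen = select_next(state, StrategyConfig(name=name), RIDGE)
        assert chosen in state.unlabeled

    def test_registry_covers_nine_al_strategies_plus_rs(self):
        assert len(STRATEGY_NAMES) == 10
        assert len(AL_STRATEGY_NAMES) == 9
        assert "rs" not in AL_STRATEGY_NAMES

    def test_committee_strategies_require_two_members(self):
        with pytest.raises(ValueError):
            StrategyConfig(name="qbc", committee_size=1)

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError):
            QueryState(
                pool_features=np.zeros((3, 1)), labeled=[0, 1], unlabeled=[1, 2],
                labeled_targets=np.zeros(2),
            )

    def test_qbc_score_is_invariant_to_member_order(self):
        rng = np.random.default_rng(14)
        preds = rng.normal(size=(5, 8))
        np.testing.assert_allclose(
            qbc_scores(preds), qbc_scores(preds[:, ::-1]), atol=1e-15
        )
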