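"""CRM working model, ordering selection, recommendation and trial engine."""

import math

import numpy as np
import pytest

import pocrmkit as pk
from pocrmkit.design import DesignConfig, crm_prob, fit_crm, ordering_score
from pocrmkit.poset import Ordering
from pocrmkit.scenarios import ToxicityScenario

SKELETON = pk.evaluation.MOTIVATING_SKELETON


class TestCrmProb:
    def test_identity_at_zero(self):
        assert crm_prob(0.0, 0.25) == pytest.approx(0.25)

    def test_square_root_case(self):
        assert crm_prob(math.log(0.5), 0.25) == pytest.approx(0.5)

    def test_decreasing_in_theta(self):
        thetas = np.linspace(-4, 4, 41)
        vals = [crm_prob(t, 0.3) for t in thetas]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals)

    def test_invalid_skeleton_value(self):
        with pytest.raises(ValueError):
            crm_prob(0.0, 1.0)


class TestFitCrm:
    def test_half_half_at_quarter_skeleton(self):
        theta, est = fit_crm([(6, 1), (6, 0)], SKELETON)
        assert theta == pytest.approx(math.log(0.5), abs=1e-5)
        assert est[5] == pytest.approx(0.5, abs=1e-5)

    def test_all_nontoxic_clamps_high(self):
        theta, est = fit_crm([(3, 0), (5, 0), (5, 0)], SKELETON)
        assert theta == pytest.approx(10.0, abs=1e-6)
        assert est.max() < 1e-10

    def test_all_toxic_clamps_low(self):
        theta, _ = fit_crm([(2, 1), (3, 1)], SKELETON)
        assert theta == pytest.approx(-10.0, abs=1e-6)

    def test_empty_data_rejected_under_ml(self):
        with pytest.raises(ValueError, match="observation"):
            fit_crm([], SKELETON)

    def test_estimates_monotone_along_positions(self):
        _, est = fit_crm([(2, 0), (7, 1), (9, 0)], SKELETON)
        assert (np.diff(est) >= 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        data = [(int(p), int(y)) for p, y in
                zip(rng.integers(1, 13, 12), rng.integers(0, 2, 12))]
        theta, _ = fit_crm(data, SKELETON)
        grid = np.linspace(-10, 10, 100_001)
        tox = np.zeros(12); ntx = np.zeros(12)
        for p, y in data:
            tox[p - 1] += y; ntx[p - 1] += 1 - y
        lp = np.minimum(np.exp(grid)[:, None] * np.log(SKELETON)[None, :], -1e-300)
        ll = tox @ lp.T + ntx @ np.log1p(-np.exp(lp)).T
        assert theta == pytest.approx(grid[np.argmax(ll)], abs=1e-3)

    def test_bayes_matches_numeric_integration(self):
        data = [(3, 0), (6, 1), (6, 0), (8, 0)]
        theta, est = fit_crm(data, SKELETON, estimation="bayes")
        grid = np.linspace(-8, 8, 20_001)
        dens = np.exp(-0.5 * (grid / 1.34) ** 2)
        tox = np.zeros(12); ntx = np.zeros(12)
        for p, y in data:
            tox[p - 1] += y; ntx[p - 1] += 1 - y
        lp = np.minimum(np.exp(grid)[:, None] * np.log(SKELETON)[None, :], -1e-300)
        pmat = np.exp(lp)
        lik = np.exp(tox @ lp.T + ntx @ np.log1p(-pmat).T)
        w = lik * dens
        assert theta == pytest.approx(float((w @ grid) / w.sum()), abs=1e-3)
        assert est[5] == pytest.approx(float((w @ pmat[:, 5]) / w.sum()), abs=1e-3)


@pytest.fixture(scope="module")
def square_setup():
    square = pk.build_grid_poset((2, 2))
    a, b = pk.enumerate_linear_extensions(square)
    return square, a, b


class TestOrderingScore:
    def test_single_ordering_positive(self, square_setup):
        _, a, _ = square_setup
        s = ordering_score([((1, 1), 0), ((2, 2), 1)], a, 1.0, [0.05, 0.15, 0.25, 0.4])
        assert s > 0

    def test_symmetric_data_equal_scores(self, square_setup):
        _, a, b = square_setup
        data = [((1, 1), 0), ((2, 2), 1)]  # combinations shared by both orderings
        skel = [0.05, 0.15, 0.25, 0.4]
        assert ordering_score(data, a, 0.5, skel) == pytest.approx(
            ordering_score(data, b, 0.5, skel)
        )

    def test_data_along_gradient_prefers_matching_ordering(self, square_setup):
        # the two orderings of the square grid disagree only on whether
        # (1,2) or (2,1) is more toxic; feed data where (1,2) clearly is
        _, a, b = square_setup
        skel = [0.05, 0.15, 0.25, 0.4]
        data = ([((1, 1), 0)] * 5 + [((2, 1), 0)] * 10
                + [((1, 2), 1)] * 5 + [((1, 2), 0)] * 5)
        sa = ordering_score(data, a, 0.5, skel)
        sb = ordering_score(data, b, 0.5, skel)
        toxic_high = b if b.position((1, 2)) > b.position((2, 1)) else a
        assert (sb > sa) == (toxic_high is b)

    def test_ml_and_bayes_agree_on_peaked_likelihood(self, square_setup):
        _, a, b = square_setup
        skel = [0.05, 0.15, 0.25, 0.4]
        data = ([(a.at(1), 0)] * 40 + [(a.at(2), 0)] * 30
                + [(a.at(3), 1)] * 12 + [(a.at(3), 0)] * 18)
        rank_ml = ordering_score(data, a, 0.5, skel) > ordering_score(data, b, 0.5, skel)
        rank_b = ordering_score(data, a, 0.5, skel, estimation="bayes") > ordering_score(
            data, b, 0.5, skel, estimation="bayes"
        )
        assert rank_ml == rank_b


class TestSelectAndRecommend:
    def test_argmax_and_ties(self):
        assert pk.select_ordering([0.1, 0.7, 0.2]) == 1
        assert pk.select_ordering([0.4, 0.4]) == 0
        with pytest.raises(ValueError):
            pk.select_ordering([])

    def test_closest_to_ttl(self):
        est = [((1,), 0.05), ((2,), 0.24), ((3,), 0.40)]
        assert pk.recommend_combination(est, 0.25) == (2,)

    def test_tie_resolves_less_toxic(self):
        est = [((1,), 0.20), ((2,), 0.30)]
        assert pk.recommend_combination(est, 0.25) == (1,)

    def test_safety_override_returns_least_toxic(self):
        est = [((1,), 0.9), ((2,), 0.95)]
        assert pk.recommend_combination(est, 0.25, safety_state=True) == (1,)


@pytest.fixture(scope="module")
def small_config(table1_poset, all_orderings):
    return pk.motivating_config(all_orderings[:8], n_max=20)


class TestRunTrial:
    def test_no_toxicity_stays_in_stage_one(self, table1_poset, small_config):
        sc = ToxicityScenario(table1_poset, {c: 0.0 for c in table1_poset})
        res = pk.run_trial(sc, small_config, rng_seed=0)
        assert set(res.stages) == {1}
        assert res.final_ordering is None
        assert res.dlt_count == 0
        # path shorter than n_max: the trial parks at the final path element
        assert res.recommended == pk.evaluation.MOTIVATING_STAGE1_PATH[-1]

    def test_certain_toxicity_triggers_safety_floor(self, table1_poset, small_config):
        sc = ToxicityScenario(table1_poset, {c: 1.0 for c in table1_poset})
        res = pk.run_trial(sc, small_config, rng_seed=0)
        assert res.dlt_count == small_config.n_max
        assert res.recommended == (1, 1, 1)
        assert res.stages[0] == 1 and set(res.stages[1:]) == {2}

    def test_seed_determinism(self, scenarios12, small_config):
        a = pk.run_trial(scenarios12[1], small_config, rng_seed=99)
        b = pk.run_trial(scenarios12[1], small_config, rng_seed=99)
        assert a == b

    def test_allocation_books_balance(self, scenarios12, small_config):
        res = pk.run_trial(scenarios12[1], small_config, rng_seed=3)
        assert sum(res.allocation.values()) == res.n_treated == small_config.n_max
        assert res.dlt_count == sum(res.outcomes)
        assert res.recommended in small_config.poset.elements

    def test_batch_rows_are_independent_replicates(self, scenarios12, small_config):
        batch = pk.run_trials(scenarios12[1], small_config, n_sims=6, rng_seed=5)
        assert batch.n_sims == 6
        assert batch.assign_hist.shape == (6, small_config.n_max)
        assert set(np.unique(batch.stage_hist)) <= {1, 2}

    def test_cohort_size_two_refits_every_other_patient(self, scenarios12, table1_poset,
                                                        all_orderings):
        import dataclasses

        cfg = dataclasses.replace(
            pk.motivating_config(all_orderings[:4], n_max=16), stage2_cohort=2
        )
        res = pk.run_trial(scenarios12[7], cfg, rng_seed=2)
        assert res.n_treated == 16

    def test_mismatched_poset_rejected(self, small_config):
        cube = pk.build_grid_poset((2, 2, 2))
        sc = ToxicityScenario(cube, {c: 0.1 for c in cube})
        with pytest.raises(ValueError, match="poset"):
            pk.run_trial(sc, small_config, rng_seed=0)


class TestDesignConfigValidation:
    def test_skeleton_must_increase(self, table1_poset, all_orderings):
        with pytest.raises(ValueError, match="increasing"):
            DesignConfig(
                poset=table1_poset,
                ttl=0.25,
                skeleton=np.full(12, 0.2),
                orderings=tuple(all_orderings[:2]),
                stage1_path=Ordering(pk.evaluation.MOTIVATING_STAGE1_PATH),
                n_max=10,
            )

    def test_path_must_respect_partial_order(self, table1_poset, all_orderings):
        bad = Ordering(tuple(reversed(pk.evaluation.MOTIVATING_STAGE1_PATH)))
        with pytest.raises(ValueError, match="stage1_path"):
            DesignConfig(
                poset=table1_poset,
                ttl=0.25,
                skeleton=np.asarray(SKELETON),
                orderings=tuple(all_orderings[:2]),
                stage1_path=bad,
                n_max=10,
            )

    def test_prior_length_checked(self, table1_poset, all_orderings):
        from pocrmkit.selection import PriorWeights

        with pytest.raises(ValueError, match="priors"):
            DesignConfig(
                poset=table1_poset,
                ttl=0.25,
                skeleton=np.asarray(SKELETON),
                orderings=tuple(all_orderings[:3]),
                stage1_path=Ordering(pk.evaluation.MOTIVATING_STAGE1_PATH),
                n_max=10,
                priors=PriorWeights(np.array([0.5, 0.5])),
            )
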