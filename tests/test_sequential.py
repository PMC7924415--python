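import numpy as np
import pytest

from crowdprior.dataset import PoolSplit
from crowdprior.reliability import ConditionalProbabilityTable, cpt_from_grids, estimate_cpt
from crowdprior.sequential import (
    Termination,
    batch_posterior,
    bayes_update,
    classify_all,
    classify_image,
)


class TestBayesUpdate:
    @pytest.mark.parametrize(
        "prior, l1, l2, expected",
        [
            (0.5, 0.4, 0.4, 0.5),  # uninformative outcome
            (0.5, 0.6, 0.3, 2 / 3),
            (0.25, 0.9, 0.0, 1.0),  # impossible under no-threat
            (0.0, 0.9, 0.2, 0.0),  # absorbing state stays
            (1.0, 0.1, 0.9, 1.0),
            (0.7, 0.0, 0.0, 0.7),  # zero denominator leaves prior
        ],
    )
    def test_hand_values(self, prior, l1, l2, expected):
        assert bayes_update(prior, l1, l2) == pytest.approx(expected, abs=1e-15)

    def test_complement_conservation(self, rng):
        # P(theta=1) and P(theta=2) stay complementary along any path.
        p1 = 0.5
        for _ in range(200):
            l1, l2 = rng.random(2)
            p1 = bayes_update(p1, l1, l2)
            assert 0.0 <= p1 <= 1.0


class TestBatchPosterior:
    def test_empty_sequence_returns_prior(self):
        assert batch_posterior([], 0.5) == 0.5
        assert batch_posterior([], 0.123) == 0.123

    def test_two_identical_updates(self):
        assert batch_posterior([(0.6, 0.3), (0.6, 0.3)], 0.5) == pytest.approx(0.8)

    def test_matches_iterated_update_randomly(self, rng):
        # Sequential and batch forms are algebraically identical.
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            pairs = [tuple(rng.random(2)) for _ in range(n)]
            prior = float(rng.random())
            p_seq = prior
            for l1, l2 in pairs:
                p_seq = bayes_update(p_seq, l1, l2)
            assert batch_posterior(pairs, prior) == pytest.approx(p_seq, abs=1e-12)

    def test_zero_likelihood_paths(self):
        assert batch_posterior([(0.0, 0.5)], 0.5) == 0.0
        assert batch_posterior([(0.5, 0.0)], 0.5) == 1.0
        assert batch_posterior([(0.0, 0.0)], 0.5) == 0.5


def simple_cpt(p_correct=0.9):
    """One class answering the truth with probability p_correct."""
    grid = np.array(
        [
            [0.0, p_correct, 1 - p_correct, 0.0],
            [0.0, 1 - p_correct, p_correct, 0.0],
        ]
    )
    return cpt_from_grids({"c": grid})


class TestClassifyImage:
    def test_single_decisive_update(self, rng):
        cpt = simple_cpt(0.9)
        res = classify_image(
            {"a": 1}, ["a"], {"a": "c"}, cpt, sigma=0.52, rng=rng
        )
        assert res.label == 1 and res.n_used == 1
        assert res.termination is Termination.THRESHOLD
        assert res.final_p1 == pytest.approx(0.9, abs=1e-8)
        assert res.trace.p1_values[0] == 0.5

    def test_uninformative_pool_exhausts_to_tie(self):
        grid = np.array([[0.25, 0.25, 0.25, 0.25], [0.25, 0.25, 0.25, 0.25]])
        cpt = cpt_from_grids({"c": grid})
        outcomes = {v: 1 for v in "abcd"}
        classes = {v: "c" for v in "abcd"}
        res = classify_image(outcomes, list("abcd"), classes, cpt, 0.9, np.random.default_rng(0))
        assert res.termination is Termination.EXHAUSTED_TIE
        assert res.final_p1 == 0.5 and res.n_used == 4
        assert res.label in (1, 2)

    def test_matches_prefix_batch_enumeration(self, rng):
        # n_used is the first prefix whose batch posterior clears sigma,
        # and the label/posterior agree with the batch computation there.
        grids = {
            "g": np.array([[0.1, 0.5, 0.2, 0.2], [0.2, 0.2, 0.5, 0.1]]),
            "h": np.array([[0.3, 0.3, 0.2, 0.2], [0.25, 0.25, 0.25, 0.25]]),
        }
        cpt = cpt_from_grids(grids)
        classes = {"a": "g", "b": "h", "c": "g"}
        outcomes = {"a": 1, "b": 0, "c": 1}
        sigma = 0.7
        seq = ["a", "b", "c"]
        res = classify_image(outcomes, seq, classes, cpt, sigma, rng)
        prefix_posts = []
        for t in range(1, len(seq) + 1):
            pairs = [
                (
                    cpt.probs(classes[v])[0, outcomes[v]],
                    cpt.probs(classes[v])[1, outcomes[v]],
                )
                for v in seq[:t]
            ]
            prefix_posts.append(batch_posterior(pairs, 0.5))
        crossing = [t for t, p in enumerate(prefix_posts, 1) if max(p, 1 - p) > sigma]
        expected_t = crossing[0] if crossing else len(seq)
        assert res.n_used == expected_t
        assert res.final_p1 == pytest.approx(prefix_posts[expected_t - 1], abs=1e-12)
        assert res.label == (1 if prefix_posts[expected_t - 1] > 0.5 else 2)

    def test_missing_class_is_error(self, rng):
        cpt = simple_cpt()
        with pytest.raises(KeyError):
            classify_image({"a": 1}, ["a"], {}, cpt, 0.9, rng)

    def test_sigma_range_enforced(self, rng):
        cpt = simple_cpt()
        for sigma in (0.5, 1.0, 0.2):
            with pytest.raises(ValueError):
                classify_image({"a": 1}, ["a"], {"a": "c"}, cpt, sigma, rng)

    def test_raising_sigma_never_stops_earlier(self, small_synthetic, rng):
        table, _, class_of = small_synthetic
        split = PoolSplit(
            train_ids=tuple(table.volunteer_ids[:20]),
            test_ids=tuple(table.volunteer_ids[20:]),
        )
        cpt = estimate_cpt(table, class_of, split, pseudocount=1.0)
        seq = list(split.test_ids)
        outcomes = table.outcomes_for_image(0)
        previous = 0
        for sigma in (0.55, 0.7, 0.85, 0.95):
            res = classify_image(outcomes, seq, class_of, cpt, sigma, rng)
            assert res.n_used >= previous
            previous = res.n_used

    def test_exhaustion_posterior_order_invariant(self, rng):
        # With likelihood ratios too mild ever to clear the threshold the
        # run always exhausts the pool, and the final posterior is a
        # product of ratios, hence permutation-invariant.
        grids = {
            "g": np.array([[0.24, 0.28, 0.24, 0.24], [0.26, 0.22, 0.27, 0.25]]),
            "h": np.array([[0.27, 0.23, 0.26, 0.24], [0.24, 0.27, 0.24, 0.25]]),
        }
        cpt = cpt_from_grids(grids)
        ids = [f"v{k}" for k in range(15)]
        classes = {v: ("g" if k % 2 else "h") for k, v in enumerate(ids)}
        outcomes = {v: int(rng.integers(0, 4)) for v in ids}
        sigma = 1.0 - 1e-9
        base = classify_image(outcomes, ids, classes, cpt, sigma, rng)
        assert base.termination is Termination.EXHAUSTED
        for _ in range(10):
            perm = [ids[k] for k in rng.permutation(len(ids))]
            res = classify_image(outcomes, perm, classes, cpt, sigma, rng)
            assert res.termination is Termination.EXHAUSTED
            assert res.final_p1 == pytest.approx(base.final_p1, abs=1e-12)


class TestClassifyAll:
    def test_perfect_decisive_volunteers(self, rng):
        from crowdprior.dataset import ResponseTable

        truth = np.array([1, 2, 1])
        outcomes = np.tile(truth, (4, 1))
        table = ResponseTable(
            volunteer_ids=list("abcd"),
            image_ids=["i1", "i2", "i3"],
            outcomes=outcomes,
            truth=truth,
        )
        cpt = simple_cpt(0.99)
        classes = {v: "c" for v in "abcd"}
        _, chi, nu = classify_all(table, list("abcd"), classes, cpt, 0.9, rng)
        assert chi == 1.0 and nu == 1.0

    def test_never_terminating_pool_exhausts(self, rng):
        from crowdprior.dataset import ResponseTable

        grid = np.full((2, 4), 0.25)
        cpt = cpt_from_grids({"c": grid})
        n_v, n_i = 7, 5
        table = ResponseTable(
            volunteer_ids=[f"v{k}" for k in range(n_v)],
            image_ids=[f"i{k}" for k in range(n_i)],
            outcomes=np.ones((n_v, n_i), dtype=int),
            truth=np.tile([1, 2], n_i)[:n_i],
        )
        classes = {v: "c" for v in table.volunteer_ids}
        results, _, nu = classify_all(table, table.volunteer_ids, classes, cpt, 0.9, rng)
        assert nu == n_v
        assert all(r.termination is Termination.EXHAUSTED_TIE for r in results)

    def test_aggregates_match_per_image_rerun(self, small_synthetic):
        table, _, class_of = small_synthetic
        split = PoolSplit(
            train_ids=tuple(table.volunteer_ids[:20]),
            test_ids=tuple(table.volunteer_ids[20:]),
        )
        cpt = estimate_cpt(table, class_of, split, pseudocount=1.0)
        seq = list(split.test_ids)
        results, chi, nu = classify_all(
            table, seq, class_of, cpt, 0.8, np.random.default_rng(0)
        )
        correct = used = 0
        for ii in range(table.n_images):
            res = classify_image(
                table.outcomes_for_image(ii), seq, class_of, cpt, 0.8,
                np.random.default_rng(0),
            )
            correct += res.label == table.truth[ii]
            used += res.n_used
        assert chi == pytest.approx(correct / table.n_images)
        assert nu == pytest.approx(used / table.n_images)
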