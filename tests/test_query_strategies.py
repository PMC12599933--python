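import math

import numpy as np
import pytest

from vteal.embeddings import cosine_similarity
from vteal.query_strategies import (
    ConfigurationError,
    QueryContext,
    StrategySpec,
    class_average_similarity,
    entropy_scores,
    least_confidence_scores,
    length_words_select,
    margin_scores,
    min_similarity_select,
    pseudo_posterior,
    select_query,
    similarity_uncertainty_select,
)


def random_posteriors(rng, n, c):
    p = rng.dirichlet(np.ones(c), size=n)
    return p


class TestUncertaintyScores:
    def test_least_confidence_cases(self):
        assert least_confidence_scores(np.array([[1.0, 0.0]]))[0] == 0.0
        assert least_confidence_scores(np.full((1, 4), 0.25))[0] == pytest.approx(0.75)
        assert least_confidence_scores(np.array([[0.6, 0.3, 0.1]]))[0] == pytest.approx(0.4)

    def test_margin_cases(self):
        assert margin_scores(np.array([[1.0, 0.0]]))[0] == pytest.approx(0.0)
        assert margin_scores(np.array([[0.5, 0.5]]))[0] == pytest.approx(1.0)
        assert margin_scores(np.array([[0.6, 0.3, 0.1]]))[0] == pytest.approx(0.7)

    def test_margin_single_class_errors(self):
        with pytest.raises(ValueError):
            margin_scores(np.array([[1.0]]))

    def test_entropy_cases(self):
        assert entropy_scores(np.array([[1.0, 0.0]]))[0] == 0.0
        assert entropy_scores(np.array([[0.5, 0.5]]))[0] == pytest.approx(math.log(2))

    def test_entropy_uniform_is_strict_max(self, rng):
        c = 5
        uniform_h = entropy_scores(np.full((1, c), 1 / c))[0]
        assert uniform_h == pytest.approx(math.log(c))
        for _ in range(100):
            row = random_posteriors(rng, 1, c)
            if np.allclose(row, 1 / c):
                continue
            assert entropy_scores(row)[0] < uniform_h + 1e-12

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            least_confidence_scores(np.empty((0, 3)))

    def test_binary_rank_equivalence(self, rng):
        # for C=2 all three functionals order candidates identically
        for _ in range(100):
            p = random_posteriors(rng, 10, 2)
            orders = [
                np.argsort(f(p), kind="stable")
                for f in (least_confidence_scores, margin_scores, entropy_scores)
            ]
            assert all(np.array_equal(orders[0], o) for o in orders[1:])

    def test_monotone_in_top_probability(self, rng):
        # raising the top-class probability (renormalizing the rest) never
        # increases any uncertainty score
        for _ in range(50):
            p = random_posteriors(rng, 1, 4)[0]
            top = p.argmax()
            bumped = p.copy()
            extra = 0.5 * (1 - p[top])
            bumped[top] += extra
            rest = np.delete(np.arange(4), top)
            bumped[rest] *= (1 - bumped[top]) / bumped[rest].sum()
            for f in (least_confidence_scores, margin_scores, entropy_scores):
                assert f(bumped[None])[0] <= f(p[None])[0] + 1e-9


def make_context(rng, n_labeled=6, n_unlabeled=12, dim=5, n_classes=3):
    ids = [f"d{i}" for i in range(n_labeled + n_unlabeled)]
    vecs = {i: rng.normal(size=dim) for i in ids}
    labels = [f"c{i % n_classes}" for i in range(n_labeled)]
    texts = {i: " ".join(["tok"] * int(rng.integers(1, 30))) for i in ids}
    return QueryContext(
        labeled_ids=ids[:n_labeled],
        labeled_labels=labels,
        unlabeled_ids=ids[n_labeled:],
        vectors=vecs,
        tfidf_vectors=vecs,
        texts=texts,
        rng=rng,
    )


class TestLengthWords:
    def test_argmax_tokens(self, rng):
        ctx = make_context(rng)
        ctx.texts = {i: ctx.texts[i] for i in ctx.unlabeled_ids}
        counts = {"a": 3, "b": 7, "c": 5}
        ctx.unlabeled_ids = list(counts)
        ctx.texts = {k: " ".join(["w"] * v) for k, v in counts.items()}
        assert length_words_select(ctx) == "b"

    def test_tie_break_lowest_index(self, rng):
        ctx = make_context(rng)
        ctx.unlabeled_ids = ["x", "y", "z"]
        ctx.texts = {k: "one two" for k in ctx.unlabeled_ids}
        assert length_words_select(ctx) == "x"

    def test_bruteforce_agreement(self, rng):
        ctx = make_context(rng, n_unlabeled=200)
        expected = max(
            ctx.unlabeled_ids, key=lambda u: (len(ctx.texts[u].split()), )
        )
        got = length_words_select(ctx)
        assert len(ctx.texts[got].split()) == len(ctx.texts[expected].split())

    def test_missing_texts_errors(self, rng):
        ctx = make_context(rng)
        ctx.texts = None
        with pytest.raises(ConfigurationError):
            length_words_select(ctx)


class TestMinSimilarity:
    def test_picks_lowest_similarity(self, rng):
        labeled = np.array([1.0, 0.0])
        ctx = QueryContext(
            labeled_ids=["l"], labeled_labels=["c0"], unlabeled_ids=["near", "far"],
            vectors={"l": labeled, "near": np.array([0.9, 0.1]),
                     "far": np.array([0.1, 0.9])},
            rng=rng,
        )
        assert min_similarity_select(ctx) == "far"

    def test_orthogonal_beats_identical(self, rng):
        v = np.array([1.0, 0.0])
        ctx = QueryContext(
            labeled_ids=["l"], labeled_labels=["c0"],
            unlabeled_ids=["same", "orth"],
            vectors={"l": v, "same": v.copy(), "orth": np.array([0.0, 1.0])},
            rng=rng,
        )
        assert min_similarity_select(ctx) == "orth"

    def test_bruteforce_oracle(self, rng):
        ctx = make_context(rng, n_labeled=10, n_unlabeled=40)
        best_u, best_score = None, np.inf
        for u in ctx.unlabeled_ids:
            sims = [
                cosine_similarity(ctx.vectors[x], ctx.vectors[u])
                for x in ctx.labeled_ids
            ]
            score = float(np.mean(sims))
            if score < best_score:
                best_u, best_score = u, score
        assert min_similarity_select(ctx) == best_u

    def test_empty_labeled_errors(self, rng):
        ctx = make_context(rng, n_labeled=0)
        ctx.labeled_labels = []
        with pytest.raises(ValueError):
            min_similarity_select(ctx)


class TestClassAverageSimilarity:
    def test_mean_of_two_members(self, rng):
        # construct members at known cosine similarities to u
        u = np.array([1.0, 0.0])
        a = np.array([0.8, 0.6])   # cos = 0.8
        b = np.array([0.6, 0.8])   # cos = 0.6
        ctx = QueryContext(
            labeled_ids=["a", "b"], labeled_labels=["c", "c"],
            unlabeled_ids=["u"], vectors={"a": a, "b": b, "u": u}, rng=rng,
        )
        names, sims = class_average_similarity(ctx, "u")
        assert names == ["c"]
        assert sims[0] == pytest.approx(0.7)

    def test_identical_sole_member_gives_one(self, rng):
        v = np.array([0.3, 0.4])
        ctx = QueryContext(
            labeled_ids=["a"], labeled_labels=["c"], unlabeled_ids=["u"],
            vectors={"a": v, "u": v.copy()}, rng=rng,
        )
        _, sims = class_average_similarity(ctx, "u")
        assert sims[0] == pytest.approx(1.0)

    def test_bruteforce_on_three_class_fixture(self, rng):
        ctx = make_context(rng, n_labeled=30, n_unlabeled=1, n_classes=3)
        u = ctx.unlabeled_ids[0]
        names, sims = class_average_similarity(ctx, u)
        for name, sim in zip(names, sims):
            members = [
                x for x, lbl in zip(ctx.labeled_ids, ctx.labeled_labels)
                if lbl == name
            ]
            expected = np.mean(
                [cosine_similarity(ctx.vectors[x], ctx.vectors[u]) for x in members]
            )
            assert sim == pytest.approx(expected)


class TestSimilarityUncertainty:
    def test_equidistant_beats_skewed_under_every_mode(self, rng):
        ca = np.array([1.0, 0.0])
        cb = np.array([0.0, 1.0])
        ambiguous = np.array([1.0, 1.0])    # cos 0.707 to both
        skewed = np.array([1.0, 0.12])      # much closer to class a
        for mode in ("least_confidence", "margin", "entropy"):
            ctx = QueryContext(
                labeled_ids=["a", "b"], labeled_labels=["ca", "cb"],
                unlabeled_ids=["amb", "skew"],
                vectors={"a": ca, "b": cb, "amb": ambiguous, "skew": skewed},
                rng=rng,
            )
            assert similarity_uncertainty_select(ctx, mode) == "amb"

    def test_flat_similarity_gives_margin_one(self):
        assert pseudo_posterior(np.array([0.6, 0.6])).tolist() == [0.5, 0.5]
        assert margin_scores(pseudo_posterior(np.array([0.6, 0.6]))[None])[0] == 1.0

    def test_single_class_falls_back_with_warning(self, rng):
        ctx = make_context(rng, n_labeled=3, n_classes=1)
        with pytest.warns(UserWarning, match="one labeled class"):
            chosen = similarity_uncertainty_select(ctx, "margin")
        assert chosen in ctx.unlabeled_ids

    @pytest.mark.parametrize("mode", ["least_confidence", "margin", "entropy"])
    def test_bruteforce_oracle(self, rng, mode):
        from vteal.query_strategies import _UNCERTAINTY

        ctx = make_context(rng, n_labeled=12, n_unlabeled=38, n_classes=3)
        best_u, best = None, -np.inf
        for u in ctx.unlabeled_ids:
            by_class = {}
            for x, lbl in zip(ctx.labeled_ids, ctx.labeled_labels):
                by_class.setdefault(lbl, []).append(
                    cosine_similarity(ctx.vectors[x], ctx.vectors[u])
                )
            sims = np.array([np.mean(v) for v in by_class.values()])
            shifted = sims - sims.min()
            pp = (
                shifted / shifted.sum()
                if shifted.sum() > 0
                else np.full(len(sims), 1 / len(sims))
            )
            score = _UNCERTAINTY[mode](pp[None])[0]
            if score > best:
                best_u, best = u, score
        assert similarity_uncertainty_select(ctx, mode) == best_u


class TestSelectQuery:
    def test_pool_of_one_any_strategy(self, rng):
        ctx = make_context(rng, n_labeled=4, n_unlabeled=1)
        ctx.posteriors = np.array([[0.2, 0.3, 0.5]])
        only = ctx.unlabeled_ids[0]
        for name in ("random", "least_confidence", "margin", "entropy",
                     "length_words", "word_similarity", "tfidf_similarity",
                     "wordsim_entropy"):
            assert select_query(StrategySpec(name), ctx) == only

    def test_random_reproducible(self, rng):
        seq = []
        for _ in range(2):
            r = np.random.default_rng(99)
            ctx = make_context(np.random.default_rng(7))
            ctx.rng = r
            seq.append([select_query(StrategySpec("random"), ctx) for _ in range(5)])
        assert seq[0] == seq[1]

    def test_missing_posteriors_is_config_error(self, rng):
        ctx = make_context(rng)
        with pytest.raises(ConfigurationError, match="posteriors"):
            select_query(StrategySpec("least_confidence"), ctx)

    def test_least_confidence_matches_direct_sweep(self, rng):
        ctx = make_context(rng, n_unlabeled=100)
        ctx.posteriors = random_posteriors(rng, 100, 4)
        expected = ctx.unlabeled_ids[
            int(np.argmax(1 - ctx.posteriors.max(axis=1)))
        ]
        assert select_query(StrategySpec("least_confidence"), ctx) == expected

    def test_selected_id_always_from_pool(self, rng):
        for _ in range(10):
            ctx = make_context(rng)
            ctx.posteriors = random_posteriors(rng, len(ctx.unlabeled_ids), 3)
            for name in ("random", "entropy", "word_similarity", "length_words"):
                assert select_query(StrategySpec(name), ctx) in ctx.unlabeled_ids

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            StrategySpec("banana")
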