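"""Cosine-similarity augmentation: vectors, calibration, injection."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st

from misinfonet.balance import (
    CosineSimilarityAugmenter,
    calibrate_threshold,
    cosine,
    doc_vector,
    inject_trustworthy,
    make_tfidf,
    similarity_to_seeds,
)
from misinfonet.corpus import Document
from misinfonet.preprocess import TokenSequence


def _ts(doc_id, *tokens):
    return TokenSequence(doc_id, tokens)


class TestDocVector:
    def test_single_doc_two_positive_weights(self):
        vec = make_tfidf([_ts("a", "covid", "real")])
        v = doc_vector(_ts("a", "covid", "real"), vec)
        assert v.nnz == 2
        assert (v.data > 0).all()

    def test_ubiquitous_term_weight_positive(self):
        corpus = [_ts("a", "covid", "aa"), _ts("b", "covid", "bb")]
        vec = make_tfidf(corpus)
        v = doc_vector(_ts("a", "covid"), vec)
        assert v.sum() > 0  # smoothed IDF floor keeps weight positive

    def test_disjoint_vocabularies_orthogonal(self):
        corpus = [_ts("a", "covid", "real"), _ts("b", "vaccine", "works")]
        vec = make_tfidf(corpus)
        u = doc_vector(corpus[0], vec)
        v = doc_vector(corpus[1], vec)
        assert cosine(u, v) == 0.0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            make_tfidf([])


class TestCosine:
    def test_self_similarity(self):
        u = np.array([0.5, 2.0, 0.0])
        assert cosine(u, u) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 3.0])) == 0.0

    def test_half(self):
        u, v = np.array([1.0, 1, 0]), np.array([1.0, 0, 1])
        assert cosine(u, v) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cosine(np.zeros(3), np.ones(3))


class TestSimilarityToSeeds:
    def test_identical_to_one_seed_scores_one(self):
        doc = sp.csr_matrix(np.array([[1.0, 2.0, 0.0]]))
        seeds = sp.csr_matrix(np.array([[0.0, 0.0, 1.0], [1.0, 2.0, 0.0]]))
        assert similarity_to_seeds(doc, seeds) == pytest.approx(1.0)

    def test_orthogonal_to_all_seeds_scores_zero(self):
        doc = sp.csr_matrix(np.array([[1.0, 0.0, 0.0]]))
        seeds = sp.csr_matrix(np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]))
        assert similarity_to_seeds(doc, seeds) == 0.0

    def test_maximum_over_seeds(self):
        # seeds engineered to give cosines 0.2, 0.7, 0.4 against the doc
        doc = np.array([[1.0, 0.0]])
        angles = [math.acos(0.2), math.acos(0.7), math.acos(0.4)]
        seeds = np.array([[math.cos(a), math.sin(a)] for a in angles])
        got = similarity_to_seeds(sp.csr_matrix(doc), sp.csr_matrix(seeds))
        assert got == pytest.approx(0.7)

    def test_mean_aggregation(self):
        doc = np.array([[1.0, 0.0]])
        seeds = np.array([[1.0, 0.0], [0.0, 1.0]])
        got = similarity_to_seeds(
            sp.csr_matrix(doc), sp.csr_matrix(seeds), aggregation="mean"
        )
        assert got == pytest.approx(0.5)

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            similarity_to_seeds(sp.csr_matrix(np.ones((1, 2))), sp.csr_matrix((0, 2)))


#: printed per-threshold verified tallies from the reference calibration table
VERIFIED_TALLIES = {
    0.1: (173, 66),
    0.15: (167, 61),
    0.2: (145, 48),
    0.25: (98, 33),
    0.3: (54, 18),
    0.35: (27, 9),
    0.4: (11, 6),
}


def scores_from_counts(counts: dict) -> list[tuple[float, str]]:
    """Reconstruct a score multiset whose per-threshold exceedance tallies
    reproduce a printed calibration table exactly."""
    thresholds = sorted(counts)
    scored = []
    for i, t in enumerate(thresholds):
        nxt = counts[thresholds[i + 1]] if i + 1 < len(thresholds) else (0, 0)
        mid = (t + thresholds[i + 1]) / 2 if i + 1 < len(thresholds) else t + 0.05
        scored += [(mid, "trustworthy")] * (counts[t][0] - nxt[0])
        scored += [(mid, "misinformation")] * (counts[t][1] - nxt[1])
    # documents below every threshold
    scored += [(thresholds[0] / 2, "misinformation")] * 4
    return scored


class TestCalibrateThreshold:
    def test_reproduces_printed_tallies_and_precisions(self):
        cal = calibrate_threshold(scores_from_counts(VERIFIED_TALLIES), sorted(VERIFIED_TALLIES))
        assert cal.true_counts == tuple(VERIFIED_TALLIES[t][0] for t in sorted(VERIFIED_TALLIES))
        assert cal.false_counts == tuple(VERIFIED_TALLIES[t][1] for t in sorted(VERIFIED_TALLIES))
        by_t = dict(zip(cal.thresholds, cal.precision))
        assert by_t[0.3] == pytest.approx(54 / 72) == pytest.approx(0.75)
        assert by_t[0.35] == pytest.approx(27 / 36) == pytest.approx(0.75)

    def test_counts_monotone_nonincreasing(self):
        cal = calibrate_threshold(scores_from_counts(VERIFIED_TALLIES), sorted(VERIFIED_TALLIES))
        assert all(a >= b for a, b in zip(cal.true_counts, cal.true_counts[1:]))
        assert all(a >= b for a, b in zip(cal.false_counts, cal.false_counts[1:]))

    def test_empty_cell_excluded_from_argmax(self):
        scored = [(0.12, "trustworthy"), (0.12, "misinformation")]
        cal = calibrate_threshold(scored, [0.1, 0.2, 0.3])
        assert math.isnan(cal.precision[1]) and math.isnan(cal.precision[2])
        assert cal.chosen == 0.1

    def test_warns_and_unset_when_nothing_exceeds(self):
        with pytest.warns(UserWarning, match="no verified document"):
            cal = calibrate_threshold([(0.05, "trustworthy")], [0.1, 0.2])
        assert cal.chosen is None

    def test_nonincreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([(0.5, "trustworthy")], [0.2, 0.2])

    @given(st.lists(st.tuples(st.floats(0, 1), st.booleans()), min_size=1, max_size=60))
    def test_matches_bruteforce_tally_exactly(self, raw):
        import warnings

        scored = [(s, "trustworthy" if b else "misinformation") for s, b in raw]
        grid = [0.1, 0.25, 0.5, 0.75]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            cal = calibrate_threshold(scored, grid, min_injected=0)
        for t, tc, fc, p in zip(grid, cal.true_counts, cal.false_counts, cal.precision):
            bt = sum(1 for s, lab in scored if s > t and lab == "trustworthy")
            bf = sum(1 for s, lab in scored if s > t and lab == "misinformation")
            assert (tc, fc) == (bt, bf)
            if bt + bf:
                assert p == bt / (bt + bf)
            else:
                assert math.isnan(p)


class TestInjectTrustworthy:
    def _candidates(self, scores):
        return [
            (Document(id=f"c{i}", text="t"), s) for i, s in enumerate(scores)
        ]

    def test_strictly_over_threshold(self):
        corpus = [Document(id="a", text="x", label="misinformation")]
        out, rep = inject_trustworthy(corpus, self._candidates([0.31, 0.30, 0.05]), 0.3)
        assert [i for i, _ in rep.injected] == ["c0"]
        assert len(out) == 2
        assert out[1].label == "trustworthy" and out[1].injected

    def test_threshold_one_injects_nothing(self):
        out, rep = inject_trustworthy([], self._candidates([0.9, 1.0]), 1.0)
        assert rep.injected == [] and out == []

    def test_higher_threshold_injects_subset(self):
        scores = [0.1, 0.25, 0.35, 0.5, 0.45]
        lo, _ = inject_trustworthy([], self._candidates(scores), 0.2)
        hi, _ = inject_trustworthy([], self._candidates(scores), 0.4)
        assert {d.id for d in hi} <= {d.id for d in lo}

    def test_existing_documents_conserved(self):
        corpus = [
            Document(id="a", text="x", label="misinformation"),
            Document(id="b", text="y", label="trustworthy"),
        ]
        out, _ = inject_trustworthy(corpus, self._candidates([0.9]), 0.3)
        assert out[:2] == corpus

    def test_duplicate_id_skipped_and_logged(self):
        corpus = [Document(id="c0", text="x", label="misinformation")]
        out, rep = inject_trustworthy(corpus, self._candidates([0.9]), 0.3)
        assert len(out) == 1
        assert rep.skipped_existing == ["c0"]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            inject_trustworthy([], [], 0.0)

    def test_minority_share_increases_when_injected(self):
        corpus = [Document(id=f"m{i}", text="x", label="misinformation") for i in range(8)]
        corpus += [Document(id="t0", text="y", label="trustworthy")]
        before = 1 / 9
        out, rep = inject_trustworthy(corpus, self._candidates([0.8, 0.9]), 0.3)
        after = sum(d.label == "trustworthy" for d in out) / len(out)
        assert len(rep.injected) == 2 and after > before


class TestAugmenterEstimator:
    def _fit(self, threshold=None):
        corpus = [
            _ts("m1", "microchip", "conspiracy", "hoax"),
            _ts("m2", "bleach", "cure", "hoax"),
            _ts("t1", "vaccine", "safe", "effective"),
        ]
        seeds = [
            (_ts("s1", "vaccine", "safe", "trial"), "trustworthy"),
            (_ts("s2", "mask", "protect", "spread"), "trustworthy"),
            (_ts("s3", "microchip", "conspiracy"), "misinformation"),
        ]
        aug = CosineSimilarityAugmenter(threshold=threshold)
        return aug.fit(corpus, seeds)

    def test_fixed_threshold_skips_calibration(self):
        aug = self._fit(threshold=0.3)
        assert aug.threshold_ == 0.3
        assert not hasattr(aug, "calibration_")

    def test_transform_injects_similar_candidates_only(self):
        aug = self._fit(threshold=0.3)
        cands = [
            Document(id="p1", text="vaccine safe booster"),
            Document(id="p2", text="alien lizard rulers"),
        ]
        ctoks = [_ts("p1", "vaccine", "safe", "booster"), _ts("p2", "alien", "lizard", "rulers")]
        out, rep = aug.transform([], cands, ctoks)
        assert [i for i, _ in rep.injected] == ["p1"]
        assert out[0].label == "trustworthy"

    def test_requires_trustworthy_seed(self):
        with pytest.raises(ValueError, match="trustworthy seed"):
            CosineSimilarityAugmenter().fit(
                [_ts("a", "xx", "yy")], [(_ts("s", "xx"), "misinformation")]
            )
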