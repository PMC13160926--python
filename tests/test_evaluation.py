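"""Ranking metrics vs. brute-force oracles; classification input strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avisep.corpus import DEFAULT_PROFILES
from avisep.evaluation import (
    BandEnergyClassifier,
    classify_with_strategy,
    multilabel_metrics,
)
from avisep.experiments import make_mixtures
from avisep.training import SISNR_CAP


# ---------------------------------------------------------------------------
# brute-force ranking oracles (independent of the implementation)
# ---------------------------------------------------------------------------

def oracle_average_precision(scores, labels):
    order = np.argsort(-scores, kind="stable")
    hits, total, precisions = 0, labels.sum(), []
    for rank, idx in enumerate(order, start=1):
        if labels[idx]:
            hits += 1
            precisions.append(hits / rank)
    return np.sum(precisions) / total


def oracle_auc(scores, labels):
    pos = scores[labels > 0]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def oracle_lwlrap(scores, labels):
    terms = []
    for s_row, l_row in zip(scores, labels):
        order = np.argsort(-s_row, kind="stable")
        ranked_labels = l_row[order]
        for rank, lab in enumerate(ranked_labels, start=1):
            if lab:
                terms.append(ranked_labels[:rank].sum() / rank)
    return np.mean(terms)


def random_instance(seed):
    rng = np.random.default_rng(seed)
    n, c = int(rng.integers(2, 9)), int(rng.integers(2, 6))
    scores = rng.random(size=(n, c))
    labels = (rng.random(size=(n, c)) < 0.4).astype(float)
    if labels.sum() == 0:
        labels[0, 0] = 1.0
    return scores, labels


class TestMultilabelMetrics:
    def test_perfect_scores_give_ones(self):
        labels = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        metrics = multilabel_metrics(labels.copy(), labels)
        assert all(metrics[m] == pytest.approx(1.0) for m in
                   ("cmap", "lwlrap", "auc", "top1"))

    def test_single_clip_hand_case(self):
        metrics = multilabel_metrics(np.array([[0.2, 0.9]]), np.array([[1.0, 0.0]]))
        assert metrics["top1"] == 0.0
        assert metrics["lwlrap"] == pytest.approx(0.5)

    @given(st.integers(min_value=0, max_value=100_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_oracles(self, seed):
        scores, labels = random_instance(seed)
        metrics = multilabel_metrics(scores, labels)
        aps = [oracle_average_precision(scores[:, c], labels[:, c])
               for c in range(scores.shape[1]) if labels[:, c].sum() > 0]
        assert metrics["cmap"] == pytest.approx(np.mean(aps), abs=1e-9)
        aucs = [oracle_auc(scores[:, c], labels[:, c])
                for c in range(scores.shape[1])
                if 0 < labels[:, c].sum() < len(labels)]
        if aucs:
            assert metrics["auc"] == pytest.approx(np.mean(aucs), abs=1e-9)
        assert metrics["lwlrap"] == pytest.approx(oracle_lwlrap(scores, labels),
                                                  abs=1e-9)
        top = np.argmax(scores, axis=1)
        expected_top1 = np.mean([labels[i, t] > 0 for i, t in enumerate(top)])
        assert metrics["top1"] == pytest.approx(expected_top1, abs=1e-12)

    def test_clip_order_invariance(self):
        scores, labels = random_instance(7)
        base = multilabel_metrics(scores, labels)
        perm = np.random.default_rng(0).permutation(len(scores))
        shuffled = multilabel_metrics(scores[perm], labels[perm])
        for key in base:
            assert base[key] == pytest.approx(shuffled[key], abs=1e-12)

    def test_no_positive_labels_rejected(self):
        with pytest.raises(ValueError):
            multilabel_metrics(np.ones((2, 2)), np.zeros((2, 2)))


@pytest.fixture(scope="module")
def classifier():
    return BandEnergyClassifier({p.name: p.band for p in DEFAULT_PROFILES})


@pytest.fixture(scope="module")
def small_mixtures():
    return make_mixtures(20, seed=3, n_sources=(2,), duration=0.25)


class TestStrategies:
    def test_band_classifier_identifies_single_species(self, classifier):
        from avisep.corpus import synth_song

        clip = synth_song(DEFAULT_PROFILES[0], 0.5, rng_seed=1)
        scores = classifier(clip.samples)
        assert classifier.species[int(np.argmax(scores))] == DEFAULT_PROFILES[0].name

    def test_mix_strategy_equals_direct_classification(self, classifier,
                                                       small_mixtures):
        result = classify_with_strategy(small_mixtures, None, classifier, "mix")
        direct = np.stack([classifier(ex.mixture) for ex in small_mixtures])
        np.testing.assert_array_equal(result.scores, direct)

    def test_max_combination_monotonicity(self, classifier, small_mixtures, recovery):
        model = recovery["model"]
        sep = classify_with_strategy(small_mixtures, model, classifier, "separation")
        both = classify_with_strategy(small_mixtures, model, classifier,
                                      "mix+separation")
        assert np.all(both.scores >= sep.scores - 1e-12)

    def test_separation_recovers_both_species_top2(self, classifier, recovery):
        # after fixture training, both mixed species should rank in the top 2
        examples = recovery["test_examples"]
        model = recovery["model"]
        result = classify_with_strategy(examples, model, classifier, "separation")
        hits = 0
        for row, ex in zip(result.scores, examples):
            top2 = {classifier.species[i] for i in np.argsort(-row)[:2]}
            hits += set(ex.species) <= top2
        assert hits / len(examples) >= 0.9

    def test_unknown_strategy_rejected(self, classifier, small_mixtures):
        with pytest.raises(ValueError):
            classify_with_strategy(small_mixtures, None, classifier, "bogus")


class TestEvalSeparation:
    def test_perfect_estimates_reach_cap(self, small_mixtures, monkeypatch):
        import avisep.evaluation as ev

        def oracle_separator(mixture, model, count_override=None):
            ex = next(e for e in small_mixtures if e.mixture is mixture)
            return count_override, np.stack(ex.sources)

        monkeypatch.setattr(ev, "count_and_separate", oracle_separator)
        table = ev.eval_separation(None, small_mixtures)
        assert np.allclose(table["si_snr"], SISNR_CAP)

    def test_mixture_as_estimate_has_zero_improvement(self, small_mixtures,
                                                      monkeypatch):
        import avisep.evaluation as ev

        def copy_separator(mixture, model, count_override=None):
            return count_override, np.tile(mixture, (count_override, 1))

        monkeypatch.setattr(ev, "count_and_separate", copy_separator)
        table = ev.eval_separation(None, small_mixtures)
        assert np.allclose(table["improvement"], 0.0, atol=1e-9)

    def test_trained_beats_untrained(self, recovery):
        assert (recovery["trained"]["si_snr"]
                >= recovery["untrained"]["si_snr"])
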