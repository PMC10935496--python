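"""Evaluation harness: splits, softmax, ranking metrics, OvR protocol."""

import math

import numpy as np
import pytest

from pathcorpus.cases import SelectionOutcome
from pathcorpus.cleaning import CorpusRecord, build_corpus
from pathcorpus.evaluate import (
    ClassTooSmallError,
    EvalResult,
    SplitSpec,
    TermFrequencyScorer,
    UndefinedMetricError,
    aggregate_results,
    auprc,
    auroc,
    run_ovr_experiment,
    softmax_scores,
    stratified_split,
)
from pathcorpus.simulate import GenSpec, PlantRates, generate_labeled_corpus


def records_for(label_counts, text_fn=None):
    out = []
    i = 0
    for label, n in label_counts.items():
        for _ in range(n):
            text = text_fn(label, i) if text_fn else f"tumor {label.lower()} t{i}"
            out.append(CorpusRecord(f"P{i:04d}", label, text))
            i += 1
    return out


class TestStratifiedSplit:
    def test_exact_division_single_class(self):
        recs = records_for({"BRCA": 100})
        tr, va, te = stratified_split(recs, SplitSpec(0.8, 0.1, 0.1, seed=0))
        assert (len(tr), len(va), len(te)) == (80, 10, 10)

    def test_two_classes_proportional(self):
        recs = records_for({"A": 10, "B": 10})
        tr, va, te = stratified_split(recs, SplitSpec(0.6, 0.2, 0.2, seed=0))
        for split, expected in ((tr, 6), (va, 2), (te, 2)):
            from collections import Counter

            counts = Counter(r.project_label for r in split)
            assert counts == {"A": expected, "B": expected}

    def test_membership_deterministic_under_shuffle(self):
        recs = records_for({"A": 17, "B": 23})
        spec = SplitSpec(seed=5)
        tr1, va1, te1 = stratified_split(recs, spec)
        rng = np.random.default_rng(0)
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        tr2, va2, te2 = stratified_split(shuffled, spec)
        for a, b in ((tr1, tr2), (va1, va2), (te1, te2)):
            assert {r.patient_id for r in a} == {r.patient_id for r in b}

    def test_disjoint_and_exhaustive(self):
        recs = records_for({"A": 13, "B": 29, "C": 7})
        tr, va, te = stratified_split(recs, SplitSpec(seed=3))
        ids = [r.patient_id for part in (tr, va, te) for r in part]
        assert len(ids) == len(set(ids)) == len(recs)

    def test_every_split_sees_every_class(self):
        recs = records_for({"A": 4, "B": 40})
        tr, va, te = stratified_split(recs, SplitSpec(seed=1))
        for part in (tr, va, te):
            assert {"A", "B"} <= {r.project_label for r in part}

    def test_class_too_small_named(self):
        recs = records_for({"A": 2, "B": 10})
        with pytest.raises(ClassTooSmallError, match="'A'"):
            stratified_split(recs, SplitSpec(seed=0))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec(0.8, 0.1, 0.2)


class TestSoftmax:
    def test_symmetric_pair_is_half(self):
        assert softmax_scores(np.array([[0.0, 0.0]]))[0] == pytest.approx(0.5)

    def test_large_margin_saturates(self):
        p = softmax_scores(np.array([[0.0, 1000.0], [1000.0, 0.0]]))
        assert p[0] == pytest.approx(1.0)
        assert p[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_logistic_oracle(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(0, 50, size=(200, 2))
        p = softmax_scores(raw)
        for (s0, s1), got in zip(raw, p):
            # independent closed form: sigmoid of the score margin
            expected = 1.0 / (1.0 + math.exp(s0 - s1))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_margin(self):
        raw = np.array([[0.0, -1.0], [0.0, 0.0], [0.0, 1.0], [0.0, 2.0]])
        p = softmax_scores(raw)
        assert np.all(np.diff(p) > 0)


def pairwise_auroc(scores, labels):
    """O(n^2) concordance oracle with half-credit ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestRankingMetrics:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_are_chance(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.2], [1, 1])
        with pytest.raises(UndefinedMetricError):
            auprc([0.1, 0.2], [0, 0])

    def test_auroc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(5, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            # mix continuous scores with deliberate ties
            scores = np.round(rng.uniform(0, 1, size=n), 1)
            assert auroc(scores, labels) == pytest.approx(
                pairwise_auroc(scores, labels), abs=1e-12
            )

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0, 1, size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        base = auroc(scores, labels)
        for f in (lambda s: 3 * s + 2, np.exp, lambda s: s ** 3):
            assert auroc(f(scores), labels) == pytest.approx(base)

    def test_auprc_matches_step_interpolation_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = 30
            labels = rng.integers(0, 2, size=n)
            labels[0], labels[1] = 0, 1
            scores = rng.uniform(0, 1, size=n)  # continuous: no ties
            order = np.argsort(-scores)
            y = labels[order]
            tp = fp = 0
            n_pos = labels.sum()
            ap = 0.0
            for yi in y:
                if yi == 1:
                    tp += 1
                    ap += (1.0 / n_pos) * (tp / (tp + fp))
                else:
                    fp += 1
            assert auprc(scores, labels) == pytest.approx(ap, abs=1e-12)


class PresenceScorer:
    """Deterministic scorer ranking by a token's presence; seed-independent."""

    max_tokens = 512

    def __init__(self, token):
        self.token = token

    def fit(self, texts, labels):
        return self

    def score(self, texts):
        d = np.array([1.0 if self.token in t else -1.0 for t in texts])
        return np.column_stack([-d, d])


@pytest.fixture(scope="module")
def corpus():
    spec = GenSpec(seed=41, class_counts={"BRCA": 40, "LUAD": 40,
                                          "COAD": 40},
                   plant_rates=PlantRates(qc_table=0.0))
    docs, _, labels = generate_labeled_corpus(spec)
    sel = SelectionOutcome(kept=[d.report_id for d in docs])
    records, _ = build_corpus(docs, sel, labels)
    return records


class TestOvrExperiment:

    def test_cardinality_classes_times_seeds(self, corpus):
        results = run_ovr_experiment(
            corpus, ["BRCA", "LUAD"], lambda s: TermFrequencyScorer(seed=s),
            seeds=[0, 1, 2], spec=SplitSpec(seed=0),
        )
        assert len(results) == 6
        assert {(r.class_label, r.seed) for r in results} == {
            (c, s) for c in ("BRCA", "LUAD") for s in (0, 1, 2)
        }

    def test_forced_separability_gives_perfect_auroc(self, corpus):
        """Disjoint class vocabularies make every one-vs-rest task
        perfectly separable for the bag-of-words baseline."""
        classes = sorted({r.project_label for r in corpus})
        results = run_ovr_experiment(
            corpus, classes, lambda s: TermFrequencyScorer(seed=s),
            seeds=[0], spec=SplitSpec(seed=0),
        )
        for r in results:
            assert r.test_auroc == 1.0
            assert r.test_auprc == 1.0

    def test_best_seed_tie_broken_low(self, corpus):
        results = run_ovr_experiment(
            corpus, ["BRCA"], lambda s: PresenceScorer("ductal"),
            seeds=[3, 1, 2], spec=SplitSpec(seed=0),
        )
        best = [r for r in results if r.is_best]
        assert len(best) == 1 and best[0].seed == 1

    def test_scorer_failure_isolated(self, corpus):
        class Exploder:
            max_tokens = 512

            def fit(self, texts, labels):
                raise RuntimeError("boom")

            def score(self, texts):
                raise RuntimeError("boom")

        results = run_ovr_experiment(
            corpus, ["BRCA"], lambda s: Exploder(), seeds=[0, 1],
            spec=SplitSpec(seed=0),
        )
        assert all(r.failed for r in results)


class TestAggregate:
    def _result(self, cls, seed, val, test_roc, test_prc, best=False):
        return EvalResult(cls, seed, val, test_roc, test_prc, 10, 2, 2,
                          is_best=best)

    def test_identical_seeds_zero_width_ci(self):
        rs = [self._result("A", s, 0.9, 0.95, 0.8, best=(s == 0))
              for s in range(5)]
        summary = aggregate_results(rs)
        (cls,) = summary.per_class
        assert cls.ci_auroc == (pytest.approx(0.95), pytest.approx(0.95))

    def test_single_class_mean_is_value(self):
        rs = [self._result("A", 0, 0.9, 0.97, 0.85, best=True)]
        summary = aggregate_results(rs)
        assert summary.mean_best_test_auroc == pytest.approx(0.97)
        assert summary.mean_best_test_auprc == pytest.approx(0.85)

    def test_three_value_t_interval_closed_form(self):
        values = [0.90, 0.94, 0.98]
        rs = [self._result("A", i, 0.9, v, v, best=(i == 0))
              for i, v in enumerate(values)]
        summary = aggregate_results(rs)
        mean = sum(values) / 3
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / 2)
        sem = sd / math.sqrt(3)
        t_crit = 4.302652729911275  # two-sided 95%, 2 degrees of freedom
        lo, hi = summary.per_class[0].ci_auroc
        assert lo == pytest.approx(mean - t_crit * sem, abs=1e-9)
        assert hi == pytest.approx(mean + t_crit * sem, abs=1e-9)

    def test_prevalence_order_respected(self):
        rs = [self._result("A", 0, 0.9, 0.9, 0.9, best=True),
              self._result("B", 0, 0.9, 0.8, 0.8, best=True)]
        summary = aggregate_results(rs, prevalence_order=["B", "A"])
        assert [c.class_label for c in summary.per_class] == ["B", "A"]
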