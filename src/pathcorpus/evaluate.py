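"""One-vs-rest cancer-type classification protocol.

The benchmark protocol is: stratify the labeled corpus into
train/validation/test splits; for each cancer type, train a binary
classifier (that type vs. all others) across several random seeds; score
with a softmax over the two raw class scores; select per class the seed
with the best validation AU-ROC; report that model's held-out test AU-ROC
and AU-PRC, plus cross-seed confidence intervals.

The classifier is pluggable through :class:`ScorerContract`; the bundled
:class:`TermFrequencyScorer` is a deterministic bag-of-words logistic
model honoring the 512-token input cap, so the whole protocol runs on one
CPU. A fine-tuned clinical transformer satisfies the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
from scipy import stats
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .cleaning import CorpusRecord


class UndefinedMetricError(ValueError):
    """Metric requested on labels containing a single class."""


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.8
    validation: float = 0.1
    test: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.train, self.validation, self.test) <= 0:
            raise ValueError("split fractions must be positive")
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


class ClassTooSmallError(ValueError):
    pass


def stratified_split(
    records: Sequence[CorpusRecord], spec: SplitSpec
) -> tuple[list[CorpusRecord], list[CorpusRecord], list[CorpusRecord]]:
    """Deterministic label-stratified three-way split.

    Per-class allocation uses largest-remainder rounding, so each class's
    count in each split differs from the exact proportion by less than 1.
    Membership depends only on the record set and the seed, not on input
    order.
    """
    by_label: dict[str, list[CorpusRecord]] = {}
    for r in sorted(records, key=lambda r: r.patient_id):
        by_label.setdefault(r.project_label, []).append(r)

    rng = np.random.default_rng(spec.seed)
    splits: tuple[list[CorpusRecord], ...] = ([], [], [])
    fractions = (spec.train, spec.validation, spec.test)
    for label in sorted(by_label):
        members = by_label[label]
        if len(members) < 3:
            raise ClassTooSmallError(
                f"class {label!r} has {len(members)} records; need >= 3"
            )
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        n = len(shuffled)
        exact = [f * n for f in fractions]
        base = [int(np.floor(e)) for e in exact]
        short = n - sum(base)
        remainders = sorted(
            range(3), key=lambda i: (exact[i] - base[i], -i), reverse=True
        )
        for i in remainders[:short]:
            base[i] += 1
        # every split must see every class at least once
        for i in range(3):
            if base[i] == 0:
                donor = int(np.argmax(base))
                base[donor] -= 1
                base[i] += 1
        cursor = 0
        for i in range(3):
            splits[i].extend(shuffled[cursor:cursor + base[i]])
            cursor += base[i]
    return splits[0], splits[1], splits[2]


# ---------------------------------------------------------------------------
# scoring


def softmax_scores(raw: np.ndarray) -> np.ndarray:
    """Positive-class probabilities from (n, 2) raw two-class scores.

    Overflow-safe: the row max is subtracted before exponentiation. The
    result is strictly increasing in ``raw[:, 1] - raw[:, 0]``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 2:
        raise ValueError(f"expected (n, 2) scores, got shape {raw.shape}")
    shifted = raw - raw.max(axis=1, keepdims=True)
    ex = np.exp(shifted)
    return ex[:, 1] / ex.sum(axis=1)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney form: the probability that a
    random positive outscores a random negative, ties counted 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AU-ROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by the step-interpolation
    (average-precision) convention: sum over recall increments of the
    precision at each threshold."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AU-PRC needs both classes present")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


class ScorerContract(Protocol):
    """Binary scorer: fit on texts and 0/1 labels, emit (n, 2) raw scores.

    ``score`` must be deterministic given the fitted state and honor the
    ``max_tokens`` truncation limit on input text.
    """

    max_tokens: int

    def fit(self, texts: Sequence[str], labels: Sequence[int]) -> "ScorerContract":
        ...

    def score(self, texts: Sequence[str]) -> np.ndarray:
        ...


class TermFrequencyScorer:
    """Deterministic bag-of-words logistic scorer.

    Texts are truncated to ``max_tokens`` whitespace tokens (matching the
    512-token cap of transformer scorers), vectorized by term counts, and
    scored by L2-regularized logistic regression. Raw output is (n, 2):
    (-d/2, +d/2) for decision value d, so the downstream softmax
    reproduces the model's own probability.
    """

    def __init__(self, max_tokens: int = 512, seed: int = 0, C: float = 1.0):
        self.max_tokens = max_tokens
        self.seed = seed
        self.C = C
        self._vec: Optional[CountVectorizer] = None
        self._clf: Optional[LogisticRegression] = None

    def _truncate(self, text: str) -> str:
        return " ".join(text.split()[: self.max_tokens])

    def fit(self, texts: Sequence[str], labels: Sequence[int]) -> "TermFrequencyScorer":
        self._vec = CountVectorizer(lowercase=True)
        X = self._vec.fit_transform(self._truncate(t) for t in texts)
        self._clf = LogisticRegression(
            C=self.C, max_iter=1000, random_state=self.seed
        )
        self._clf.fit(X, np.asarray(labels))
        return self

    def score(self, texts: Sequence[str]) -> np.ndarray:
        if self._vec is None or self._clf is None:
            raise RuntimeError("scorer is not fitted")
        X = self._vec.transform(self._truncate(t) for t in texts)
        d = self._clf.decision_function(X)
        return np.column_stack([-d / 2.0, d / 2.0])


# ---------------------------------------------------------------------------
# experiment


@dataclass(frozen=True)
class EvalResult:
    class_label: str
    seed: int
    val_auroc: float
    test_auroc: float
    test_auprc: float
    n_pos_train: int
    n_pos_val: int
    n_pos_test: int
    is_best: bool = False
    failed: bool = False


ScorerFactory = Callable[[int], ScorerContract]


def run_ovr_experiment(
    records: Sequence[CorpusRecord],
    classes: Sequence[str],
    scorer_factory: ScorerFactory,
    seeds: Sequence[int],
    spec: SplitSpec,
) -> list[EvalResult]:
    """Train and evaluate one-vs-rest scorers for every class x seed.

    For each class the labels are binarized (class vs. rest) on a shared
    stratified split; per class, the seed with the highest validation
    AU-ROC is marked best (ties broken toward the lowest seed). A scorer
    failure in one cell is recorded and the experiment continues.
    """
    train, val, test = stratified_split(records, spec)
    results: list[EvalResult] = []
    for cls in classes:
        y = {
            split_name: np.array(
                [1 if r.project_label == cls else 0 for r in split], dtype=int
            )
            for split_name, split in (("train", train), ("val", val), ("test", test))
        }
        texts = {
            "train": [r.text for r in train],
            "val": [r.text for r in val],
            "test": [r.text for r in test],
        }
        cls_results: list[EvalResult] = []
        for seed in seeds:
            try:
                scorer = scorer_factory(seed)
                scorer.fit(texts["train"], y["train"])
                val_p = softmax_scores(scorer.score(texts["val"]))
                test_p = softmax_scores(scorer.score(texts["test"]))
                cls_results.append(
                    EvalResult(
                        class_label=cls,
                        seed=seed,
                        val_auroc=auroc(val_p, y["val"]),
                        test_auroc=auroc(test_p, y["test"]),
                        test_auprc=auprc(test_p, y["test"]),
                        n_pos_train=int(y["train"].sum()),
                        n_pos_val=int(y["val"].sum()),
                        n_pos_test=int(y["test"].sum()),
                    )
                )
            except Exception:  # noqa: BLE001 - isolate cell failures
                cls_results.append(
                    EvalResult(
                        class_label=cls, seed=seed, val_auroc=float("nan"),
                        test_auroc=float("nan"), test_auprc=float("nan"),
                        n_pos_train=0, n_pos_val=0, n_pos_test=0, failed=True,
                    )
                )
        ok = [r for r in cls_results if not r.failed]
        if ok:
            best = max(ok, key=lambda r: (r.val_auroc, -r.seed))
            cls_results = [
                EvalResult(**{**r.__dict__, "is_best": r is best})
                for r in cls_results
            ]
        results.extend(cls_results)
    return results


@dataclass(frozen=True)
class ClassSummary:
    class_label: str
    best_seed: int
    best_test_auroc: float
    best_test_auprc: float
    mean_test_auroc: float
    ci_auroc: tuple[float, float]
    mean_test_auprc: float
    ci_auprc: tuple[float, float]
    n_seeds: int


@dataclass(frozen=True)
class ExperimentSummary:
    per_class: list[ClassSummary]
    mean_best_test_auroc: float
    mean_best_test_auprc: float


def _t_interval(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval for the mean across seeds; width 0
    when all values coincide or only one value exists."""
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return (mean, mean)
    sem = float(np.std(values, ddof=1)) / np.sqrt(n)
    if sem == 0:
        return (mean, mean)
    half = float(stats.t.ppf(0.5 + level / 2, df=n - 1)) * sem
    return (mean - half, mean + half)


def aggregate_results(
    results: Sequence[EvalResult],
    prevalence_order: Optional[Sequence[str]] = None,
) -> ExperimentSummary:
    """Summarize per-class best-seed test metrics and cross-seed CIs.

    The headline numbers are the means over classes of the best-by-
    validation model's test AU-ROC and AU-PRC. ``prevalence_order``
    controls the row order of the per-class table (most prevalent first).
    """
    by_class: dict[str, list[EvalResult]] = {}
    for r in results:
        if not r.failed:
            by_class.setdefault(r.class_label, []).append(r)
    order = list(prevalence_order) if prevalence_order else sorted(by_class)
    summaries: list[ClassSummary] = []
    for cls in order:
        rs = by_class.get(cls)
        if not rs:
            continue
        best = next((r for r in rs if r.is_best), rs[0])
        aurocs = np.array([r.test_auroc for r in rs])
        auprcs = np.array([r.test_auprc for r in rs])
        summaries.append(
            ClassSummary(
                class_label=cls,
                best_seed=best.seed,
                best_test_auroc=best.test_auroc,
                best_test_auprc=best.test_auprc,
                mean_test_auroc=float(aurocs.mean()),
                ci_auroc=_t_interval(aurocs),
                mean_test_auprc=float(auprcs.mean()),
                ci_auprc=_t_interval(auprcs),
                n_seeds=len(rs),
            )
        )
    if not summaries:
        raise ValueError("no successful results to aggregate")
    return ExperimentSummary(
        per_class=summaries,
        mean_best_test_auroc=float(
            np.mean([s.best_test_auroc for s in summaries])
        ),
        mean_best_test_auprc=float(
            np.mean([s.best_test_auprc for s in summaries])
        ),
    )
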