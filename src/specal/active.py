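"""Pool-based active learning around the boosted-tree learner.

The protocol mirrors a field-labeling campaign: a stratified test split is
held out, a small initial labeled pool (at least one sample per class) is
drawn from the remainder, and the rest forms the unlabeled pool.  Each
iteration the learner is fitted on the labeled set, scores the pool with an
uncertainty criterion — least confidence (one minus the top class
probability) by default — and the most uncertain batch is "annotated" from
the hidden ground truth and moved into the labeled set, until the query
budget is spent.  Baselines: random querying, a logistic-regression active
learner, and passive random-forest / decision-tree classifiers trained on
the same number of labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import boosting
from .exceptions import ConfigError, ProtocolError
from .metrics import MetricsReport, evaluate

__all__ = [
    "ALConfig",
    "ALState",
    "init_pools",
    "least_confidence",
    "entropy_score",
    "select_batch",
    "run_eal",
    "run_comparison",
    "BoostLearner",
    "SKLearner",
]

logger = logging.getLogger(__name__)


@dataclass
class ALConfig:
    """Active-learning protocol settings.

    Defaults follow the study protocol on a 750-sample, 15-class pool:
    30% held out for testing, 52 initial labels (~9.9% of the remainder,
    at least one per class), a budget of 60 queries spent over 5 equal
    iterations of 12.
    """

    initial_labeled: float | int = 52
    budget: int = 60
    n_iterations: int = 5
    batch_size: int | None = None
    query_strategy: str = "least_confidence"
    test_fraction: float = 0.3
    n_runs: int = 5
    label_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.budget < 0:
            raise ConfigError("budget must be non-negative")
        if self.budget == 0:
            self.batch_size = 0
        elif self.batch_size is None:
            if self.budget % self.n_iterations:
                raise ConfigError(
                    f"budget {self.budget} not divisible by "
                    f"{self.n_iterations} iterations; set batch_size")
            self.batch_size = self.budget // self.n_iterations
        elif self.batch_size * self.n_iterations != self.budget:
            raise ConfigError("batch_size * n_iterations must equal budget")
        if self.query_strategy not in ("least_confidence", "entropy", "random"):
            raise ConfigError(f"unknown query strategy '{self.query_strategy}'")
        if not 0 <= self.label_flip_rate < 1:
            raise ConfigError("label_flip_rate must be in [0, 1)")


@dataclass
class ALState:
    """Index partition plus per-iteration history."""

    labeled_idx: np.ndarray
    unlabeled_idx: np.ndarray
    test_idx: np.ndarray
    history: list = field(default_factory=list)

    def check_partition(self, n_total: int) -> None:
        combined = np.concatenate(
            [self.labeled_idx, self.unlabeled_idx, self.test_idx])
        if combined.size != n_total or np.unique(combined).size != n_total:
            raise ProtocolError("pools do not partition the dataset")

    @property
    def final_report(self) -> MetricsReport:
        return self.history[-1]["report"]


def _stratified_counts(class_sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of `total` across classes."""
    exact = class_sizes * total / class_sizes.sum()
    counts = np.floor(exact).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        frac = exact - counts
        # ties toward the lower class index
        order = np.lexsort((np.arange(frac.size), -frac))
        counts[order[:remainder]] += 1
    return counts


def init_pools(labels: np.ndarray, config: ALConfig,
               n_classes: int | None = None) -> ALState:
    """Partition samples into test / initial-labeled / unlabeled pools.

    The test split is stratified to ``test_fraction``; the initial labeled
    pool takes one random sample per class first, then fills uniformly at
    random.  Deterministic for a fixed ``config.seed``.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    rng = np.random.default_rng(config.seed)

    class_members = [np.where(labels == c)[0] for c in range(n_classes)]
    class_sizes = np.array([m.size for m in class_members])
    if (class_sizes == 0).any():
        raise ConfigError("every class must have at least one sample")

    n_test = int(round(n * config.test_fraction))
    test_counts = _stratified_counts(class_sizes, n_test)
    test_parts = []
    for members, count in zip(class_members, test_counts):
        test_parts.append(rng.choice(members, size=count, replace=False))
    test_idx = np.sort(np.concatenate(test_parts))

    remainder = np.setdiff1d(np.arange(n), test_idx)
    n_initial = (config.initial_labeled
                 if isinstance(config.initial_labeled, (int, np.integer))
                 else int(round(config.initial_labeled * remainder.size)))
    if n_initial < n_classes:
        raise ConfigError(
            f"initial_labeled {n_initial} is below the class count {n_classes}")
    if n_initial + config.budget > remainder.size:
        raise ConfigError(
            "initial labels plus budget exceed the non-test sample count")

    # one guaranteed sample per class, then uniform fill
    labeled_parts = []
    for c in range(n_classes):
        pool_c = np.intersect1d(class_members[c], remainder)
        if pool_c.size == 0:
            raise ConfigError(f"class {c} has no non-test samples")
        labeled_parts.append(rng.choice(pool_c, size=1))
    labeled_idx = np.concatenate(labeled_parts)
    fill_pool = np.setdiff1d(remainder, labeled_idx)
    extra = n_initial - labeled_idx.size
    if extra > 0:
        labeled_idx = np.concatenate(
            [labeled_idx, rng.choice(fill_pool, size=extra, replace=False)])
    labeled_idx = np.sort(labeled_idx)
    unlabeled_idx = np.setdiff1d(remainder, labeled_idx)

    state = ALState(labeled_idx=labeled_idx, unlabeled_idx=unlabeled_idx,
                    test_idx=test_idx)
    state.check_partition(n)
    return state


def least_confidence(proba: np.ndarray) -> np.ndarray:
    """Uncertainty ``1 - max_c p_c``: 0 for a one-hot row, maximal for uniform."""
    proba = np.atleast_2d(np.asarray(proba, dtype=float))
    return 1.0 - proba.max(axis=1)


def entropy_score(proba: np.ndarray) -> np.ndarray:
    """Shannon entropy per row in nats, with ``0 log 0 = 0``."""
    proba = np.atleast_2d(np.asarray(proba, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(proba > 0, proba * np.log(proba), 0.0)
    return -terms.sum(axis=1)


def select_batch(scores: np.ndarray, pool_idx: np.ndarray,
                 batch_size: int) -> np.ndarray:
    """The ``batch_size`` most uncertain pool members; ties to lowest index."""
    order = np.lexsort((pool_idx, -np.asarray(scores, dtype=float)))
    return pool_idx[order[:batch_size]]


class BoostLearner:
    """Adapter exposing the from-scratch booster as a pool learner."""

    def __init__(self, params: boosting.BoostParams):
        self.params = params
        self.ensemble_ = None

    def fit(self, X, y):
        self.ensemble_ = boosting.fit(X, y, self.params)
        return self

    def predict_proba(self, X):
        return boosting.predict_proba(self.ensemble_, X)

    def predict(self, X):
        return boosting.predict(self.ensemble_, X)


class SKLearner:
    """Adapter for scikit-learn classifiers (comparison baselines)."""

    def __init__(self, estimator, n_classes: int):
        self.estimator = estimator
        self.n_classes = n_classes

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def predict_proba(self, X):
        proba = self.estimator.predict_proba(X)
        full = np.zeros((proba.shape[0], self.n_classes))
        full[:, np.asarray(self.estimator.classes_, dtype=int)] = proba
        return full

    def predict(self, X):
        return np.asarray(self.estimator.predict(X), dtype=int)


def run_eal(X: np.ndarray, y: np.ndarray, config: ALConfig, learner,
            state: ALState | None = None,
            n_classes: int | None = None) -> ALState:
    """Run the pool-based loop with the given learner and query strategy.

    Features ``X`` are whatever representation the pipeline produced
    (raw, scatter-corrected, or manifold coordinates); the embedding is
    computed once before the loop, not refitted per iteration.  With
    ``budget = 0`` this degenerates to passive learning with a single
    evaluation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if n_classes is None:
        n_classes = int(y.max()) + 1
    if state is None:
        state = init_pools(y, config, n_classes)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 997]))
    y_observed = y.copy()

    def annotate(idx: np.ndarray) -> None:
        if config.label_flip_rate > 0:
            flips = rng.random(idx.size) < config.label_flip_rate
            for i in idx[flips]:
                wrong = [c for c in range(n_classes) if c != y[i]]
                y_observed[i] = rng.choice(wrong)

    learner.fit(X[state.labeled_idx], y_observed[state.labeled_idx])

    if config.budget == 0:
        report = evaluate(y[state.test_idx],
                          learner.predict(X[state.test_idx]), n_classes)
        state.history.append({"iteration": 0, "queried": np.array([], int),
                              "scores": np.array([]), "report": report})
        return state

    n_total = y.size
    for iteration in range(1, config.n_iterations + 1):
        if state.unlabeled_idx.size < config.batch_size:
            raise ProtocolError(
                f"unlabeled pool exhausted at iteration {iteration}")
        proba = learner.predict_proba(X[state.unlabeled_idx])
        if config.query_strategy == "least_confidence":
            scores = least_confidence(proba)
        elif config.query_strategy == "entropy":
            scores = entropy_score(proba)
        else:  # random
            scores = rng.random(state.unlabeled_idx.size)
        queried = select_batch(scores, state.unlabeled_idx, config.batch_size)
        queried_scores = scores[np.searchsorted(state.unlabeled_idx, queried)]
        logger.debug("iteration %d queried %s", iteration, queried.tolist())
        annotate(queried)
        state.labeled_idx = np.sort(np.concatenate([state.labeled_idx, queried]))
        state.unlabeled_idx = np.setdiff1d(state.unlabeled_idx, queried)
        state.check_partition(n_total)
        learner.fit(X[state.labeled_idx], y_observed[state.labeled_idx])
        report = evaluate(y[state.test_idx],
                          learner.predict(X[state.test_idx]), n_classes)
        state.history.append({
            "iteration": iteration,
            "queried": queried,
            "queried_scores": queried_scores,
            "scores": scores,
            "report": report,
        })
    return state


def _default_learners(n_classes: int, boost_params, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.tree import DecisionTreeClassifier

    params = boosting.BoostParams(**{**vars(boost_params),
                                     "n_classes": n_classes, "seed": seed})
    return {
        "EAL": ("least_confidence", lambda: BoostLearner(params)),
        "AL": ("least_confidence", lambda: SKLearner(
            LogisticRegression(max_iter=2000), n_classes)),
        "Random": ("random", lambda: BoostLearner(params)),
        "RF": ("passive", lambda: SKLearner(
            RandomForestClassifier(n_estimators=100, random_state=seed),
            n_classes)),
        "DT": ("passive", lambda: SKLearner(
            DecisionTreeClassifier(random_state=seed), n_classes)),
    }


def run_comparison(X: np.ndarray, y: np.ndarray, config: ALConfig,
                   boost_params: boosting.BoostParams | None = None,
                   learners: dict | None = None,
                   base_state: ALState | None = None) -> pd.DataFrame:
    """Compare active learners and passive baselines at equal label counts.

    Every method sees the same per-run pools.  Passive methods (strategy
    ``"passive"``) are trained once on the random-query run's final labeled
    set, so all methods consume exactly ``initial + budget`` labels.
    Metrics are averaged over ``config.n_runs`` with explicit per-run seeds
    derived from ``config.seed``.  A precomputed ``base_state`` (e.g. the
    split a feature representation was fitted on) may be supplied when
    ``n_runs`` is 1.
    """
    y = np.asarray(y, dtype=int)
    n_classes = int(y.max()) + 1
    boost_params = boost_params or boosting.BoostParams(n_classes=n_classes)
    if base_state is not None and config.n_runs != 1:
        raise ConfigError("base_state requires n_runs == 1")
    rows: list[dict] = []
    for run in range(config.n_runs):
        run_seed = int(np.random.SeedSequence(
            [config.seed, run]).generate_state(1)[0] % 2**31)
        run_config = ALConfig(**{**vars(config), "seed": run_seed,
                                 "batch_size": None})
        methods = learners or _default_learners(n_classes, boost_params,
                                                run_seed)
        run_base = (base_state if base_state is not None
                    else init_pools(y, run_config, n_classes))
        random_final_labels: np.ndarray | None = None
        for name, (strategy, make_learner) in methods.items():
            state = ALState(labeled_idx=run_base.labeled_idx.copy(),
                            unlabeled_idx=run_base.unlabeled_idx.copy(),
                            test_idx=run_base.test_idx.copy())
            if strategy == "passive":
                if random_final_labels is None:
                    raise ConfigError(
                        "passive methods need a preceding random-query run")
                learner = make_learner()
                learner.fit(X[random_final_labels], y[random_final_labels])
                report = evaluate(y[state.test_idx],
                                  learner.predict(X[state.test_idx]),
                                  n_classes)
                n_labels = random_final_labels.size
            else:
                cfg = ALConfig(**{**vars(run_config),
                                  "query_strategy": strategy,
                                  "batch_size": None})
                state = run_eal(X, y, cfg, make_learner(), state=state,
                                n_classes=n_classes)
                report = state.final_report
                n_labels = state.labeled_idx.size
                if name == "Random":
                    random_final_labels = state.labeled_idx.copy()
            rows.append({"run": run, "method": name, "n_labels": n_labels,
                         "OA": report.oa, "Kappa": report.kappa,
                         "Macro": report.macro_precision,
                         "Recall": report.macro_recall,
                         "F1": report.macro_f1})
    frame = pd.DataFrame(rows)
    order = list((learners or {}).keys()) or ["EAL", "AL", "Random", "RF", "DT"]
    mean = frame.groupby("method")[["OA", "Kappa", "Macro", "Recall",
                                    "F1", "n_labels"]].mean()
    return mean.reindex([m for m in order if m in mean.index])
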