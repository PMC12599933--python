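"""Pool-based active-learning experiment driver.

Protocol per epoch: draw 8 seed labels uniformly from the training pool,
fit a fresh classifier, then repeatedly (i) score the unlabeled pool with
the configured query strategy, (ii) move the selected sample into the
labeled set, (iii) retrain from scratch and (iv) record macro-F1 on the
fixed test set — until the labeling budget is reached.  Whole experiments
repeat the epoch with derived seeds and aggregate per-iteration F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.svm import SVC

from .data_model import Corpus, SplitSpec, split_corpus
from .embeddings import DenseEmbedder, Vocabulary, tf_vectorize, tfidf_weight
from .evaluation import LearningCurve, curve_aggregate, macro_f1
from .query_strategies import (
    ConfigurationError,
    QueryContext,
    StrategySpec,
    select_query,
)

__all__ = [
    "CLASSIFIER_FAMILIES",
    "EMBEDDING_CHOICES",
    "ClassifierSpec",
    "ALConfig",
    "FeatureSet",
    "make_classifier",
    "posterior_matrix",
    "build_features",
    "run_epoch",
    "run_experiment",
]

CLASSIFIER_FAMILIES = ("random_forest", "svm", "svm_sgd", "gradient_boosting")
EMBEDDING_CHOICES = ("tf", "tfidf", "word_average", "document")

_NEEDS_POSTERIORS = {"least_confidence", "margin", "entropy"}


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family plus free-form hyperparameter overrides."""

    family: str = "random_forest"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")


@dataclass(frozen=True)
class ALConfig:
    """Active-learning experiment configuration.

    ``budget`` is a fraction of the training pool when in (0, 1], an
    absolute labeled-count target when > 1.
    """

    seed_size: int = 8
    budget: float = 0.5
    epochs: int = 50
    strategy: StrategySpec = field(default_factory=lambda: StrategySpec("random"))
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    embedding: str = "tf"
    master_seed: int = 0
    train_fraction: float = 0.8
    stratified_split: bool = True

    def __post_init__(self) -> None:
        if self.embedding not in EMBEDDING_CHOICES:
            raise ValueError(f"unknown embedding {self.embedding!r}")
        if self.seed_size < 1:
            raise ValueError("seed_size must be >= 1")
        if self.budget <= 0:
            raise ValueError("budget must be positive")

    def budget_count(self, pool_size: int) -> int:
        target = (
            int(np.floor(self.budget * pool_size))
            if self.budget <= 1.0
            else int(self.budget)
        )
        target = min(target, pool_size)
        if target <= self.seed_size:
            raise ValueError(
                f"budget ({target} labels) must exceed seed_size ({self.seed_size})"
            )
        return target


@dataclass
class FeatureSet:
    """Aligned ids / features / labels (plus texts and similarity vectors)."""

    ids: list[str]
    X: np.ndarray
    y: list[str]
    texts: list[str]
    vectors: Optional[np.ndarray] = None  # dense space for similarity strategies

    def __len__(self) -> int:
        return len(self.ids)


def make_classifier(spec: ClassifierSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.family == "svm":
        hp.setdefault("probability", True)
        return SVC(random_state=seed, **hp)
    if spec.family == "svm_sgd":
        # modified_huber = smoothed hinge; the standard probability-capable
        # margin loss for SGD
        hp.setdefault("loss", "modified_huber")
        return SGDClassifier(random_state=seed, **hp)
    if spec.family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **hp)
    raise ValueError(spec.family)  # pragma: no cover


def posterior_matrix(model, X: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    """Class posteriors over the full scheme; classes the model has never
    seen get probability 0."""
    if not hasattr(model, "predict_proba"):
        raise ConfigurationError(
            f"{type(model).__name__} cannot emit class probabilities"
        )
    proba = model.predict_proba(X)
    out = np.zeros((proba.shape[0], len(classes)))
    col = {c: j for j, c in enumerate(classes)}
    for k, cls in enumerate(model.classes_):
        out[:, col[cls]] = proba[:, k]
    return out


def build_features(
    train: Corpus, test: Corpus, embedding: str, seed: int = 0
) -> tuple[FeatureSet, FeatureSet]:
    """Vectorize train/test under one embedding scheme.

    The vocabulary (or dense model) is fitted on the training pool only;
    test documents never extend it.
    """
    train_texts, test_texts = train.texts(), test.texts()
    if embedding in ("tf", "tfidf"):
        vocab = Vocabulary.from_texts(train_texts)
        Xtr = tf_vectorize(train_texts, vocab)
        Xte = tf_vectorize(test_texts, vocab)
        if embedding == "tfidf":
            Xtr = tfidf_weight(Xtr, vocab)
            Xte = tfidf_weight(Xte, vocab)
        Xtr, Xte = Xtr.toarray(), Xte.toarray()
        vec_tr, vec_te = Xtr, Xte
    else:
        mode = "word_average" if embedding == "word_average" else "document"
        embedder = DenseEmbedder(mode=mode, dim=100, seed=seed)
        embedder.fit(train_texts)
        Xtr = embedder.transform(train_texts)
        Xte = embedder.transform(test_texts)
        vec_tr, vec_te = Xtr, Xte
    ftr = FeatureSet(
        ids=[r.id for r in train], X=Xtr, y=train.label_list(),
        texts=train_texts, vectors=vec_tr,
    )
    fte = FeatureSet(
        ids=[r.id for r in test], X=Xte, y=test.label_list(),
        texts=test_texts, vectors=vec_te,
    )
    return ftr, fte


def _strategy_needs(name: str) -> tuple[bool, bool, bool]:
    """(posteriors, vectors, texts) requirements for a strategy name."""
    needs_post = name in _NEEDS_POSTERIORS
    needs_vec = name in ("word_similarity", "tfidf_similarity") or name.startswith(
        "wordsim_"
    )
    needs_text = name == "length_words"
    return needs_post, needs_vec, needs_text


def run_epoch(
    config: ALConfig,
    pool: FeatureSet,
    test: FeatureSet,
    epoch_rng: np.random.Generator,
    scheme: str | Sequence[str] = "7-class",
    audit: Optional[list[tuple[int, str]]] = None,
) -> list[float]:
    """One active-learning epoch; returns the F1 trajectory
    (index 0 = seed model, index i = after i queries)."""
    n = len(pool)
    budget = config.budget_count(n)
    if len(test) == 0:
        raise ValueError("test set is empty")
    model_seed = int(epoch_rng.integers(2**31 - 1))
    seed_idx = sorted(epoch_rng.choice(n, size=config.seed_size, replace=False))
    labeled = list(seed_idx)
    unlabeled = [i for i in range(n) if i not in set(labeled)]

    needs_post, needs_vec, needs_text = _strategy_needs(config.strategy.name)
    if needs_vec and pool.vectors is None:
        raise ConfigurationError(
            f"{config.strategy.name} requires document vectors in the pool"
        )

    def fit_and_score() -> tuple[object, float]:
        model = make_classifier(config.classifier, model_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny fits trip convergence warnings
            model.fit(pool.X[labeled], [pool.y[i] for i in labeled])
        preds = model.predict(test.X)
        return model, macro_f1(test.y, list(preds), scheme)

    model, f1 = fit_and_score()
    trajectory = [f1]
    iteration = 0
    while len(labeled) < budget:
        iteration += 1
        id_of = pool.ids
        posteriors = (
            posterior_matrix(model, pool.X[unlabeled], sorted(set(pool.y)))
            if needs_post
            else None
        )
        vec_map = None
        tfidf_map = None
        if needs_vec:
            vec_map = {id_of[i]: pool.vectors[i] for i in labeled + unlabeled}
            tfidf_map = vec_map
        texts_map = (
            {id_of[i]: pool.texts[i] for i in unlabeled} if needs_text else None
        )
        context = QueryContext(
            labeled_ids=[id_of[i] for i in labeled],
            labeled_labels=[pool.y[i] for i in labeled],
            unlabeled_ids=[id_of[i] for i in unlabeled],
            posteriors=posteriors,
            vectors=vec_map,
            tfidf_vectors=tfidf_map,
            texts=texts_map,
            rng=epoch_rng,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            chosen = select_query(config.strategy, context)
        chosen_idx = pool.ids.index(chosen)
        labeled.append(chosen_idx)
        unlabeled.remove(chosen_idx)
        if audit is not None:
            audit.append((iteration, chosen))
        model, f1 = fit_and_score()
        trajectory.append(f1)
    return trajectory


def run_experiment(config: ALConfig, corpus: Corpus) -> LearningCurve:
    """Split once, fix the test set, run ``config.epochs`` independent
    epochs with derived seeds, and aggregate per-iteration mean/sd F1."""
    train, test = split_corpus(
        corpus,
        SplitSpec(
            train_fraction=config.train_fraction,
            seed=config.master_seed,
            stratified=config.stratified_split,
        ),
    )
    pool_fs, test_fs = build_features(
        train, test, config.embedding, seed=config.master_seed
    )
    trajectories = []
    for epoch in range(config.epochs):
        epoch_rng = np.random.default_rng(config.master_seed + epoch)
        trajectories.append(
            run_epoch(config, pool_fs, test_fs, epoch_rng, scheme=corpus.label_scheme)
        )
    return curve_aggregate(trajectories)
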