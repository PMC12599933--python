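"""Active-learning query strategies.

Scores unlabeled candidates and returns the single id to label next.
Available strategies: random, the three uncertainty functionals
(least confidence, margin, entropy), Length-Words, word / TF-IDF
cosine-similarity novelty, and the combined word-similarity uncertainty
strategies which turn per-class average similarities into a
pseudo-posterior before applying an uncertainty functional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .embeddings import cosine_similarity, tokenize

__all__ = [
    "STRATEGY_NAMES",
    "PosteriorMatrix",
    "QueryContext",
    "StrategySpec",
    "ConfigurationError",
    "least_confidence_scores",
    "margin_scores",
    "entropy_scores",
    "length_words_select",
    "min_similarity_select",
    "class_average_similarity",
    "similarity_uncertainty_select",
    "select_query",
]

STRATEGY_NAMES = (
    "random",
    "least_confidence",
    "margin",
    "entropy",
    "length_words",
    "word_similarity",
    "tfidf_similarity",
    "wordsim_least_confidence",
    "wordsim_margin",
    "wordsim_entropy",
)

PosteriorMatrix = np.ndarray  # (n_unlabeled, n_classes); rows sum to 1


class ConfigurationError(ValueError):
    """A strategy was asked to run without its required inputs."""


@dataclass
class QueryContext:
    """Everything a query strategy may read.

    ``vectors`` is the dense embedding space, ``tfidf_vectors`` the sparse
    TF-IDF space (both keyed by report id); either may be absent when no
    similarity strategy is in play.  ``posteriors`` rows align with
    ``unlabeled_ids``.
    """

    labeled_ids: list[str]
    labeled_labels: list[str]
    unlabeled_ids: list[str]
    posteriors: Optional[PosteriorMatrix] = None
    vectors: Optional[Mapping[str, np.ndarray]] = None
    tfidf_vectors: Optional[Mapping[str, np.ndarray]] = None
    texts: Optional[Mapping[str, str]] = None
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self) -> None:
        if len(self.labeled_ids) != len(self.labeled_labels):
            raise ValueError("labeled_ids and labeled_labels length mismatch")
        overlap = set(self.labeled_ids) & set(self.unlabeled_ids)
        if overlap:
            raise ValueError(f"ids both labeled and unlabeled: {sorted(overlap)[:5]}")


@dataclass(frozen=True)
class StrategySpec:
    name: str
    tie_break: str = "lowest_index"
    #: "mean" (default) or "min" aggregation of similarity to labeled samples
    similarity_aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}")
        if self.tie_break not in ("lowest_index", "random"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        if self.similarity_aggregate not in ("mean", "min"):
            raise ValueError(f"unknown similarity_aggregate {self.similarity_aggregate!r}")


# ---------------------------------------------------------------------------
# uncertainty functionals
# ---------------------------------------------------------------------------

def _check_posteriors(posteriors: np.ndarray) -> np.ndarray:
    p = np.asarray(posteriors, dtype=np.float64)
    if p.ndim == 1:
        p = p[None, :]
    if p.size == 0:
        raise ValueError("empty posterior matrix")
    return p


def least_confidence_scores(posteriors: PosteriorMatrix) -> np.ndarray:
    """``1 - max_c P(c | x)`` per row; larger = more uncertain."""
    p = _check_posteriors(posteriors)
    return 1.0 - p.max(axis=1)


def margin_scores(posteriors: PosteriorMatrix) -> np.ndarray:
    """``1 - (top1 - top2)`` per row; larger = more uncertain."""
    p = _check_posteriors(posteriors)
    if p.shape[1] < 2:
        raise ValueError("margin requires at least 2 classes")
    part = np.sort(p, axis=1)
    return 1.0 - (part[:, -1] - part[:, -2])


def entropy_scores(posteriors: PosteriorMatrix) -> np.ndarray:
    """Shannon entropy (natural log) per row, with ``0 log 0 := 0``."""
    p = _check_posteriors(posteriors)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=1)


_UNCERTAINTY = {
    "least_confidence": least_confidence_scores,
    "margin": margin_scores,
    "entropy": entropy_scores,
}


# ---------------------------------------------------------------------------
# selection helpers
# ---------------------------------------------------------------------------

def _argbest(
    scores: np.ndarray,
    ids: Sequence[str],
    rng: np.random.Generator,
    tie_break: str,
    maximize: bool = True,
) -> str:
    scores = np.asarray(scores, dtype=np.float64)
    best = scores.max() if maximize else scores.min()
    ties = np.flatnonzero(scores == best)
    if tie_break == "random" and len(ties) > 1:
        return ids[int(rng.choice(ties))]
    return ids[int(ties[0])]


def length_words_select(
    context: QueryContext, spec: Optional[StrategySpec] = None
) -> str:
    """Unlabeled document with the most tokens (more words, more information)."""
    spec = spec or StrategySpec("length_words")
    if context.texts is None:
        raise ConfigurationError("length_words requires context.texts")
    if not context.unlabeled_ids:
        raise ValueError("unlabeled pool is empty")
    counts = np.array(
        [len(tokenize(context.texts[u])) for u in context.unlabeled_ids],
        dtype=np.float64,
    )
    return _argbest(counts, context.unlabeled_ids, context.rng, spec.tie_break)


def _space_vectors(context: QueryContext, space: str) -> Mapping[str, np.ndarray]:
    vecs = context.vectors if space == "word" else context.tfidf_vectors
    if vecs is None:
        raise ConfigurationError(
            f"{space}-space similarity requires vectors in the context"
        )
    return vecs


def min_similarity_select(
    context: QueryContext, space: str = "word", spec: Optional[StrategySpec] = None
) -> str:
    """Most novel candidate: lowest aggregate cosine similarity to the
    labeled set (mean aggregation by default, min behind the spec flag)."""
    spec = spec or StrategySpec("word_similarity")
    if not context.labeled_ids:
        raise ValueError("labeled set is empty")
    if not context.unlabeled_ids:
        raise ValueError("unlabeled pool is empty")
    vecs = _space_vectors(context, space)
    agg = np.mean if spec.similarity_aggregate == "mean" else np.min
    labeled = [np.asarray(vecs[x]) for x in context.labeled_ids]
    scores = np.array(
        [
            agg([cosine_similarity(xv, np.asarray(vecs[u])) for xv in labeled])
            for u in context.unlabeled_ids
        ]
    )
    return _argbest(
        scores, context.unlabeled_ids, context.rng, spec.tie_break, maximize=False
    )


def class_average_similarity(
    context: QueryContext, u: str, space: str = "word"
) -> tuple[list[str], np.ndarray]:
    """Mean cosine similarity of candidate ``u`` to each labeled class.

    Returns ``(class_names, similarities)`` over the classes that have at
    least one labeled member, in first-labeled order.
    """
    if not context.labeled_ids:
        raise ValueError("labeled set is empty")
    vecs = _space_vectors(context, space)
    uv = np.asarray(vecs[u])
    by_class: dict[str, list[float]] = {}
    for x, lbl in zip(context.labeled_ids, context.labeled_labels):
        by_class.setdefault(lbl, []).append(
            cosine_similarity(np.asarray(vecs[x]), uv)
        )
    names = list(by_class)
    sims = np.array([float(np.mean(by_class[c])) for c in names])
    return names, sims


def pseudo_posterior(similarities: np.ndarray) -> np.ndarray:
    """Shift a per-class similarity vector to be non-negative and
    L1-normalize it; degenerate (all-equal) vectors become uniform."""
    s = np.asarray(similarities, dtype=np.float64)
    shifted = s - s.min()
    total = shifted.sum()
    if total <= 0:
        return np.full_like(s, 1.0 / len(s))
    return shifted / total


def similarity_uncertainty_select(
    context: QueryContext,
    mode: str,
    space: str = "word",
    spec: Optional[StrategySpec] = None,
) -> str:
    """Word-similarity uncertainty sampling: per-class average similarities
    become a pseudo-posterior and the chosen uncertainty functional picks
    the most ambiguous candidate.

    Falls back to plain similarity novelty when only one class is labeled.
    """
    spec = spec or StrategySpec(f"wordsim_{mode}")
    if mode not in _UNCERTAINTY:
        raise ValueError(f"unknown uncertainty mode {mode!r}")
    if not context.unlabeled_ids:
        raise ValueError("unlabeled pool is empty")
    n_classes = len(set(context.labeled_labels))
    if n_classes < 2:
        warnings.warn(
            "only one labeled class; falling back to similarity novelty",
            stacklevel=2,
        )
        return min_similarity_select(context, space=space, spec=spec)
    score_fn = _UNCERTAINTY[mode]
    scores = np.empty(len(context.unlabeled_ids))
    for i, u in enumerate(context.unlabeled_ids):
        _, sims = class_average_similarity(context, u, space=space)
        scores[i] = score_fn(pseudo_posterior(sims)[None, :])[0]
    return _argbest(scores, context.unlabeled_ids, context.rng, spec.tie_break)


def select_query(spec: StrategySpec, context: QueryContext) -> str:
    """Dispatch to the named strategy and return the chosen unlabeled id."""
    if not context.unlabeled_ids:
        raise ValueError("unlabeled pool is empty")
    name = spec.name
    if name == "random":
        return context.unlabeled_ids[
            int(context.rng.integers(len(context.unlabeled_ids)))
        ]
    if name in _UNCERTAINTY:
        if context.posteriors is None:
            raise ConfigurationError(f"{name} requires context.posteriors")
        scores = _UNCERTAINTY[name](context.posteriors)
        if len(scores) != len(context.unlabeled_ids):
            raise ValueError("posteriors/unlabeled_ids length mismatch")
        return _argbest(scores, context.unlabeled_ids, context.rng, spec.tie_break)
    if name == "length_words":
        return length_words_select(context, spec)
    if name == "word_similarity":
        return min_similarity_select(context, space="word", spec=spec)
    if name == "tfidf_similarity":
        return min_similarity_select(context, space="tfidf", spec=spec)
    if name.startswith("wordsim_"):
        return similarity_uncertainty_select(
            context, mode=name.removeprefix("wordsim_"), space="word", spec=spec
        )
    raise ValueError(f"unknown strategy {name!r}")  # pragma: no cover
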