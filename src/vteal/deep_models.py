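"""Small neural text classifiers with the study's training protocol.

Architectures: ``lstm``, ``cnn1d`` (single kernel), ``multikernel_cnn1d``
(kernels 3/4/5, max-over-time pooling, concatenation) and
``multikernel_cnn1d_pretrained`` (multi-kernel with the embedding layer
initialized from word vectors — by default trained on the corpus itself so
no download is ever needed; an external ``token v1 ... vD`` table can be
supplied instead).

Protocol: documents are index-encoded to exactly ``max_length`` tokens
(right-padded, truncated from the end), models train with Adam for up to
50 epochs with early stopping when validation accuracy fails to improve by
at least 1e-4 for two consecutive epochs, and evaluation runs stratified
5-fold cross-validation.  A timing harness measures per-report inference
(batch size 1, tokenization included).
"""

from __future__ import annotations

import importlib
import platform
import time
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from ._nn import Adam, CNNNet, LSTMNet, cross_entropy_grad, softmax
from .data_model import Corpus, restrict_labels
from .embeddings import DenseEmbedder, Vocabulary, load_word_vectors, tokenize
from .evaluation import aggregate_f1, confusion_from_predictions, precision_recall_f1

__all__ = [
    "ARCHITECTURES",
    "TokenizerSpec",
    "DLConfig",
    "TimingReport",
    "OptionalDependencyError",
    "encode_batch",
    "early_stop_check",
    "NeuralTextClassifier",
    "train_cv",
    "measure_inference_time",
    "TextClassifierPlugin",
    "resolve_plugin",
    "plugin_transformer_interface",
]

ARCHITECTURES = (
    "lstm",
    "cnn1d",
    "multikernel_cnn1d",
    "multikernel_cnn1d_pretrained",
)

PAD_INDEX = 0
UNK_INDEX = 1
_VOCAB_OFFSET = 2  # token indices shift past pad/unk


class OptionalDependencyError(ImportError):
    """An optional plug-in (e.g. a transformer encoder) is unavailable."""


@dataclass(frozen=True)
class TokenizerSpec:
    """Fixed-length index encoding: right-pad short documents, truncate
    long ones from the end."""

    max_length: int = 256
    pad_index: int = PAD_INDEX
    truncation: str = "end"

    def __post_init__(self) -> None:
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        if self.truncation != "end":
            raise ValueError("only end-truncation is supported")


@dataclass(frozen=True)
class DLConfig:
    architecture: str = "lstm"
    kernel_sizes: tuple[int, ...] = (3, 4, 5)
    embed_dim: int = 64
    hidden_dim: int = 64
    n_filters: int = 32
    max_epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    min_delta: float = 1e-4
    patience: int = 2
    folds: int = 5
    max_length: int = 256
    val_fraction: float = 0.1
    early_stopping: bool = True
    pretrained_vectors: Optional[str] = None  # path to token v1..vD table
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.min_delta <= 0:
            raise ValueError("min_delta must be positive")


@dataclass(frozen=True)
class TimingReport:
    mean_seconds: float
    n_samples: int
    batch_size: int = 1
    includes_tokenization: bool = True
    machine: str = ""


def encode_batch(
    texts: Sequence[str], spec: TokenizerSpec, vocab: Vocabulary
) -> tuple[np.ndarray, np.ndarray]:
    """Index-encode documents to shape ``(n_docs, max_length)``.

    Returns ``(ids, lengths)``; vocabulary indices are shifted by 2 so 0 is
    the pad token and 1 the unknown token.  The vocabulary must be fitted
    on training folds only.
    """
    n = len(texts)
    ids = np.full((n, spec.max_length), spec.pad_index, dtype=np.int64)
    lengths = np.zeros(n, dtype=np.int64)
    for d, text in enumerate(texts):
        toks = tokenize(text)[: spec.max_length]
        row = [
            vocab.index.get(t, UNK_INDEX - _VOCAB_OFFSET) + _VOCAB_OFFSET
            for t in toks
        ]
        ids[d, : len(row)] = row
        lengths[d] = len(row)
    return ids, lengths


def early_stop_check(
    history: Sequence[float], min_delta: float = 1e-4, patience: int = 2
) -> bool:
    """Stop when each of the last ``patience`` epochs improved the running
    best by less than ``min_delta``."""
    if not history:
        raise ValueError("history must be non-empty")
    deltas = [
        history[i] - max(history[:i]) for i in range(1, len(history))
    ]
    if len(deltas) < patience:
        return False
    return all(d < min_delta for d in deltas[-patience:])


class NeuralTextClassifier:
    """Scikit-learn-flavoured wrapper around the NumPy networks.

    ``fit`` builds its vocabulary from the provided training texts only;
    an optional held-out ``validation`` pair drives early stopping.
    """

    def __init__(self, config: DLConfig):
        self.config = config
        self.vocab: Optional[Vocabulary] = None
        self.classes_: list[str] = []
        self.net = None
        self.spec = TokenizerSpec(max_length=config.max_length)
        self.n_epochs_run_: int = 0
        self.val_history_: list[float] = []

    # -- construction -------------------------------------------------
    def _build_net(self, vocab_size: int, n_classes: int,
                   rng: np.random.Generator):
        cfg = self.config
        if cfg.architecture == "lstm":
            return LSTMNet(vocab_size, cfg.embed_dim, cfg.hidden_dim,
                           n_classes, rng)
        kernels = (3,) if cfg.architecture == "cnn1d" else cfg.kernel_sizes
        return CNNNet(vocab_size, cfg.embed_dim, cfg.n_filters, kernels,
                      n_classes, rng)

    def _pretrained_embedding(self, texts: Sequence[str]) -> None:
        """Initialize embedding rows from a word-vector table (external
        file if configured, else vectors trained on ``texts``)."""
        assert self.vocab is not None and self.net is not None
        cfg = self.config
        if cfg.pretrained_vectors is not None:
            table = load_word_vectors(cfg.pretrained_vectors)
        else:
            emb = DenseEmbedder(
                mode="word_average", dim=cfg.embed_dim, seed=cfg.seed
            ).fit(texts)
            assert emb.word_vectors is not None and emb.vocab is not None
            table = {
                tok: emb.word_vectors[i] for tok, i in emb.vocab.index.items()
            }
        e = self.net.params["E"]
        for tok, i in self.vocab.index.items():
            vec = table.get(tok)
            if vec is not None and len(vec) == e.shape[1]:
                e[i + _VOCAB_OFFSET] = vec
            elif vec is not None:
                e[i + _VOCAB_OFFSET, : min(len(vec), e.shape[1])] = vec[
                    : e.shape[1]
                ]

    # -- training -----------------------------------------------------
    def fit(
        self,
        texts: Sequence[str],
        labels: Sequence[str],
        validation: Optional[tuple[Sequence[str], Sequence[str]]] = None,
    ) -> "NeuralTextClassifier":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.vocab = Vocabulary.from_texts(texts)
        self.classes_ = sorted(set(labels))
        lbl_idx = {c: i for i, c in enumerate(self.classes_)}
        y = np.array([lbl_idx[c] for c in labels])
        ids, lengths = encode_batch(texts, self.spec, self.vocab)
        self.net = self._build_net(
            len(self.vocab) + _VOCAB_OFFSET, len(self.classes_), rng
        )
        if cfg.architecture == "multikernel_cnn1d_pretrained":
            self._pretrained_embedding(texts)
        opt = Adam(self.net.params, lr=cfg.learning_rate)
        n = len(texts)
        val = None
        if validation is not None:
            vx, vl = validation
            vids, vlens = encode_batch(vx, self.spec, self.vocab)
            vy = np.array([lbl_idx.get(c, -1) for c in vl])
            val = (vids, vlens, vy)
        self.val_history_ = []
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                logits, cache = self.net.forward(ids[batch], lengths[batch])
                _, dlogits = cross_entropy_grad(logits, y[batch])
                grads = self.net.backward(cache, dlogits)
                opt.step(grads)
            self.n_epochs_run_ = epoch + 1
            if val is not None:
                vids, vlens, vy = val
                acc = float((self._predict_ids(vids, vlens) == vy).mean())
                self.val_history_.append(acc)
                if cfg.early_stopping and early_stop_check(
                    self.val_history_, cfg.min_delta, cfg.patience
                ):
                    break
        return self

    # -- inference ----------------------------------------------------
    def _logits(self, ids: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        assert self.net is not None
        out = []
        for start in range(0, len(ids), 256):
            sl = slice(start, start + 256)
            logits, _ = self.net.forward(ids[sl], lengths[sl])
            out.append(logits)
        return np.concatenate(out, axis=0)

    def _predict_ids(self, ids: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        return self._logits(ids, lengths).argmax(axis=1)

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        if self.vocab is None:
            raise RuntimeError("model is not fitted")
        ids, lengths = encode_batch(texts, self.spec, self.vocab)
        return softmax(self._logits(ids, lengths))

    def predict(self, texts: Sequence[str]) -> list[str]:
        if self.vocab is None:
            raise RuntimeError("model is not fitted")
        ids, lengths = encode_batch(texts, self.spec, self.vocab)
        return [self.classes_[i] for i in self._predict_ids(ids, lengths)]


# ---------------------------------------------------------------------------
# cross-validation protocol
# ---------------------------------------------------------------------------

def _cv_protocol(
    fit_predict,
    texts: list[str],
    labels: list[str],
    scheme_labels: list[str],
    folds: int,
    seed: int,
    val_fraction: float = 0.0,
) -> dict:
    """Shared stratified-CV engine for native models and plug-ins.

    ``fit_predict(train_texts, train_labels, val, test_texts)`` must return
    predicted labels for the test fold.
    """
    counts: dict[str, int] = {}
    for lbl in labels:
        counts[lbl] = counts.get(lbl, 0) + 1
    missing = [c for c in scheme_labels if counts.get(c, 0) == 0]
    if missing:
        raise ValueError(f"classes with zero members under the scheme: {missing}")
    thin = [c for c, n in counts.items() if n < folds]
    y = np.array(labels, dtype=object)
    if thin:
        warnings.warn(
            f"classes with fewer members than folds (stratification degrades): {thin}",
            stacklevel=3,
        )
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(kf.split(np.zeros(len(labels))))
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            splits = list(skf.split(np.zeros(len(labels)), y))
    fold_records = []
    for fold_no, (tr_idx, te_idx) in enumerate(splits):
        tr_texts = [texts[i] for i in tr_idx]
        tr_labels = [labels[i] for i in tr_idx]
        val = None
        if val_fraction > 0:
            try:
                tr_texts, v_texts, tr_labels, v_labels = train_test_split(
                    tr_texts, tr_labels, test_size=val_fraction,
                    random_state=seed + fold_no, stratify=tr_labels,
                )
            except ValueError:  # a class too small to stratify the val split
                tr_texts, v_texts, tr_labels, v_labels = train_test_split(
                    tr_texts, tr_labels, test_size=val_fraction,
                    random_state=seed + fold_no,
                )
            val = (v_texts, v_labels)
        te_texts = [texts[i] for i in te_idx]
        te_labels = [labels[i] for i in te_idx]
        preds = fit_predict(tr_texts, tr_labels, val, te_texts)
        cc = confusion_from_predictions(te_labels, list(preds), scheme_labels)
        rep = precision_recall_f1(cc)
        fold_records.append(
            {
                "fold": fold_no,
                "n_test": len(te_idx),
                "macro_f1": aggregate_f1(rep, "macro"),
                "weighted_f1": aggregate_f1(rep, "weighted"),
                "micro_f1": aggregate_f1(rep, "micro", cc),
                "per_class": rep.per_class(),
            }
        )
    return {
        "folds": fold_records,
        "mean_macro_f1": float(np.mean([f["macro_f1"] for f in fold_records])),
        "mean_weighted_f1": float(
            np.mean([f["weighted_f1"] for f in fold_records])
        ),
    }


def train_cv(config: DLConfig, corpus: Corpus, scheme: str = "7-class") -> dict:
    """Stratified k-fold cross-validation of a neural architecture.

    The corpus is projected onto ``scheme`` first; per fold, a fresh model
    (with its own vocabulary, fitted on the fold's training portion) trains
    with Adam and early stopping on a stratified 10% validation split.
    Returns per-fold metric records and their mean.
    """
    if corpus.label_scheme == "7-class" and scheme == "6-class":
        corpus = restrict_labels(corpus, scheme)
    texts, labels = corpus.texts(), corpus.label_list()
    scheme_labels = list(corpus.labels)

    def fit_predict(tr_texts, tr_labels, val, te_texts):
        model = NeuralTextClassifier(config)
        model.fit(tr_texts, tr_labels, validation=val)
        return model.predict(te_texts)

    result = _cv_protocol(
        fit_predict, texts, labels, scheme_labels, config.folds, config.seed,
        val_fraction=config.val_fraction if config.early_stopping else 0.0,
    )
    result["architecture"] = config.architecture
    result["scheme"] = scheme
    return result


def measure_inference_time(
    model: NeuralTextClassifier,
    texts: Sequence[str],
    spec: Optional[TokenizerSpec] = None,
) -> TimingReport:
    """Mean wall-clock seconds to classify one report (batch size 1,
    tokenization included).  Hardware-dependent; no numeric target."""
    if len(texts) == 0:
        raise ValueError("empty test set")
    spec = spec or model.spec
    assert model.vocab is not None
    t0 = time.perf_counter()
    for text in texts:
        ids, lengths = encode_batch([text], spec, model.vocab)
        model._predict_ids(ids, lengths)
    elapsed = time.perf_counter() - t0
    return TimingReport(
        mean_seconds=elapsed / len(texts),
        n_samples=len(texts),
        machine=f"{platform.machine()} / {platform.python_implementation()} "
        f"{platform.python_version()}",
    )


# ---------------------------------------------------------------------------
# transformer plug-in contract
# ---------------------------------------------------------------------------

class TextClassifierPlugin(Protocol):
    """Contract an external fine-tunable encoder must satisfy."""

    def fit(self, texts: Sequence[str], labels: Sequence[str]) -> object: ...

    def predict(self, texts: Sequence[str]) -> Sequence[str]: ...


def resolve_plugin(descriptor: str) -> TextClassifierPlugin:
    """Resolve a ``"module.path:attr"`` descriptor to a plug-in factory.

    Raises :class:`OptionalDependencyError` when the module (typically an
    optional heavyweight dependency) cannot be imported.
    """
    if ":" not in descriptor:
        raise ValueError(
            f"plug-in descriptor must look like 'module:attr', got {descriptor!r}"
        )
    mod_name, attr = descriptor.split(":", 1)
    try:
        module = importlib.import_module(mod_name)
    except ImportError as exc:
        raise OptionalDependencyError(
            f"optional plug-in dependency {mod_name!r} is not installed: {exc}"
        ) from exc
    try:
        factory = getattr(module, attr)
    except AttributeError as exc:
        raise OptionalDependencyError(
            f"plug-in attribute {attr!r} not found in {mod_name!r}"
        ) from exc
    return factory() if callable(factory) else factory


def plugin_transformer_interface(
    plugin: TextClassifierPlugin | str,
    corpus: Corpus,
    scheme: str = "7-class",
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Run the identical CV protocol through an external classifier plug-in."""
    if isinstance(plugin, str):
        plugin_obj = resolve_plugin(plugin)
    else:
        plugin_obj = plugin
    if corpus.label_scheme == "7-class" and scheme == "6-class":
        corpus = restrict_labels(corpus, scheme)
    texts, labels = corpus.texts(), corpus.label_list()

    def fit_predict(tr_texts, tr_labels, val, te_texts):
        plugin_obj.fit(tr_texts, tr_labels)
        return plugin_obj.predict(te_texts)

    result = _cv_protocol(
        fit_predict, texts, labels, list(corpus.labels), folds, seed
    )
    result["architecture"] = "plugin"
    result["scheme"] = scheme
    return result
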