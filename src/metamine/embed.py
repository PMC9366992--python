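"""Paragraph-vector document embeddings (distributed-memory flavour).

Each document gets a trainable dense vector that, combined with the mean of
the context-word vectors in a sliding window, is trained to predict the
centre word by negative sampling.  Defaults follow the conventional
configuration for document embeddings in this setting: 200 dimensions,
window 5, 15 epochs.  With ``workers=1`` and a fixed seed, training is
bit-reproducible; the ``workers`` field is a parallelism hint retained for
interface parity (training here is always single-threaded).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_WORD = re.compile(r"[a-z0-9][a-z0-9'′-]*")


def _tokenize(text: str) -> list[str]:
    return _WORD.findall(text.lower())


@dataclass
class EmbeddingModel:
    dim: int = 200
    window: int = 5
    epochs: int = 15
    workers: int = 8
    seed: int = 9
    negative: int = 5
    alpha: float = 0.05
    min_alpha: float = 1e-3

    # fitted state
    vocab: dict[str, int] = field(default_factory=dict, repr=False)
    word_vectors: np.ndarray | None = field(default=None, repr=False)
    out_vectors: np.ndarray | None = field(default=None, repr=False)
    doc_vectors: np.ndarray | None = field(default=None, repr=False)
    _noise_cdf: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")

    @property
    def is_fitted(self) -> bool:
        return self.word_vectors is not None


def fit_doc_embeddings(
    texts: list[str], params: EmbeddingModel | None = None
) -> EmbeddingModel:
    """Train document and word vectors on a corpus (>= 2 texts)."""
    if len(texts) < 2:
        raise ValueError("need at least 2 texts to fit document embeddings")
    model = params or EmbeddingModel()
    rng = np.random.default_rng(model.seed)

    counts: dict[str, int] = {}
    docs_tokens = []
    for text in texts:
        toks = _tokenize(text)
        docs_tokens.append(toks)
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
    model.vocab = {w: i for i, w in enumerate(sorted(counts))}
    v = len(model.vocab)
    if v == 0:
        raise ValueError("corpus contains no tokens")

    scale = 1.0 / model.dim
    model.word_vectors = rng.uniform(-scale, scale, size=(v, model.dim))
    model.out_vectors = np.zeros((v, model.dim))
    model.doc_vectors = rng.uniform(-scale, scale, size=(len(texts), model.dim))

    freq = np.array([counts[w] for w in sorted(counts)], dtype=float) ** 0.75
    model._noise_cdf = np.cumsum(freq / freq.sum())

    doc_ids = [[model.vocab[t] for t in toks] for toks in docs_tokens]
    _train(model, model.doc_vectors, doc_ids, rng, update_words=True)
    return model


def _train(
    model: EmbeddingModel,
    doc_vecs: np.ndarray,
    doc_ids: list[list[int]],
    rng: np.random.Generator,
    update_words: bool,
) -> None:
    W, O = model.word_vectors, model.out_vectors
    win, k = model.window, model.negative
    total = max(1, model.epochs * len(doc_ids))
    step = 0
    for _ in range(model.epochs):
        for d, ids in enumerate(doc_ids):
            alpha = model.alpha + (model.min_alpha - model.alpha) * step / total
            step += 1
            n = len(ids)
            for t in range(n):
                lo, hi = max(0, t - win), min(n, t + win + 1)
                ctx_ids = ids[lo:t] + ids[t + 1:hi]
                if ctx_ids:
                    ctx = (doc_vecs[d] + W[ctx_ids].sum(axis=0)) / (len(ctx_ids) + 1)
                else:
                    ctx = doc_vecs[d]
                center = ids[t]
                neg = np.searchsorted(
                    model._noise_cdf, rng.random(k)
                ).astype(int)
                targets = np.concatenate(([center], neg))
                labels = np.zeros(k + 1)
                labels[0] = 1.0
                scores = O[targets] @ ctx
                preds = 1.0 / (1.0 + np.exp(-scores))
                g = (labels - preds) * alpha
                grad_ctx = g @ O[targets]
                O[targets] += np.outer(g, ctx)
                doc_vecs[d] += grad_ctx
                if update_words and ctx_ids:
                    W[ctx_ids] += grad_ctx / (len(ctx_ids) + 1)


def infer(model: EmbeddingModel, text: str, epochs: int | None = None) -> np.ndarray:
    """Infer a vector for an unseen text with word/output vectors frozen."""
    if not model.is_fitted:
        raise ValueError("model is not fitted")
    rng = np.random.default_rng(model.seed)
    ids = [model.vocab[t] for t in _tokenize(text) if t in model.vocab]
    vec = rng.uniform(-1.0 / model.dim, 1.0 / model.dim, size=(1, model.dim))
    if not ids:
        return vec[0]
    sub = EmbeddingModel(**{
        f: getattr(model, f)
        for f in ("dim", "window", "epochs", "workers", "seed",
                  "negative", "alpha", "min_alpha")
    })
    sub.vocab = model.vocab
    sub.word_vectors = model.word_vectors
    sub.out_vectors = model.out_vectors.copy()  # outputs frozen for the caller
    sub._noise_cdf = model._noise_cdf
    if epochs is not None:
        sub.epochs = epochs
    _train(sub, vec, [ids], rng, update_words=False)
    return vec[0]


def transform_corpus(model: EmbeddingModel, texts: list[str]) -> np.ndarray:
    """Infer vectors for a list of texts (rows align with input order)."""
    return np.vstack([infer(model, t) for t in texts])
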