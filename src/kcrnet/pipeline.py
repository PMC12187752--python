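"""Glue between windows, embedding, network and training.

The embedding is always fitted on training windows only and then applied to
whatever needs encoding, so evaluation data never leaks into the encoder.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from kcrnet.embedding import (
    EmbeddingMatrix,
    build_vocabulary,
    encode_dataset,
    tokenize,
    train_embedding,
)
from kcrnet.windows import PeptideWindow

DEFAULT_EMBED_EPOCHS = 25


def corpus_of(windows: Sequence[PeptideWindow | str], k: int = 1, stride: int = 1):
    return [tokenize(w, k=k, stride=stride) for w in windows]


def fit_encoder(
    train_windows: Sequence[PeptideWindow | str],
    d: int = 80,
    k: int = 1,
    stride: int = 1,
    context_window: int = 5,
    epochs: int = DEFAULT_EMBED_EPOCHS,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Train the k-mer embedding on the training windows only."""
    corpus = corpus_of(train_windows, k=k, stride=stride)
    vocab = build_vocabulary(corpus)
    return train_embedding(
        corpus, d=d, context_window=context_window, epochs=epochs, seed=seed, vocab=vocab
    )


def encode(windows: Sequence[PeptideWindow | str], emb: EmbeddingMatrix) -> np.ndarray:
    """(N, d, L) feature tensor for a window collection."""
    return encode_dataset(windows, emb)


def leakage_free_encoder(d: int = 80, epochs: int = DEFAULT_EMBED_EPOCHS, seed: int = 0):
    """An ``encoder(train_windows, all_windows)`` callable for cross_validate:
    refits the embedding on each fold's training portion."""

    def _encoder(train_windows, all_windows):
        emb = fit_encoder(train_windows, d=d, epochs=epochs, seed=seed)
        return encode(all_windows, emb)

    return _encoder
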