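"""k-mer tokenization and word-embedding encoding of peptide windows.

Each 29-residue window is split into overlapping k-mers (default k=1,
stride 1, i.e. single residues), and a shallow two-layer network —
skip-gram with negative sampling — is trained on the window corpus to give
every token a dense d-dimensional vector (default d=80).  Encoding a window
stacks the token vectors column-wise into a d x L feature matrix (80 x 29
under defaults), exactly the embedding-weight matrix multiplied by the
window's one-hot encoding.  A one-hot encoder is kept as a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from kcrnet.windows import PAD_SYMBOL, UNKNOWN_SYMBOL, PeptideWindow

DEFAULT_DIM = 80


def _residues(window: "PeptideWindow | str") -> str:
    return window if isinstance(window, str) else window.residues


def tokenize(window: "PeptideWindow | str", k: int = 1, stride: int = 1) -> list[str]:
    """Split a window into the k-mers starting at 0, stride, 2*stride, ...

    Only k-mers fully inside the window are emitted, so for k=1, stride=1
    the token count equals the window length.
    """
    seq = _residues(window)
    if k < 1 or k > len(seq):
        raise ValueError(f"k must satisfy 1 <= k <= window length, got k={k}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return [seq[i : i + k] for i in range(0, len(seq) - k + 1, stride)]


@dataclass(frozen=True)
class Vocabulary:
    """Deterministic (lexicographic) token index, pad and unknown always present."""

    tokens: tuple[str, ...]
    pad_token: str = PAD_SYMBOL
    unk_token: str = UNKNOWN_SYMBOL

    @property
    def index_of(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        idx = self.index_of
        if token in idx:
            return idx[token]
        return idx[self.unk_token]


def build_vocabulary(
    corpus: Iterable[Sequence[str]],
    pad_token: str = PAD_SYMBOL,
    unk_token: str = UNKNOWN_SYMBOL,
) -> Vocabulary:
    """Collect corpus tokens in lexicographic order; append pad/unk if absent."""
    seen: set[str] = set()
    empty = True
    for seq in corpus:
        empty = False
        seen.update(seq)
    if empty:
        raise ValueError("empty corpus")
    ordered = sorted(seen)
    for special in (pad_token, unk_token):
        if special not in seen:
            ordered.append(special)
    return Vocabulary(tokens=tuple(ordered), pad_token=pad_token, unk_token=unk_token)


@dataclass
class EmbeddingMatrix:
    """Trained token vectors: one row of length d per vocabulary entry."""

    weights: np.ndarray  # (|V|, d)
    vocabulary: Vocabulary
    k: int = 1
    stride: int = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2 or self.weights.shape[0] != len(self.vocabulary):
            raise ValueError(
                f"weights shape {self.weights.shape} inconsistent with |V|={len(self.vocabulary)}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite embedding weights")

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for tok, row in zip(self.vocabulary.tokens, self.weights):
                fh.write(tok + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def load_tsv(cls, path, k: int = 1, stride: int = 1) -> "EmbeddingMatrix":
        tokens, rows = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                tokens.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        vocab = Vocabulary(tokens=tuple(tokens))
        return cls(weights=np.array(rows), vocabulary=vocab, k=k, stride=stride)


def one_hot_encode(window: "PeptideWindow | str", vocab: Vocabulary, k: int = 1, stride: int = 1) -> np.ndarray:
    """|V| x L binary matrix, one 1 per column (unknown row catches OOV tokens)."""
    toks = tokenize(window, k=k, stride=stride)
    mat = np.zeros((len(vocab), len(toks)), dtype=np.float64)
    for j, tok in enumerate(toks):
        mat[vocab.index(tok), j] = 1.0
    return mat


def embed_encode(window: "PeptideWindow | str", emb: EmbeddingMatrix) -> np.ndarray:
    """d x L feature matrix; column j is the embedding row of token j.

    Identical (exactly, not just numerically) to ``emb.weights.T @ one_hot``.
    """
    toks = tokenize(window, k=emb.k, stride=emb.stride)
    idx = [emb.vocabulary.index(t) for t in toks]
    return emb.weights[idx].T.copy()


def encode_dataset(windows: Iterable["PeptideWindow | str"], emb: EmbeddingMatrix) -> np.ndarray:
    """Stack embed_encode over windows into an (N, d, L) array."""
    mats = [embed_encode(w, emb) for w in windows]
    return np.stack(mats) if mats else np.zeros((0, emb.dim, 0))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_embedding(
    corpus: Sequence[Sequence[str]],
    d: int = DEFAULT_DIM,
    context_window: int = 5,
    epochs: int = 25,
    seed: int = 0,
    learning_rate: float = 0.3,
    negatives: int = 5,
    vocab: Vocabulary | None = None,
) -> EmbeddingMatrix:
    """Train skip-gram-with-negative-sampling token vectors on a corpus.

    The corpus is a collection of token sequences (one per peptide window).
    Every (center, context) pair within ``context_window`` contributes one
    positive update and ``negatives`` noise updates drawn from the unigram
    distribution raised to the 3/4 power.  Deterministic for a fixed seed.
    """
    corpus = [list(s) for s in corpus]
    if not corpus:
        raise ValueError("empty corpus")
    if d < 1:
        raise ValueError(f"embedding dimension must be >= 1, got {d}")
    if vocab is None:
        vocab = build_vocabulary(corpus)
    index = vocab.index_of
    unk = index[vocab.unk_token]
    encoded = [np.array([index.get(t, unk) for t in seq], dtype=np.int64) for seq in corpus]

    V = len(vocab)
    counts = np.zeros(V)
    for seq in encoded:
        np.add.at(counts, seq, 1.0)
    noise = np.maximum(counts, 1.0) ** 0.75
    noise /= noise.sum()

    # All (center, context) pairs; windows share a fixed length so this is
    # built once and reused every epoch.
    centers_l, contexts_l = [], []
    for seq in encoded:
        n = len(seq)
        for pos in range(n):
            lo = max(0, pos - context_window)
            hi = min(n, pos + context_window + 1)
            for cpos in range(lo, hi):
                if cpos != pos:
                    centers_l.append(seq[pos])
                    contexts_l.append(seq[cpos])
    centers = np.array(centers_l, dtype=np.int64)
    contexts = np.array(contexts_l, dtype=np.int64)
    n_pairs = len(centers)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, d)) - 0.5) / d  # word2vec-style init
    W_out = np.zeros((V, d))

    batch = 4096
    labels_template = np.zeros((batch, negatives + 1))
    labels_template[:, 0] = 1.0
    for epoch in range(epochs):
        lr = learning_rate * max(1.0 - epoch / max(epochs, 1), 0.1)
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            sel = order[start : start + batch]
            c = centers[sel]
            # column 0 = true context, rest = unigram^(3/4) noise draws
            targets = np.empty((len(sel), negatives + 1), dtype=np.int64)
            targets[:, 0] = contexts[sel]
            targets[:, 1:] = rng.choice(V, size=(len(sel), negatives), p=noise)
            labels = labels_template[: len(sel)]
            v = W_in[c]  # (B, d)
            u = W_out[targets]  # (B, K+1, d)
            scores = _sigmoid(np.einsum("bkd,bd->bk", u, v))
            # mini-batch mean gradient of the SGNS logistic loss
            g = (scores - labels) * (lr / len(sel))  # (B, K+1)
            grad_v = np.einsum("bk,bkd->bd", g, u)
            grad_u = g[:, :, None] * v[:, None, :]
            np.add.at(W_out, targets.ravel(), -grad_u.reshape(-1, d))
            np.add.at(W_in, c, -grad_v)
    return EmbeddingMatrix(weights=W_in, vocabulary=vocab, k=1, stride=1)
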