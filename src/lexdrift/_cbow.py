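"""Numba kernel for CBOW word2vec training with negative sampling.

The kernel is strictly sequential and uses its own xorshift64* generator, so a
given (corpus, hyperparameters, seed) triple always produces bit-identical
vectors. Conventions follow the original word2vec reference implementation:

* reduced windows — the effective window at each position is drawn uniformly
  from 1..window;
* CBOW with context averaging (``cbow_mean``): the hidden layer is the mean of
  the context input vectors, and the accumulated error is added to each
  context vector un-scaled;
* negative sampling from the unigram distribution raised to the 3/4 power;
* learning rate decayed linearly from ``alpha0`` to ``min_alpha`` over
  ``epochs * n_tokens`` updates;
* frequent-word subsampling with threshold ``sample`` (default 1e-3): token w
  with corpus frequency f is kept with probability
  (sqrt(f / sample) + 1) * sample / f, redrawn each epoch. Without it, very
  frequent tokens dominate every context and collapse all vectors onto one
  shared direction;
* input vectors initialised uniformly in [-0.5/dim, 0.5/dim), output (context)
  matrix initialised to zero.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_NEG_TABLE_SIZE = 100_000
_MAX_EXP = 6.0


@njit(cache=True, inline="always")
def _xorshift64s(state):
    """xorshift64* step; returns (new_state, uint64 draw)."""
    x = state
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    x = x * np.uint64(2685821657736338717)
    return x, x


@njit(cache=True)
def _train_cbow_kernel(
    tokens,
    doc_offsets,
    vocab_size,
    dim,
    window,
    epochs,
    negative,
    alpha0,
    min_alpha,
    neg_table,
    keep_prob,
    doc_weights,
    seed,
):
    state = np.uint64(seed * 2654435761 + 0x9E3779B97F4A7C15)
    # warm up the generator so small seeds decorrelate
    for _ in range(8):
        state, _ = _xorshift64s(state)

    syn0 = np.empty((vocab_size, dim), dtype=np.float64)
    for i in range(vocab_size):
        for j in range(dim):
            state, r = _xorshift64s(state)
            u = (r >> np.uint64(11)) * (1.0 / 9007199254740992.0)  # [0, 1)
            syn0[i, j] = (u - 0.5) / dim
    syn1 = np.zeros((vocab_size, dim), dtype=np.float64)

    neu1 = np.empty(dim, dtype=np.float64)
    neu1e = np.empty(dim, dtype=np.float64)

    n_tokens = tokens.shape[0]
    total = np.float64(epochs) * np.float64(max(n_tokens, 1))
    table_size = neg_table.shape[0]
    processed = 0

    max_doc = 0
    for d in range(doc_offsets.shape[0] - 1):
        ln = doc_offsets[d + 1] - doc_offsets[d]
        if ln > max_doc:
            max_doc = ln
    kept = np.empty(max_doc, dtype=np.int64)

    for _epoch in range(epochs):
        for d in range(doc_offsets.shape[0] - 1):
            start = doc_offsets[d]
            end = doc_offsets[d + 1]
            # frequent-word subsampling, redrawn each epoch
            nk = 0
            for c in range(start, end):
                w = tokens[c]
                if keep_prob[w] >= 1.0:
                    kept[nk] = w
                    nk += 1
                else:
                    state, r = _xorshift64s(state)
                    u = (r >> np.uint64(11)) * (1.0 / 9007199254740992.0)
                    if u < keep_prob[w]:
                        kept[nk] = w
                        nk += 1
            # linear decay tracked against raw (pre-subsampling) progress;
            # per-document weights scale the whole document's updates
            alpha = alpha0 - (alpha0 - min_alpha) * (processed / total)
            if alpha < min_alpha:
                alpha = min_alpha
            alpha *= doc_weights[d]
            processed += end - start
            if alpha == 0.0:
                continue
            for pos in range(nk):
                state, r = _xorshift64s(state)
                b = int(r % np.uint64(window))
                cstart = pos - window + b
                if cstart < 0:
                    cstart = 0
                cend = pos + window - b + 1
                if cend > nk:
                    cend = nk
                cw = cend - cstart - 1  # context size excluding the centre
                if cw <= 0:
                    continue

                for j in range(dim):
                    neu1[j] = 0.0
                    neu1e[j] = 0.0
                for c in range(cstart, cend):
                    if c == pos:
                        continue
                    wc = kept[c]
                    for j in range(dim):
                        neu1[j] += syn0[wc, j]
                inv_cw = 1.0 / cw
                for j in range(dim):
                    neu1[j] *= inv_cw

                centre = kept[pos]
                for k in range(negative + 1):
                    if k == 0:
                        tgt = centre
                        label = 1.0
                    else:
                        state, r = _xorshift64s(state)
                        tgt = neg_table[int(r % np.uint64(table_size))]
                        if tgt == centre:
                            continue
                        label = 0.0
                    f = 0.0
                    for j in range(dim):
                        f += neu1[j] * syn1[tgt, j]
                    if f > _MAX_EXP:
                        g = (label - 1.0) * alpha
                    elif f < -_MAX_EXP:
                        g = label * alpha
                    else:
                        g = (label - 1.0 / (1.0 + math.exp(-f))) * alpha
                    if g == 0.0:
                        continue
                    for j in range(dim):
                        neu1e[j] += g * syn1[tgt, j]
                        syn1[tgt, j] += g * neu1[j]

                for c in range(cstart, cend):
                    if c == pos:
                        continue
                    wc = kept[c]
                    for j in range(dim):
                        syn0[wc, j] += neu1e[j]

    return syn0


def build_negative_table(counts: np.ndarray, power: float = 0.75) -> np.ndarray:
    """Unigram**power sampling table, word2vec style."""
    weights = np.asarray(counts, dtype=np.float64) ** power
    cum = np.cumsum(weights)
    cum /= cum[-1]
    positions = (np.arange(_NEG_TABLE_SIZE) + 0.5) / _NEG_TABLE_SIZE
    return np.searchsorted(cum, positions).astype(np.int64)


def train_cbow(
    doc_ids: list[np.ndarray],
    vocab_size: int,
    counts: np.ndarray,
    *,
    dim: int,
    window: int,
    epochs: int,
    negative: int,
    alpha0: float = 0.025,
    min_alpha: float = 1e-4,
    sample: float = 1e-3,
    seed: int = 0,
    doc_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Train CBOW input vectors over integer-encoded documents.

    ``doc_weights`` (one non-negative float per document, default all ones)
    scales each document's learning-rate contribution — the hook the
    Bayesian-bootstrap resampler uses to reweight documents without
    discarding any."""
    lengths = [len(d) for d in doc_ids]
    offsets = np.zeros(len(doc_ids) + 1, dtype=np.int64)
    np.cumsum(lengths, out=offsets[1:])
    tokens = (
        np.concatenate(doc_ids).astype(np.int64)
        if offsets[-1] > 0
        else np.zeros(0, dtype=np.int64)
    )
    neg_table = build_negative_table(counts)
    counts = np.asarray(counts, dtype=np.float64)
    total_count = counts.sum()
    if sample > 0 and total_count > 0:
        freq = counts / total_count
        keep_prob = np.minimum(1.0, (np.sqrt(freq / sample) + 1.0) * sample / freq)
    else:
        keep_prob = np.ones_like(counts)
    return _train_cbow_kernel(
        tokens,
        offsets,
        vocab_size,
        dim,
        window,
        epochs,
        negative,
        float(alpha0),
        float(min_alpha),
        neg_table,
        keep_prob,
        (
            np.ones(len(doc_ids), dtype=np.float64)
            if doc_weights is None
            else np.asarray(doc_weights, dtype=np.float64)
        ),
        np.uint64(seed & 0x7FFFFFFF),
    )
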