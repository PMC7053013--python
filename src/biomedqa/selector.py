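"""Supervised keyword selection: which question tokens belong in the query?

A sequence-labeling classifier marks each question token as keyword or
not.  Questions are encoded as fixed-length (40-position) sequences of
word-embedding vectors, zero-padded or truncated, with 40 sigmoid output
units — one per position.  The encoder layer comes from a small
architecture family: a flattened dense layer, an LSTM, or a 1-D
convolution, each optionally paired with a POS-tag branch (one-hot tags
passed through a dense rectifier layer and concatenated to the word
features).  Training runs 8-fold cross-validation and reports per-fold
token precision/recall/F1 (padding positions excluded), with mean and
standard deviation.

Selected keywords are used to *force-include* their constructs in the
initial retrieval query: those constructs are protected from the greedy
relaxation until everything unselected is exhausted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import (
    Adam,
    Concat,
    Conv1D,
    Dropout,
    FlatDense,
    LSTMLayer,
    TimeDense,
    masked_bce_grad,
    sigmoid,
)
from .annotation import AnnotatedText, _tag
from .lexicon import EmbeddingStore
from .retrieval import KeywordQuery

__all__ = [
    "MAX_LEN",
    "POS_TAGS",
    "ARCHITECTURES",
    "EncodedQuestion",
    "SelectorConfig",
    "KeywordSelector",
    "encode_question",
    "train_selector",
    "select_keywords",
    "force_include",
    "load_keyword_annotations",
]

MAX_LEN = 40

#: fixed POS tag inventory of the fallback tagger (code 0 is the pad)
POS_TAGS = (
    "NN", "NNS", "VB", "VBD", "VBG", "VBZ", "MD", "DT", "IN", "CC", "PRP",
    "WDT", "WRB", "JJ", "JJR", "JJS", "RB", "RBR", "RBS", "CD", "PUNCT",
)
_POS_CODE = {t: i + 1 for i, t in enumerate(POS_TAGS)}

ARCHITECTURES = ("dense", "lstm", "conv1d", "dense_dense", "lstm_dense", "lstm_lstm")


@dataclass
class EncodedQuestion:
    """Fixed-length encoding: (40, D) embeddings, POS codes, 0/1 labels."""

    embeddings: np.ndarray  # (MAX_LEN, D)
    pos_codes: np.ndarray  # (MAX_LEN,) ints, 0 = pad
    labels: np.ndarray  # (MAX_LEN,) 0/1, padding positions 0
    true_length: int
    tokens: list[str] = field(default_factory=list)
    prediction_only: bool = False


@dataclass
class SelectorConfig:
    architecture: str = "lstm"
    dropout: float = 0.2
    threshold: float = 0.5
    seed: int = 0
    folds: int = 8
    hidden: int = 24
    filters: int = 32
    pos_units: int = 8
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def encode_question(
    q: AnnotatedText | Sequence[str],
    embeddings: EmbeddingStore,
    labels: Sequence[int] | None = None,
    pos_tags: Sequence[str] | None = None,
) -> EncodedQuestion:
    """Encode a question to exactly 40 positions.

    Accepts an annotated question or a bare token sequence (when labels
    come from an external annotation whose own tokenization is
    authoritative).  OOV tokens map to zero vectors; sequences longer than
    40 are truncated, shorter ones zero-padded with label 0.
    """
    if isinstance(q, AnnotatedText):
        tokens = [t.surface for t in q.tokens]
        tags = [t.pos for t in q.tokens]
    else:
        tokens = list(q)
        tags = list(pos_tags) if pos_tags is not None else [
            _tag(t, None) for t in tokens
        ]
    tokens = tokens[:MAX_LEN]
    tags = tags[:MAX_LEN]
    D = embeddings.dimension
    X = np.zeros((MAX_LEN, D))
    P = np.zeros(MAX_LEN, dtype=np.int64)
    y = np.zeros(MAX_LEN)
    for i, tok in enumerate(tokens):
        v = embeddings.get(tok)
        if v is not None:
            X[i] = v
        P[i] = _POS_CODE.get(tags[i], _POS_CODE["NN"])
    prediction_only = labels is None
    if labels is not None:
        lab = list(labels)[:MAX_LEN]
        y[: len(lab)] = lab
    return EncodedQuestion(X, P, y, len(tokens), tokens, prediction_only)


def _one_hot_pos(P: np.ndarray) -> np.ndarray:
    n_codes = len(POS_TAGS) + 1
    out = np.zeros((*P.shape, n_codes))
    idx = np.indices(P.shape)
    out[(*idx, P)] = 1.0
    out[..., 0] = 0.0  # pad code stays all-zero
    return out


class _Network:
    """Encoder + per-position sigmoid readout for one architecture."""

    def __init__(self, arch: str, d_emb: int, cfg: SelectorConfig, rng: np.random.Generator):
        self.arch = arch
        self.cfg = cfg
        n_pos = len(POS_TAGS) + 1
        self.pos_branch = None
        d_in = d_emb
        if arch in ("dense_dense", "lstm_dense", "lstm_lstm"):
            self.pos_branch = TimeDense(n_pos, cfg.pos_units, rng, relu=True)
            self.concat = Concat(d_emb)
            d_in = d_emb + cfg.pos_units

        self.layers: list = []
        self.drop = Dropout(cfg.dropout, np.random.default_rng(rng.integers(2**31)))
        if arch in ("dense", "dense_dense"):
            self.layers = [self.drop, FlatDense(MAX_LEN, d_in, rng)]
        elif arch in ("lstm", "lstm_dense"):
            self.layers = [
                LSTMLayer(d_in, cfg.hidden, rng),
                self.drop,
                TimeDense(cfg.hidden, 1, rng),
            ]
        elif arch == "conv1d":
            self.layers = [
                Conv1D(d_in, cfg.filters, 3, rng),
                self.drop,
                TimeDense(cfg.filters, 1, rng),
            ]
        elif arch == "lstm_lstm":
            # word LSTM and POS LSTM run side by side; hidden states concat
            self.word_lstm = LSTMLayer(d_emb, cfg.hidden, rng)
            self.pos_lstm = LSTMLayer(cfg.pos_units, cfg.pos_units, rng)
            self.out_concat = Concat(cfg.hidden)
            self.layers = [self.drop, TimeDense(cfg.hidden + cfg.pos_units, 1, rng)]

        self.all_layers = list(self.layers)
        if self.pos_branch is not None:
            self.all_layers.append(self.pos_branch)
        if arch == "lstm_lstm":
            self.all_layers += [self.word_lstm, self.pos_lstm]

    def parameters(self) -> tuple[list, list]:
        params, grads = [], []
        for layer in self.all_layers:
            params += layer.params
            grads += layer.grads
        return params, grads

    def forward(self, X: np.ndarray, P: np.ndarray, train: bool) -> np.ndarray:
        if self.arch == "lstm_lstm":
            pe = self.pos_branch.forward(_one_hot_pos(P), train)
            hw = self.word_lstm.forward(X, train)
            hp = self.pos_lstm.forward(pe, train)
            h = self.out_concat.forward(hw, hp)
        elif self.pos_branch is not None:
            pe = self.pos_branch.forward(_one_hot_pos(P), train)
            h = self.concat.forward(X, pe)
        else:
            h = X
        for layer in self.layers:
            h = layer.forward(h, train)
        if h.ndim == 3:
            h = h[..., 0]
        return sigmoid(h)

    def backward(self, dz: np.ndarray) -> None:
        d = dz
        last = self.layers[-1]
        if isinstance(last, TimeDense):
            d = d[..., None]
        for layer in reversed(self.layers):
            d = layer.backward(d)
        if self.arch == "lstm_lstm":
            dw, dp = self.out_concat.backward(d)
            dxw = self.word_lstm.backward(dw)
            dpe = self.pos_lstm.backward(dp)
            self.pos_branch.backward(dpe)
        elif self.pos_branch is not None:
            _, dpe = self.concat.backward(d)
            self.pos_branch.backward(dpe)


class KeywordSelector(BaseEstimator):
    """Sequence-labeling keyword classifier (scikit-learn style estimator).

    Parameters mirror :class:`SelectorConfig`.  ``fit`` takes
    ``X`` of shape (n, 40, D) word-embedding sequences, ``y`` of shape
    (n, 40) binary labels, plus ``pos`` codes and a padding ``mask``;
    ``predict_proba`` returns per-position keyword probabilities.
    """

    def __init__(self, architecture: str = "lstm", dropout: float = 0.2,
                 threshold: float = 0.5, seed: int = 0, hidden: int = 24,
                 filters: int = 32, pos_units: int = 8, epochs: int = 60,
                 batch_size: int = 32, learning_rate: float = 0.02):
        self.architecture = architecture
        self.dropout = dropout
        self.threshold = threshold
        self.seed = seed
        self.hidden = hidden
        self.filters = filters
        self.pos_units = pos_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate

    def _config(self) -> SelectorConfig:
        return SelectorConfig(
            architecture=self.architecture, dropout=self.dropout,
            threshold=self.threshold, seed=self.seed, hidden=self.hidden,
            filters=self.filters, pos_units=self.pos_units, epochs=self.epochs,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
        )

    def fit(self, X, y, pos=None, mask=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != MAX_LEN:
            raise ValueError(f"X must be (n, {MAX_LEN}, D)")
        if mask is None:
            mask = (np.abs(X).sum(-1) > 0).astype(np.float64)
        mask = np.asarray(mask, dtype=np.float64)
        if pos is None:
            pos = np.zeros(X.shape[:2], dtype=np.int64)
        pos = np.asarray(pos, dtype=np.int64)
        on = (y * mask).sum()
        if on == 0 or on == mask.sum():
            raise ValueError("labels are single-class; cannot train")

        cfg = self._config()
        rng = np.random.default_rng(self.seed)
        net = _Network(cfg.architecture, X.shape[2], cfg, rng)
        params, grads = net.parameters()
        opt = Adam(params, grads, lr=cfg.learning_rate)
        n = X.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for s in range(0, n, cfg.batch_size):
                bi = order[s : s + cfg.batch_size]
                prob = net.forward(X[bi], pos[bi], train=True)
                _, dz = masked_bce_grad(prob, y[bi], mask[bi])
                net.backward(dz)
                opt.step()
        self.net_ = net
        self.n_features_in_ = X.shape[2]
        return self

    def predict_proba(self, X, pos=None):
        X = np.asarray(X, dtype=np.float64)
        if pos is None:
            pos = np.zeros(X.shape[:2], dtype=np.int64)
        return self.net_.forward(X, np.asarray(pos, dtype=np.int64), train=False)

    def predict(self, X, pos=None):
        return (self.predict_proba(X, pos) >= self.threshold).astype(int)


def _prf(y_true: np.ndarray, y_pred: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    m = mask > 0
    yt = (y_true > 0) & m
    yp = (y_pred > 0) & m
    tp = int((yt & yp).sum())
    fp = int((~yt & yp).sum())
    fn = int((yt & ~yp).sum())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"precision": prec, "recall": rec, "f1": f1}


def _stack(data: Sequence[EncodedQuestion]):
    X = np.stack([e.embeddings for e in data])
    P = np.stack([e.pos_codes for e in data])
    y = np.stack([e.labels for e in data])
    mask = np.zeros((len(data), MAX_LEN))
    for i, e in enumerate(data):
        mask[i, : e.true_length] = 1.0
    return X, P, y, mask


def train_selector(
    data: Sequence[EncodedQuestion], config: SelectorConfig
) -> tuple[KeywordSelector, list[dict[str, float]], dict[str, float]]:
    """K-fold cross-validated training.

    One k-th of the data is held out per fold (a seeded permutation
    partitions the examples, so every example is held out exactly once);
    per-fold precision/recall/F1 exclude padding positions.  Returns a
    model trained on all data, the per-fold metrics, and their mean/sd
    summary.
    """
    if len(data) < config.folds:
        raise ValueError(f"need at least {config.folds} examples")
    X, P, y, mask = _stack(data)
    if (y * mask).sum() == 0:
        raise ValueError("labels are all zero; nothing to learn")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(data))
    folds = np.array_split(order, config.folds)
    fold_metrics: list[dict[str, float]] = []
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        model = KeywordSelector(
            architecture=config.architecture, dropout=config.dropout,
            threshold=config.threshold, seed=config.seed + k,
            hidden=config.hidden, filters=config.filters,
            pos_units=config.pos_units, epochs=config.epochs,
            batch_size=config.batch_size, learning_rate=config.learning_rate,
        )
        model.fit(X[train_idx], y[train_idx], pos=P[train_idx], mask=mask[train_idx])
        pred = model.predict(X[test_idx], pos=P[test_idx])
        fold_metrics.append(_prf(y[test_idx], pred, mask[test_idx]))

    summary = {}
    for key in ("precision", "recall", "f1"):
        vals = np.array([m[key] for m in fold_metrics])
        summary[f"{key}_mean"] = float(vals.mean())
        summary[f"{key}_sd"] = float(vals.std(ddof=1))

    final = KeywordSelector(
        architecture=config.architecture, dropout=config.dropout,
        threshold=config.threshold, seed=config.seed, hidden=config.hidden,
        filters=config.filters, pos_units=config.pos_units,
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate,
    )
    final.fit(X, y, pos=P, mask=mask)
    return final, fold_metrics, summary


def select_keywords(
    q: AnnotatedText,
    model: KeywordSelector,
    embeddings: EmbeddingStore,
    threshold: float | None = None,
) -> list[str]:
    """Question tokens whose keyword probability reaches the threshold, at
    unpadded positions, in question order (one entry per position)."""
    enc = encode_question(q, embeddings)
    prob = model.predict_proba(enc.embeddings[None], pos=enc.pos_codes[None])[0]
    thr = model.threshold if threshold is None else threshold
    return [
        enc.tokens[i] for i in range(enc.true_length) if prob[i] >= thr
    ]


def force_include(query: KeywordQuery, keywords: Sequence[str]) -> KeywordQuery:
    """Protect every construct containing a selected keyword so relaxation
    drops unselected constructs first (among protected constructs the base
    drop order applies)."""
    kws = {k.lower() for k in keywords}
    if not kws:
        return query
    for st in query.constructs:
        for surface in st.surfaces():
            if surface.lower() in kws or set(surface.lower().split()) & kws:
                st.protected = True
                break
    return query


def load_keyword_annotations(path: str) -> list[tuple[list[str], list[int]]]:
    """Loader for deposited keyword annotations: JSONL records
    {"question": str, "keyword_labels": [0/1, ...]} with whitespace
    tokenization (the annotation's tokenization is authoritative)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            tokens = rec["question"].split()
            labels = [int(x) for x in rec["keyword_labels"]]
            if len(labels) != len(tokens):
                raise ValueError(
                    f"label/token length mismatch for {rec['question']!r}"
                )
            out.append((tokens, labels))
    return out
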