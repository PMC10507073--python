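"""Estimator-style model classes: BIRNN, text scorer, fusion, RF baseline.

The classes follow scikit-learn conventions — constructor hyperparameters,
``fit``/``predict_proba``, fitted attributes with trailing underscores,
``get_params``/``set_params`` — so they compose with sklearn pipelines and
model selection. The sequence models train with the AUPRC-checkpointing
protocol of :mod:`icureadmit.training`.
"""

from __future__ import annotations

import abc

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .abstraction import EncodedSample
from .encoding import NoteChunks
from .evaluation import aggregate_chunk_scores
from .nn.networks import BirnnNetwork, FusionNetwork, TransformerTextNetwork
from .training import ArrayDataset, TrainConfig, predict_scores, train


def samples_to_arrays(samples: list[EncodedSample],
                      extra: np.ndarray | None = None) -> dict:
    """Stack EncodedSamples into the batched array dict the networks consume."""
    out = {
        "indices": np.stack([s.indices for s in samples]),
        "mask": np.stack([s.mask for s in samples]),
    }
    if samples and samples[0].dense is not None:
        out["dense"] = np.stack([s.dense for s in samples])
    if extra is not None:
        out["extra"] = np.asarray(extra, dtype=np.float64)
    return out


def birnn_forward(network: BirnnNetwork, sample: EncodedSample,
                  extra: np.ndarray | None = None) -> float:
    """Score a single encoded sample (convenience over the batched forward)."""
    batch = samples_to_arrays([sample], None if extra is None else extra[None, :])
    return float(network.forward(batch).data[0])


def _auto_val_split(inputs: dict, y: np.ndarray, val_fraction: float, seed: int):
    idx = np.arange(len(y))
    tr, va = train_test_split(idx, test_size=val_fraction, random_state=seed,
                              stratify=y)

    def take(d, sel):
        return {k: take(v, sel) if isinstance(v, dict) else v[sel]
                for k, v in d.items()}

    return (ArrayDataset(take(inputs, tr), y[tr]),
            ArrayDataset(take(inputs, va), y[va]))


class _SequenceClassifier(BaseEstimator, ClassifierMixin, abc.ABC):
    """Shared fit/predict plumbing for the autodiff-backed classifiers."""

    @abc.abstractmethod
    def _build_network(self, inputs: dict):
        ...

    @abc.abstractmethod
    def _train_config(self) -> TrainConfig:
        ...

    def _inputs(self, X) -> dict:
        if isinstance(X, dict):
            return X
        return samples_to_arrays(list(X))

    def fit(self, X, y, X_val=None, y_val=None):
        inputs = self._inputs(X)
        y = np.asarray(y, dtype=np.float64)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("fit requires both classes")
        self.network_ = self._build_network(inputs)
        if X_val is None:
            train_ds, val_ds = _auto_val_split(inputs, y, self.val_fraction, self.seed)
        else:
            train_ds = ArrayDataset(inputs, y)
            val_ds = ArrayDataset(self._inputs(X_val), np.asarray(y_val, dtype=np.float64))
        self.network_, self.history_ = train(
            self.network_, train_ds, val_ds, self._train_config())
        return self

    @staticmethod
    def _first_leaf(d):
        for v in d.values():
            if isinstance(v, dict):
                return _SequenceClassifier._first_leaf(v)
            return v

    def decision_function(self, X) -> np.ndarray:
        inputs = self._inputs(X)
        n = len(self._first_leaf(inputs))
        return predict_scores(self.network_, ArrayDataset(inputs, np.zeros(n)),
                              batch_size=256)

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)


class BirnnClassifier(_SequenceClassifier):
    """Bidirectional GRU sequence classifier with attention pooling.

    Consumes padded token-index sequences (vocabulary size D embeds into
    ``floor(D ** 1/4)`` dimensions) or, with ``dense_input=True``, the
    interpolated multivariate per-timestep layout which bypasses the
    embedding. An optional static vector per sample ("extra", e.g. the
    demographics one-hot) is concatenated after attention pooling.
    """

    def __init__(self, hidden_size: int = 64, extra_dims: int = 0,
                 dense_input: bool = False, batch_size: int = 64,
                 eval_every_steps: int = 200, stop_loss: int = 7,
                 lr_initial: float = 1e-3, lr_decay: float = 0.97,
                 max_steps: int | None = None, pos_weight: float | None = None,
                 val_fraction: float = 0.125, seed: int = 0):
        self.hidden_size = hidden_size
        self.extra_dims = extra_dims
        self.dense_input = dense_input
        self.batch_size = batch_size
        self.eval_every_steps = eval_every_steps
        self.stop_loss = stop_loss
        self.lr_initial = lr_initial
        self.lr_decay = lr_decay
        self.max_steps = max_steps
        self.pos_weight = pos_weight
        self.val_fraction = val_fraction
        self.seed = seed

    def _build_network(self, inputs: dict) -> BirnnNetwork:
        if self.dense_input:
            L, F = inputs["dense"].shape[1:]
            return BirnnNetwork(vocab_size=F, max_len=L, hidden=self.hidden_size,
                                extra_dims=self.extra_dims, dense_dim=F, seed=self.seed)
        L = inputs["indices"].shape[1]
        D = getattr(self, "vocab_size_", None) or int(inputs["indices"].max() + 1)
        return BirnnNetwork(vocab_size=D, max_len=L, hidden=self.hidden_size,
                            extra_dims=self.extra_dims, seed=self.seed)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(batch_size=self.batch_size,
                           eval_every_steps=self.eval_every_steps,
                           stop_loss=self.stop_loss, lr_initial=self.lr_initial,
                           lr_decay=self.lr_decay, max_steps=self.max_steps,
                           pos_weight=self.pos_weight, seed=self.seed)

    def fit(self, X, y, X_val=None, y_val=None, vocab_size: int | None = None):
        if vocab_size is not None:
            self.vocab_size_ = vocab_size
        elif isinstance(X, list) and X and isinstance(X[0], EncodedSample):
            self.vocab_size_ = X[0].vocab_size
        return super().fit(X, y, X_val=X_val, y_val=y_val)


class TextScorer(abc.ABC):
    """Contract for note-chunk scorers: probabilities in [0, 1] per chunk,
    fine-tunable on labelled chunks. Pretrained clinical encoders satisfy
    this interface; the bundled implementation is a tiny random-initialized
    transformer."""

    @abc.abstractmethod
    def fit(self, chunk_ids: np.ndarray, chunk_mask: np.ndarray, y: np.ndarray,
            **kwargs):
        ...

    @abc.abstractmethod
    def score_chunks(self, chunks: NoteChunks) -> np.ndarray:
        ...

    def score_note(self, chunks: NoteChunks) -> float:
        """Patient-level probability via the max/mean chunk aggregation."""
        return aggregate_chunk_scores(self.score_chunks(chunks))


class TransformerTextScorer(TextScorer, _SequenceClassifier):
    """Two-layer, width-32, single-head transformer encoder chunk scorer."""

    def __init__(self, vocab_size: int = 1000, chunk_length: int = 64,
                 width: int = 32, n_layers: int = 2, batch_size: int = 64,
                 eval_every_steps: int = 200, stop_loss: int = 7,
                 lr_initial: float = 2e-5, lr_decay: float = 0.9,
                 max_steps: int | None = None, val_fraction: float = 0.125,
                 seed: int = 0):
        self.vocab_size = vocab_size
        self.chunk_length = chunk_length
        self.width = width
        self.n_layers = n_layers
        self.batch_size = batch_size
        self.eval_every_steps = eval_every_steps
        self.stop_loss = stop_loss
        self.lr_initial = lr_initial
        self.lr_decay = lr_decay
        self.max_steps = max_steps
        self.val_fraction = val_fraction
        self.seed = seed

    def _build_network(self, inputs: dict) -> TransformerTextNetwork:
        return TransformerTextNetwork(vocab_size=self.vocab_size,
                                      max_len=self.chunk_length, width=self.width,
                                      n_layers=self.n_layers, seed=self.seed)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(batch_size=self.batch_size,
                           eval_every_steps=self.eval_every_steps,
                           stop_loss=self.stop_loss, lr_initial=self.lr_initial,
                           lr_decay=self.lr_decay, max_steps=self.max_steps,
                           seed=self.seed)

    def pad_chunks(self, chunks: NoteChunks) -> tuple[np.ndarray, np.ndarray]:
        """Pad each chunk to chunk_length; empty chunks give all-pad rows."""
        ids = np.zeros((chunks.n, self.chunk_length), dtype=np.int64)
        mask = np.zeros((chunks.n, self.chunk_length), dtype=bool)
        for i, c in enumerate(chunks.chunks):
            c = c[:self.chunk_length]
            ids[i, :len(c)] = c
            mask[i, :len(c)] = True
        return ids, mask

    def fit(self, chunk_ids, chunk_mask=None, y=None, X_val=None, y_val=None):
        if chunk_mask is None or y is None:
            raise ValueError("fit requires chunk_ids, chunk_mask and labels")
        inputs = {"indices": np.asarray(chunk_ids), "mask": np.asarray(chunk_mask)}
        return _SequenceClassifier.fit(self, inputs, y, X_val=X_val, y_val=y_val)

    def score_chunks(self, chunks: NoteChunks) -> np.ndarray:
        ids, mask = self.pad_chunks(chunks)
        return self.decision_function({"indices": ids, "mask": mask})


class FusedClassifier(_SequenceClassifier):
    """Joint multimodal model over named component networks.

    ``components`` maps name -> an *unfitted* component classifier whose
    network supplies the pre-classifier vector; ``static_dims`` appends a
    raw static vector from ``X["static"]``. All parameters, including the
    components', are trained jointly under one affine fusion head.
    """

    def __init__(self, components: dict, static_dims: int = 0,
                 batch_size: int = 64, eval_every_steps: int = 200,
                 stop_loss: int = 7, lr_initial: float = 1e-3,
                 lr_decay: float = 0.97, max_steps: int | None = None,
                 pos_weight: float | None = None, val_fraction: float = 0.125,
                 seed: int = 0):
        self.components = components
        self.static_dims = static_dims
        self.batch_size = batch_size
        self.eval_every_steps = eval_every_steps
        self.stop_loss = stop_loss
        self.lr_initial = lr_initial
        self.lr_decay = lr_decay
        self.max_steps = max_steps
        self.pos_weight = pos_weight
        self.val_fraction = val_fraction
        self.seed = seed

    def _build_network(self, inputs: dict) -> FusionNetwork:
        nets = {}
        for name, comp in self.components.items():
            nets[name] = comp._build_network(inputs[name])
        return FusionNetwork(nets, static_dims=self.static_dims, seed=self.seed)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(batch_size=self.batch_size,
                           eval_every_steps=self.eval_every_steps,
                           stop_loss=self.stop_loss, lr_initial=self.lr_initial,
                           lr_decay=self.lr_decay, max_steps=self.max_steps,
                           pos_weight=self.pos_weight, seed=self.seed)


def fit_tabular_baseline(features: np.ndarray, labels: np.ndarray,
                         n_estimators: int = 200, seed: int = 0) -> RandomForestClassifier:
    """Random-forest probability scorer on the concatenated ICD-9 one-hot and
    demographics one-hot feature matrix."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("tabular baseline requires both classes")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                n_jobs=1)
    rf.fit(np.asarray(features), labels)
    return rf


def combine_multimodal(components: dict, static_dims: int = 0, **kwargs) -> FusedClassifier:
    """Build the joint multimodal classifier from component classifiers."""
    return FusedClassifier(components=components, static_dims=static_dims, **kwargs)
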