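"""Training protocol: AUPRC-driven checkpointing, LR decay, stop-loss.

Models are trained on binary cross-entropy in fixed-size batches. Every
``eval_every_steps`` optimizer steps the validation AUPRC is computed: if
it exceeds the best value so far the model is checkpointed and the
non-improvement counter resets; otherwise the learning rate is multiplied
by ``lr_decay`` and the counter increments. Training stops once the
counter exceeds ``stop_loss`` consecutive non-improvements (or a safety
step cap is hit) and the last saved model is returned.

The learning rate never resets on improvement — decay is monotone
annealing — while the patience counter does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

from .nn.autodiff import Adam, Tensor, bce_with_logits

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Protocol constants; text models use lr 2e-5 / decay 0.9, others 1e-3 / 0.97."""

    batch_size: int = 64
    eval_every_steps: int = 200
    stop_loss: int = 7
    lr_initial: float = 1e-3
    lr_decay: float = 0.97
    max_steps: int | None = None   # default: 20 * (train size / batch size)
    pos_weight: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.eval_every_steps, self.stop_loss) <= 0:
            raise ValueError("batch_size, eval_every_steps, stop_loss must be positive")
        if not 0.0 < self.lr_decay < 1.0:
            raise ValueError("lr_decay must lie in (0, 1)")
        if self.lr_initial <= 0:
            raise ValueError("lr_initial must be positive")

    @classmethod
    def for_text_model(cls, **overrides) -> "TrainConfig":
        return cls(lr_initial=2e-5, lr_decay=0.9, **overrides)


@dataclass
class EvalRecord:
    step: int
    val_auprc: float
    lr: float
    improved: bool
    checkpoint_saved: bool


@dataclass
class TrainHistory:
    records: list[EvalRecord] = field(default_factory=list)
    stopped_by: str = "max_steps"

    @property
    def n_evaluations(self) -> int:
        return len(self.records)

    @property
    def ever_improved(self) -> bool:
        return any(r.improved for r in self.records)


class TrainingProtocol:
    """The checkpoint / learning-rate / stop-loss state machine.

    Pure bookkeeping over a stream of validation AUPRC values; usable on
    simulated sequences independently of any model.
    """

    def __init__(self, stop_loss: int, lr_initial: float, lr_decay: float):
        self.stop_loss = stop_loss
        self.lr_decay = lr_decay
        self.lr = lr_initial
        self.best = -np.inf
        self.failures = 0

    def observe(self, val_auprc: float) -> tuple[bool, float, bool]:
        """Process one evaluation; returns (save_checkpoint, lr, stop)."""
        improved = val_auprc > self.best
        if improved:
            self.best = val_auprc
            self.failures = 0
        else:
            self.failures += 1
            self.lr *= self.lr_decay
        return improved, self.lr, self.failures > self.stop_loss


class ArrayDataset:
    """Labelled samples as a (possibly nested) dict of aligned arrays."""

    def __init__(self, inputs: dict, labels: np.ndarray):
        self.inputs = inputs
        self.labels = np.asarray(labels, dtype=np.float64)
        n = len(self.labels)

        def check(d):
            for v in d.values():
                if isinstance(v, dict):
                    check(v)
                elif len(v) != n:
                    raise ValueError("input arrays must align with labels")

        check(inputs)

    def __len__(self) -> int:
        return len(self.labels)

    def batch(self, idx: np.ndarray) -> tuple[dict, np.ndarray]:
        def take(d):
            return {k: take(v) if isinstance(v, dict) else v[idx] for k, v in d.items()}
        return take(self.inputs), self.labels[idx]


def predict_scores(network, data: ArrayDataset, batch_size: int = 256) -> np.ndarray:
    """Probability scores in inference mode (sigmoid of the network score)."""
    out = np.empty(len(data))
    for start in range(0, len(data), batch_size):
        idx = np.arange(start, min(start + batch_size, len(data)))
        batch, _ = data.batch(idx)
        logits = network.forward(batch).data
        out[idx] = 1.0 / (1.0 + np.exp(-logits))
    return out


def train(network, train_data: ArrayDataset, val_data: ArrayDataset,
          config: TrainConfig):
    """Run the training protocol; returns (best network, TrainHistory).

    The network is a parameter Module exposing ``forward(batch) -> scores``.
    On completion its parameters are those of the last saved checkpoint;
    if no evaluation ever improved the initial parameters are restored and
    a warning is logged.
    """
    if len(train_data) == 0:
        raise ValueError("empty training data")
    if len(np.unique(val_data.labels)) < 2:
        raise ValueError("validation data must contain both classes")
    rng = np.random.default_rng(config.seed)
    max_steps = config.max_steps
    if max_steps is None:
        max_steps = 20 * max(1, int(np.ceil(len(train_data) / config.batch_size)))
    protocol = TrainingProtocol(config.stop_loss, config.lr_initial, config.lr_decay)
    optimizer = Adam(network.params, lr=config.lr_initial)
    initial_state = network.state_dict()
    best_state = None
    history = TrainHistory()

    step = 0
    order = rng.permutation(len(train_data))
    cursor = 0
    while step < max_steps:
        if cursor + config.batch_size > len(order):
            order = rng.permutation(len(train_data))
            cursor = 0
        idx = order[cursor:cursor + config.batch_size]
        cursor += config.batch_size
        batch, y = train_data.batch(idx)
        optimizer.zero_grad()
        logits = network.forward(batch)
        if config.pos_weight is None:
            loss = bce_with_logits(logits, y)
        else:
            w = np.where(y == 1, config.pos_weight, 1.0)
            raw = bce_per_sample(logits, y)
            loss = (raw * Tensor(w)).sum() / float(w.sum())
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite loss at step {step}: {float(loss.data)!r} "
                f"(lr={optimizer.lr:.3g}, batch={idx[:5]}...)")
        loss.backward()
        optimizer.step()
        step += 1

        if step % config.eval_every_steps == 0:
            val_scores = predict_scores(network, val_data)
            auprc = float(average_precision_score(val_data.labels, val_scores))
            improved, lr, stop = protocol.observe(auprc)
            optimizer.lr = lr
            if improved:
                best_state = network.state_dict()
            history.records.append(EvalRecord(step, auprc, lr, improved, improved))
            if stop:
                history.stopped_by = "stop_loss"
                break

    if best_state is not None:
        network.load_state_dict(best_state)
    else:
        network.load_state_dict(initial_state)
        logger.warning("no evaluation ever improved; returning the initial model")
    return network, history


def bce_per_sample(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Per-sample binary cross-entropy vector (for loss weighting)."""
    y = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss, parents=(logits,))

    def backward(g):
        if logits.grad is not None:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits.grad += g * (sig - y)

    out._backward = backward
    return out
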