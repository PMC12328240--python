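"""Per-residue insertion-tolerance classifier.

The classifier is a small two-layer perceptron head with ReLU activation
applied independently to every residue's embedding row, producing two
logits per position (insertion-tolerant vs other). Training uses
sequence-specific *positional masking* to cope with extreme class
imbalance: each optimization step visits one sequence and computes the
cross-entropy only over the labelled positive positions (the junction and
its neighbours) plus one freshly sampled unknown position, which serves as
the negative example for that step.

The head, its gradients and the Adam optimizer are implemented directly in
NumPy: the model is tiny (at most a few million parameters), runs
comfortably on one CPU, and a self-contained implementation keeps training
bit-reproducible from a single seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import LABEL_POSITIVE, LabelVector
from .encoding import EncodedSequence

logger = logging.getLogger(__name__)

TOLERANT_CLASS = 1  # column index of the insertion-tolerant logit


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Parameters and configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Weights of the two-layer perceptron head.

    ``W1``: (D, H), ``b1``: (H,), ``W2``: (H, 2), ``b2``: (2,). The forward
    map is ``relu(x W1 + b1) W2 + b2`` applied row-wise.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    encoder_id: str = ""

    def __post_init__(self) -> None:
        D, H = self.W1.shape
        if self.b1.shape != (H,) or self.W2.shape != (H, 2) or self.b2.shape != (2,):
            raise ModelError("inconsistent parameter shapes")
        for arr in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(arr)):
                raise ModelError("non-finite parameter values")

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[1]

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.W1.copy(),
            self.b1.copy(),
            self.W2.copy(),
            self.b2.copy(),
            self.encoder_id,
        )


def init_params(
    input_dim: int,
    hidden_dim: int = 512,
    seed: int = 0,
    encoder_id: str = "",
) -> ModelParams:
    """Fan-in-scaled (He) random initialization from a seeded generator."""
    rng = np.random.default_rng(seed)
    W1 = rng.standard_normal((input_dim, hidden_dim)) * np.sqrt(2.0 / input_dim)
    W2 = rng.standard_normal((hidden_dim, 2)) * np.sqrt(2.0 / hidden_dim)
    return ModelParams(
        W1, np.zeros(hidden_dim), W2, np.zeros(2), encoder_id
    )


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    total_steps: int = 1500
    checkpoint_every: int = 100
    seed: int = 0
    hidden_dim: int = 512
    window_radius: int = 1  # adjacency extension of positive labels

    def __post_init__(self) -> None:
        if self.total_steps < 1:
            raise ModelError("total_steps must be >= 1")
        if self.learning_rate <= 0:
            raise ModelError("learning_rate must be > 0")
        if self.checkpoint_every < 1:
            raise ModelError("checkpoint_every must be >= 1")


@dataclass(frozen=True)
class MaskSample:
    """The positions contributing to one step's loss."""

    positive_indices: tuple[int, ...]
    negative_index: int

    def __post_init__(self) -> None:
        if not self.positive_indices:
            raise ModelError("mask must cover at least one positive position")
        if self.negative_index in self.positive_indices:
            raise ModelError("negative index collides with positives")

    @property
    def indices(self) -> tuple[int, ...]:
        return self.positive_indices + (self.negative_index,)

    @property
    def targets(self) -> tuple[int, ...]:
        return (TOLERANT_CLASS,) * len(self.positive_indices) + (
            1 - TOLERANT_CLASS,
        )


# ---------------------------------------------------------------------------
# Forward pass and loss
# ---------------------------------------------------------------------------


def forward_logits(params: ModelParams, matrix: np.ndarray) -> np.ndarray:
    """Row-wise two-layer perceptron: (L, D) -> (L, 2) logits."""
    if matrix.shape[1] != params.input_dim:
        raise ModelError(
            f"input dimension {matrix.shape[1]} != model input "
            f"{params.input_dim}"
        )
    hidden = np.maximum(matrix @ params.W1 + params.b1, 0.0)
    return hidden @ params.W2 + params.b2


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    params: ModelParams, encoded: EncodedSequence
) -> tuple[np.ndarray, np.ndarray]:
    """Logits plus the per-residue tolerant-class probability trace.

    Scores are the two-class softmax probability of the tolerant class,
    hence strictly inside (0, 1).
    """
    logits = forward_logits(params, encoded.matrix)
    scores = _softmax(logits)[:, TOLERANT_CLASS]
    return logits, scores


def sample_mask(labels: LabelVector, rng: np.random.Generator) -> MaskSample:
    """All positive positions plus one uniformly drawn unknown position."""
    positives = labels.positive_indices
    unknowns = labels.unknown_indices
    if not positives:
        raise ModelError("label vector has no positive positions")
    if not unknowns:
        raise ModelError(
            "label vector has no unknown positions to sample a negative from"
        )
    negative = unknowns[rng.integers(len(unknowns))]
    return MaskSample(positives, int(negative))


def masked_loss(
    logits: np.ndarray, labels: LabelVector, mask: MaskSample
) -> float:
    """Mean two-class cross-entropy over the masked positions only.

    Positive positions target the tolerant class; the sampled negative
    targets the other class. Positions outside the mask contribute exactly
    zero — their logits never enter the computation.
    """
    idx = np.asarray(mask.indices)
    if idx.size == 0:
        raise ModelError("empty mask")
    if idx.max() >= logits.shape[0]:
        raise ModelError("mask index beyond sequence length")
    for i in mask.positive_indices:
        if labels.labels[i] != LABEL_POSITIVE:
            raise ModelError(f"mask marks position {i} positive but labels do not")
    targets = np.asarray(mask.targets)
    sub = logits[idx]
    shifted = sub - sub.max(axis=1, keepdims=True)
    log_probs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return float(-log_probs[np.arange(idx.size), targets].mean())


def _masked_loss_and_grads(
    params: ModelParams,
    matrix: np.ndarray,
    mask: MaskSample,
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and analytic gradients, computed only through masked rows."""
    idx = np.asarray(mask.indices)
    targets = np.asarray(mask.targets)
    x = matrix[idx]  # (m, D)
    pre = x @ params.W1 + params.b1
    hidden = np.maximum(pre, 0.0)
    logits = hidden @ params.W2 + params.b2
    shifted = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    m = idx.size
    loss = float(
        -np.log(probs[np.arange(m), targets] + 1e-300).mean()
    )
    dlogits = probs.copy()
    dlogits[np.arange(m), targets] -= 1.0
    dlogits /= m
    grads = {
        "W2": hidden.T @ dlogits,
        "b2": dlogits.sum(axis=0),
    }
    dhidden = (dlogits @ params.W2.T) * (pre > 0)
    grads["W1"] = x.T @ dhidden
    grads["b1"] = dhidden.sum(axis=0)
    return loss, grads


# ---------------------------------------------------------------------------
# Adam optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with the standard default moment settings (0.9, 0.999, 1e-8)."""

    def __init__(
        self,
        params: ModelParams,
        learning_rate: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {k: np.zeros_like(getattr(params, k)) for k in ("W1", "b1", "W2", "b2")}
        self._v = {k: np.zeros_like(getattr(params, k)) for k in ("W1", "b1", "W2", "b2")}

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self._m[k] = self.beta1 * self._m[k] + (1 - self.beta1) * g
            self._v[k] = self.beta2 * self._v[k] + (1 - self.beta2) * g * g
            m_hat = self._m[k] / b1c
            v_hat = self._v[k] / b2c
            getattr(params, k)[...] -= (
                self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingExample:
    """One encoded sequence with its label vector."""

    accession: str
    matrix: np.ndarray
    labels: LabelVector
    encoder_id: str

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.labels.length:
            raise ModelError(
                f"{self.accession}: encoding has {self.matrix.shape[0]} rows "
                f"but labels cover {self.labels.length} positions"
            )


@dataclass
class Checkpoint:
    step: int
    params: ModelParams
    train_loss: float
    validation_auroc: float | None = None

    @property
    def checkpoint_id(self) -> str:
        return f"{self.params.encoder_id}-step{self.step}"


@dataclass
class TrainingLog:
    steps: list[int] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)

    def record(self, step: int, loss: float) -> None:
        self.steps.append(step)
        self.losses.append(loss)


def _validation_auroc(
    params: ModelParams, examples: Sequence[TrainingExample]
) -> float | None:
    """AUROC of positive-labelled vs unknown positions, pooled over sequences."""
    from .evaluation import _auroc_from_scores  # local import, no cycle at module load

    pos_scores: list[np.ndarray] = []
    neg_scores: list[np.ndarray] = []
    for ex in examples:
        logits = forward_logits(params, ex.matrix)
        scores = _softmax(logits)[:, TOLERANT_CLASS]
        lab = np.asarray(ex.labels.labels)
        pos_scores.append(scores[lab == LABEL_POSITIVE])
        neg_scores.append(scores[lab != LABEL_POSITIVE])
    pos = np.concatenate(pos_scores) if pos_scores else np.array([])
    neg = np.concatenate(neg_scores) if neg_scores else np.array([])
    if pos.size == 0 or neg.size == 0:
        return None
    return _auroc_from_scores(pos, neg)


def _check_single_encoder(examples: Iterable[TrainingExample]) -> str:
    ids = {ex.encoder_id for ex in examples}
    if len(ids) != 1:
        raise ModelError(
            f"all training examples must share one encoder; found {sorted(ids)}"
        )
    return ids.pop()


def train(
    train_examples: Sequence[TrainingExample],
    config: TrainConfig,
    validation_examples: Sequence[TrainingExample] = (),
    params: ModelParams | None = None,
    checkpoint_dir: str | Path | None = None,
) -> tuple[list[Checkpoint], TrainingLog]:
    """Run masked-loss training and return the checkpoint ladder.

    One optimization step consumes one sequence, drawn by seeded shuffle
    and reshuffled every epoch; a fresh mask (all positives + one random
    unknown) is sampled at every visit. Checkpoints are snapshotted every
    ``checkpoint_every`` steps and at ``total_steps``; each carries the
    validation AUROC (positive vs unknown positions) when a validation set
    is given. The whole trajectory is a pure function of (data, config).
    """
    if not train_examples:
        raise ModelError("no training examples")
    encoder_id = _check_single_encoder(
        list(train_examples) + list(validation_examples)
    )
    if params is None:
        params = init_params(
            input_dim=train_examples[0].matrix.shape[1],
            hidden_dim=config.hidden_dim,
            seed=config.seed,
            encoder_id=encoder_id,
        )
    elif params.encoder_id and params.encoder_id != encoder_id:
        raise ModelError(
            f"model was built for encoder {params.encoder_id!r}, "
            f"data encoded with {encoder_id!r}"
        )
    params = params.copy()

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(params, config.learning_rate)
    log = TrainingLog()
    checkpoints: list[Checkpoint] = []
    order: list[int] = []

    for step in range(1, config.total_steps + 1):
        if not order:
            order = list(rng.permutation(len(train_examples)))
        ex = train_examples[order.pop()]
        mask = sample_mask(ex.labels, rng)
        loss, grads = _masked_loss_and_grads(params, ex.matrix, mask)
        optimizer.step(params, grads)
        log.record(step, loss)
        if step % config.checkpoint_every == 0 or step == config.total_steps:
            val = (
                _validation_auroc(params, validation_examples)
                if validation_examples
                else None
            )
            ckpt = Checkpoint(step, params.copy(), loss, val)
            checkpoints.append(ckpt)
            logger.info(
                "step %d: loss %.4f%s",
                step,
                loss,
                f", val AUROC {val:.4f}" if val is not None else "",
            )
            if checkpoint_dir is not None:
                save_checkpoint(
                    ckpt,
                    Path(checkpoint_dir) / f"step{step:06d}",
                    config=config,
                )
    return checkpoints, log


@dataclass(frozen=True)
class ExperimentalPoint:
    """One experimentally assayed position with a definite class."""

    accession: str
    position: int
    tolerated: bool


def fine_tune(
    params: ModelParams,
    points: Sequence[ExperimentalPoint],
    encodings: dict[str, np.ndarray],
    config: TrainConfig,
) -> ModelParams:
    """Continue optimization on experimental screen points.

    Each step's mask is the full set of assayed positions of one sequence,
    with both classes supplied explicitly — no random negative sampling.
    ``config.total_steps`` counts sequence visits; zero points or zero
    steps leave the parameters untouched (a fresh copy is still returned).
    """
    params = params.copy()
    if not points:
        return params
    by_acc: dict[str, list[ExperimentalPoint]] = {}
    for p in points:
        matrix = encodings.get(p.accession)
        if matrix is None:
            raise ModelError(f"no encoding supplied for {p.accession}")
        if not 0 <= p.position < matrix.shape[0]:
            raise ModelError(
                f"{p.accession}: experimental position {p.position} outside "
                f"sequence of length {matrix.shape[0]}"
            )
        by_acc.setdefault(p.accession, []).append(p)

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(params, config.learning_rate)
    accessions = sorted(by_acc)
    order: list[int] = []
    for _ in range(config.total_steps):
        if not order:
            order = list(rng.permutation(len(accessions)))
        acc = accessions[order.pop()]
        pts = by_acc[acc]
        idx = np.array([p.position for p in pts])
        targets = np.array(
            [TOLERANT_CLASS if p.tolerated else 1 - TOLERANT_CLASS for p in pts]
        )
        loss, grads = _points_loss_and_grads(
            params, encodings[acc], idx, targets
        )
        optimizer.step(params, grads)
    return params


def _points_loss_and_grads(
    params: ModelParams,
    matrix: np.ndarray,
    idx: np.ndarray,
    targets: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    x = matrix[idx]
    pre = x @ params.W1 + params.b1
    hidden = np.maximum(pre, 0.0)
    logits = hidden @ params.W2 + params.b2
    shifted = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    m = idx.size
    loss = float(-np.log(probs[np.arange(m), targets] + 1e-300).mean())
    dlogits = probs.copy()
    dlogits[np.arange(m), targets] -= 1.0
    dlogits /= m
    grads = {"W2": hidden.T @ dlogits, "b2": dlogits.sum(axis=0)}
    dhidden = (dlogits @ params.W2.T) * (pre > 0)
    grads["W1"] = x.T @ dhidden
    grads["b1"] = dhidden.sum(axis=0)
    return loss, grads


def points_loss(
    params: ModelParams,
    points: Sequence[ExperimentalPoint],
    encodings: dict[str, np.ndarray],
) -> float:
    """Mean cross-entropy of experimental points under the current params."""
    total, n = 0.0, 0
    by_acc: dict[str, list[ExperimentalPoint]] = {}
    for p in points:
        by_acc.setdefault(p.accession, []).append(p)
    for acc, pts in by_acc.items():
        idx = np.array([p.position for p in pts])
        targets = np.array(
            [TOLERANT_CLASS if p.tolerated else 1 - TOLERANT_CLASS for p in pts]
        )
        loss, _ = _points_loss_and_grads(params, encodings[acc], idx, targets)
        total += loss * len(pts)
        n += len(pts)
    return total / n


# ---------------------------------------------------------------------------
# Checkpoint I/O: .npz weights + JSON sidecar
# ---------------------------------------------------------------------------


def save_checkpoint(
    ckpt: Checkpoint,
    stem: str | Path,
    config: TrainConfig | None = None,
) -> Path:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        stem.with_suffix(".npz"),
        W1=ckpt.params.W1,
        b1=ckpt.params.b1,
        W2=ckpt.params.W2,
        b2=ckpt.params.b2,
    )
    meta = {
        "encoder_id": ckpt.params.encoder_id,
        "input_dim": ckpt.params.input_dim,
        "hidden_dim": ckpt.params.hidden_dim,
        "step": ckpt.step,
        "train_loss": ckpt.train_loss,
        "validation_auroc": ckpt.validation_auroc,
    }
    if config is not None:
        meta["config"] = {
            "learning_rate": config.learning_rate,
            "total_steps": config.total_steps,
            "checkpoint_every": config.checkpoint_every,
            "seed": config.seed,
            "hidden_dim": config.hidden_dim,
            "window_radius": config.window_radius,
        }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return stem.with_suffix(".npz")


def load_checkpoint(stem: str | Path) -> Checkpoint:
    stem = Path(stem)
    with np.load(stem.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in ("W1", "b1", "W2", "b2")}
    meta = json.loads(stem.with_suffix(".json").read_text())
    params = ModelParams(**arrays, encoder_id=meta["encoder_id"])
    return Checkpoint(
        step=meta["step"],
        params=params,
        train_loss=meta["train_loss"],
        validation_auroc=meta.get("validation_auroc"),
    )
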