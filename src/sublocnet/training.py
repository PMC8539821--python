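"""Loss, training loop, and the cross-validation ablation harness.

The loss is binary cross-entropy averaged over label terms plus an L2
penalty on the convolution kernels only:

    L = -(1/n) sum_i [ y_i log(y^_i) + (1 - y_i) log(1 - y^_i) ] + lambda ||w||^2

Predictions are epsilon-clipped (1e-7) before the logs.  Training is plain
mini-batch Adam with a seeded shuffle each epoch, fully deterministic for a
fixed seed on a single thread.

``run_cross_validation`` rotates k folds over an annotated protein set,
trains a fresh model per fold on the train split only, scores the held-out
split, and aggregates each metric as mean +/- sd across folds.  Labels with
no positive (or no negative) example in a fold yield undefined per-label
metrics; those are excluded from the macro-averages rather than imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from sublocnet import metrics as metrics_mod
from sublocnet.datasets import AnnotatedProteinSet, cross_validation_folds
from sublocnet.encoding import EncodingConfig, PSSMatrix, normalize_pssm, one_hot_encode
from sublocnet.errors import TrainingDivergedError, ValidationError
from sublocnet.model import ModelConfig, SubcellularModel, build_model
from sublocnet.nn import Adam, sigmoid

__all__ = [
    "TrainingConfig",
    "FoldResult",
    "CrossValidationResult",
    "bce_l2_loss",
    "train_model",
    "encode_proteins",
    "run_cross_validation",
]

logger = logging.getLogger(__name__)

EPS = 1e-7


@dataclass
class TrainingConfig:
    """Optimization hyperparameters (none are stated by the architecture itself)."""

    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    l2_lambda: float = 1e-4
    seed: int = 0
    early_stop_patience: int | None = None
    threshold: float = 0.5  # binarization for F1 / MCC only
    init_output_bias: bool = True  # start output biases at the label base-rate logits

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if not 0 < self.threshold < 1:
            raise ValidationError("threshold must be in (0, 1)")
        if self.optimizer != "adam":
            raise ValidationError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class FoldResult:
    """Held-out evaluation of one cross-validation fold."""

    fold_index: int
    report: metrics_mod.EvaluationReport
    history: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fold_index": self.fold_index,
            "report": json.loads(self.report.to_json()),
            "history": self.history,
        }


@dataclass
class CrossValidationResult:
    folds: list[FoldResult]
    aggregate: dict[str, dict[str, float | None]]  # metric -> {mean, sd}

    def to_json(self) -> str:
        return json.dumps(
            {"folds": [f.to_dict() for f in self.folds], "aggregate": self.aggregate},
            indent=2,
        )


def bce_l2_loss(
    y: np.ndarray,
    y_hat: np.ndarray,
    kernels: Sequence[np.ndarray] = (),
    lam: float = 0.0,
) -> float:
    """Mean binary cross-entropy over all label terms plus lam * sum of squared kernels."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValidationError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("targets must be binary")
    p = np.clip(y_hat, EPS, 1.0 - EPS)
    bce = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    penalty = lam * sum(float(np.sum(np.square(k))) for k in kernels)
    return float(bce + penalty)


def _epoch_order(rng: np.random.Generator, n: int, batch_size: int):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_model(
    model: SubcellularModel,
    onehot: np.ndarray | None,
    pssm: np.ndarray | None,
    y: np.ndarray,
    config: TrainingConfig,
    epoch_callback=None,
) -> tuple[SubcellularModel, list[float]]:
    """Train in place with mini-batch Adam; returns (model, per-epoch mean loss).

    Deterministic for a fixed ``config.seed``.  Raises
    :class:`TrainingDivergedError` naming the epoch if the loss goes
    NaN/Inf.  ``early_stop_patience`` stops after that many epochs without
    improvement of the training loss.  ``epoch_callback(epoch_index, model)``
    runs after every epoch; returning True stops training (used e.g. to
    monitor a held-out metric).
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    if n < 1:
        raise ValidationError("need at least one training example")
    for name, arr in (("onehot", onehot), ("pssm", pssm)):
        if arr is not None and arr.shape[0] != n:
            raise ValidationError(f"{name} batch size {arr.shape[0]} != labels {n}")
    if config.init_output_bias:
        # calibrating the output biases to the training base rates up front
        # saves the optimizer the long flat phase of learning them
        base = np.clip(y.mean(axis=0), 1.0 / (2 * n + 2), 1.0 - 1.0 / (2 * n + 2))
        model.head[-1].b.value[...] = np.log(base / (1.0 - base))
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    lam = config.l2_lambda
    kernel_params = model.conv_kernel_params()
    history: list[float] = []
    best = np.inf
    since_best = 0
    for epoch in range(config.epochs):
        epoch_losses = []
        for idx in _epoch_order(rng, n, config.batch_size):
            xb = onehot[idx] if onehot is not None else None
            pb = pssm[idx] if pssm is not None else None
            yb = y[idx]
            logits = model.forward(xb, pb)
            probs = sigmoid(logits)
            loss = bce_l2_loss(yb, probs, [p.value for p in kernel_params], lam)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"loss diverged at epoch {epoch + 1}")
            opt.zero_grad()
            # d(mean BCE)/dlogits for sigmoid outputs; clipping region has zero grad
            p_clip = np.clip(probs, EPS, 1.0 - EPS)
            dlogits = (p_clip - yb) / yb.size
            model.backward(dlogits)
            for kp in kernel_params:
                kp.grad += 2.0 * lam * kp.value
            opt.step()
            epoch_losses.append(loss)
        mean_loss = float(np.mean(epoch_losses))
        history.append(mean_loss)
        logger.info("epoch %d/%d: loss %.6f", epoch + 1, config.epochs, mean_loss)
        if epoch_callback is not None and epoch_callback(epoch, model):
            break
        if mean_loss < best - 1e-9:
            best = mean_loss
            since_best = 0
        else:
            since_best += 1
            if config.early_stop_patience and since_best >= config.early_stop_patience:
                logger.info("early stop at epoch %d", epoch + 1)
                break
    return model, history


def encode_proteins(
    data: AnnotatedProteinSet,
    pssms: Mapping[str, np.ndarray | PSSMatrix] | None,
    encoding: EncodingConfig,
    need_pssm: bool,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Stack per-protein encodings into batch arrays (onehot, pssm-or-None, labels)."""
    oh = np.stack([one_hot_encode(r.sequence, encoding).values for r in data.records])
    ps = None
    if need_pssm:
        if pssms is None:
            raise ValidationError("PSSM store required for this variant")
        mats = []
        for r in data.records:
            if r.id not in pssms:
                raise ValidationError(f"missing PSSM for protein {r.id!r}")
            entry = pssms[r.id]
            if isinstance(entry, PSSMatrix):
                if entry.values.shape[0] != encoding.l_max:
                    raise ValidationError(
                        f"PSSM for {r.id!r} has {entry.values.shape[0]} rows, "
                        f"expected l_max={encoding.l_max}"
                    )
                mats.append(entry.values)
            else:
                mats.append(normalize_pssm(entry, encoding).values)
        ps = np.stack(mats)
    return oh, ps, data.label_matrix().astype(np.float64)


def _aggregate(folds: list[FoldResult]) -> dict[str, dict[str, float | None]]:
    keys = ["macro_f1", "macro_mcc", "macro_auc", "ranking_loss", "coverage", "average_precision"]
    out: dict[str, dict[str, float | None]] = {}
    for key in keys:
        values = [getattr(f.report, key) for f in folds]
        defined = [v for v in values if v is not None]
        if defined:
            out[key] = {
                "mean": float(np.mean(defined)),
                "sd": float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0,
            }
        else:
            out[key] = {"mean": None, "sd": None}
    return out


def run_cross_validation(
    data: AnnotatedProteinSet,
    pssms: Mapping[str, np.ndarray | PSSMatrix] | None,
    model_config: ModelConfig,
    train_config: TrainingConfig,
    k: int,
    encoding: EncodingConfig | None = None,
) -> CrossValidationResult:
    """k-fold cross-validation of one variant; per-fold held-out metrics + aggregate."""
    if model_config.n_labels != len(data.vocabulary):
        raise ValidationError(
            f"model n_labels {model_config.n_labels} != vocabulary size {len(data.vocabulary)}"
        )
    encoding = encoding or EncodingConfig(l_max=model_config.l_max)
    if encoding.l_max != model_config.l_max:
        raise ValidationError(
            f"encoding l_max {encoding.l_max} != model l_max {model_config.l_max}"
        )
    folds = cross_validation_folds(data, k, seed=train_config.seed)
    results: list[FoldResult] = []
    for fold_index, (train_ids, test_ids) in enumerate(folds):
        train_set = data.subset(train_ids)
        test_set = data.subset(test_ids)
        oh_tr, ps_tr, y_tr = encode_proteins(train_set, pssms, encoding, model_config.uses_pssm)
        oh_te, ps_te, y_te = encode_proteins(test_set, pssms, encoding, model_config.uses_pssm)
        model = build_model(
            model_config, seed=train_config.seed + fold_index, vocabulary=data.vocabulary.names
        )
        fold_cfg = TrainingConfig(**{**asdict(train_config), "seed": train_config.seed + fold_index})
        model, history = train_model(
            model,
            oh_tr if model_config.uses_blstm else None,
            ps_tr,
            y_tr,
            fold_cfg,
        )
        scores = model.predict_batch(oh_te if model_config.uses_blstm else None, ps_te)
        report = metrics_mod.evaluate_all(y_te.astype(int), scores, train_config.threshold)
        undefined = [
            j for j, d in enumerate(report.per_label) if any(v is None for v in d.values())
        ]
        if undefined:
            logger.warning(
                "fold %d: labels %s have undefined metrics (degenerate column); "
                "excluded from macro-averages",
                fold_index,
                undefined,
            )
        results.append(FoldResult(fold_index=fold_index, report=report, history=history))
    return CrossValidationResult(folds=results, aggregate=_aggregate(results))
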