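"""The four localization network variants and their forward/backward passes.

Architecture (matching the published ablation):

* ``blstm`` — a stack of bidirectional LSTM layers encodes the one-hot
  sequence matrix; the two directions' final hidden states feed the dense
  sigmoid head directly.
* ``blstm_conv1`` — the per-position BLSTM state matrix (l_max x 256 at the
  default width) is treated as a single-channel image and passed through
  ConvNet1: four convolution layers (kernels 256/128/64/32, sizes 4x3 then
  3x3) with ReLU and a max-pool after each of the first three, then
  flattened into the dense head.
* ``conv2`` — ConvNet2, an identical 7-layer conv/pool stack, reads the
  l_max x 43 PSSM directly (no sequence branch).
* ``full`` — both branches run; their flattened feature vectors are
  concatenated before the dense head.

The head emits one logit per location; a sigmoid turns each into an
independent probability, so scores do not sum to 1 (multi-label contract).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from sublocnet import nn
from sublocnet.encoding import OneHotMatrix, PSSMatrix
from sublocnet.errors import GeometryError, ValidationError

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "SubcellularModel",
    "relu",
    "sigmoid",
    "convolve2d",
    "build_model",
    "blstm_encode",
    "predict_scores",
    "save_model",
    "load_model",
]

VARIANTS = ("blstm", "blstm_conv1", "conv2", "full")

PSSM_WIDTH = 43
ONEHOT_WIDTH = 23


def relu(x):
    """Rectified linear activation max(0, x)."""
    return np.maximum(0, x)


def sigmoid(x):
    """Logistic function e^x / (e^x + 1), stable for large |x|."""
    return nn.sigmoid(x)


def convolve2d(input: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid 2-D cross-correlation: C[i,j] = sum_{m,n} w[m,n] X[i+m, j+n].

    No kernel flip — the index form is exactly as written, which is what
    convolution layers actually compute.
    """
    X = np.asarray(input, dtype=np.float64)
    w = np.asarray(kernel, dtype=np.float64)
    if X.ndim != 2 or w.ndim != 2:
        raise ValidationError("convolve2d expects 2-D input and kernel")
    if w.shape[0] > X.shape[0] or w.shape[1] > X.shape[1]:
        raise ValidationError(f"kernel {w.shape} larger than input {X.shape}")
    patches = sliding_window_view(X, w.shape)
    return np.tensordot(patches, w, axes=([2, 3], [0, 1]))


@dataclass
class ModelConfig:
    """Architecture specification for one model variant.

    Defaults follow the published architecture: 2 bidirectional LSTM layers
    whose concatenated directional width is 256 (128 per direction), four
    convolution layers with 256/128/64/32 kernels of sizes 4x3, 3x3, 3x3,
    3x3, and 2x2 max-pooling after each of the first three convolutions.
    ``desk_scale`` returns a narrow configuration of the same wiring for
    CPU-scale experiments.
    """

    variant: str
    n_labels: int
    l_max: int = 1000
    lstm_layers: int = 2
    lstm_hidden_per_direction: int = 128
    conv_kernel_counts: tuple[int, ...] = (256, 128, 64, 32)
    conv_kernel_sizes: tuple[tuple[int, int], ...] = ((4, 3), (3, 3), (3, 3), (3, 3))
    pool_size: tuple[int, int] = (2, 2)
    dense_hidden: int = 0  # 0 = single dense layer straight to the labels
    l2_lambda: float = 1e-4
    mask_padding: bool = False
    dtype: str = "float32"  # compute precision; float64 for gradient checking

    def __post_init__(self) -> None:
        if self.dtype not in ("float32", "float64"):
            raise ValidationError(f"dtype must be float32 or float64, got {self.dtype!r}")
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}, expected one of {VARIANTS}")
        if self.n_labels < 2:
            raise ValidationError(f"n_labels must be >= 2, got {self.n_labels}")
        if len(self.conv_kernel_counts) != 4 or len(self.conv_kernel_sizes) != 4:
            raise ValidationError("conv kernel counts/sizes must list exactly 4 layers")
        if self.l2_lambda < 0:
            raise ValidationError("l2_lambda must be >= 0")
        if self.lstm_layers < 1 or self.lstm_hidden_per_direction < 1:
            raise ValidationError("LSTM stack needs >= 1 layer and >= 1 hidden unit")
        self.conv_kernel_sizes = tuple(tuple(s) for s in self.conv_kernel_sizes)
        self.conv_kernel_counts = tuple(self.conv_kernel_counts)
        self.pool_size = tuple(self.pool_size)

    @property
    def uses_blstm(self) -> bool:
        return self.variant in ("blstm", "blstm_conv1", "full")

    @property
    def uses_pssm(self) -> bool:
        return self.variant in ("conv2", "full")

    @classmethod
    def desk_scale(cls, variant: str, n_labels: int, l_max: int = 400) -> "ModelConfig":
        """Narrow same-wiring configuration sized for a single CPU.

        One BLSTM layer of 32 units per direction, 8 kernels per conv layer,
        and 4x2 pooling — the aggressive height pooling makes the flattened
        features nearly position-invariant, which suits signals at unknown
        sequence positions, and the 64-wide state matrix gives the first
        convolution enough reservoir dimensions to separate motif signatures.
        """
        return cls(
            variant=variant,
            n_labels=n_labels,
            l_max=l_max,
            lstm_layers=1,
            lstm_hidden_per_direction=32,
            conv_kernel_counts=(8, 8, 8, 8),
            conv_kernel_sizes=((4, 3), (3, 3), (3, 3), (3, 3)),
            pool_size=(4, 2),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def _conv_stack_geometry(config: ModelConfig, h: int, w: int) -> tuple[int, int, int]:
    """Walk the conv/pool stack; return final (channels, h, w) or raise."""
    for layer_idx in range(4):
        kh, kw = config.conv_kernel_sizes[layer_idx]
        h, w = h - kh + 1, w - kw + 1
        if h < 1 or w < 1:
            raise GeometryError(
                f"conv layer {layer_idx + 1} (kernel {kh}x{kw}) collapses spatial "
                f"size to {h}x{w}"
            )
        if layer_idx < 3:
            h, w = h // config.pool_size[0], w // config.pool_size[1]
            if h < 1 or w < 1:
                raise GeometryError(
                    f"maxpool after conv layer {layer_idx + 1} collapses spatial "
                    f"size to {h}x{w}"
                )
    return config.conv_kernel_counts[-1], h, w


def _build_conv_stack(
    config: ModelConfig, rng: np.random.Generator, dtype, first_needs_grad: bool
) -> list:
    layers: list = []
    in_ch = 1
    for layer_idx in range(4):
        layers.append(
            nn.Conv2D(in_ch, config.conv_kernel_counts[layer_idx],
                      config.conv_kernel_sizes[layer_idx], rng, dtype,
                      needs_input_grad=first_needs_grad or layer_idx > 0)
        )
        layers.append(nn.ReLU())
        if layer_idx < 3:
            layers.append(nn.MaxPool2D(config.pool_size))
        in_ch = config.conv_kernel_counts[layer_idx]
    layers.append(nn.Flatten())
    return layers


class SubcellularModel:
    """A wired (possibly untrained) network for one variant.

    Use :func:`build_model` to construct; :func:`predict_scores` /
    :meth:`predict_batch` to score proteins.  ``forward_backward`` is the
    training entry point and accumulates gradients on every parameter.
    """

    def __init__(self, config: ModelConfig, seed: int, vocabulary: tuple[str, ...] | None = None):
        self.config = config
        self.seed = seed
        self.vocabulary = tuple(vocabulary) if vocabulary is not None else None
        if self.vocabulary is not None and len(self.vocabulary) != config.n_labels:
            raise ValidationError(
                f"vocabulary size {len(self.vocabulary)} != n_labels {config.n_labels}"
            )
        rng = np.random.default_rng(seed)
        self.dtype = np.dtype(config.dtype).type

        self.blstm_stack: list[nn.BiLSTM] = []
        self.conv1_stack: list = []
        self.conv2_stack: list = []
        head_in = 0

        if config.uses_blstm:
            in_dim = ONEHOT_WIDTH
            for _ in range(config.lstm_layers):
                self.blstm_stack.append(
                    nn.BiLSTM(in_dim, config.lstm_hidden_per_direction, rng, self.dtype)
                )
                in_dim = 2 * config.lstm_hidden_per_direction
        enc_width = 2 * config.lstm_hidden_per_direction

        if config.variant == "blstm":
            head_in = enc_width  # concatenated final states of the two directions
        if config.variant in ("blstm_conv1", "full"):
            c, h, w = _conv_stack_geometry(config, config.l_max, enc_width)
            self.conv1_stack = _build_conv_stack(config, rng, self.dtype, first_needs_grad=True)
            head_in += c * h * w
        if config.uses_pssm:
            c, h, w = _conv_stack_geometry(config, config.l_max, PSSM_WIDTH)
            self.conv2_stack = _build_conv_stack(config, rng, self.dtype, first_needs_grad=False)
            head_in += c * h * w

        self.head: list = []
        if config.dense_hidden > 0:
            self.head.append(nn.Dense(head_in, config.dense_hidden, rng, self.dtype))
            self.head.append(nn.ReLU())
            head_in = config.dense_hidden
        self.head.append(nn.Dense(head_in, config.n_labels, rng, self.dtype))

    # ---- parameter access -------------------------------------------------
    def named_params(self) -> list[tuple[str, nn.Param]]:
        out = []
        for i, layer in enumerate(self.blstm_stack):
            for j, p in enumerate(layer.params):
                out.append((f"blstm.{i}.{j}", p))
        for stack_name, stack in (("conv1", self.conv1_stack), ("conv2", self.conv2_stack)):
            for i, layer in enumerate(stack):
                for j, p in enumerate(layer.params):
                    out.append((f"{stack_name}.{i}.{j}", p))
        for i, layer in enumerate(self.head):
            for j, p in enumerate(layer.params):
                out.append((f"head.{i}.{j}", p))
        return out

    @property
    def params(self) -> list[nn.Param]:
        return [p for _, p in self.named_params()]

    def conv_kernels(self) -> list[np.ndarray]:
        """Convolution kernel tensors — the only weights the L2 penalty touches."""
        kernels = []
        for stack in (self.conv1_stack, self.conv2_stack):
            for layer in stack:
                if isinstance(layer, nn.Conv2D):
                    kernels.append(layer.W.value)
        return kernels

    def conv_kernel_params(self) -> list[nn.Param]:
        out = []
        for stack in (self.conv1_stack, self.conv2_stack):
            for layer in stack:
                if isinstance(layer, nn.Conv2D):
                    out.append(layer.W)
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    # ---- forward / backward ----------------------------------------------
    def _encode(self, onehot: np.ndarray, lengths: np.ndarray | None) -> np.ndarray:
        h = onehot
        for layer in self.blstm_stack:
            h = layer.forward(h)
        if self.config.mask_padding and lengths is not None:
            pos = np.arange(h.shape[1])[None, :, None]
            self._enc_mask = pos < lengths[:, None, None]
            h = np.where(self._enc_mask, h, 0.0)
        else:
            self._enc_mask = None
        return h

    def _run_stack(self, stack: list, x: np.ndarray) -> np.ndarray:
        for layer in stack:
            x = layer.forward(x)
        return x

    def _back_stack(self, stack: list, d: np.ndarray) -> np.ndarray:
        for layer in reversed(stack):
            d = layer.backward(d)
        return d

    def forward(self, onehot: np.ndarray | None, pssm: np.ndarray | None) -> np.ndarray:
        """Batch logits. onehot: (N, l_max, 23); pssm: (N, l_max, 43)."""
        cfg = self.config
        feats = []
        self._split = []
        if cfg.uses_blstm:
            if onehot is None:
                raise ValidationError("one-hot input required for this variant")
            if onehot.shape[1] != cfg.l_max or onehot.shape[2] != ONEHOT_WIDTH:
                raise ValidationError(
                    f"one-hot batch shape {onehot.shape[1:]} != ({cfg.l_max}, {ONEHOT_WIDTH})"
                )
            onehot = np.asarray(onehot, dtype=self.dtype)
            lengths = (onehot.sum(axis=2) > 0).sum(axis=1)
            enc = self._encode(onehot, lengths)
            self._enc_shape = enc.shape
            if cfg.variant == "blstm":
                hdim = cfg.lstm_hidden_per_direction
                final = np.concatenate([enc[:, -1, :hdim], enc[:, 0, hdim:]], axis=1)
                feats.append(final)
                self._split.append(final.shape[1])
            else:
                flat = self._run_stack(self.conv1_stack, enc[:, :, :, None])
                feats.append(flat)
                self._split.append(flat.shape[1])
        if cfg.uses_pssm:
            if pssm is None:
                raise ValidationError(f"variant {cfg.variant!r} requires a PSSM input")
            if pssm.shape[1] != cfg.l_max or pssm.shape[2] != PSSM_WIDTH:
                raise ValidationError(
                    f"PSSM batch shape {pssm.shape[1:]} != ({cfg.l_max}, {PSSM_WIDTH})"
                )
            pssm = np.asarray(pssm, dtype=self.dtype)
            flat = self._run_stack(self.conv2_stack, pssm[:, :, :, None])
            feats.append(flat)
            self._split.append(flat.shape[1])
        x = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        return self._run_stack(self.head, x)

    def backward(self, dlogits: np.ndarray) -> None:
        cfg = self.config
        dlogits = np.asarray(dlogits, dtype=self.dtype)
        d = self._back_stack(self.head, dlogits)
        chunks = np.split(d, np.cumsum(self._split)[:-1], axis=1)
        idx = 0
        if cfg.uses_blstm:
            dchunk = chunks[idx]; idx += 1
            if cfg.variant == "blstm":
                hdim = cfg.lstm_hidden_per_direction
                denc = np.zeros(self._enc_shape, dtype=self.dtype)
                denc[:, -1, :hdim] += dchunk[:, :hdim]
                denc[:, 0, hdim:] += dchunk[:, hdim:]
            else:
                dimg = self._back_stack(self.conv1_stack, dchunk)
                denc = dimg[:, :, :, 0]
            if self._enc_mask is not None:
                denc = np.where(self._enc_mask, denc, 0.0)
            dd = denc
            for layer in reversed(self.blstm_stack):
                dd = layer.backward(dd)
        if cfg.uses_pssm:
            self._back_stack(self.conv2_stack, chunks[idx])

    # ---- prediction -------------------------------------------------------
    def predict_batch(
        self,
        onehot: np.ndarray | None,
        pssm: np.ndarray | None = None,
        chunk_size: int = 64,
    ) -> np.ndarray:
        """Scores for a batch, processed in chunks to bound peak memory."""
        n = onehot.shape[0] if onehot is not None else pssm.shape[0]
        outputs = []
        for start in range(0, n, chunk_size):
            oh = onehot[start : start + chunk_size] if onehot is not None else None
            ps = pssm[start : start + chunk_size] if pssm is not None else None
            logits = self.forward(oh, ps)
            outputs.append(sigmoid(logits))
        scores = np.concatenate(outputs, axis=0)
        # sigmoid saturates to exactly 0/1 in float64 for huge logits; keep open interval
        return np.clip(scores, 1e-12, 1.0 - 1e-12)


def build_model(
    config: ModelConfig, seed: int, vocabulary: tuple[str, ...] | None = None
) -> SubcellularModel:
    """Construct a model with deterministic seed-controlled initialization."""
    return SubcellularModel(config, seed, vocabulary)


def blstm_encode(model: SubcellularModel, onehot: OneHotMatrix) -> np.ndarray:
    """Run only the BLSTM encoder on one protein: l_max x (2 * hidden) state matrix.

    Every entry lies strictly in (-1, 1): each hidden value is a sigmoid gate
    times a tanh of the cell state.
    """
    if not model.config.uses_blstm:
        raise ValidationError(f"variant {model.config.variant!r} has no BLSTM branch")
    x = onehot.values[None, :, :]
    if x.shape[1] != model.config.l_max:
        raise ValidationError(
            f"one-hot rows {x.shape[1]} != configured l_max {model.config.l_max}"
        )
    h = x
    for layer in model.blstm_stack:
        h = layer.forward(h)
    return h[0].copy()  # detach from the layer's reusable output buffer


def predict_scores(
    model: SubcellularModel,
    onehot: OneHotMatrix | None,
    pssm: PSSMatrix | None = None,
) -> np.ndarray:
    """Per-location probabilities for one protein, each independently in (0, 1)."""
    cfg = model.config
    oh = onehot.values[None] if onehot is not None else None
    ps = pssm.values[None] if pssm is not None else None
    if cfg.uses_pssm and ps is None:
        raise ValidationError(f"variant {cfg.variant!r} requires a PSSM input")
    return model.predict_batch(oh, ps)[0]


def save_model(model: SubcellularModel, path: str | Path) -> None:
    """Save parameters + config + vocabulary into a single .npz checkpoint."""
    arrays = {name: p.value for name, p in model.named_params()}
    meta = {
        "config": model.config.to_dict(),
        "seed": model.seed,
        "vocabulary": list(model.vocabulary) if model.vocabulary else None,
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> SubcellularModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig.from_dict(meta["config"])
        vocab = tuple(meta["vocabulary"]) if meta["vocabulary"] else None
        model = SubcellularModel(config, meta["seed"], vocab)
        for name, p in model.named_params():
            stored = data[name]
            if stored.shape != p.value.shape:
                raise ValidationError(
                    f"checkpoint mismatch at {name}: {stored.shape} vs {p.value.shape}"
                )
            p.value[...] = stored
    return model
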