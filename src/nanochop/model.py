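"""Per-base adapter classifier: tokenization, network, loss, training, metrics.

The classifier labels every nucleotide of a read as adapter (1) or non-adapter
(0). Architecture, front to back:

* single-nucleotide tokenization over {A, C, G, T, N} plus PAD, with a hard
  input-length cap (default 32,770 nt; longer reads are excluded);
* a learned embedding per token;
* a **quality block**: per-read z-scored Phred qualities passed through two
  ReLU MLPs with a residual connection, projected to the embedding width and
  added to the sequence embeddings (project-then-add), so zeroing the quality
  input leaves a valid sequence-only path;
* an attention-free backbone of gated, dilated 1-D convolutions with residual
  connections (WaveNet-style ``tanh * sigmoid`` gating), giving a long
  receptive field at per-position resolution;
* a two-layer classification head with a softmax over the two classes; a read
  position is called adapter when ``P(adapter) > 0.5``.

The loss is per-read mean binary cross-entropy over unpadded tokens, then an
unweighted mean over the reads of the mini-batch. Optimization is Adam. The
network and its backward pass are implemented directly in numpy; training is
deterministic given the configured seeds (single-threaded numerics).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .io_fastq import ReadRecord
from .simulate import LabeledRead

logger = logging.getLogger(__name__)

PAD_ID = 0
VOCAB = {"PAD": PAD_ID, "A": 1, "C": 2, "G": 3, "T": 4, "N": 5}
VOCAB_SIZE = 6
MAX_INPUT_LENGTH = 32770

_CHAR_TO_ID = np.full(128, -1, dtype=np.int8)
for _base, _tid in VOCAB.items():
    if len(_base) == 1:
        _CHAR_TO_ID[ord(_base)] = _tid

_EPS = 1e-7  # probability clipping in log terms


class ReadTooLongError(ValueError):
    """Raised when a read exceeds the model's maximum input length."""


# ---------------------------------------------------------------------------
# Tokenization and quality normalization
# ---------------------------------------------------------------------------


@dataclass
class TokenizedRead:
    token_ids: np.ndarray  # int64, one id per base, no padding
    length: int


def tokenize(record: ReadRecord, max_input_length: int = MAX_INPUT_LENGTH) -> TokenizedRead:
    """Map a read to single-nucleotide token ids (bijective per position).

    Raises :class:`ReadTooLongError` for reads longer than ``max_input_length``
    and ``ValueError`` for characters outside {A, C, G, T, N}.
    """
    n = len(record.sequence)
    if n > max_input_length:
        raise ReadTooLongError(
            f"read {record.read_id!r} has {n} nt > max input length {max_input_length}"
        )
    raw = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    ids = _CHAR_TO_ID[raw].astype(np.int64)
    if n and ids.min() < 1:
        bad = sorted(set(record.sequence) - set("ACGTN"))
        raise ValueError(f"read {record.read_id!r}: untokenizable characters {bad}")
    return TokenizedRead(ids, n)


def tokenize_reads(
    records: Sequence[ReadRecord], max_input_length: int = MAX_INPUT_LENGTH
) -> Tuple[List[TokenizedRead], List[int]]:
    """Tokenize many reads, excluding over-long ones with a logged warning.

    Returns the tokenized reads plus the indices (into ``records``) that were
    kept, so callers can align labels/qualities with the survivors.
    """
    kept: List[TokenizedRead] = []
    kept_idx: List[int] = []
    for i, rec in enumerate(records):
        try:
            kept.append(tokenize(rec, max_input_length))
            kept_idx.append(i)
        except ReadTooLongError as exc:
            logger.warning("excluding read: %s", exc)
    return kept, kept_idx


def normalize_qualities(qualities: Sequence[int]) -> np.ndarray:
    """Z-score standardize Phred qualities per read (population sd).

    Constant input maps to all zeros.
    """
    q = np.asarray(qualities, dtype=np.float64)
    if q.size == 0:
        raise ValueError("cannot normalize an empty quality list")
    sd = q.std()
    if sd == 0.0:
        return np.zeros(q.size, dtype=np.float32)
    return ((q - q.mean()) / sd).astype(np.float32)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The defaults mirror the reference scale (256-dim features). For CPU-scale
    training use :meth:`small`, which keeps the same architecture at a fraction
    of the width. ``dilation_base`` sets layer ``l``'s dilation to ``base**l``,
    so the receptive field grows geometrically with depth.
    """

    embed_dim: int = 256
    quality_hidden_dim: int = 256
    backbone_layers: int = 4
    kernel_width: int = 5
    dilation_base: int = 4
    max_input_length: int = MAX_INPUT_LENGTH
    use_quality: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("embed_dim", "quality_hidden_dim", "backbone_layers", "kernel_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kernel_width % 2 == 0:
            raise ValueError("kernel_width must be odd")

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Desk-scale preset: same topology, 24-dim features (~20k parameters)."""
        params = dict(
            embed_dim=24,
            quality_hidden_dim=24,
            backbone_layers=4,
            kernel_width=5,
            dilation_base=4,
        )
        params.update(overrides)
        return cls(**params)

    def dilations(self) -> List[int]:
        return [self.dilation_base**l for l in range(self.backbone_layers)]

    def receptive_field(self) -> int:
        half = (self.kernel_width - 1) // 2
        return 1 + 2 * half * sum(self.dilations())


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference recipe)."""

    batch_size: int = 64
    beta1: float = 0.9
    beta2: float = 0.999
    initial_lr: float = 2e-5
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    val_interval_steps: int = 20000
    max_epochs: int = 60
    early_stop_patience: int = 10
    early_stopping_metric: str = "f1"
    max_val_reads: Optional[int] = None
    grad_clip: float = 5.0
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("betas must be in (0, 1)")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Short-schedule recipe for training the small model from scratch on CPU."""
        params = dict(
            initial_lr=1e-2,
            batch_size=32,
            val_interval_steps=250,
            max_epochs=2,
            plateau_patience=3,
            early_stop_patience=6,
            max_val_reads=500,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class PredictionTrack:
    """Per-base class probabilities and thresholded labels for one read.

    ``probabilities`` has shape (L, 2) with columns (p_adapter, p_nonadapter);
    every row sums to 1. ``labels[i] == 1`` iff ``p_adapter > 0.5``.
    """

    probabilities: np.ndarray
    labels: np.ndarray

    @property
    def p_adapter(self) -> np.ndarray:
        return self.probabilities[:, 0]


@dataclass
class EvalReport:
    """Pooled per-base confusion counts and derived metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    accuracy: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "EvalReport":
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        total = tp + fp + fn + tn
        accuracy = (tp + tn) / total if total else 0.0
        return cls(tp, fp, fn, tn, precision, recall, f1, accuracy)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """Unfold (B, T, D) into (B*T, k*D) dilated windows with zero padding."""
    B, T, D = x.shape
    half = (k - 1) // 2
    zp = half * dilation
    xp = np.zeros((B, T + 2 * zp, D), dtype=x.dtype)
    xp[:, zp : zp + T] = x
    cols = np.empty((B, T, k, D), dtype=x.dtype)
    for j in range(k):
        cols[:, :, j, :] = xp[:, j * dilation : j * dilation + T]
    return cols.reshape(B * T, k * D)


def _conv1d(
    cols: np.ndarray, W: np.ndarray, b: np.ndarray, shape: Tuple[int, int]
) -> np.ndarray:
    """Dilated conv as a single GEMM over unfolded windows.

    ``cols`` from :func:`_im2col`; ``W`` has shape (k*D, out); returns
    (B, T, out).
    """
    B, T = shape
    return (cols @ W + b).reshape(B, T, W.shape[1])


def _conv1d_backward(
    cols: np.ndarray,
    dY: np.ndarray,
    W: np.ndarray,
    k: int,
    dilation: int,
    shape: Tuple[int, int, int],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the im2col conv: input, weight and bias grads."""
    B, T, D = shape
    dY_flat = dY.reshape(B * T, W.shape[1])
    dW = cols.T @ dY_flat
    db = dY_flat.sum(axis=0)
    dcols = (dY_flat @ W.T).reshape(B, T, k, D)
    half = (k - 1) // 2
    zp = half * dilation
    dXp = np.zeros((B, T + 2 * zp, D), dtype=dY.dtype)
    for j in range(k):
        dXp[:, j * dilation : j * dilation + T] += dcols[:, :, j, :]
    return dXp[:, zp : zp + T], dW, db


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # overflow-safe via tanh: sigma(x) = (1 + tanh(x/2)) / 2
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class AdapterClassifier:
    """Quality-aware per-base two-class classifier (numpy implementation)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: Dict[str, np.ndarray] = {}
        self._init_params()

    # -- parameters ---------------------------------------------------------

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        D, H, k = cfg.embed_dim, cfg.quality_hidden_dim, cfg.kernel_width

        def normal(shape, fan_in):
            scale = np.sqrt(2.0 / fan_in)
            return (rng.normal(0.0, scale, size=shape)).astype(np.float32)

        p = self.params
        p["emb"] = normal((VOCAB_SIZE, D), D)
        if cfg.use_quality:
            p["qw1"] = normal((1, H), 1)
            p["qb1"] = np.zeros(H, np.float32)
            p["qw2"] = normal((H, D), H)
            p["qb2"] = np.zeros(D, np.float32)
            p["qw3"] = normal((D, H), D)
            p["qb3"] = np.zeros(H, np.float32)
            p["qw4"] = normal((H, D), H)
            p["qb4"] = np.zeros(D, np.float32)
        for l in range(cfg.backbone_layers):
            # filter and gate convolutions fused: columns [:D] filter, [D:] gate
            p[f"c{l}W"] = normal((k * D, 2 * D), k * D)
            p[f"c{l}b"] = np.zeros(2 * D, np.float32)
        p["hw1"] = normal((D, D), D)
        p["hb1"] = np.zeros(D, np.float32)
        p["hw2"] = normal((D, 2), D)
        p["hb2"] = np.zeros(2, np.float32)

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward ------------------------------------------------------------

    def _forward_batch(
        self,
        tokens: np.ndarray,
        qz: np.ndarray,
        mask: np.ndarray,
        want_cache: bool = False,
    ):
        """Forward pass over a padded batch.

        tokens: (B, T) int; qz: (B, T) z-scored qualities (0 at PAD);
        mask: (B, T) float32 {0, 1}. Returns class probabilities (B, T, 2)
        with column order (adapter, nonadapter), plus a cache when training.
        """
        cfg = self.config
        p = self.params
        m = mask[..., None]
        cache: Dict[str, object] = {"tokens": tokens, "mask": m}

        x = p["emb"][tokens]
        if cfg.use_quality:
            q = (qz * mask)[..., None].astype(np.float32)
            h1a = q @ p["qw1"] + p["qb1"]
            h1 = np.maximum(h1a, 0.0)
            u = h1 @ p["qw2"] + p["qb2"]
            h2a = u @ p["qw3"] + p["qb3"]
            h2 = np.maximum(h2a, 0.0)
            v = u + h2 @ p["qw4"] + p["qb4"]
            x = (x + v) * m
            if want_cache:
                cache.update(q=q, h1=h1, u=u, h2=h2)
        else:
            x = x * m

        B, T = tokens.shape
        D = cfg.embed_dim
        k = cfg.kernel_width
        layer_cache = []
        for l, dil in enumerate(cfg.dilations()):
            cols = _im2col(x, k, dil)
            ag = _conv1d(cols, p[f"c{l}W"], p[f"c{l}b"], (B, T))
            ta = np.tanh(ag[..., :D])
            sg = _sigmoid(ag[..., D:])
            x_new = (x + ta * sg) * m
            if want_cache:
                layer_cache.append((cols, ta, sg, dil))
            x = x_new
        cache["layers"] = layer_cache

        h = np.maximum(x @ p["hw1"] + p["hb1"], 0.0)
        logits = h @ p["hw2"] + p["hb2"]
        zmax = logits.max(axis=-1, keepdims=True)
        ez = np.exp(logits - zmax)
        probs = ez / ez.sum(axis=-1, keepdims=True)
        if want_cache:
            cache.update(x_final=x, h=h, probs=probs)
            return probs, cache
        return probs, None

    def _backward_batch(self, cache: Dict[str, object], dlogits: np.ndarray):
        """Backprop of d(loss)/d(logits) through the network; returns grads."""
        cfg = self.config
        p = self.params
        grads: Dict[str, np.ndarray] = {}
        B, T, _ = dlogits.shape
        h = cache["h"]
        x = cache["x_final"]
        m = cache["mask"]

        dl = dlogits.reshape(B * T, 2)
        grads["hw2"] = cache["h"].reshape(B * T, -1).T @ dl
        grads["hb2"] = dl.sum(axis=0)
        dh = (dlogits @ p["hw2"].T) * (h > 0)
        dh_flat = dh.reshape(B * T, -1)
        grads["hw1"] = x.reshape(B * T, -1).T @ dh_flat
        grads["hb1"] = dh_flat.sum(axis=0)
        dx = dh @ p["hw1"].T

        D = cfg.embed_dim
        k = cfg.kernel_width
        for l in reversed(range(cfg.backbone_layers)):
            cols, ta, sg, dil = cache["layers"][l]
            dxm = dx * m
            da = (dxm * sg) * (1.0 - ta * ta)
            dg = (dxm * ta) * sg * (1.0 - sg)
            dag = np.concatenate([da, dg], axis=-1)
            dxc, dW, db = _conv1d_backward(
                cols, dag, p[f"c{l}W"], k, dil, (B, T, D)
            )
            grads[f"c{l}W"], grads[f"c{l}b"] = dW, db
            dx = dxm + dxc

        dxm = dx * m
        demb = np.zeros_like(p["emb"])
        np.add.at(
            demb, cache["tokens"].reshape(-1), dxm.reshape(-1, dxm.shape[-1])
        )
        grads["emb"] = demb

        if cfg.use_quality:
            q, h1, u, h2 = cache["q"], cache["h1"], cache["u"], cache["h2"]
            dv = dxm
            dv_flat = dv.reshape(B * T, -1)
            grads["qw4"] = h2.reshape(B * T, -1).T @ dv_flat
            grads["qb4"] = dv_flat.sum(axis=0)
            dh2 = (dv @ p["qw4"].T) * (h2 > 0)
            dh2_flat = dh2.reshape(B * T, -1)
            grads["qw3"] = u.reshape(B * T, -1).T @ dh2_flat
            grads["qb3"] = dh2_flat.sum(axis=0)
            du = dv + dh2 @ p["qw3"].T
            du_flat = du.reshape(B * T, -1)
            grads["qw2"] = h1.reshape(B * T, -1).T @ du_flat
            grads["qb2"] = du_flat.sum(axis=0)
            dh1 = (du @ p["qw2"].T) * (h1 > 0)
            dh1_flat = dh1.reshape(B * T, -1)
            grads["qw1"] = q.reshape(B * T, -1).T @ dh1_flat
            grads["qb1"] = dh1_flat.sum(axis=0)
        return grads

    # -- inference ----------------------------------------------------------

    def predict(
        self, records: Sequence[ReadRecord], batch_size: int = 64
    ) -> List[PredictionTrack]:
        """Per-base prediction tracks for a collection of reads (file order).

        Reads are batched by similar length internally; empty reads yield
        empty tracks. Over-long reads must be filtered by the caller (see
        :func:`tokenize_reads`).
        """
        tracks: List[Optional[PredictionTrack]] = [None] * len(records)
        items = []
        for i, rec in enumerate(records):
            tok = tokenize(rec, self.config.max_input_length)
            if tok.length == 0:
                tracks[i] = PredictionTrack(
                    np.zeros((0, 2), np.float32), np.zeros(0, np.uint8)
                )
                continue
            qz = normalize_qualities(rec.qualities)
            items.append((i, tok.token_ids, qz))
        items.sort(key=lambda it: len(it[1]))
        for start in range(0, len(items), batch_size):
            chunk = items[start : start + batch_size]
            T = max(len(it[1]) for it in chunk)
            B = len(chunk)
            tokens = np.zeros((B, T), dtype=np.int64)
            qz = np.zeros((B, T), dtype=np.float32)
            mask = np.zeros((B, T), dtype=np.float32)
            for b, (_, ids, q) in enumerate(chunk):
                L = len(ids)
                tokens[b, :L] = ids
                qz[b, :L] = q
                mask[b, :L] = 1.0
            probs, _ = self._forward_batch(tokens, qz, mask)
            for b, (i, ids, _) in enumerate(chunk):
                L = len(ids)
                pr = probs[b, :L].astype(np.float32)
                tracks[i] = PredictionTrack(pr, (pr[:, 0] > 0.5).astype(np.uint8))
        return tracks  # type: ignore[return-value]

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Self-describing checkpoint: config JSON plus weight arrays."""
        payload = {f"param_{k}": v for k, v in self.params.items()}
        payload["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "AdapterClassifier":
        with np.load(path) as data:
            cfg = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
            model = cls(cfg)
            for key in data.files:
                if key.startswith("param_"):
                    model.params[key[len("param_") :]] = data[key].astype(np.float32)
        return model


def forward(
    model: AdapterClassifier,
    tokens: TokenizedRead,
    qualities: Sequence[int],
) -> PredictionTrack:
    """Single-read forward pass: softmax class probabilities per position.

    ``qualities`` are raw Phred scores; they are z-scored per read internally.
    PAD positions never appear in the output.
    """
    if tokens.length != len(qualities):
        raise ValueError(
            f"token/quality length mismatch: {tokens.length} != {len(qualities)}"
        )
    if tokens.length == 0:
        return PredictionTrack(np.zeros((0, 2), np.float32), np.zeros(0, np.uint8))
    qz = normalize_qualities(qualities)[None, :]
    ids = tokens.token_ids[None, :]
    mask = np.ones_like(qz, dtype=np.float32)
    probs, _ = model._forward_batch(ids, qz, mask)
    pr = probs[0].astype(np.float32)
    return PredictionTrack(pr, (pr[:, 0] > 0.5).astype(np.uint8))


# ---------------------------------------------------------------------------
# Loss and metrics
# ---------------------------------------------------------------------------


def loss(
    probabilities: Sequence[np.ndarray],
    labels: Sequence[np.ndarray],
    eps: float = _EPS,
) -> float:
    """Mean binary cross-entropy: per-read token mean, then unweighted read mean.

    ``probabilities`` holds, per read, either the adapter-class probabilities
    (1-D) or an (L, 2) array whose first column is the adapter class. The read
    mean is over that read's own tokens, so the batch mean is NOT a pooled
    token mean: two reads with per-read losses 0.2 and 0.4 give 0.3 regardless
    of their lengths.
    """
    if len(probabilities) != len(labels):
        raise ValueError("probabilities and labels must have equal batch size")
    per_read = []
    for prob, y in zip(probabilities, labels):
        p = np.asarray(prob, dtype=np.float64)
        if p.ndim == 2:
            p = p[:, 0]
        y = np.asarray(y, dtype=np.float64)
        if p.shape != y.shape:
            raise ValueError("per-read probability/label length mismatch")
        p = np.clip(p, eps, 1.0 - eps)
        per_read.append(float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean()))
    return float(np.mean(per_read))


def evaluate(
    predictions: Sequence[Union[np.ndarray, PredictionTrack]],
    truths: Sequence[np.ndarray],
) -> EvalReport:
    """Pooled per-base confusion counts over all reads, with derived metrics.

    Zero-denominator metrics are defined as 0.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    tp = fp = fn = tn = 0
    for pred, true in zip(predictions, truths):
        if isinstance(pred, PredictionTrack):
            pred = pred.labels
        pred = np.asarray(pred).astype(bool)
        true = np.asarray(true).astype(bool)
        if pred.shape != true.shape:
            raise ValueError("prediction/truth length mismatch")
        tp += int(np.sum(pred & true))
        fp += int(np.sum(pred & ~true))
        fn += int(np.sum(~pred & true))
        tn += int(np.sum(~pred & ~true))
    return EvalReport.from_counts(tp, fp, fn, tn)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _prepare(reads: Sequence[LabeledRead], max_len: int):
    """Tokenize labeled reads, z-score qualities, drop over-long reads."""
    out = []
    for read in reads:
        try:
            tok = tokenize(read.record, max_len)
        except ReadTooLongError as exc:
            logger.warning("excluding read from training: %s", exc)
            continue
        if tok.length == 0:
            continue
        out.append(
            (
                tok.token_ids,
                normalize_qualities(read.record.qualities),
                np.asarray(read.labels, dtype=np.float32),
            )
        )
    return out


def _pad_batch(items):
    B = len(items)
    T = max(len(it[0]) for it in items)
    tokens = np.zeros((B, T), dtype=np.int64)
    qz = np.zeros((B, T), dtype=np.float32)
    mask = np.zeros((B, T), dtype=np.float32)
    y = np.zeros((B, T), dtype=np.float32)
    for b, (ids, q, lab) in enumerate(items):
        L = len(ids)
        tokens[b, :L] = ids
        qz[b, :L] = q
        mask[b, :L] = 1.0
        y[b, :L] = lab
    return tokens, qz, mask, y


class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps=1e-8):
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= (
                self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            )


def _validate(model, val_items, batch_size):
    """Pooled F1 and mean per-read loss on the validation items."""
    tp = fp = fn = tn = 0
    per_read_losses = []
    order = sorted(range(len(val_items)), key=lambda i: len(val_items[i][0]))
    for start in range(0, len(order), batch_size):
        chunk = [val_items[i] for i in order[start : start + batch_size]]
        tokens, qz, mask, y = _pad_batch(chunk)
        probs, _ = model._forward_batch(tokens, qz, mask)
        p_ad = probs[..., 0]
        pred = p_ad > 0.5
        true = y > 0.5
        valid = mask > 0
        tp += int(np.sum(pred & true & valid))
        fp += int(np.sum(pred & ~true & valid))
        fn += int(np.sum(~pred & true & valid))
        tn += int(np.sum(~pred & ~true & valid))
        pc = np.clip(p_ad.astype(np.float64), _EPS, 1.0 - _EPS)
        bce = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)) * mask
        lens = mask.sum(axis=1)
        per_read_losses.extend((bce.sum(axis=1) / np.maximum(lens, 1.0)).tolist())
    report = EvalReport.from_counts(tp, fp, fn, tn)
    return report.f1, float(np.mean(per_read_losses))


def train(
    train_reads: Sequence[LabeledRead],
    val_reads: Sequence[LabeledRead],
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
) -> Tuple[AdapterClassifier, List[Dict[str, float]]]:
    """Train the classifier; return the checkpoint maximizing validation F1.

    The history records one row per validation pass (step, epoch, train_loss
    since the previous pass, val_loss, val_f1, lr). A plateau scheduler halves
    the learning rate when validation loss stops improving; early stopping
    fires when validation F1 stops improving. Fully seeded and deterministic
    in single-threaded mode.
    """
    if not train_reads or not val_reads:
        raise ValueError("train and validation sets must be non-empty")
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    cfg, tc = model_config, train_config

    model = AdapterClassifier(cfg)
    train_items = _prepare(train_reads, cfg.max_input_length)
    val_items = _prepare(val_reads, cfg.max_input_length)
    if not train_items or not val_items:
        raise ValueError("no usable reads after length filtering")
    if tc.max_val_reads is not None and len(val_items) > tc.max_val_reads:
        sub_rng = np.random.default_rng(tc.shuffle_seed)
        idx = sub_rng.choice(len(val_items), size=tc.max_val_reads, replace=False)
        val_items = [val_items[i] for i in sorted(idx)]

    # sort by length so padded batches are homogeneous, then shuffle batch order
    train_items.sort(key=lambda it: len(it[0]))
    batches = [
        train_items[i : i + tc.batch_size]
        for i in range(0, len(train_items), tc.batch_size)
    ]
    rng = np.random.default_rng(tc.shuffle_seed)
    adam = _Adam(model.params, tc.initial_lr, tc.beta1, tc.beta2)

    history: List[Dict[str, float]] = []
    best_f1 = -1.0
    best_params = {k: v.copy() for k, v in model.params.items()}
    best_val_loss = np.inf
    plateau_wait = 0
    stop_wait = 0
    lr = tc.initial_lr
    step = 0
    running_losses: List[float] = []
    stop = False

    def run_validation(epoch: int) -> None:
        nonlocal best_f1, best_params, best_val_loss, plateau_wait, stop_wait, lr, stop
        val_f1, val_loss = _validate(model, val_items, tc.batch_size)
        train_loss = float(np.mean(running_losses)) if running_losses else float("nan")
        running_losses.clear()
        history.append(
            dict(
                step=step,
                epoch=epoch,
                train_loss=train_loss,
                val_loss=val_loss,
                val_f1=val_f1,
                lr=lr,
            )
        )
        logger.info(
            "step %d epoch %d train_loss %.4f val_loss %.4f val_f1 %.4f lr %.2e",
            step, epoch, train_loss, val_loss, val_f1, lr,
        )
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_params = {k: v.copy() for k, v in model.params.items()}
            stop_wait = 0
        else:
            stop_wait += 1
            if stop_wait >= tc.early_stop_patience:
                stop = True
        if val_loss < best_val_loss - 1e-6:
            best_val_loss = val_loss
            plateau_wait = 0
        else:
            plateau_wait += 1
            if plateau_wait >= tc.plateau_patience:
                lr *= tc.plateau_factor
                adam.lr = lr
                plateau_wait = 0

    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(batches))
        for bi in order:
            batch = batches[bi]
            tokens, qz, mask, y = _pad_batch(batch)
            probs, cache = model._forward_batch(tokens, qz, mask, want_cache=True)
            p_ad = np.clip(probs[..., 0].astype(np.float64), _EPS, 1.0 - _EPS)
            lens = mask.sum(axis=1)
            bce = -(y * np.log(p_ad) + (1.0 - y) * np.log(1.0 - p_ad)) * mask
            batch_loss = float((bce.sum(axis=1) / np.maximum(lens, 1.0)).mean())
            running_losses.append(batch_loss)
            # d(loss)/d(logits): softmax-CE with per-read mean weights
            w = (mask / np.maximum(lens, 1.0)[:, None] / mask.shape[0]).astype(
                np.float32
            )
            target = np.stack([y, 1.0 - y], axis=-1)
            dlogits = (probs - target) * w[..., None]
            grads = model._backward_batch(cache, dlogits)
            gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if tc.grad_clip and gnorm > tc.grad_clip:
                scale = tc.grad_clip / gnorm
                grads = {k: g * scale for k, g in grads.items()}
            adam.step(model.params, grads)
            step += 1
            if step % tc.val_interval_steps == 0:
                run_validation(epoch)
                if stop:
                    break
        if stop:
            break
        if step % tc.val_interval_steps != 0:
            run_validation(epoch)
            if stop:
                break

    model.params = best_params
    return model, history


def write_history_tsv(history: Sequence[Dict[str, float]], path) -> None:
    """Per-validation metrics log (TSV: step, train_loss, val_loss, val_f1)."""
    with open(path, "wt", encoding="ascii") as fh:
        fh.write("step\tepoch\ttrain_loss\tval_loss\tval_f1\tlr\n")
        for row in history:
            fh.write(
                f"{int(row['step'])}\t{int(row['epoch'])}\t{row['train_loss']:.6f}"
                f"\t{row['val_loss']:.6f}\t{row['val_f1']:.6f}\t{row['lr']:.6e}\n"
            )
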