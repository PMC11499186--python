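"""3D CNN age regressor: architecture, splitting, augmentation, training.

The network is a stack of ``[3x3x3 conv -> batch norm -> 2x2x2 max pool
-> ReLU]`` blocks, followed by a ``1x1x1 conv -> batch norm -> ReLU``
block, global average pooling, dropout, and a single linear output unit
that regresses age in years. Training uses Adam with L2 weight decay,
optional random-translation augmentation, and keeps the checkpoint with
the best validation mean absolute error.
"""

from __future__ import annotations

import json
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import nn
from .stats import PredictionRecord

SPLIT_NAMES = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.75, 0.225, 0.025)


@dataclass
class ModelSpec:
    """Architecture hyperparameters of the age regressor."""

    conv_block_filters: list[int] = field(
        default_factory=lambda: [32, 64, 128, 256, 256])
    conv_kernel: int = 3
    post_block_filters: int = 64
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if len(self.conv_block_filters) < 1:
            raise ValueError("at least one conv block is required")
        if any(f <= 0 for f in self.conv_block_filters):
            raise ValueError("conv block filter counts must be positive")
        if self.post_block_filters <= 0:
            raise ValueError("post_block_filters must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrainConfig:
    epochs: int = 300
    learning_rate: float = 0.001
    weight_decay: float = 0.0003
    batch_size: int = 8
    augment_prob: float = 0.5
    max_shift: int = 5
    seed: int = 0
    loss: str = "mae"  # or "mse"
    # Start the output bias at the mean training age so the regressor
    # fits residuals instead of travelling tens of years from zero.
    init_output_bias: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.augment_prob <= 1.0:
            raise ValueError("augment_prob must be in [0, 1]")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        if self.loss not in ("mae", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")


def spatial_shape_before_pool(input_shape: Sequence[int],
                              n_blocks: int) -> tuple[int, ...]:
    """Spatial grid entering global average pooling: floor-halved once
    per conv block (e.g. 162 -> 81 -> 40 -> 20 -> 10 -> 5)."""
    shape = tuple(int(s) for s in input_shape)
    for _ in range(n_blocks):
        shape = tuple(s // 2 for s in shape)
    return shape


class AgeModel:
    """The network plus the input geometry it was built for."""

    def __init__(self, net: nn.Sequential, spec: ModelSpec,
                 input_shape: tuple[int, int, int],
                 dropout_rng: np.random.Generator) -> None:
        self.net = net
        self.spec = spec
        self.input_shape = input_shape
        self._dropout_rng = dropout_rng

    # -- forward passes -------------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        if tuple(x.shape[-3:]) != self.input_shape:
            raise ValueError(
                f"volume shape {tuple(x.shape[-3:])} does not match the "
                f"model input shape {self.input_shape}")

    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        """batch (N, D, H, W) -> predictions (N,)."""
        self._check_shape(batch)
        x = batch[:, None].astype(np.float32, copy=False)
        out = self.net.forward(x, train=train)
        return out[:, 0]

    def predict_ages(self, vols: np.ndarray,
                     batch_size: int = 16) -> np.ndarray:
        """Inference-mode predictions, invariant to batch composition."""
        self._check_shape(vols)
        preds = [self.net.forward(
            vols[i:i + batch_size, None].astype(np.float32, copy=False),
            train=False)[:, 0]
            for i in range(0, len(vols), batch_size)]
        return np.concatenate(preds) if preds else np.empty(0)

    def value_and_input_grad(self, vol: np.ndarray
                             ) -> tuple[float, np.ndarray]:
        """Predicted age and d(prediction)/d(input voxel), eval mode."""
        self._check_shape(vol)
        x = vol[None, None].astype(np.float32, copy=False)
        pred = self.net.forward(x, train=False)
        grad = self.net.backward(np.ones((1, 1), dtype=np.float32))
        return float(pred[0, 0]), grad[0, 0]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.net.params())


def build_model(spec: ModelSpec, input_shape: Sequence[int],
                seed: int = 0) -> AgeModel:
    """Assemble the network for the given input grid."""
    input_shape = tuple(int(s) for s in input_shape)
    if len(input_shape) != 3:
        raise ValueError("input_shape must be 3D")
    n_blocks = len(spec.conv_block_filters)
    final = spatial_shape_before_pool(input_shape, n_blocks)
    if min(final) < 1:
        raise ValueError(
            f"input shape {input_shape} too small for {n_blocks} pooling "
            f"layers (needs >= {2 ** n_blocks} voxels per axis)")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    for f in spec.conv_block_filters:
        layers += [nn.Conv3d(in_ch, f, rng, kernel=spec.conv_kernel),
                   nn.BatchNorm3d(f), nn.MaxPool3d(), nn.ReLU()]
        in_ch = f
    layers += [nn.PointwiseConv3d(in_ch, spec.post_block_filters, rng),
               nn.BatchNorm3d(spec.post_block_filters), nn.ReLU(),
               nn.GlobalAvgPool3d()]
    dropout_rng = np.random.default_rng(seed + 1)
    layers += [nn.Dropout(spec.dropout_rate, dropout_rng),
               nn.Linear(spec.post_block_filters, 1, rng)]
    return AgeModel(nn.Sequential(layers), spec, input_shape, dropout_rng)


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def stratified_split(records: Sequence, fractions: Sequence[float]
                     = DEFAULT_FRACTIONS, age_bin_width: float = 10.0,
                     seed: int = 0) -> dict[str, str]:
    """Partition subjects into train/validation/test, stratified by
    (age bin x sex), with per-stratum largest-remainder rounding.

    ``records`` must expose ``subject_id``, ``age`` and ``sex``
    attributes (or mapping keys). Returns ``{subject_id: split_name}``.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != len(SPLIT_NAMES):
        raise ValueError(f"expected {len(SPLIT_NAMES)} fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if age_bin_width <= 0:
        raise ValueError("age_bin_width must be positive")

    def _get(r, name):
        return r[name] if isinstance(r, Mapping) else getattr(r, name)

    strata: dict[tuple, list[str]] = {}
    for r in records:
        key = (int(_get(r, "age") // age_bin_width), str(_get(r, "sex")))
        strata.setdefault(key, []).append(str(_get(r, "subject_id")))

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for key in sorted(strata):
        ids = sorted(strata[key])
        order = rng.permutation(len(ids))
        ids = [ids[i] for i in order]
        counts = _largest_remainder(len(ids), fractions)
        pos = 0
        for name, c in zip(SPLIT_NAMES, counts):
            for sid in ids[pos:pos + c]:
                assignment[sid] = name
            pos += c
    return assignment


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    leftover = n - sum(base)
    # ties broken by position: train before validation before test
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    return base


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def translate(vol: np.ndarray, shift: Sequence[int]) -> np.ndarray:
    """Integer-shift a volume, zero-filling vacated voxels."""
    out = np.zeros_like(vol)
    src: list[slice] = []
    dst: list[slice] = []
    for s, size in zip(shift, vol.shape):
        s = int(s)
        if abs(s) >= size:
            return out
        if s >= 0:
            dst.append(slice(s, size))
            src.append(slice(0, size - s))
        else:
            dst.append(slice(0, size + s))
            src.append(slice(-s, size))
    out[tuple(dst)] = vol[tuple(src)]
    return out


def augment_translate(vol: np.ndarray, max_shift: int,
                      rng: np.random.Generator | int) -> np.ndarray:
    """Random +/-``max_shift``-voxel translation, uniform per axis."""
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    shift = rng.integers(-max_shift, max_shift + 1, size=3)
    return translate(vol, shift)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    model: AgeModel
    spec: ModelSpec
    config: TrainConfig
    best_val_mae: float
    epoch_of_best: int
    history: pd.DataFrame  # columns: epoch, train_loss, val_mae


def train(model: AgeModel, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray],
          cfg: TrainConfig) -> TrainedModel:
    """Train and return the checkpoint with minimum validation MAE.

    ``train_set``/``val_set`` are ``(volumes (N, D, H, W), ages (N,))``
    pairs of already-preprocessed volumes. Fully deterministic for a
    fixed ``cfg.seed``.
    """
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be non-empty")
    y_tr = np.asarray(y_tr, dtype=np.float32)
    y_va = np.asarray(y_va, dtype=np.float64)

    rng = np.random.default_rng(cfg.seed)
    model._dropout_rng.bit_generator.state = \
        np.random.default_rng(cfg.seed + 7919).bit_generator.state
    if cfg.init_output_bias:
        head = model.net.layers[-1]
        assert isinstance(head, nn.Linear)
        head.b.value[...] = float(y_tr.mean())
    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate,
                  weight_decay=cfg.weight_decay)

    best_state: dict | None = None
    best_mae = np.inf
    best_epoch = -1
    rows = []
    n = len(x_tr)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            batch = x_tr[idx].astype(np.float32, copy=True)
            if cfg.max_shift > 0 and cfg.augment_prob > 0:
                for i in range(len(batch)):
                    if rng.random() < cfg.augment_prob:
                        batch[i] = augment_translate(
                            batch[i], cfg.max_shift, rng)
            yb = y_tr[idx]
            model.net.zero_grad()
            pred = model.forward(batch, train=True)
            err = pred - yb
            if cfg.loss == "mae":
                loss = float(np.abs(err).mean())
                dpred = np.sign(err) / len(err)
            else:
                loss = float((err ** 2).mean())
                dpred = 2.0 * err / len(err)
            model.net.backward(dpred[:, None].astype(np.float32))
            opt.step()
            epoch_loss += loss * len(err)
        val_pred = model.predict_ages(x_va)
        val_mae = float(np.abs(val_pred - y_va).mean())
        rows.append({"epoch": epoch, "train_loss": epoch_loss / n,
                     "val_mae": val_mae})
        if val_mae < best_mae:
            best_mae = val_mae
            best_epoch = epoch
            best_state = model.net.state_dict()

    assert best_state is not None
    model.net.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    return TrainedModel(model=model, spec=model.spec, config=cfg,
                        best_val_mae=best_mae, epoch_of_best=best_epoch,
                        history=history)


def predict(trained: TrainedModel | AgeModel, vols: np.ndarray,
            records: Sequence | None = None) -> list[PredictionRecord]:
    """Inference-mode predictions, one record per input volume.

    ``records`` supplies ``subject_id`` and ``age`` per volume; if
    omitted, ids are positional and chronological age is NaN.
    """
    model = trained.model if isinstance(trained, TrainedModel) else trained
    preds = model.predict_ages(np.asarray(vols))
    out = []
    for i, p in enumerate(preds):
        if records is not None:
            r = records[i]
            sid = r["subject_id"] if isinstance(r, Mapping) \
                else getattr(r, "subject_id")
            age = float(r["age"] if isinstance(r, Mapping)
                        else getattr(r, "age"))
        else:
            sid, age = str(i), float("nan")
        out.append(PredictionRecord(subject_id=str(sid), chronological_age=age,
                                    predicted_age=float(p)))
    return out


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(trained: TrainedModel, path: str | Path) -> None:
    """Write weights (npz) plus a JSON sidecar with spec and config."""
    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **trained.model.net.state_dict())
    sidecar = {
        "spec": dataclasses.asdict(trained.spec),
        "config": dataclasses.asdict(trained.config),
        "input_shape": list(trained.model.input_shape),
        "best_val_mae": trained.best_val_mae,
        "epoch_of_best": trained.epoch_of_best,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path).with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = ModelSpec(**sidecar["spec"])
    cfg = TrainConfig(**sidecar["config"])
    model = build_model(spec, sidecar["input_shape"], seed=cfg.seed)
    with np.load(path) as npz:
        model.net.load_state_dict(dict(npz))
    return TrainedModel(model=model, spec=spec, config=cfg,
                        best_val_mae=sidecar["best_val_mae"],
                        epoch_of_best=sidecar["epoch_of_best"],
                        history=pd.DataFrame())
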