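"""DBCNet and the residual 1D/2D baseline models, with the training protocol.

DBCNet maps a batch of RPM images through a shared residual convolutional
backbone to a feature vector per spectrum, then refines that feature in two
metabolite-specific branches.  Each branch applies a fully connected layer,
the batch-correlation update (a cosine-similarity-weighted convex mixing of
features across the mini-batch), and a scalar regression head; the two heads
output the GSH (mM) and H2O2 (uM) concentrations.  The baselines share the
I/O contract: the 2D baseline is the same backbone with a single linear head
and no batch correlation, and the 1D baseline runs a residual Conv1d stack on
the raw preprocessed spectra.

The reference training protocol is Nadam at 1e-3, MAE loss, batch size
32, up to 400 epochs with learning-rate reduction (patience 25, factor 0.1)
and early stopping (patience 30) on validation loss.  Labels are scaled to
comparable ranges (GSH/mM, H2O2 per 10 uM) so the two MAE terms weigh
similarly.  A "reduced" backbone (fewer, narrower stages) is first-class for
desk-scale work; the full 18-layer topology remains available.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .rpm import rpm_batch
from .spectra import DatasetSplit, LabeledSpectrum

LABEL_SCALE = np.array([1.0, 0.1])  # GSH in mM, H2O2 in units of 10 uM

BACKBONES = ("reduced", "paper_resnet18")
INPUT_MODES = ("rpm_2d", "raw_1d")


@dataclass
class ModelConfig:
    """Architecture configuration shared by DBCNet and the baselines."""

    backbone: str = "reduced"          # "reduced" | "paper_resnet18"
    input_mode: str = "rpm_2d"         # "rpm_2d" | "raw_1d"
    branch_width: int = 16
    bc_mode: str = "softmax"           # batch-correlation weight normalization
    # cosine similarities of post-ReLU features concentrate near 1, so the
    # softmax needs a temperature well below the typical similarity gap to be
    # selective; at tau ~ 1 the update collapses toward the batch mean
    bc_temperature: float = 0.02
    cohort_inference: bool = False     # True: batch statistics at predict time
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        if self.branch_width < 1:
            raise ValueError("branch_width must be >= 1")


@dataclass
class TrainConfig:
    """The reference training protocol (desk-scale epochs configurable)."""

    lr: float = 1e-3
    epochs: int = 400
    batch_size: int = 32
    lr_patience: int = 25
    lr_factor: float = 0.1
    early_stop_patience: int = 30
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.lr <= 0:
            raise ValueError("epochs/batch_size must be >= 1 and lr > 0")
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr_factor must be in (0, 1)")


def _backbone_2d(kind: str, rng, dtype):
    if kind == "reduced":
        feat = 16
        net = nn.Sequential(
            nn.AvgPool2d(2),
            nn.Conv2d(1, 8, 5, rng, stride=4, pad=2, dtype=dtype),
            nn.BatchNorm(8, dtype=dtype),
            nn.ReLU(),
            nn.ResidualBlock2d(8, 8, rng, dtype=dtype),
            nn.ResidualBlock2d(8, 16, rng, stride=2, dtype=dtype),
            nn.GlobalAvgPool(),
        )
        return net, feat
    # the full 18-layer topology: 7x7/2 stem, maxpool, four 2-block stages
    layers = [
        nn.Conv2d(1, 64, 7, rng, stride=2, pad=3, dtype=dtype),
        nn.BatchNorm(64, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool2d(3, 2, 1),
    ]
    widths = [(64, 64, 1), (64, 64, 1), (64, 128, 2), (128, 128, 1),
              (128, 256, 2), (256, 256, 1), (256, 512, 2), (512, 512, 1)]
    for in_c, out_c, stride in widths:
        layers.append(nn.ResidualBlock2d(in_c, out_c, rng, stride=stride, dtype=dtype))
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers), 512


def _backbone_1d(kind: str, rng, dtype):
    if kind == "reduced":
        net = nn.Sequential(
            nn.Conv1d(1, 16, 7, rng, stride=2, dtype=dtype),
            nn.BatchNorm(16, dtype=dtype),
            nn.ReLU(),
            nn.ResidualBlock1d(16, 16, rng, dtype=dtype),
            nn.ResidualBlock1d(16, 32, rng, stride=2, dtype=dtype),
            nn.GlobalAvgPool(),
        )
        return net, 32
    layers = [
        nn.Conv1d(1, 64, 7, rng, stride=2, dtype=dtype),
        nn.BatchNorm(64, dtype=dtype),
        nn.ReLU(),
    ]
    widths = [(64, 64, 1), (64, 64, 1), (64, 128, 2), (128, 128, 1),
              (128, 256, 2), (256, 256, 1), (256, 512, 2), (512, 512, 1)]
    for in_c, out_c, stride in widths:
        layers.append(nn.ResidualBlock1d(in_c, out_c, rng, stride=stride, dtype=dtype))
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers), 512


class _RegressionModel(nn.Module):
    """Shared plumbing: trained flag, batched prediction, label rescaling."""

    kind: str = ""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.trained = False
        self.input_length: Optional[int] = None

    def predict_scaled(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        self.eval()
        out = [self.forward(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
        return np.concatenate(out, axis=0)

    def output_heads(self) -> list[nn.Linear]:  # pragma: no cover - overridden
        raise NotImplementedError

    def init_output_bias(self, y_mean: np.ndarray) -> None:
        """Start the regression heads at the mean scaled label, so early
        epochs refine structure instead of walking the output range."""
        heads = self.output_heads()
        if len(heads) == 1:
            heads[0].b.value[...] = y_mean.astype(heads[0].b.value.dtype)
        else:
            for head, m in zip(heads, y_mean):
                head.b.value[...] = np.asarray([m], dtype=head.b.value.dtype)


class DBCNet(_RegressionModel):
    kind = "dbcnet"

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        super().__init__(cfg)
        rng = np.random.default_rng(cfg.seed)
        builder = _backbone_2d if cfg.input_mode == "rpm_2d" else _backbone_1d
        self.backbone, feat = builder(cfg.backbone, rng, dtype)
        self.feature_dim = feat
        w = cfg.branch_width

        def branch():
            return nn.Sequential(
                nn.Linear(feat, w, rng, dtype=dtype),
                nn.ReLU(),
                nn.BatchCorrelation(
                    mode=cfg.bc_mode,
                    temperature=cfg.bc_temperature,
                    cohort_inference=cfg.cohort_inference,
                ),
                nn.Linear(w, 1, rng, dtype=dtype),
            )

        self.branch_gsh = branch()
        self.branch_h2o2 = branch()

    def children(self):
        return [self.backbone, self.branch_gsh, self.branch_h2o2]

    def output_heads(self):
        return [self.branch_gsh.layers[-1], self.branch_h2o2.layers[-1]]

    def forward(self, x):
        f = self.backbone.forward(x)
        return np.concatenate(
            [self.branch_gsh.forward(f), self.branch_h2o2.forward(f)], axis=1
        )

    def backward(self, dy):
        df = self.branch_gsh.backward(dy[:, 0:1]) + self.branch_h2o2.backward(dy[:, 1:2])
        return self.backbone.backward(df)


class ResNetBaseline(_RegressionModel):
    """Residual CNN with a single shared two-output head (no batch correlation)."""

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        super().__init__(cfg)
        rng = np.random.default_rng(cfg.seed)
        builder = _backbone_2d if cfg.input_mode == "rpm_2d" else _backbone_1d
        self.backbone, feat = builder(cfg.backbone, rng, dtype)
        self.feature_dim = feat
        self.head = nn.Linear(feat, 2, rng, dtype=dtype)
        self.kind = "resnet2d" if cfg.input_mode == "rpm_2d" else "resnet1d"

    def children(self):
        return [self.backbone, self.head]

    def forward(self, x):
        return self.head.forward(self.backbone.forward(x))

    def backward(self, dy):
        return self.backbone.backward(self.head.backward(dy))

    def output_heads(self):
        return [self.head]


def build_model(cfg: ModelConfig, dtype=np.float32) -> DBCNet:
    """DBCNet per the configuration (dual branches with batch correlation)."""
    return DBCNet(cfg, dtype=dtype)


def build_baseline(kind: str, cfg: Optional[ModelConfig] = None, dtype=np.float32):
    """`resnet_1d` / `resnet_2d` comparison models with build_model's I/O."""
    cfg = cfg or ModelConfig()
    if kind in ("resnet_2d", "resnet2d"):
        cfg.input_mode = "rpm_2d"
    elif kind in ("resnet_1d", "resnet1d"):
        cfg.input_mode = "raw_1d"
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return ResNetBaseline(cfg, dtype=dtype)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def stack_intensities(records: Sequence[LabeledSpectrum], dtype=np.float32) -> np.ndarray:
    lengths = {len(r.spectrum) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"records have mixed spectrum lengths {sorted(lengths)}")
    return np.stack([r.spectrum.intensities for r in records]).astype(dtype)


def prepare_inputs(
    records: Sequence[LabeledSpectrum], input_mode: str = "rpm_2d", dtype=np.float32
) -> np.ndarray:
    """Model-ready array: (N, 1, M, M) RPM images or (N, 1, M) raw spectra."""
    X = stack_intensities(records, dtype=dtype)
    if input_mode == "rpm_2d":
        return rpm_batch(X, dtype=dtype)[:, None, :, :]
    if input_mode == "raw_1d":
        return X[:, None, :]
    raise ValueError(f"unknown input_mode {input_mode!r}")


def labels_array(records: Sequence[LabeledSpectrum]) -> np.ndarray:
    """(N, 2) ground-truth array (c_gsh mM, c_h2o2 uM); labels must be present."""
    out = np.empty((len(records), 2))
    for i, r in enumerate(records):
        if r.c_gsh is None or r.c_h2o2 is None:
            raise ValueError(f"record {i} lacks a concentration label")
        out[i] = (r.c_gsh, r.c_h2o2)
    return out


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def train(
    model: _RegressionModel,
    X: np.ndarray,
    y: np.ndarray,
    split: DatasetSplit,
    tcfg: Optional[TrainConfig] = None,
) -> dict:
    """Fit the model on the split's train part, monitoring validation MAE.

    Applies learning-rate reduction and early stopping on the validation loss
    and restores the best-validation weights before returning.  The history
    dict records per-epoch train/val losses and the learning rate.
    """
    tcfg = tcfg or TrainConfig()
    if split.train.size == 0 or split.val.size == 0:
        raise ValueError("need non-empty train and val sets")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels contain non-finite values")
    ys = (np.asarray(y, dtype=float) * LABEL_SCALE).astype(X.dtype)
    Xtr, ytr = X[split.train], ys[split.train]
    Xval, yval = X[split.val], ys[split.val]

    if not model.trained:
        model.init_output_bias(ytr.mean(axis=0))
    rng = np.random.default_rng(tcfg.seed)
    opt = nn.Nadam(model.params(), lr=tcfg.lr)
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm)]

    def snapshot():
        return (
            [p.value.copy() for p in model.params()],
            [(b.running_mean.copy(), b.running_var.copy()) for b in bns],
        )

    def restore(snap):
        for p, v in zip(model.params(), snap[0]):
            p.value[...] = v
        for b, (rm, rv) in zip(bns, snap[1]):
            b.running_mean[...] = rm
            b.running_var[...] = rv

    history = {"train_loss": [], "val_loss": [], "lr": [], "best_epoch": 0}
    best_val, best_snap = np.inf, snapshot()
    since_improve = since_lr = 0
    n = Xtr.shape[0]
    for epoch in range(tcfg.epochs):
        model.train()
        perm = rng.permutation(n)
        tot = 0.0
        for start in range(0, n, tcfg.batch_size):
            idx = perm[start : start + tcfg.batch_size]
            model.zero_grad()
            pred = model.forward(Xtr[idx])
            loss, grad = nn.mae_loss(pred, ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")
            model.backward(grad)
            opt.step()
            tot += loss * idx.size
        val_pred = model.predict_scaled(Xval)
        val_loss = float(np.abs(val_pred - yval).mean())
        history["train_loss"].append(tot / n)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best_val:
            best_val, best_snap = val_loss, snapshot()
            history["best_epoch"] = epoch
            since_improve = since_lr = 0
        else:
            since_improve += 1
            since_lr += 1
            if since_lr >= tcfg.lr_patience:
                opt.lr *= tcfg.lr_factor
                since_lr = 0
            if since_improve >= tcfg.early_stop_patience:
                break
    restore(best_snap)
    model.trained = True
    model.input_length = X.shape[-1]
    return history


def predict(model: _RegressionModel, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """(N, 2) predicted (c_gsh mM, c_h2o2 uM) for model-ready inputs.

    Per-sample inference is the default: batch correlation degenerates to the
    identity, so each prediction is independent of co-batched spectra.  With
    ``cohort_inference`` configured, predictions use true batch statistics and
    ``batch_size`` becomes part of the measurement protocol.
    """
    if not model.trained:
        raise RuntimeError("model is not trained")
    if model.input_length is not None and X.shape[-1] != model.input_length:
        raise ValueError(
            f"input length {X.shape[-1]} does not match training length {model.input_length}"
        )
    return (model.predict_scaled(X, batch_size=batch_size) / LABEL_SCALE).astype(float)


def predict_spectra(
    model: _RegressionModel, records: Sequence[LabeledSpectrum], batch_size: int = 64
) -> np.ndarray:
    return predict(model, prepare_inputs(records, model.cfg.input_mode), batch_size)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: _RegressionModel, path) -> None:
    """Persist weights + config + preprocessing metadata as one .npz file."""
    path = Path(path)
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm)]
    for i, b in enumerate(bns):
        arrays[f"bn_mean_{i}"] = b.running_mean
        arrays[f"bn_var_{i}"] = b.running_var
    meta = {
        "kind": model.kind,
        "cfg": asdict(model.cfg),
        "trained": model.trained,
        "input_length": model.input_length,
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> _RegressionModel:
    data = np.load(Path(path), allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg = ModelConfig(**meta["cfg"])
    if meta["kind"] == "dbcnet":
        model = build_model(cfg)
    else:
        model = build_baseline(meta["kind"], cfg)
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"param_{i}"]
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm)]
    for i, b in enumerate(bns):
        b.running_mean[...] = data[f"bn_mean_{i}"]
        b.running_var[...] = data[f"bn_var_{i}"]
    model.trained = bool(meta["trained"])
    model.input_length = meta["input_length"]
    return model
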