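"""Training loop, evaluation metrics and the robustness/ablation experiments.

Training uses Adam (first-moment coefficient from the "momentum" setting,
second moment 0.999), a two-phase learning-rate schedule, L2 weight decay
and the label-smoothed composite loss.  Evaluation reports the 6×6 confusion
matrix (rows actual, columns predicted), per-class precision/recall/F1 and
their unweighted macro averages.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .data import DatasetManifest, LABELS, load_and_resize, iterations_per_epoch
from .model import MFRANet, ModelConfig, total_loss
from .synth import NoiseSpec, add_noise


@dataclass
class TrainConfig:
    """Optimizer and schedule settings.

    ``lr_schedule`` is a list of ``(first_epoch, last_epoch_or_None, rate)``
    phases; the default keeps 0.001 for epochs 1–20 and 0.005 afterwards.
    """

    batch_size: int = 32
    epochs: int = 30
    lr_schedule: tuple = ((1, 20, 0.001), (21, None, 0.005))
    weight_decay: float = 1e-4
    moment_coeff: float = 0.9
    seed: int = 0
    width_multiplier: float = 1.0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        for start, end, rate in self.lr_schedule:
            if rate <= 0:
                raise ValueError("learning rates must be positive")

    def lr_at(self, epoch: int) -> float:
        for start, end, rate in self.lr_schedule:
            if epoch >= start and (end is None or epoch <= end):
                return rate
        return self.lr_schedule[-1][2]


def load_split(manifest: DatasetManifest, split: str, root,
               size: tuple = (224, 224)):
    """Images (N, H, W, 3 in [0, 1]) and integer labels for one split."""
    df = manifest.subset(split)
    root = Path(root)
    imgs = np.stack([load_and_resize(root / p, size) for p in df["path"]]) \
        if len(df) else np.zeros((0,) + size + (3,), dtype=np.float32)
    y = np.array([LABELS.index(l) for l in df["label"]], dtype=np.int64)
    return imgs, y


def as_batch(images_hwc: np.ndarray) -> np.ndarray:
    """HWC [0,1] stack to centred NCHW float32 model input."""
    return np.ascontiguousarray(
        np.transpose(images_hwc, (0, 3, 1, 2)).astype(np.float32) - 0.5)


def accuracy(model: MFRANet, images_hwc: np.ndarray, y: np.ndarray,
             batch_size: int = 32) -> float:
    pred = model.predict(as_batch(images_hwc), batch_size)
    return float((pred == y).mean())


def train(model: MFRANet, manifest: DatasetManifest, config: TrainConfig,
          root, early_stop_train_acc: float | None = None,
          early_stop_loss_ratio: float | None = None,
          log_stream=None, log_file=None):
    """Train on the manifest's train split; return (model, per-epoch log).

    The log has one row per epoch: epoch, learning rate, mean loss,
    running training accuracy (over that epoch's batches) and the iteration
    count.  With ``early_stop_train_acc`` set, epochs whose running accuracy
    comes near the target trigger a full evaluation pass (the running figure
    understates the fitted model: it averages over the epoch and uses batch
    statistics); training stops once the evaluated accuracy (logged in
    ``train_acc_eval``) reaches the target; with ``early_stop_loss_ratio``
    also set, stopping additionally requires the epoch-mean loss to have
    fallen to that fraction of the initial (pre-update) loss, recorded in
    the ``initial_loss`` column.
    """
    X, y = load_split(manifest, "train", root)
    if len(X) == 0:
        raise ValueError("manifest has an empty train split")
    Xn = as_batch(X)
    opt = nn.Adam(model.parameters(), lr=config.lr_at(1),
                  beta1=config.moment_coeff, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    n = len(Xn)
    log_stream = sys.stderr if log_stream is None else log_stream
    rows = []
    initial_loss = None
    fh = open(log_file, "a") if log_file else None
    try:
        for epoch in range(1, config.epochs + 1):
            opt.lr = config.lr_at(epoch)
            perm = rng.permutation(n)
            losses, hits, iterations = [], 0, 0
            model.train()
            for i in range(0, n, config.batch_size):
                idx = perm[i:i + config.batch_size]
                logits, aux, probs = model.forward(Xn[idx])
                loss = total_loss(logits, aux, y[idx], model.config)
                model.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
                if initial_loss is None:
                    initial_loss = losses[0]  # computed before the first update
                hits += int((probs.argmax(axis=1) == y[idx]).sum())
                iterations += 1
            row = {
                "epoch": epoch, "lr": opt.lr,
                "loss": float(np.mean(losses)),
                "initial_loss": initial_loss,
                "train_acc": hits / n,
                "iterations": iterations,
                "train_acc_eval": np.nan,
            }
            if (early_stop_train_acc is not None
                    and row["train_acc"] >= early_stop_train_acc - 0.1):
                row["train_acc_eval"] = accuracy(model, X, y, config.batch_size)
            line = (f"epoch {epoch:3d}  lr {opt.lr:.4g}  loss {row['loss']:.4f}  "
                    f"train_acc {row['train_acc']:.3f}")
            print(line, file=log_stream)
            if fh:
                print(line, file=fh)
            rows.append(row)
            loss_ok = (early_stop_loss_ratio is None
                       or row["loss"] <= early_stop_loss_ratio * initial_loss)
            if (early_stop_train_acc is not None and loss_ok
                    and row["train_acc_eval"] >= early_stop_train_acc):
                break
    finally:
        if fh:
            fh.close()
    return model, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def confusion_from_predictions(y_true, y_pred, n_classes: int = 6) -> np.ndarray:
    """Rows = actual class, columns = predicted class."""
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return cm


def confusion(model: MFRANet, manifest: DatasetManifest, split: str, root,
              batch_size: int = 32) -> np.ndarray:
    """Confusion matrix of argmax predictions on one split.

    Probability ties break toward the lower class index (argmax convention).
    """
    X, y = load_split(manifest, split, root)
    if len(X) == 0:
        raise ValueError(f"split {split!r} is empty")
    pred = model.predict(as_batch(X), batch_size)
    return confusion_from_predictions(y, pred, model.config.n_classes)


@dataclass
class MetricsReport:
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float


def metrics(cm: np.ndarray) -> MetricsReport:
    """Per-class and macro precision/recall/F1 from a confusion matrix.

    ``P = TP/(TP+FP)``, ``R = TP/(TP+FN)``, ``F1 = 2PR/(P+R)``; macro values
    are unweighted means over classes.  A class with no predicted (or no
    actual) samples contributes precision (or recall) 0 with a warning.
    """
    cm = np.asarray(cm)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    if ((tp + fp) == 0).any() or ((tp + fn) == 0).any():
        warnings.warn("class with no predicted or no actual samples: "
                      "precision/recall reported as 0", RuntimeWarning,
                      stacklevel=2)
    pr = precision + recall
    f1 = np.where(pr > 0, 2.0 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    return MetricsReport(
        tp=tp.astype(int), fp=fp.astype(int), fn=fn.astype(int),
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        accuracy=float(tp.sum() / cm.sum()),
    )


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

ABLATION_KEYS = {"amsr", "use_ram", "use_detail", "activation", "smoothing"}


def ablation_run(variants: dict, synth_spec, train_config: TrainConfig,
                 workdir, model_config: ModelConfig | None = None):
    """Train one model per variant on the same seeded synthetic dataset.

    ``variants`` maps a row name to overrides over the full model:
    ``amsr`` (bool, preprocessing on/off), ``use_ram``, ``use_detail``
    (bools), ``activation`` ('elu'/'relu'), ``smoothing`` (bool).  Returns a
    comparison DataFrame plus the per-variant test confusion matrices; no
    ordering between variants is asserted anywhere.
    """
    from .amsr import enhance, EnhancementConfig
    from .data import SplitSpec, split_manifest
    from .image import RgbImage
    from .synth import generate_dataset

    for name, overrides in variants.items():
        bad = set(overrides) - ABLATION_KEYS
        if bad:
            raise ValueError(f"unknown ablation keys {sorted(bad)} in variant {name!r}")

    workdir = Path(workdir)
    raw = workdir / "raw"
    manifest = generate_dataset(synth_spec, raw)
    manifest = split_manifest(manifest, SplitSpec(seed=train_config.seed))
    base = model_config or ModelConfig(
        width_multiplier=train_config.width_multiplier, seed=train_config.seed)

    enh_root = None
    if any(v.get("amsr", False) for v in variants.values()):
        enh_root = workdir / "amsr"
        ecfg = EnhancementConfig()
        for p in manifest.records["path"]:
            enhance(RgbImage.load(raw / p), ecfg).save(enh_root / p)

    rows, cms = [], {}
    for name, overrides in variants.items():
        cfg = ModelConfig(**{
            **base.to_dict(),
            "rfe_weights": tuple(base.rfe_weights),
            "use_ram": overrides.get("use_ram", base.use_ram),
            "use_detail": overrides.get("use_detail", base.use_detail),
            "activation": overrides.get("activation", base.activation),
            "smoothing": base.smoothing if overrides.get("smoothing", True) else 0.0,
        })
        root = enh_root if overrides.get("amsr", False) else raw
        model = MFRANet(cfg)
        model, _ = train(model, manifest, train_config, root)
        cm = confusion(model, manifest, "test", root, train_config.batch_size)
        rep = metrics(cm)
        cms[name] = cm
        rows.append({
            "variant": name, "accuracy": rep.accuracy,
            "macro_precision": rep.macro_precision,
            "macro_recall": rep.macro_recall, "macro_f1": rep.macro_f1,
        })
    return pd.DataFrame(rows), cms


def noise_robustness(model: MFRANet, manifest: DatasetManifest,
                     noise_specs, root, split: str = "test",
                     batch_size: int = 32) -> pd.DataFrame:
    """Accuracy on the clean split and on each noisy variant.

    A level-0 spec skips the noise step entirely, so its accuracy equals the
    clean evaluation exactly.  Per-image noise seeds derive from the spec
    seed plus the record index.
    """
    X, y = load_split(manifest, split, root)
    rows = []
    for spec in noise_specs:
        if spec.level == 0:
            Xn = X
        else:
            Xn = np.stack([
                add_noise(X[i], NoiseSpec(spec.kind, spec.level,
                                          seed=spec.seed + i)).pixels
                for i in range(len(X))
            ])
        pred = model.predict(as_batch(Xn), batch_size)
        rows.append({"kind": spec.kind, "level": spec.level,
                     "accuracy": float((pred == y).mean()), "n": len(X)})
    return pd.DataFrame(rows)
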