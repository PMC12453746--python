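"""Training, cross-validation and whole-volume inference.

The training protocol mirrors the patch-based regime the architecture was
designed for: batch size 1, Dice + cross-entropy loss, AdamW with initial
learning rate 1e-4, early stopping when the validation Dice has not improved
for a fixed number of epochs, and 5-fold cross-validation with one fifth held
out for testing and 1/8 of the remaining training cases for validation.

An "epoch" is one pass over ``patches_per_epoch`` freshly sampled patches
(the iteration cap and the patience are both honored); validation Dice is
the mean foreground DSC over the validation cases under sliding-window
inference. All randomness flows from the config seed, so histories are
reproducible.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from . import nn, preprocessing
from .data import LabeledCase
from .network import AblationFlags, MDMUNet, NetworkConfig, build_model

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "dice_ce_loss",
    "make_cv_splits",
    "AdamW",
    "fit",
    "FitResult",
    "sliding_window_predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 1
    max_iterations: int = 40_000
    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    early_stop_patience_epochs: int = 15
    folds: int = 5
    val_fraction_of_train: float = 1.0 / 8.0
    seed: int = 0
    patches_per_epoch: int = 250
    target_val_dsc: float | None = None  # optional: stop once validation DSC reaches this

    def __post_init__(self):
        if self.early_stop_patience_epochs < 1:
            raise ValueError("patience must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 < self.val_fraction_of_train < 1.0:
            raise ValueError("val_fraction_of_train must lie in (0, 1)")


@dataclass(frozen=True)
class FoldSplit:
    fold: int
    train: tuple
    val: tuple
    test: tuple


def make_cv_splits(case_ids, cfg: TrainConfig) -> list[FoldSplit]:
    """Seeded k-fold splits; per fold the validation set is a random
    ``val_fraction_of_train`` share (at least one case) of the non-test cases."""
    ids = list(case_ids)
    if len(ids) < cfg.folds:
        raise ValueError(f"need at least {cfg.folds} cases, got {len(ids)}")
    rng = np.random.default_rng(cfg.seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    parts = [list(p) for p in np.array_split(np.arange(len(order)), cfg.folds)]
    splits = []
    for fold, part in enumerate(parts):
        test = [order[i] for i in part]
        rest = [x for x in order if x not in test]
        n_val = max(1, int(round(len(rest) * cfg.val_fraction_of_train)))
        val_idx = rng.choice(len(rest), size=n_val, replace=False)
        val = [rest[i] for i in sorted(val_idx)]
        train = [x for x in rest if x not in val]
        splits.append(FoldSplit(fold=fold, train=tuple(train), val=tuple(val), test=tuple(test)))
    return splits


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

DICE_SMOOTH = 1e-5


def _log_softmax(logits):
    m = anp.max(logits, axis=1, keepdims=True)
    z = logits - m
    return z - anp.log(anp.sum(anp.exp(z), axis=1, keepdims=True))


def one_hot(labels, num_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(
            f"labels outside 0..{num_classes - 1}: found range "
            f"[{labels.min()}, {labels.max()}]"
        )
    eye = np.eye(num_classes, dtype=np.float32)
    return np.moveaxis(eye[labels], -1, 1)  # (B, C, D, H, W)


def dice_ce_loss(logits, target_labels, num_classes: int | None = None):
    """Soft multi-class Dice loss plus voxelwise cross-entropy, equal weights.

    ``logits``: (B, C, D, H, W); ``target_labels``: integer (B, D, H, W).
    Dice averages over all classes including background, with smoothing
    ``DICE_SMOOTH`` in numerator and denominator.
    """
    num_classes = num_classes or logits.shape[1]
    target = one_hot(target_labels, num_classes)
    logp = _log_softmax(logits)
    ce = -anp.mean(anp.sum(target * logp, axis=1))
    probs = anp.exp(logp)
    inter = anp.sum(probs * target, axis=(0, 2, 3, 4))
    denom = anp.sum(probs, axis=(0, 2, 3, 4)) + anp.sum(target, axis=(0, 2, 3, 4))
    dice = anp.mean((2.0 * inter + DICE_SMOOTH) / (denom + DICE_SMOOTH))
    return (1.0 - dice) + ce


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """Decoupled weight-decay Adam on a nested parameter dict."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-2):
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = nn.tree_map(np.zeros_like, params)
        self.v = nn.tree_map(np.zeros_like, params)
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t

        def upd(p, g, m, v):
            m[...] = b1 * m + (1.0 - b1) * g
            v[...] = b2 * v + (1.0 - b2) * g * g
            step = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            return (p - self.lr * (step + self.weight_decay * p)).astype(p.dtype)

        return nn.tree_map(upd, params, grads, self.m, self.v)


# ---------------------------------------------------------------------------
# sliding-window inference
# ---------------------------------------------------------------------------

def _window_starts(extent: int, window: int, stride: int) -> list[int]:
    if extent <= window:
        return [0]
    starts = list(range(0, extent - window, stride))
    starts.append(extent - window)  # flush with the far edge
    return sorted(set(starts))


def sliding_window_predict(
    model: MDMUNet,
    params,
    image: np.ndarray,
    window=(96, 96, 96),
    overlap: float = 0.25,
) -> np.ndarray:
    """Tile the volume, average class probabilities in overlaps, argmax to labels.

    Volumes smaller than the window are symmetrically zero-padded and the
    prediction is cropped back.
    """
    window = tuple(int(w) for w in window)
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    image = np.asarray(image, dtype=np.float32)
    orig_shape = image.shape
    pads = [(max(0, w - s) // 2, max(0, w - s) - max(0, w - s) // 2)
            for s, w in zip(orig_shape, window)]
    if any(lo or hi for lo, hi in pads):
        image = np.pad(image, pads)

    num_classes = model.cfg.num_classes
    prob_sum = np.zeros((num_classes,) + image.shape, dtype=np.float32)
    weight = np.zeros(image.shape, dtype=np.float32)
    strides = [max(1, int(round(w * (1.0 - overlap)))) for w in window]
    for d0 in _window_starts(image.shape[0], window[0], strides[0]):
        for h0 in _window_starts(image.shape[1], window[1], strides[1]):
            for w0 in _window_starts(image.shape[2], window[2], strides[2]):
                sl = (
                    slice(d0, d0 + window[0]),
                    slice(h0, h0 + window[1]),
                    slice(w0, w0 + window[2]),
                )
                tile = image[sl][None, None]
                probs = np.asarray(model(params, tile))[0]
                prob_sum[(slice(None),) + sl] += probs
                weight[sl] += 1.0
    labels = np.argmax(prob_sum / weight[None], axis=0)
    crop = tuple(slice(lo, lo + s) for (lo, _), s in zip(pads, orig_shape))
    return labels[crop].astype(np.int64)


def _foreground_dsc(gt: np.ndarray, pr: np.ndarray, num_classes: int) -> float:
    from .metrics import overlap_metrics

    scores = [overlap_metrics(gt == c, pr == c).dsc for c in range(1, num_classes)]
    return float(np.mean(scores)) if scores else math.nan


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: dict
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dsc: float = -math.inf
    iterations: int = 0

    def history_csv(self, path) -> Path:
        import csv

        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "loss", "val_dsc"])
            writer.writeheader()
            for row in self.history:
                writer.writerow(row)
        return path


def fit(
    model: MDMUNet,
    train_cases: list[LabeledCase],
    val_cases: list[LabeledCase],
    train_cfg: TrainConfig,
    preprocess_cfg: preprocessing.PreprocessConfig,
    params=None,
    augment: bool = True,
    val_overlap: float = 0.25,
) -> FitResult:
    """Patch-based training with early stopping on validation Dice.

    Cases are assumed preprocessed (resampled/remapped/cropped). The best
    validation checkpoint is returned; if there are no validation cases the
    final parameters are returned and the patience criterion is ignored.
    """
    rng = np.random.default_rng(train_cfg.seed)
    if params is None:
        params = model.init(rng)
    opt = AdamW(
        params,
        lr=train_cfg.learning_rate,
        betas=train_cfg.betas,
        eps=train_cfg.adam_eps,
        weight_decay=train_cfg.weight_decay,
    )
    num_classes = model.cfg.num_classes
    loss_grad = value_and_grad(
        lambda p, x, y: dice_ce_loss(model.forward_logits(p, x), y, num_classes)
    )

    result = FitResult(params=params)
    iterations = 0
    epoch = 0
    stale = 0
    while iterations < train_cfg.max_iterations:
        epoch += 1
        losses = []
        for _ in range(train_cfg.patches_per_epoch):
            if iterations >= train_cfg.max_iterations:
                break
            case = train_cases[rng.integers(len(train_cases))]
            img, lbl = preprocessing.sample_patch(case, preprocess_cfg, rng)
            if augment:
                img, lbl = preprocessing.augment(img, lbl, preprocess_cfg, rng)
            x = img[None, None].astype(np.float32)
            y = lbl[None].astype(np.int64)
            loss, grads = loss_grad(params, x, y)
            loss = float(loss)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss} at iteration {iterations}"
                )
            params = opt.step(params, grads)
            losses.append(loss)
            iterations += 1

        if val_cases:
            val_dsc = float(np.mean([
                _foreground_dsc(
                    c.labels,
                    sliding_window_predict(model, params, c.image,
                                           preprocess_cfg.patch_size, val_overlap),
                    num_classes,
                )
                for c in val_cases
            ]))
        else:
            val_dsc = math.nan
        result.history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "val_dsc": val_dsc}
        )

        if not val_cases:
            result.params = params
            result.best_epoch = epoch
        elif train_cfg.target_val_dsc is not None and val_dsc >= train_cfg.target_val_dsc:
            result.best_val_dsc = val_dsc
            result.best_epoch = epoch
            result.params = params
            break
        elif val_dsc > result.best_val_dsc:
            result.best_val_dsc = val_dsc
            result.best_epoch = epoch
            result.params = copy.deepcopy(params)
            stale = 0
        else:
            stale += 1
            if stale >= train_cfg.early_stop_patience_epochs:
                break
    result.iterations = iterations
    return result


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model_cfg: NetworkConfig, params, train_cfg: TrainConfig | None = None,
                    history: list[dict] | None = None) -> Path:
    path = Path(path)
    meta = {
        "network": asdict(model_cfg),
        "train": asdict(train_cfg) if train_cfg else None,
        "history": history or [],
    }
    flat = nn.flatten_tree(params)
    np.savez_compressed(path, __meta__=json.dumps(meta), **flat)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path) -> tuple[MDMUNet, dict, dict]:
    """Returns (model, params, meta)."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        flat = {k: archive[k] for k in archive.files if k != "__meta__"}
    net_meta = dict(meta["network"])
    net_meta["ablation"] = AblationFlags(**net_meta["ablation"])
    for key in ("level_widths", "blocks_per_level", "kernel_scales"):
        net_meta[key] = tuple(net_meta[key])
    cfg = NetworkConfig(**net_meta)
    model = build_model(cfg)
    params = nn.unflatten_tree(flat)
    return model, params, meta
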