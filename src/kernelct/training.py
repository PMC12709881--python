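"""Dataset splitting, the training loop, checkpointing and evaluation.

Training follows the method's recipe: RMSprop, batch size 1, initial
learning rate 1e-4 decayed toward a floor of 1e-5 (reduce-on-plateau on
validation Dice by default, cosine decay by flag), the composite
focal-Tversky + boundary objective, and an 8:1 train:validation split.
Everything is seeded, so two runs of the same configuration produce
identical loss trajectories.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .csftu_net import CSFTUNet, NetworkConfig, build_model, predict_slices
from .losses import LossConfig, multiclass_scores, total_loss
from .nn import RMSprop, ReduceLROnPlateau, CosineSchedule, Tensor, softmax_channels


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults are the method's published recipe."""

    epochs: int = 50
    batch_size: int = 1
    optimizer: str = "rmsprop"
    lr_init: float = 1e-4
    lr_min: float = 1e-5
    lr_schedule: str = "plateau"   # 'plateau' | 'cosine' | 'none'
    seed: int = 0
    augment: bool = False
    augment_transforms: tuple[str, ...] = ("hflip", "vflip", "rot90")
    split_ratio_train_val: tuple[int, int] = (8, 1)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 < self.lr_min <= self.lr_init):
            raise ValueError("need 0 < lr_min <= lr_init")
        if self.optimizer != "rmsprop":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("plateau", "cosine", "none"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test identifier lists."""

    train_ids: list
    val_ids: list
    test_ids: list

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("split parts are not pairwise disjoint")


def split_dataset(
    ids: Sequence,
    ratio: tuple[int, int] = (8, 1),
    test_count: int = 0,
    seed: int = 0,
) -> DatasetSplit:
    """Deterministically shuffle and split identifiers.

    ``test_count`` ids are withheld first; the remainder is split
    train:val at ``ratio`` with rounding toward train.
    """
    ids = list(ids)
    r_train, r_val = ratio
    if r_train < 1 or r_val < 1:
        raise ValueError(f"invalid ratio {ratio}")
    if len(ids) < test_count + r_train + r_val:
        raise ValueError(
            f"too few ids ({len(ids)}) for test_count={test_count} and ratio {ratio}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    test_ids = shuffled[:test_count]
    remain = shuffled[test_count:]
    n_val = int(len(remain) * r_val / (r_train + r_val))  # rounding toward train
    n_val = max(1, n_val)
    val_ids = remain[:n_val]
    train_ids = remain[n_val:]
    return DatasetSplit(train_ids=train_ids, val_ids=val_ids, test_ids=test_ids)


def _augment_pair(image: np.ndarray, label: np.ndarray, rng: np.random.Generator,
                  transforms: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    if "hflip" in transforms and rng.random() < 0.5:
        image, label = image[:, ::-1], label[:, ::-1]
    if "vflip" in transforms and rng.random() < 0.5:
        image, label = image[::-1, :], label[::-1, :]
    if "rot90" in transforms:
        k = int(rng.integers(0, 4))
        image, label = np.rot90(image, k), np.rot90(label, k)
    return np.ascontiguousarray(image), np.ascontiguousarray(label)


@dataclass
class TrainHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_dice", "lr"])
            for row in zip(self.epoch, self.train_loss, self.val_dice, self.lr):
                w.writerow(row)


def save_checkpoint(model: CSFTUNet, path: str | Path) -> Path:
    """Save parameters + architecture config in one npz."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(p, **state)
    return p


def load_checkpoint(path: str | Path) -> CSFTUNet:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        cfg_json = bytes(data["__config__"]).decode()
        config = NetworkConfig(**json.loads(cfg_json))
        model = build_model(config)
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model


def _mean_val_dice(model: CSFTUNet, pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    images = np.stack([im for im, _ in pairs])
    preds = predict_slices(model, images)
    scores = [multiclass_scores(p, lab)["dice_mean"] for p, (_, lab) in zip(preds, pairs)]
    return float(np.mean(scores))


def train_model(
    model: CSFTUNet,
    train_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    val_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    train_config: TrainConfig | None = None,
    loss_config: LossConfig | None = None,
    checkpoint_path: str | Path | None = None,
    progress: Callable[[int, float, float], None] | None = None,
) -> tuple[CSFTUNet, TrainHistory]:
    """Run the training loop; returns the model and its history.

    ``train_pairs`` / ``val_pairs`` are (image, label) slice pairs:
    image float in [0, 1] of shape (H, W), label uint8 {0, 1, 2} of the
    same shape.  The best-validation-Dice parameters are restored at the
    end (and written to ``checkpoint_path`` when given).

    Raises on an empty train set, and aborts with a diagnostic if the
    loss turns non-finite.
    """
    if not len(train_pairs):
        raise ValueError("empty training set")
    tc = train_config or TrainConfig()
    lc = loss_config or LossConfig()
    rng = np.random.default_rng(tc.seed)
    opt = RMSprop(model.parameters(), lr=tc.lr_init)
    if tc.lr_schedule == "plateau":
        sched = ReduceLROnPlateau(opt, lr_min=tc.lr_min)
    elif tc.lr_schedule == "cosine":
        sched = CosineSchedule(opt, lr_min=tc.lr_min, total=tc.epochs)
    else:
        sched = None

    history = TrainHistory()
    best_dice = -1.0
    best_state = None
    for epoch in range(1, tc.epochs + 1):
        model.train()
        order = rng.permutation(len(train_pairs))
        losses = []
        for start in range(0, len(order), tc.batch_size):
            batch_idx = order[start:start + tc.batch_size]
            imgs, labs = [], []
            for i in batch_idx:
                im, lab = train_pairs[i]
                if tc.augment:
                    im, lab = _augment_pair(im, lab, rng, tc.augment_transforms)
                imgs.append(im)
                labs.append(lab)
            x = Tensor(np.stack(imgs)[:, None].astype(np.float32))
            y = np.stack(labs)
            logits = model(x)
            probs = softmax_channels(logits)
            loss = total_loss(probs, y, lc)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.item()!r}; "
                    "check learning rate and input scaling"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_dice = _mean_val_dice(model, val_pairs) if len(val_pairs) else float("nan")
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_dice.append(val_dice)
        history.lr.append(opt.lr)
        if sched is not None:
            sched.step(val_dice)
        if len(val_pairs) and val_dice > best_dice:
            best_dice = val_dice
            best_state = model.state_dict()
        if progress is not None:
            progress(epoch, history.train_loss[-1], val_dice)

    if best_state is not None:
        model.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return model, history


def evaluate_model(
    model: CSFTUNet,
    test_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
) -> dict:
    """Per-sample and mean Dice/IoU per foreground class on a test set."""
    if not len(test_pairs):
        raise ValueError("empty test set")
    images = np.stack([im for im, _ in test_pairs])
    preds = predict_slices(model, images)
    per_sample = [multiclass_scores(p, lab) for p, (_, lab) in zip(preds, test_pairs)]
    keys = per_sample[0].keys()
    report = {k: float(np.mean([s[k] for s in per_sample])) for k in keys}
    report["n_samples"] = len(per_sample)
    report["per_sample"] = per_sample
    return report
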