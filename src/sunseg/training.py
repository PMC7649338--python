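"""Losses, augmentation and the SGD training loop for both stages.

Stage 1 (nucleus-vs-background) trains with per-pixel binary cross-entropy;
stage 2 (overlap-vs-rest) trains with focal loss, which down-weights the
abundant easy background pixels by the factor (1 - p_t)^gamma. During
stage-2 training the ground-truth semantic mask is supplied as the 4th
input channel (teacher forcing); at inference the stage-1 prediction takes
its place.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np

from .errors import DataError, DivergenceError, ShapeError
from .network import SUNets
from .nn import F32, SGD
from .synthetic import SyntheticSample

EPS = 1e-7
THRESHOLD = 0.5  # probability -> binary mask

AUGMENT_ALL = ("rot90s", "vflip", "hflip")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the reference training recipe
    (SGD, lr 1e-4, momentum 0.9, batch 4, 20 epochs, right-angle rotation
    and flip augmentation)."""

    lr: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 4
    epochs: int = 20
    loss: str = "cross_entropy"
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    seed: int = 0
    augment: tuple[str, ...] = AUGMENT_ALL

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in ("cross_entropy", "focal"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not (0 < self.focal_alpha <= 1):
            raise ValueError("focal_alpha must be in (0, 1]")
        unknown = set(self.augment) - set(AUGMENT_ALL)
        if unknown:
            raise ValueError(f"unknown augmentations: {sorted(unknown)}")


def _check_shapes(prob: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prob.shape != target.shape:
        raise ShapeError(f"prob shape {prob.shape} != target shape {target.shape}")
    return prob, target


def cross_entropy_loss(prob: np.ndarray, target: np.ndarray, eps: float = EPS) -> float:
    """Mean binary cross-entropy -[t log p + (1-t) log(1-p)], p clamped to
    [eps, 1-eps]."""
    prob, target = _check_shapes(prob, target)
    p = np.clip(prob, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def focal_loss(
    prob: np.ndarray,
    target: np.ndarray,
    gamma: float = 2.0,
    alpha: float = 0.25,
    eps: float = EPS,
) -> float:
    """Mean focal loss -alpha_t (1 - p_t)^gamma log(p_t).

    With ``gamma=0, alpha=0.5`` this reduces to half the cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    prob, target = _check_shapes(prob, target)
    p = np.clip(prob, eps, 1.0 - eps)
    pt = np.where(target > 0.5, p, 1.0 - p)
    at = np.where(target > 0.5, alpha, 1.0 - alpha)
    return float(np.mean(-at * (1.0 - pt) ** gamma * np.log(pt)))


def _loss_and_logit_grad(prob: np.ndarray, target: np.ndarray, cfg: TrainConfig):
    """Loss value and its gradient w.r.t. the pre-sigmoid logit."""
    n = prob.size
    if cfg.loss == "cross_entropy":
        loss = cross_entropy_loss(prob, target)
        gz = (prob - target) / n
    else:
        g, a = cfg.focal_gamma, cfg.focal_alpha
        loss = focal_loss(prob, target, gamma=g, alpha=a)
        p = np.clip(prob.astype(np.float64), EPS, 1.0 - EPS)
        t = target.astype(np.float64)
        pt = np.where(t > 0.5, p, 1.0 - p)
        at = np.where(t > 0.5, a, 1.0 - a)
        # dL/dp_t of -a_t (1-p_t)^g log(p_t)
        dpt = at * (g * (1.0 - pt) ** (g - 1.0) * np.log(pt) - (1.0 - pt) ** g / pt)
        sign = np.where(t > 0.5, 1.0, -1.0)
        gz = dpt * sign * prob * (1.0 - prob) / n
    return loss, gz.astype(F32)


_TRANSFORMS = {
    "identity": lambda a: a,
    "rot90": lambda a: np.rot90(a, 1, axes=(0, 1)),
    "rot180": lambda a: np.rot90(a, 2, axes=(0, 1)),
    "rot270": lambda a: np.rot90(a, 3, axes=(0, 1)),
    "vflip": lambda a: a[::-1],
    "hflip": lambda a: a[:, ::-1],
}


def augment_pair(image: np.ndarray, masks, rng: np.random.Generator, config=AUGMENT_ALL):
    """Apply one randomly chosen transform to an (H, W[, C]) image and every
    mask alike. The candidate set is {identity} plus the enabled right-angle
    rotations and flips."""
    names = ["identity"]
    if "rot90s" in config:
        names += ["rot90", "rot180", "rot270"]
    if "vflip" in config:
        names.append("vflip")
    if "hflip" in config:
        names.append("hflip")
    fn = _TRANSFORMS[names[rng.integers(len(names))]]
    return np.ascontiguousarray(fn(image)), [np.ascontiguousarray(fn(m)) for m in masks]


def _sample_inputs(s: SyntheticSample, target_channel: str, rng, augment):
    """Build (input CHW float32 in [0,1], target 1HW float32) for one sample."""
    img = s.image.pixels
    sem = s.semantic_mask
    ovl = s.overlap_mask
    if augment:
        img, (sem, ovl) = augment_pair(img, [sem, ovl], rng, config=augment)
    x = img.astype(F32).transpose(2, 0, 1) / F32(255.0)
    if target_channel == "overlap":
        # teacher forcing: GT semantic mask as the 4th channel
        x = np.concatenate([x, sem.astype(F32)[None]], axis=0)
        t = ovl
    else:
        t = sem
    return x, t.astype(F32)[None]


def train_stage(
    model: SUNets,
    dataset: list[SyntheticSample],
    target_channel: str,
    cfg: TrainConfig,
    log=None,
) -> list[float]:
    """Train one stage in place; returns the per-epoch mean loss history.

    ``target_channel`` selects the learning target: ``"semantic"`` (stage 1,
    3-channel input) or ``"overlap"`` (stage 2, 4-channel input with the
    semantic mask appended).
    """
    if target_channel not in ("semantic", "overlap"):
        raise ValueError("target_channel must be 'semantic' or 'overlap'")
    dataset = list(dataset)
    if not dataset:
        raise DataError("empty training dataset")
    want_c = 4 if target_channel == "overlap" else 3
    if model.cfg.in_channels != want_c:
        raise ShapeError(
            f"model has {model.cfg.in_channels} input channels; "
            f"target '{target_channel}' needs {want_c}"
        )
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.params(), lr=cfg.lr, momentum=cfg.momentum)
    history: list[float] = []
    n = len(dataset)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xs, ts = zip(*(_sample_inputs(dataset[i], target_channel, rng, cfg.augment) for i in idx))
            x = np.stack(xs)
            t = np.stack(ts)
            prob = model.forward(x, train=True)
            loss, gz = _loss_and_logit_grad(prob, t, cfg)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch + 1}", epoch=epoch + 1, history=history
                )
            opt.zero_grad()
            model.backward(gz)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if log:
            out = log if hasattr(log, "write") else sys.stderr
            print(f"epoch {epoch + 1}/{cfg.epochs} {target_channel} loss {history[-1]:.5f}",
                  file=out)
    return history
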