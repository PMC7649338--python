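"""Stacked U-Nets: four scale-specific encoder-decoder backbones fused by an
attention generation module (AGM).

Each backbone is a VGG-style U-Net: blocks of two same-padded 3x3
convolutions with ReLU and 2x2 max pooling on the way down, 2x2
transposed-convolution upsampling with skip copy-and-concatenation on the
way up, and a 1x1 logit head. The four backbones see the input resampled at
the fixed scale factors 1.25x, 1.0x, 0.75x and 0.5x and have independent
parameters. Their logit maps, resampled back to the base resolution, are
concatenated and fed to the AGM - eight 3x3 convolutions arranged as
ResNet-style residual blocks plus ReLU - which emits one weight map per
backbone; a per-pixel softmax turns these into a convex combination, and the
fused logit is the weighted sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ShapeError
from .nn import F32

PYRAMID_FACTORS: tuple[float, ...] = (1.25, 1.0, 0.75, 0.5)


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture of one scale-specific backbone net.

    ``base_width`` is the channel count of the first convolution block;
    widths double at each of the ``depth`` pooling stages, capped at
    ``8 * base_width`` (the VGG16 pattern). Spatial size is preserved
    end-to-end, so the input side length must be divisible by ``2**depth``.
    """

    in_channels: int = 3
    base_width: int = 16
    depth: int = 4

    def __post_init__(self) -> None:
        if self.in_channels not in (3, 4):
            raise ValueError("in_channels must be 3 or 4")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")

    @property
    def widths(self) -> list[int]:
        cap = 8 * self.base_width
        return [min(self.base_width * 2**i, cap) for i in range(self.depth + 1)]


class _Concat(nn.Layer):
    """Channel concatenation of two inputs (skip, upsampled)."""

    def __init__(self) -> None:
        self._split = 0

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        self._split = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return gy[:, : self._split], gy[:, self._split :]


class UNetBackbone(nn.Layer):
    """Encoder-decoder with skip connections and a 1-channel logit head."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        w = cfg.widths
        self.enc: list[nn.Sequential] = []
        cin = cfg.in_channels
        for i in range(cfg.depth):
            self.enc.append(
                nn.Sequential(
                    nn.Conv2d(cin, w[i], 3, rng), nn.ReLU(),
                    nn.Conv2d(w[i], w[i], 3, rng), nn.ReLU(),
                )
            )
            cin = w[i]
        self.pools = [nn.MaxPool2x2() for _ in range(cfg.depth)]
        self.bottleneck = nn.Sequential(
            nn.Conv2d(w[cfg.depth - 1], w[cfg.depth], 3, rng), nn.ReLU(),
            nn.Conv2d(w[cfg.depth], w[cfg.depth], 3, rng), nn.ReLU(),
        )
        self.ups: list[nn.ConvTranspose2x2] = []
        self.dec: list[nn.Sequential] = []
        self.concats = [_Concat() for _ in range(cfg.depth)]
        prev = w[cfg.depth]
        for i in reversed(range(cfg.depth)):
            self.ups.append(nn.ConvTranspose2x2(prev, w[i], rng))
            self.dec.append(
                nn.Sequential(
                    nn.Conv2d(2 * w[i], w[i], 3, rng), nn.ReLU(),
                    nn.Conv2d(w[i], w[i], 3, rng), nn.ReLU(),
                )
            )
            prev = w[i]
        self.head = nn.Conv2d(w[0], 1, 1, rng)

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for up, blk in zip(self.ups, self.dec):
            out += up.params()
            out += blk.params()
        out += self.head.params()
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        d = self.cfg.depth
        h, w = x.shape[2:]
        if h % 2**d or w % 2**d:
            raise ShapeError(
                f"input size {h}x{w} not divisible by 2^depth = {2**d}"
            )
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        for i, (up, cat, blk) in enumerate(zip(self.ups, self.concats, self.dec)):
            x = blk.forward(cat.forward(skips[d - 1 - i], up.forward(x)))
        return self.head.forward(x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        d = self.cfg.depth
        g = self.head.backward(gy)
        gskips: list[np.ndarray | None] = [None] * d
        for i in reversed(range(d)):
            g = self.dec[i].backward(g)
            gskip, gup = self.concats[i].backward(g)
            gskips[d - 1 - i] = gskip
            g = self.ups[i].backward(gup)
        g = self.bottleneck.backward(g)
        for i in reversed(range(d)):
            g = self.pools[i].backward(g)
            g = g + gskips[i]
            g = self.enc[i].backward(g)
        return g


class _ResidualBlock(nn.Layer):
    """Two 3x3 convolutions with an identity skip (ResNet basic block)."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.c1 = nn.Conv2d(width, width, 3, rng)
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(width, width, 3, rng)
        self.rout = nn.ReLU()

    def params(self) -> list[nn.Param]:
        return self.c1.params() + self.c2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.c2.forward(self.r1.forward(self.c1.forward(x)))
        return self.rout.forward(y + x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.rout.backward(gy)
        gx = self.c1.backward(self.r1.backward(self.c2.backward(g)))
        return gx + g


class AttentionGenerationModule(nn.Layer):
    """Produces per-pixel logits for the four backbone weight maps.

    A stem convolution lifts the four concatenated prediction maps to
    ``width`` channels; eight 3x3 convolutions follow, arranged as four
    residual basic blocks (two ResNet-34-style stages of two blocks each);
    a 1x1 head maps back to four channels. The caller normalizes the output
    with a per-pixel softmax so the weights form a convex combination.
    """

    def __init__(self, width: int, rng: np.random.Generator, n_nets: int = 4):
        if n_nets != 4:
            raise ValueError("the stacked U-Nets fuse exactly 4 backbone nets")
        self.n_nets = n_nets
        self.stem = nn.Conv2d(n_nets, width, 3, rng)
        self.stem_relu = nn.ReLU()
        self.blocks = [_ResidualBlock(width, rng) for _ in range(4)]
        self.head = nn.Conv2d(width, n_nets, 1, rng)

    def params(self) -> list[nn.Param]:
        out = self.stem.params()
        for b in self.blocks:
            out += b.params()
        return out + self.head.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.n_nets:
            raise ShapeError(f"AGM expects {self.n_nets} input maps, got {x.shape[1]}")
        x = self.stem_relu.forward(self.stem.forward(x))
        for b in self.blocks:
            x = b.forward(x)
        return self.head.forward(x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.head.backward(gy)
        for b in reversed(self.blocks):
            g = b.backward(g)
        return self.stem.backward(self.stem_relu.backward(g))


class _PadCrop:
    """Reflect-pads a level to the next multiple of ``2**depth`` and crops
    the logits back; gradient flows through the reflected indices."""

    def __init__(self, hw: tuple[int, int], multiple: int):
        self.hw = hw
        ph = (-hw[0]) % multiple
        pw = (-hw[1]) % multiple
        self.ridx = np.pad(np.arange(hw[0]), (0, ph), mode="reflect")
        self.cidx = np.pad(np.arange(hw[1]), (0, pw), mode="reflect")
        self.padded_hw = (hw[0] + ph, hw[1] + pw)

    @property
    def identity(self) -> bool:
        return self.padded_hw == self.hw

    def pad(self, x: np.ndarray) -> np.ndarray:
        if self.identity:
            return x
        return np.ascontiguousarray(x[:, :, self.ridx][:, :, :, self.cidx])

    def crop(self, y: np.ndarray) -> np.ndarray:
        if self.identity:
            return y
        return np.ascontiguousarray(y[:, :, : self.hw[0], : self.hw[1]])

    def crop_backward(self, gy: np.ndarray) -> np.ndarray:
        if self.identity:
            return gy
        g = np.zeros(gy.shape[:2] + self.padded_hw, dtype=F32)
        g[:, :, : self.hw[0], : self.hw[1]] = gy
        return g

    def pad_backward(self, gxp: np.ndarray) -> np.ndarray:
        if self.identity:
            return gxp
        n, c = gxp.shape[:2]
        t = np.zeros((self.hw[0], n, c, gxp.shape[3]), dtype=F32)
        np.add.at(t, self.ridx, gxp.transpose(2, 0, 1, 3))
        g = np.zeros((self.hw[1], n, c, self.hw[0]), dtype=F32)
        np.add.at(g, self.cidx, t.transpose(3, 1, 2, 0))
        return np.ascontiguousarray(g.transpose(1, 2, 3, 0))


class SUNets:
    """Four parallel scale-specific backbones fused by the AGM.

    ``forward`` consumes a float32 ``(N, C, S, S)`` batch with channels in
    [0, 1] (a binary mask as channel 3 for the 4-channel stage) and returns
    per-pixel foreground probabilities ``(N, 1, S, S)``. ``backward``
    consumes the loss gradient w.r.t. the fused logit.
    """

    def __init__(
        self,
        cfg: BackboneConfig,
        seed: int = 0,
        factors: tuple[float, ...] = PYRAMID_FACTORS,
    ):
        self.cfg = cfg
        self.factors = tuple(factors)
        rng = np.random.default_rng(seed)
        self.backbones = [UNetBackbone(cfg, rng) for _ in self.factors]
        self.agm = AttentionGenerationModule(cfg.base_width, rng, n_nets=len(self.factors))
        self._resize_cache: dict[tuple[int, int], nn.BilinearResize] = {}
        self._cache: dict | None = None

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for b in self.backbones:
            out += b.params()
        return out + self.agm.params()

    # -- forward / backward -------------------------------------------------

    def _level_resize(self, in_hw: tuple[int, int], out_hw: tuple[int, int]) -> nn.BilinearResize:
        key = in_hw + out_hw
        if key not in self._resize_cache:
            self._resize_cache[key] = nn.BilinearResize(in_hw, out_hw)
        return self._resize_cache[key]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ShapeError(
                f"expected (N, {self.cfg.in_channels}, S, S) input, got {x.shape}"
            )
        if x.shape[2] != x.shape[3]:
            raise ShapeError("stacked U-Nets expect square patches")
        s = x.shape[2]
        mult = 2 ** self.cfg.depth
        x = x.astype(F32, copy=False)
        grad_ctx = nn.no_grad() if not train else None
        if grad_ctx is not None:
            grad_ctx.__enter__()
        level_logits = []
        padcrops = []
        for k, f in enumerate(self.factors):
            sk = int(round(s * f))
            xk = nn.resize_bilinear(x[:, :3], (sk, sk))
            if self.cfg.in_channels == 4:
                mk = nn.resize_nearest(x[:, 3:4], (sk, sk))
                xk = np.concatenate([xk, mk.astype(F32)], axis=1)
            pc = _PadCrop((sk, sk), mult)
            zk = pc.crop(self.backbones[k].forward(pc.pad(xk)))
            padcrops.append(pc)
            level_logits.append(self._level_resize((sk, sk), (s, s)).forward(zk))
        zs = np.concatenate(level_logits, axis=1)  # (N, 4, S, S)
        a = self.agm.forward(zs)
        w = nn.softmax_channels(a)
        z = (w * zs).sum(axis=1, keepdims=True)
        self._last_weights = w
        if train:
            self._cache = {"zs": zs, "w": w, "s": s, "padcrops": padcrops}
        else:
            self._cache = None
            grad_ctx.__exit__(None, None, None)
        return nn.sigmoid(z)

    def backward(self, gz: np.ndarray) -> None:
        """Backpropagate the gradient w.r.t. the fused logit into all params."""
        c = self._cache
        if c is None:
            raise RuntimeError("forward(train=True) must precede backward")
        zs, w, s = c["zs"], c["w"], c["s"]
        gw = gz * zs
        gzs = gz * w
        ga = w * (gw - (w * gw).sum(axis=1, keepdims=True))
        gzs = gzs + self.agm.backward(ga)
        for k, f in enumerate(self.factors):
            sk = int(round(s * f))
            gk = self._level_resize((sk, sk), (s, s)).backward(gzs[:, k : k + 1])
            pc = c["padcrops"][k]
            gk = pc.crop_backward(gk)
            # gradient w.r.t. the resampled input is discarded (input is data)
            self.backbones[k].backward(gk)
        self._cache = None

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel fusion weights (N, 4, H, W); sums to 1 over axis 1."""
        self.forward(x)
        return self._last_weights


def build_backbone(cfg: BackboneConfig, seed: int = 0) -> UNetBackbone:
    """Construct one scale-specific U-Net backbone."""
    return UNetBackbone(cfg, np.random.default_rng(seed))


def build_agm(n_nets: int = 4, width: int = 16, seed: int = 0) -> AttentionGenerationModule:
    """Construct the attention generation module for ``n_nets`` backbones."""
    return AttentionGenerationModule(width, np.random.default_rng(seed), n_nets=n_nets)


def build_sunets(
    in_channels: int = 3, base_width: int = 16, depth: int = 4, seed: int = 0
) -> SUNets:
    return SUNets(BackboneConfig(in_channels, base_width, depth), seed=seed)


def sunets_forward(patch: np.ndarray, model: SUNets) -> np.ndarray:
    """Run one (H, W, C) uint8 patch through the model; returns an (H, W)
    probability map in [0, 1]. Channel 3, if present, must be binary {0, 1}
    or {0, 255} and is passed through as the stage-2 mask channel."""
    if patch.ndim != 3 or patch.shape[2] != model.cfg.in_channels:
        raise ShapeError(
            f"expected (H, W, {model.cfg.in_channels}) patch, got {patch.shape}"
        )
    x = patch.astype(F32).transpose(2, 0, 1)[None]
    x[:, :3] /= 255.0
    if x.shape[1] == 4:
        x[:, 3] = (x[:, 3] > 0).astype(F32)
    return model.forward(x)[0, 0]


# -- serialization ----------------------------------------------------------

def save_model(path, model: SUNets) -> None:
    """Save parameters and architecture to an .npz checkpoint."""
    meta = {
        "in_channels": model.cfg.in_channels,
        "base_width": model.cfg.base_width,
        "depth": model.cfg.depth,
        "factors": list(model.factors),
    }
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> SUNets:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        model = SUNets(
            BackboneConfig(meta["in_channels"], meta["base_width"], meta["depth"]),
            factors=tuple(meta["factors"]),
        )
        for i, p in enumerate(model.params()):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ShapeError(f"checkpoint parameter {i} has shape {arr.shape}")
            p.data[...] = arr
    return model
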