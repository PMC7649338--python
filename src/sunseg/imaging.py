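"""Image and label-map I/O, patch tiling/stitching, and scale pyramids.

Conventions: 0-based (row, col) coordinates, (H, W) shapes, half-open
intervals. RGB images are 8-bit PNG/TIFF; instance label maps are 16-bit
single-channel PNG/TIFF with 0 = background. Border tiles are shifted
inward (never zero-padded) so every patch contains real pixels; stitching
averages wherever patches overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import nn
from .errors import CoverageError, FormatError, ShapeError, SizeError

DEFAULT_PATCH_SIZE = 384
PYRAMID_FACTORS: tuple[float, ...] = (1.25, 1.0, 0.75, 0.5)


@dataclass
class RgbPatch:
    """An 8-bit RGB patch plus its (row, col) offset in the source image."""

    pixels: np.ndarray
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ShapeError(f"RgbPatch needs an (H, W, 3) array, got {p.shape}")
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise ShapeError("RgbPatch must be non-empty")
        self.pixels = p.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class InstanceLabelMap:
    """Instance segmentation stored as per-object masks.

    Pixels may belong to several objects (overlapping nuclei); the flattened
    integer rendering assigns shared pixels to the lowest label id.
    """

    shape: tuple[int, int]
    objects: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        objs = []
        for label_id, mask in self.objects:
            label_id = int(label_id)
            if label_id <= 0:
                raise ShapeError("label ids must be positive integers")
            if label_id in seen:
                raise ShapeError(f"duplicate label id {label_id}")
            seen.add(label_id)
            mask = np.asarray(mask).astype(bool)
            if mask.shape != tuple(self.shape):
                raise ShapeError(
                    f"object {label_id} mask shape {mask.shape} != map shape {self.shape}"
                )
            if not mask.any():
                raise ShapeError(f"object {label_id} has an empty mask")
            objs.append((label_id, mask))
        self.objects = objs
        self.shape = tuple(self.shape)

    def __len__(self) -> int:
        return len(self.objects)

    @classmethod
    def from_flat(cls, labels: np.ndarray) -> "InstanceLabelMap":
        labels = np.asarray(labels)
        ids = np.unique(labels)
        objs = [(int(i), labels == i) for i in ids if i > 0]
        return cls(shape=labels.shape, objects=objs)

    def to_flat(self, dtype=np.uint16) -> np.ndarray:
        """Flattened integer view; shared pixels take the lowest label id."""
        out = np.zeros(self.shape, dtype=np.int64)
        for label_id, mask in sorted(self.objects, key=lambda o: -o[0]):
            out[mask] = label_id
        return out.astype(dtype)

    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for _, mask in self.objects:
            out |= mask
        return out

    def overlap_mask(self) -> np.ndarray:
        """Pixels covered by two or more objects."""
        count = np.zeros(self.shape, dtype=np.int32)
        for _, mask in self.objects:
            count += mask
        return count >= 2


@dataclass
class ScalePyramid:
    """The four rescaled copies of a patch at factors 1.25, 1.0, 0.75, 0.5."""

    levels: list[tuple[float, np.ndarray]]


def read_image(path) -> RgbPatch:
    """Read a PNG/TIFF as an RGB patch.

    Grayscale is replicated to 3 channels; an alpha channel is dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        if arr.dtype == np.uint16:
            arr = (arr // 257).astype(np.uint8)
        else:
            raise FormatError(f"unsupported bit depth {arr.dtype} in {path}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"unsupported channel layout {arr.shape} in {path}")
    return RgbPatch(pixels=arr, origin=(0, 0))


def write_image(path, patch: RgbPatch | np.ndarray) -> None:
    arr = patch.pixels if isinstance(patch, RgbPatch) else np.asarray(patch)
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_label_map(path) -> InstanceLabelMap:
    """Read a 16-bit single-channel label image (0 = background)."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read label map {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"label map must be single-channel, got {arr.shape} in {path}")
    return InstanceLabelMap.from_flat(arr)


def write_label_map(path, labels: InstanceLabelMap | np.ndarray) -> None:
    arr = labels.to_flat() if isinstance(labels, InstanceLabelMap) else np.asarray(labels)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise FormatError("more than 65535 labels cannot be stored as 16-bit")
    iio.imwrite(Path(path), arr.astype(np.uint16))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (np.asarray(mask).astype(bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def _tile_starts(extent: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, extent - patch + 1, stride))
    if starts[-1] != extent - patch:
        starts.append(extent - patch)  # shift the border tile inward
    return starts


def tile_patches(image: RgbPatch | np.ndarray, patch_size: int, stride: int | None = None):
    """Cover an image with ``patch_size`` tiles; border tiles shift inward.

    Returns a list of patches carrying their origins. Works on an
    ``RgbPatch`` (returns ``RgbPatch``) or a raw H×W[×C] array (returns
    ``(array, origin)`` tuples).
    """
    if stride is None:
        stride = patch_size
    if patch_size < 1 or stride < 1 or stride > patch_size:
        raise SizeError("need patch_size >= 1 and 1 <= stride <= patch_size")
    as_patch = isinstance(image, RgbPatch)
    arr = image.pixels if as_patch else np.asarray(image)
    h, w = arr.shape[:2]
    if h < patch_size or w < patch_size:
        raise SizeError(f"image {h}x{w} smaller than patch size {patch_size}")
    out = []
    for r in _tile_starts(h, patch_size, stride):
        for c in _tile_starts(w, patch_size, stride):
            crop = arr[r : r + patch_size, c : c + patch_size]
            out.append(
                RgbPatch(crop, (r, c)) if as_patch else (crop.copy(), (r, c))
            )
    return out


def stitch_patches(pieces, out_shape: tuple[int, int]) -> np.ndarray:
    """Reassemble per-patch maps into one map, averaging overlaps.

    ``pieces`` is an iterable of ``(map, origin)``; every output pixel must
    be covered by at least one piece.
    """
    h, w = out_shape
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.int64)
    for arr, (r, c) in pieces:
        arr = np.asarray(arr)
        ph, pw = arr.shape[:2]
        if r < 0 or c < 0 or r + ph > h or c + pw > w:
            raise CoverageError(
                f"piece at ({r}, {c}) size {ph}x{pw} extends past canvas {h}x{w}"
            )
        acc[r : r + ph, c : c + pw] += arr
        cnt[r : r + ph, c : c + pw] += 1
    if (cnt == 0).any():
        raise CoverageError(f"{int((cnt == 0).sum())} pixels not covered by any piece")
    return acc / cnt


def build_pyramid(
    patch: RgbPatch | np.ndarray,
    factors: tuple[float, ...] = PYRAMID_FACTORS,
    binary_channels: tuple[int, ...] = (3,),
) -> ScalePyramid:
    """Resample a square patch at the four fixed scale factors.

    Continuous channels are resampled bilinearly; channels listed in
    ``binary_channels`` (the stage-2 mask channel) use nearest-neighbour so
    they stay binary.
    """
    arr = patch.pixels if isinstance(patch, RgbPatch) else np.asarray(patch)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    h, w = arr.shape[:2]
    if h != w:
        raise ShapeError(f"pyramid base patch must be square, got {h}x{w}")
    chw = arr.transpose(2, 0, 1)[None].astype(np.float32)
    levels = []
    for f in factors:
        size = int(round(h * f))
        lvl = nn.resize_bilinear(chw, (size, size))[0]
        for ch in binary_channels:
            if ch < arr.shape[2]:
                lvl[ch] = nn.resize_nearest(chw[0, ch][None], (size, size))[0]
        out = np.clip(np.rint(lvl), 0, 255).astype(np.uint8).transpose(1, 2, 0)
        levels.append((f, out if out.shape[2] > 1 else out[:, :, 0]))
    return ScalePyramid(levels=levels)
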