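"""Synthetic H&E-like scenes of overlapping elliptical nuclei.

The generator draws filled, rotated ellipses on a stain-colored background
and composes colors subtractively: each nucleus attenuates the background
toward the hematoxylin-like nucleus color, so pixels covered by two nuclei
come out darker than either nucleus alone — the visual cue (as in a real
stain, where stacked chromatin absorbs more light) that makes overlap
regions learnable. Ground truth is exact: per-nucleus masks, their union
(the semantic target) and the pixels covered by >= 2 nuclei (the overlap
target).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .errors import GenerationError, SunsegError
from .imaging import (
    InstanceLabelMap,
    RgbPatch,
    write_image,
    write_label_map,
    write_mask,
)

_MAX_TRIES = 200


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``overlap_fraction`` is the probability that each nucleus after the
    first is deliberately placed within one diameter of an existing nucleus
    so their masks intersect; the remaining nuclei are placed pairwise
    disjoint. Colors are mean RGB triples; each nucleus jitters its color
    slightly and Gaussian pixel noise with std ``noise_sd`` is added last.
    """

    canvas: tuple[int, int] = (64, 64)
    n_nuclei: int = 6
    radius_range: tuple[float, float] = (5.0, 9.0)
    overlap_fraction: float = 0.3
    nucleus_color: tuple[float, float, float] = (90.0, 60.0, 150.0)
    background_color: tuple[float, float, float] = (230.0, 200.0, 215.0)
    color_jitter_sd: float = 8.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        rmin, rmax = self.radius_range
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise SunsegError("overlap_fraction must be in [0, 1]")
        if not (0 < rmin <= rmax):
            raise SunsegError("radius_range must be positive and ordered")
        for c in (*self.nucleus_color, *self.background_color):
            if not (0 <= c <= 255):
                raise SunsegError("colors must be in [0, 255]")
        if self.canvas[0] < 2 * rmax + 2 or self.canvas[1] < 2 * rmax + 2:
            raise SunsegError("canvas too small to hold one max-radius nucleus")


@dataclass
class SyntheticSample:
    """One generated scene with its full ground truth."""

    image: RgbPatch
    instances: InstanceLabelMap
    semantic_mask: np.ndarray
    overlap_mask: np.ndarray


def _ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    rr, cc = _draw_ellipse(center[0], center[1], axes[0], axes[1], shape=shape, rotation=angle)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def generate_sample(spec: SceneSpec) -> SyntheticSample:
    """Generate one scene; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    rmin, rmax = spec.radius_range
    placed: list[dict] = []  # center, axes (a >= b), angle, mask

    for i in range(spec.n_nuclei):
        want_overlap = i > 0 and rng.random() < spec.overlap_fraction
        ok = False
        for _ in range(_MAX_TRIES):
            axes = np.sort(rng.uniform(rmin, rmax, size=2))[::-1]  # (major, minor)
            angle = rng.uniform(0.0, np.pi)
            margin = axes[0] + 1.0
            if want_overlap:
                anchor = placed[rng.integers(len(placed))]
                # center within one (minor-axis) diameter; distance below the
                # sum of minor semi-axes guarantees mask intersection
                dist = rng.uniform(0.35, 0.9) * (anchor["axes"][1] + axes[1])
                theta = rng.uniform(0.0, 2 * np.pi)
                center = (
                    anchor["center"][0] + dist * np.sin(theta),
                    anchor["center"][1] + dist * np.cos(theta),
                )
                if not (margin <= center[0] <= h - 1 - margin and margin <= center[1] <= w - 1 - margin):
                    continue
            else:
                center = (
                    rng.uniform(margin, h - 1 - margin),
                    rng.uniform(margin, w - 1 - margin),
                )
            mask = _ellipse_mask((h, w), center, axes, angle)
            if not mask.any():
                continue
            if want_overlap:
                if not (mask & anchor["mask"]).any():
                    continue
            else:
                if any((mask & p["mask"]).any() for p in placed):
                    continue
            placed.append({"center": center, "axes": axes, "angle": angle, "mask": mask})
            ok = True
            break
        if not ok:
            raise GenerationError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei} after "
                f"{_MAX_TRIES} tries; achieved {len(placed)}"
            )

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_color
    attenuation_base = np.asarray(spec.background_color) - np.asarray(spec.nucleus_color)
    for p in placed:
        jitter = rng.normal(0.0, spec.color_jitter_sd, size=3)
        img[p["mask"]] -= attenuation_base + jitter
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = RgbPatch(np.clip(np.rint(img), 0, 255).astype(np.uint8))

    instances = InstanceLabelMap(
        shape=(h, w), objects=[(i + 1, p["mask"]) for i, p in enumerate(placed)]
    )
    return SyntheticSample(
        image=image,
        instances=instances,
        semantic_mask=instances.union_mask(),
        overlap_mask=instances.overlap_mask(),
    )


def sample_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample seed derived from the master seed."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % 2**31)


def generate_batch(spec: SceneSpec, n_images: int) -> list[SyntheticSample]:
    """Generate ``n_images`` samples in memory with derived per-sample seeds."""
    from dataclasses import replace

    return [
        generate_sample(replace(spec, seed=sample_seed(spec.seed, i)))
        for i in range(n_images)
    ]


def generate_dataset(spec: SceneSpec, n_images: int, out_dir) -> Path:
    """Write a dataset to disk and return the manifest path.

    Per sample: ``<id>_image.png``, ``<id>_instances.png`` (16-bit flattened
    labels, lowest id wins on shared pixels), ``<id>_semantic.png`` and
    ``<id>_overlap.png`` (0/255 masks), plus one ``manifest.csv``.
    """
    from dataclasses import replace

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_images):
        sid = f"sample_{i:04d}"
        s = generate_sample(replace(spec, seed=sample_seed(spec.seed, i)))
        paths = {
            "image": f"{sid}_image.png",
            "instances": f"{sid}_instances.png",
            "semantic": f"{sid}_semantic.png",
            "overlap": f"{sid}_overlap.png",
        }
        write_image(out_dir / paths["image"], s.image)
        write_label_map(out_dir / paths["instances"], s.instances)
        write_mask(out_dir / paths["semantic"], s.semantic_mask)
        write_mask(out_dir / paths["overlap"], s.overlap_mask)
        rows.append(
            {
                "sample_id": sid,
                **paths,
                "n_nuclei": len(s.instances),
                "n_overlap_pixels": int(s.overlap_mask.sum()),
                "seed": sample_seed(spec.seed, i),
            }
        )
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()) if rows else ["sample_id"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest
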