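"""Instance extraction and overlap merging downstream of the two networks.

Stage 1's binary nucleus mask is split into instances with a marker-based
watershed on the Euclidean distance transform. Stage 2's binary overlap
mask is decomposed into 8-connected components; each component is unioned
into every watershed instance it intersects by at least ``min_overlap``
pixels (default 10), so pixels in an overlap region may end up belonging to
several final instances — the representation of two nuclei sharing pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import ShapeError
from .imaging import InstanceLabelMap, RgbPatch

MIN_OVERLAP_PIXELS = 10  # merge threshold: "at least 10 overlapped pixels"
DEFAULT_MIN_SIZE = 20
DEFAULT_MARKER_H = 0.5


@dataclass
class OverlapComponents:
    """8-connected components of the predicted overlap mask."""

    components: list[tuple[int, np.ndarray]]


def watershed_instances(
    mask: np.ndarray,
    min_size: int = DEFAULT_MIN_SIZE,
    marker_h: float = DEFAULT_MARKER_H,
) -> InstanceLabelMap:
    """Split a binary nucleus mask into disjoint instances.

    Markers are the h-maxima of the Euclidean distance transform — maxima
    whose prominence over the surrounding saddle exceeds ``marker_h``
    pixels — so one marker forms per nucleus core regardless of how unequal
    the fused nuclei are, while the flat distance ridge of a single
    elongated nucleus stays one marker. The watershed then floods the
    negated distance restricted to the mask; objects below ``min_size``
    pixels are dropped.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return InstanceLabelMap(shape=mask.shape, objects=[])
    dist = ndi.distance_transform_edt(mask)
    markers = cc_label(h_maxima(dist, marker_h), connectivity=2)
    seg = watershed(-dist, markers=markers, mask=mask)
    objects = []
    next_id = 1
    for lab in range(1, seg.max() + 1):
        m = seg == lab
        if m.sum() >= min_size:
            objects.append((next_id, m))
            next_id += 1
    return InstanceLabelMap(shape=mask.shape, objects=objects)


def make_stage2_input(patch: RgbPatch | np.ndarray, stage1_mask: np.ndarray) -> np.ndarray:
    """Concatenate the RGB patch with the stage-1 mask as a 4th channel.

    The mask channel is scaled to {0, 255} so all channels share the 8-bit
    intensity range.
    """
    rgb = patch.pixels if isinstance(patch, RgbPatch) else np.asarray(patch)
    stage1_mask = np.asarray(stage1_mask)
    if rgb.shape[:2] != stage1_mask.shape:
        raise ShapeError(
            f"patch {rgb.shape[:2]} and mask {stage1_mask.shape} shapes differ"
        )
    ch4 = (stage1_mask.astype(bool) * np.uint8(255))[:, :, None]
    return np.concatenate([rgb.astype(np.uint8), ch4], axis=2)


def extract_overlap_components(overlap_mask: np.ndarray) -> OverlapComponents:
    """8-connected components of a binary overlap mask."""
    overlap_mask = np.asarray(overlap_mask).astype(bool)
    labeled = cc_label(overlap_mask, connectivity=2)
    comps = [(int(i), labeled == i) for i in range(1, labeled.max() + 1)]
    return OverlapComponents(components=comps)


def merge_overlaps(
    instances: InstanceLabelMap,
    overlaps: OverlapComponents,
    min_overlap: int = MIN_OVERLAP_PIXELS,
) -> InstanceLabelMap:
    """Union each overlap component into every instance it sufficiently hits.

    A component is added to every instance it intersects by at least
    ``min_overlap`` pixels (so its pixels may join several instances);
    components hitting no instance that hard are discarded. No pixel is ever
    removed from an instance.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    masks = {lid: m.copy() for lid, m in instances.objects}
    for _, comp in overlaps.components:
        if comp.shape != tuple(instances.shape):
            raise ShapeError(
                f"component shape {comp.shape} != instance map shape {instances.shape}"
            )
        for lid, m in instances.objects:
            if int((comp & m).sum()) >= min_overlap:
                masks[lid] |= comp
    return InstanceLabelMap(
        shape=instances.shape, objects=[(lid, masks[lid]) for lid, _ in instances.objects]
    )
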