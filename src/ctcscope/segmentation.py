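"""Fluorescent-object detection: per-channel thresholding + event merging.

Each channel of each frame is segmented independently with an adaptive
global threshold (triangle method by default, with a floor at the estimated
background level plus three noise standard deviations, both taken robustly
from the frame median/MAD).  Connected components below a minimum area are
discarded.

Components from different channels are then merged into candidate *events*:
two components belong to the same event when their footprints overlap or
approach within a configurable dilation radius (default 1 pixel, Chebyshev),
with transitive closure.  A DAPI nucleus therefore joins its surrounding CK
ring even across a 1-pixel thresholding gap.  Events must contain signal in
at least one *seed* channel (CK or DAPI by default); groups made of
exclusion-channel signal only (CD45, FITC) are dropped, since those channels
only ever contribute intensity measurements.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label as cc_label

from .core import (
    CartridgeError,
    CartridgeStack,
    DetectedObject,
    PHYSICAL_FOR_LOGICAL,
)

#: Channels segmented for event formation (m1 is virtual and always empty).
SEGMENTED_CHANNELS = ("dapi", "ck", "cd45", "m2")


@dataclass
class SegmentationParams:
    """Segmentation and merging parameters.

    threshold_method : "triangle" (default) or "otsu".
    min_area : components with fewer pixels are removed (default 4).
    noise_floor_k : threshold floor = median + k * MAD-based noise SD.
    dilation_radius : Chebyshev distance within which components of
        different channels are merged into one event.
    seed_channels : an event must contain at least one component from
        these channels.
    """

    threshold_method: str = "triangle"
    min_area: int = 4
    noise_floor_k: float = 3.0
    dilation_radius: int = 1
    seed_channels: tuple[str, ...] = ("ck", "dapi")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def segment_channel(
    image: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Label fluorescent objects in a single-channel frame.

    Returns an int32 label mask (0 = background).  A constant image yields
    an empty mask; that is a valid result, not an error.
    """
    if params is None:
        params = SegmentationParams()
    image = np.asarray(image)
    if image.ndim != 2:
        raise CartridgeError(f"expected a 2-D image, got shape {image.shape}")
    if image.size and float(image.min()) < 0:
        raise CartridgeError("negative intensities in channel image")
    img = image.astype(float)
    if img.max() == img.min():
        return np.zeros(image.shape, dtype=np.int32)

    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    floor = med + params.noise_floor_k * 1.4826 * mad
    if params.threshold_method == "triangle":
        thr = float(threshold_triangle(img))
    elif params.threshold_method == "otsu":
        thr = float(threshold_otsu(img))
    else:
        raise CartridgeError(
            f"unknown threshold method {params.threshold_method!r}"
        )
    thr = max(thr, floor)

    mask = img > thr
    labels = cc_label(mask, connectivity=2).astype(np.int32)
    if params.min_area > 1 and labels.max():
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < params.min_area)
        if small.size:
            labels[np.isin(labels, small)] = 0
        # relabel compactly for stable ids
        labels = cc_label(labels > 0, connectivity=2).astype(np.int32)
    return labels


@dataclass
class _Component:
    channel: str
    bbox: tuple[int, int, int, int]  # half-open
    mask: np.ndarray  # bbox-shaped bool


def _components(labels: np.ndarray, channel: str) -> list[_Component]:
    comps = []
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        rs, cs = sl
        comps.append(
            _Component(
                channel=channel,
                bbox=(rs.start, rs.stop, cs.start, cs.stop),
                mask=labels[sl] == i,
            )
        )
    return comps


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _gap_within(a: _Component, b: _Component, radius: int) -> bool:
    """True when at most ``radius`` background pixels (Chebyshev) separate
    the two footprints, i.e. a 1-pixel thresholding gap merges at the
    default radius 1."""
    reach = radius + 1  # centre distance <= radius + 1
    ar0, ar1, ac0, ac1 = a.bbox
    br0, br1, bc0, bc1 = b.bbox
    if (
        ar0 > br1 + reach
        or br0 > ar1 + reach
        or ac0 > bc1 + reach
        or bc0 > ac1 + reach
    ):
        return False
    r0 = min(ar0, br0) - reach
    c0 = min(ac0, bc0) - reach
    r1 = max(ar1, br1) + reach
    c1 = max(ac1, bc1) + reach
    h, w = r1 - r0, c1 - c0
    ca = np.zeros((h, w), dtype=bool)
    cb = np.zeros((h, w), dtype=bool)
    ca[ar0 - r0 : ar1 - r0, ac0 - c0 : ac1 - c0] = a.mask
    cb[br0 - r0 : br1 - r0, bc0 - c0 : bc1 - c0] = b.mask
    ca = ndimage.binary_dilation(
        ca, structure=np.ones((2 * reach + 1, 2 * reach + 1), bool)
    )
    return bool((ca & cb).any())


def merge_events(
    channel_labels: dict[str, np.ndarray],
    frame_index: int = 0,
    params: SegmentationParams | None = None,
    id_offset: int = 0,
) -> list[DetectedObject]:
    """Merge per-channel label masks of one frame into DetectedObjects.

    ``channel_labels`` maps logical channel names to label masks of equal
    shape.  Merging is transitive; events are sorted by the top-left corner
    of their bounding box for stable ids (offset by ``id_offset``).
    """
    if params is None:
        params = SegmentationParams()
    shapes = {m.shape for m in channel_labels.values()}
    if len(shapes) > 1:
        raise CartridgeError(f"channel masks differ in shape: {shapes}")
    comps: list[_Component] = []
    for ch in SEGMENTED_CHANNELS:
        if ch in channel_labels:
            comps.extend(_components(channel_labels[ch], ch))
    if not comps:
        return []

    uf = _UnionFind(len(comps))
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            if _gap_within(comps[i], comps[j], params.dilation_radius):
                uf.union(i, j)

    groups: dict[int, list[_Component]] = {}
    for i, c in enumerate(comps):
        groups.setdefault(uf.find(i), []).append(c)

    events = []
    for members in groups.values():
        if not any(c.channel in params.seed_channels for c in members):
            continue  # exclusion-channel signal only: never seeds an event
        r0 = min(c.bbox[0] for c in members)
        r1 = max(c.bbox[1] for c in members)
        c0 = min(c.bbox[2] for c in members)
        c1 = max(c.bbox[3] for c in members)
        masks: dict[str, np.ndarray] = {}
        for c in members:
            m = masks.setdefault(
                c.channel, np.zeros((r1 - r0, c1 - c0), dtype=bool)
            )
            cr0, cr1, cc0, cc1 = c.bbox
            m[cr0 - r0 : cr1 - r0, cc0 - c0 : cc1 - c0] |= c.mask
        events.append(((r0, c0), (r0, r1, c0, c1), masks))

    events.sort(key=lambda e: e[0])
    return [
        DetectedObject(
            object_id=id_offset + k,
            frame_index=frame_index,
            bbox=bbox,
            masks=masks,
            provenance=params.hash(),
        )
        for k, (_, bbox, masks) in enumerate(events)
    ]


def detect_cartridge(
    stack: CartridgeStack, params: SegmentationParams | None = None
) -> list[DetectedObject]:
    """Segment every channel of every frame and merge into events.

    Event ids are consecutive over the whole cartridge, ordered by
    (frame, bbox top-left corner).
    """
    if params is None:
        params = SegmentationParams()
    events: list[DetectedObject] = []
    for f in range(stack.n_frames):
        channel_labels = {}
        for ch in SEGMENTED_CHANNELS:
            if PHYSICAL_FOR_LOGICAL[ch] is None:
                continue
            channel_labels[ch] = segment_channel(
                stack.logical_channel(f, ch), params
            )
        events.extend(
            merge_events(
                channel_labels, frame_index=f, params=params,
                id_offset=len(events),
            )
        )
    return events
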