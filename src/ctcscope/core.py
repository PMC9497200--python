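"""Shared data model: cartridge image stacks and detected objects.

A cartridge is imaged as an ordered series of frames, each acquired in four
fluorescence channels (DAPI, PE, APC, FITC).  Downstream code works with
*logical* channel names that carry the staining semantics:

==========  ================  =========================================
logical     physical layer    meaning
==========  ================  =========================================
``dapi``    DAPI              DNA stain; identifies the nucleus
``ck``      PE                cytokeratin; epithelial marker
``cd45``    APC               pan-leukocyte exclusion marker
``m2``      FITC              exclusion marker 2
``m1``      (virtual)         exclusion marker 1; constant-zero layer
==========  ================  =========================================

``m1`` exists because the gate table lists five logical channels while the
instrument acquires four layers; its predicates are all of the form
"mean <= 5 AU" and pass vacuously on the constant-zero virtual channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Physical page order inside a cartridge TIFF (frame-major, channel-minor).
CHANNEL_ORDER: tuple[str, ...] = ("DAPI", "PE", "APC", "FITC")

#: Logical channels used by features and gates.
LOGICAL_CHANNELS: tuple[str, ...] = ("dapi", "ck", "cd45", "m1", "m2")

#: logical -> physical layer name (None = virtual constant-zero channel).
PHYSICAL_FOR_LOGICAL: dict[str, str | None] = {
    "dapi": "DAPI",
    "ck": "PE",
    "cd45": "APC",
    "m1": None,
    "m2": "FITC",
}

#: 12-bit acquisition: intensities live in [0, 4095] AU.
ADU_MAX = 4095

#: Default pixel pitch in micrometres per pixel (configurable everywhere).
DEFAULT_PIXEL_SIZE_UM = 0.64


class CartridgeError(ValueError):
    """Raised for malformed stacks, masks or configuration."""


@dataclass(frozen=True)
class Disc:
    """One rendered component: a uniform-intensity disc in one channel.

    Objects are built from discs so that footprint area (``pi r^2``), channel
    overlap (circle-circle lens) and image moments stay in closed form; a
    mean-preserving sinusoidal texture of coefficient of variation ``cv`` is
    multiplied on top for heterogeneous staining.

    ``dr``/``dc`` are offsets (pixels) from the parent object centre;
    ``radius`` is in pixels; ``peak`` is the background-free plateau
    intensity in AU.
    """

    channel: str  # logical: "dapi", "ck" or "cd45"
    dr: float
    dc: float
    radius: float
    peak: float
    cv: float = 0.0


@dataclass
class CartridgeStack:
    """Ordered frames of co-registered four-channel images.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, n_channels, height, width)``, unsigned
        integer, 12-bit range.
    pixel_size
        Micrometres per pixel (isotropic).
    cartridge_id
        Free-form identifier carried through to output tables.
    channel_names
        Physical channel order of axis 1; defaults to ``CHANNEL_ORDER``.
    """

    frames: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    cartridge_id: str = "cartridge"
    channel_names: tuple[str, ...] = CHANNEL_ORDER

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise CartridgeError(
                f"frames must be 4-D (frame, channel, row, col); got shape "
                f"{self.frames.shape}"
            )
        if self.frames.shape[1] != len(self.channel_names):
            raise CartridgeError(
                f"stack has {self.frames.shape[1]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if self.pixel_size <= 0:
            raise CartridgeError("pixel_size must be positive")
        if np.issubdtype(self.frames.dtype, np.floating):
            if self.frames.min() < 0:
                raise CartridgeError("negative intensities in stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[2], self.frames.shape[3]

    def physical_channel(self, frame_index: int, name: str) -> np.ndarray:
        """Return one acquired channel image of one frame."""
        try:
            c = self.channel_names.index(name)
        except ValueError:
            raise CartridgeError(f"unknown physical channel {name!r}") from None
        return self.frames[frame_index, c]

    def logical_channel(self, frame_index: int, name: str) -> np.ndarray:
        """Return a logical channel image (virtual channels are all-zero)."""
        if name not in PHYSICAL_FOR_LOGICAL:
            raise CartridgeError(f"unknown logical channel {name!r}")
        phys = PHYSICAL_FOR_LOGICAL[name]
        if phys is None:
            return np.zeros(self.frame_shape, dtype=self.frames.dtype)
        return self.physical_channel(frame_index, phys)


@dataclass
class DetectedObject:
    """A segmented event: per-channel masks within one bounding box.

    ``bbox`` is 0-based, half-open ``(row_start, row_stop, col_start,
    col_stop)``.  ``masks`` maps logical channel names (a subset of
    ``dapi, ck, cd45, m2``) to boolean arrays of bbox shape; only channels
    with at least one foreground pixel are present.
    """

    object_id: int
    frame_index: int
    bbox: tuple[int, int, int, int]
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.bbox
        if not (r1 > r0 and c1 > c0):
            raise CartridgeError(f"degenerate bbox {self.bbox}")
        shape = (r1 - r0, c1 - c0)
        if not self.masks:
            raise CartridgeError("event with no channel masks")
        for ch, m in self.masks.items():
            if m.shape != shape:
                raise CartridgeError(
                    f"mask for {ch} has shape {m.shape}, bbox implies {shape}"
                )
        if not any(m.any() for m in self.masks.values()):
            raise CartridgeError("event with all-empty masks")

    def mask(self, channel: str) -> np.ndarray:
        """Boolean mask for a logical channel (all-False if absent)."""
        r0, r1, c0, c1 = self.bbox
        m = self.masks.get(channel)
        if m is None:
            return np.zeros((r1 - r0, c1 - c0), dtype=bool)
        return m

    @property
    def footprint(self) -> np.ndarray:
        """Union of all channel masks within the bbox."""
        out = np.zeros_like(self.mask("dapi"))
        for m in self.masks.values():
            out |= m
        return out

    @property
    def centroid(self) -> tuple[float, float]:
        """(row, col) centroid of the union footprint, frame coordinates."""
        rr, cc = np.nonzero(self.footprint)
        r0, _, c0, _ = self.bbox
        return float(rr.mean() + r0), float(cc.mean() + c0)
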