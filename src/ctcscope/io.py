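"""File formats, pipeline orchestration and thumbnail rendering.

Cartridges are stored as multi-page TIFF, pages ordered frame-major /
channel-minor (frame 0: DAPI, PE, APC, FITC; frame 1: ...), with a JSON
blob in the first page description carrying pixel size, channel order and
cartridge id.  Tabular artifacts are CSV with a one-line ``#`` header
comment embedding the config hash and seed for provenance.  All
coordinates in outputs are 0-based, half-open.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    ADU_MAX,
    CHANNEL_ORDER,
    CartridgeError,
    CartridgeStack,
    DEFAULT_PIXEL_SIZE_UM,
    DetectedObject,
)
from .gating import (
    GateSet,
    apply_review,
    default_gateset,
    enumerate_events,
    load_gateset,
)
from .morphometry import measure_events
from .segmentation import SegmentationParams, detect_cartridge
from .subclassify import SubclassParams, classify_events
from .synthetic import CartridgeConfig, GroundTruth, generate_cartridge

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# TIFF round trip
# --------------------------------------------------------------------------

def write_cartridge(stack: CartridgeStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF (frame-major, channel-minor)."""
    path = Path(path)
    meta = {
        "cartridge_id": stack.cartridge_id,
        "pixel_size_um": stack.pixel_size,
        "channels": list(stack.channel_names),
        "n_frames": stack.n_frames,
    }
    pages = stack.frames.reshape(-1, *stack.frame_shape)
    tifffile.imwrite(
        path, pages, photometric="minisblack", description=json.dumps(meta)
    )


def read_cartridge(
    path: str | Path,
    channel_order: tuple[str, ...] | None = None,
    pixel_size: float | None = None,
) -> CartridgeStack:
    """Read a multi-page TIFF into a CartridgeStack.

    Metadata (pixel size, channel names, id) come from the first page
    description when present; ``channel_order`` overrides the channel
    naming for foreign stacks (page count must be divisible by the channel
    count).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
        if not isinstance(meta, dict):
            meta = {}
    except (json.JSONDecodeError, TypeError):
        meta = {}
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise CartridgeError(f"{path}: expected a page series, got shape {pages.shape}")
    names = tuple(channel_order or meta.get("channels") or CHANNEL_ORDER)
    n_ch = len(names)
    if pages.shape[0] % n_ch:
        raise CartridgeError(
            f"{path}: {pages.shape[0]} pages not divisible by "
            f"{n_ch} declared channels"
        )
    frames = pages.reshape(-1, n_ch, *pages.shape[1:])
    if names != CHANNEL_ORDER and set(names) == set(CHANNEL_ORDER):
        # foreign page order: permute axis 1 into the canonical order
        perm = [names.index(ch) for ch in CHANNEL_ORDER]
        frames = frames[:, perm]
        names = CHANNEL_ORDER
    return CartridgeStack(
        frames=frames,
        pixel_size=float(pixel_size or meta.get("pixel_size_um")
                         or DEFAULT_PIXEL_SIZE_UM),
        cartridge_id=str(meta.get("cartridge_id", path.stem)),
        channel_names=names,
    )


# --------------------------------------------------------------------------
# CSV with provenance header
# --------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, provenance: dict) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(provenance, sort_keys=True) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# --------------------------------------------------------------------------
# thumbnails
# --------------------------------------------------------------------------

def render_thumbnail(
    event: DetectedObject,
    stack: CartridgeStack,
    size: int = 48,
) -> np.ndarray:
    """Composite RGB crop of one event: DAPI in blue, CK in green, CD45 in
    red, per-channel min-max scaled over the crop; frame-edge crops are
    zero-padded.  Deterministic."""
    r0, r1, c0, c1 = event.bbox
    cr = (r0 + r1) // 2
    cc = (c0 + c1) // 2
    half = size // 2
    h, w = stack.frame_shape
    out = np.zeros((size, size, 3), dtype=np.uint8)
    rs, re = cr - half, cr - half + size
    cs, ce = cc - half, cc - half + size
    vr0, vr1 = max(rs, 0), min(re, h)
    vc0, vc1 = max(cs, 0), min(ce, w)
    for ch, plane in (("cd45", 0), ("ck", 1), ("dapi", 2)):
        img = stack.logical_channel(event.frame_index, ch).astype(float)
        crop = np.zeros((size, size))
        crop[vr0 - rs : vr1 - rs, vc0 - cs : vc1 - cs] = img[vr0:vr1, vc0:vc1]
        lo, hi = crop.min(), crop.max()
        if hi > lo:
            crop = (crop - lo) / (hi - lo)
        else:
            crop = np.zeros_like(crop)
        out[..., plane] = np.rint(255 * crop).astype(np.uint8)
    return out


def save_thumbnail(
    event: DetectedObject, stack: CartridgeStack, path: str | Path,
    size: int = 48,
) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), render_thumbnail(event, stack, size=size))


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration; fully serializable, hashed into every
    output header."""

    input_path: str | None = None       # existing cartridge TIFF ...
    simulate: CartridgeConfig | None = None  # ... or generate one
    channel_order: tuple[str, ...] | None = None
    pixel_size: float | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    gate_file: str | None = None        # None = shipped default gates
    subclass: SubclassParams = field(default_factory=SubclassParams)
    annotations_path: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = dict(doc)
    if "simulate" in kwargs and kwargs["simulate"] is not None:
        sim = dict(kwargs["simulate"])
        if "frame_shape" in sim:
            sim["frame_shape"] = tuple(sim["frame_shape"])
        kwargs["simulate"] = CartridgeConfig(**sim)
    if "segmentation" in kwargs and kwargs["segmentation"] is not None:
        seg = dict(kwargs["segmentation"])
        if "seed_channels" in seg:
            seg["seed_channels"] = tuple(seg["seed_channels"])
        kwargs["segmentation"] = SegmentationParams(**seg)
    if "subclass" in kwargs and kwargs["subclass"] is not None:
        kwargs["subclass"] = SubclassParams(**kwargs["subclass"])
    if kwargs.get("channel_order"):
        kwargs["channel_order"] = tuple(kwargs["channel_order"])
    return PipelineConfig(**kwargs)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute detect -> measure -> gate -> review -> classify and write all
    artifacts under ``out_dir``.

    Returns a dict with the in-memory results (stack, events, tables,
    counts).  Any stage failure aborts with the stage name in the log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.hash(), "seed": config.seed}
    t0 = time.time()

    def stage(name: str) -> None:
        log.info("[%7.2fs] stage: %s", time.time() - t0, name)

    truth: GroundTruth | None = None
    stage("load")
    if config.simulate is not None:
        stack, truth = generate_cartridge(config.simulate, seed=config.seed)
        write_cartridge(stack, out_dir / "cartridge.tiff")
        truth.to_csv(out_dir / "ground_truth.csv")
    elif config.input_path:
        stack = read_cartridge(
            config.input_path,
            channel_order=config.channel_order,
            pixel_size=config.pixel_size,
        )
    else:
        raise CartridgeError("config needs input_path or simulate")

    stage("detect")
    events = detect_cartridge(stack, config.segmentation)
    stage("measure")
    features = measure_events(events, stack)
    write_table(features, out_dir / "events.csv", provenance)

    stage("gate")
    if config.gate_file:
        gateset: GateSet = load_gateset(config.gate_file)
    else:
        gateset = default_gateset()
    gated, counts = enumerate_events(features, gateset)
    annotations = None
    if config.annotations_path:
        annotations = read_table(config.annotations_path)
    gated, counts = apply_review(gated, annotations)
    write_table(gated, out_dir / "gated.csv", provenance)

    stage("classify")
    classified = classify_events(events, stack, gated, config.subclass)
    write_table(classified, out_dir / "classified.csv", provenance)

    stage("report")
    counts_doc = {
        **provenance,
        "cartridge_id": stack.cartridge_id,
        "ctc_accept": counts.ctc_accept,
        "ctc_accept_corrected": counts.ctc_accept_corrected,
        "tdev_accept": counts.tdev_accept,
        "subclass_counts": (
            classified[classified["gate_label"] == "CTC"]["subclass"]
            .value_counts()
            .to_dict()
        ),
    }
    with open(out_dir / "counts.json", "w") as fh:
        json.dump(counts_doc, fh, indent=2, sort_keys=True)
    stage("done")
    return {
        "stack": stack,
        "truth": truth,
        "events": events,
        "features": features,
        "gated": gated,
        "classified": classified,
        "counts": counts,
        "counts_doc": counts_doc,
    }
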