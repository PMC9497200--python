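"""Per-object intensity and shape measurements feeding the gates.

For every detected event the measurements below are computed per logical
channel on that channel's own mask:

* ``mean_<ch>``, ``max_<ch>`` -- background-inclusive intensities in AU;
* ``area_<ch>`` -- mask pixel count times ``pixel_size**2`` (um^2);
* ``empty_<ch>`` -- flag set when the channel mask is empty (all numeric
  features of that channel are then reported as 0, not missing).

Cytokeratin additionally gets the gate-specific shape features:

* ``size_ck`` -- alias of ``area_ck`` (the gate table lists both "Area CK"
  and "CK size"; they are treated as the same measurement, applied as
  printed);
* ``eccentricity_ck`` -- ellipse-of-inertia eccentricity of the CK mask
  (0 = circle);
* ``perimeter_ck`` -- number of CK mask pixels with at least one 4-connected
  background neighbour (pixel-count convention; the gate threshold is stated
  in pixels);
* ``perimeter_to_area_ck`` -- boundary pixel count / mask pixel count;
* ``overlay_ck_dapi`` -- |CK mask intersect DAPI mask| / |CK mask| (0 when
  CK is empty; denominator configurable).

``idealized_features`` computes the same quantities in closed form from an
object's disc layout, without rendering; it is the labelling oracle used to
attach expected gate outcomes to synthetic ground truth.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ADU_MAX,
    CartridgeError,
    CartridgeStack,
    DetectedObject,
    Disc,
    LOGICAL_CHANNELS,
)

#: (feature, channel) -> feature-table column used by the gating layer.
COLUMN_FOR: dict[tuple[str, str], str] = {
    **{("mean_intensity", ch): f"mean_{ch}" for ch in LOGICAL_CHANNELS},
    **{("max_intensity", ch): f"max_{ch}" for ch in LOGICAL_CHANNELS},
    **{("area", ch): f"area_{ch}" for ch in LOGICAL_CHANNELS},
    ("size", "ck"): "size_ck",
    ("eccentricity", "ck"): "eccentricity_ck",
    ("perimeter", "ck"): "perimeter_ck",
    ("perimeter_to_area", "ck"): "perimeter_to_area_ck",
    ("overlay_ck_dapi", "ck"): "overlay_ck_dapi",
}

#: Column order of the feature table (ids/bbox first, then features).
ID_COLUMNS = ["object_id", "frame", "bbox_r0", "bbox_r1", "bbox_c0", "bbox_c1"]
FEATURE_COLUMNS = (
    [f"{stat}_{ch}" for ch in LOGICAL_CHANNELS for stat in ("mean", "max", "area")]
    + [f"empty_{ch}" for ch in LOGICAL_CHANNELS]
    + [
        "size_ck",
        "eccentricity_ck",
        "perimeter_ck",
        "perimeter_to_area_ck",
        "overlay_ck_dapi",
    ]
)


# --------------------------------------------------------------------------
# shape primitives (shared by the measured and the idealized path)
# --------------------------------------------------------------------------

def boundary_pixel_count(mask: np.ndarray) -> int:
    """Mask pixels with at least one 4-connected background neighbour."""
    if not mask.any():
        return 0
    m = np.pad(mask, 1, mode="constant")
    interior = (
        m[1:-1, 1:-1]
        & m[:-2, 1:-1]
        & m[2:, 1:-1]
        & m[1:-1, :-2]
        & m[1:-1, 2:]
    )
    return int(mask.sum() - interior.sum())


def eccentricity_from_cov(cov: np.ndarray) -> float:
    """Ellipse eccentricity (0 = circle) from a 2x2 coordinate covariance."""
    lam = np.linalg.eigvalsh(cov)
    lam_minor, lam_major = float(lam[0]), float(lam[1])
    if lam_major <= 0:
        return 0.0
    ratio = max(lam_minor, 0.0) / lam_major
    return float(np.sqrt(max(0.0, 1.0 - ratio)))


def mask_eccentricity(mask: np.ndarray) -> float:
    rr, cc = np.nonzero(mask)
    if rr.size <= 1:
        return 0.0
    cov = np.cov(np.stack([rr, cc]).astype(float), ddof=0)
    return eccentricity_from_cov(cov)


def circle_lens_area(r1: float, r2: float, d: float) -> float:
    """Intersection area of two circles with radii r1, r2 at centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return float(np.pi * min(r1, r2) ** 2)
    a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    k = 0.5 * np.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return float(a1 + a2 - k)


def rasterize_discs(
    discs: Sequence[Disc], bounds_discs: Sequence[Disc] | None = None
) -> np.ndarray:
    """Boolean raster of a disc union on an integer grid (origin-centred).

    ``bounds_discs`` optionally fixes the grid extent (so that rasters of
    different channels of the same object share a coordinate frame).
    """
    ref = list(bounds_discs or discs)
    if not discs or not ref:
        return np.zeros((1, 1), dtype=bool)
    lo_r = int(np.floor(min(d.dr - d.radius for d in ref))) - 1
    hi_r = int(np.ceil(max(d.dr + d.radius for d in ref))) + 1
    lo_c = int(np.floor(min(d.dc - d.radius for d in ref))) - 1
    hi_c = int(np.ceil(max(d.dc + d.radius for d in ref))) + 1
    rr, cc = np.meshgrid(
        np.arange(lo_r, hi_r + 1), np.arange(lo_c, hi_c + 1), indexing="ij"
    )
    out = np.zeros(rr.shape, dtype=bool)
    for d in discs:
        out |= (rr - d.dr) ** 2 + (cc - d.dc) ** 2 <= d.radius**2
    return out


# --------------------------------------------------------------------------
# measured features
# --------------------------------------------------------------------------

def _empty_features() -> dict[str, float]:
    fv: dict[str, float] = {}
    for ch in LOGICAL_CHANNELS:
        fv[f"mean_{ch}"] = 0.0
        fv[f"max_{ch}"] = 0.0
        fv[f"area_{ch}"] = 0.0
        fv[f"empty_{ch}"] = True
    fv["size_ck"] = 0.0
    fv["eccentricity_ck"] = 0.0
    fv["perimeter_ck"] = 0.0
    fv["perimeter_to_area_ck"] = 0.0
    fv["overlay_ck_dapi"] = 0.0
    return fv


def measure_object(
    obj: DetectedObject,
    stack: CartridgeStack,
    overlay_denominator: str = "ck",
) -> dict[str, float]:
    """Compute the FeatureVector of one detected event.

    Intensities are background-inclusive means/maxima over each channel's
    own mask; see the module docstring for the full feature list.
    """
    r0, r1, c0, c1 = obj.bbox
    h, w = stack.frame_shape
    if not (0 <= r0 and r1 <= h and 0 <= c0 and c1 <= w):
        raise CartridgeError(
            f"object {obj.object_id}: bbox {obj.bbox} outside frame {(h, w)}"
        )
    fv = _empty_features()
    px_area = stack.pixel_size**2
    for ch in LOGICAL_CHANNELS:
        m = obj.masks.get(ch)
        if m is None or not m.any():
            continue
        img = stack.logical_channel(obj.frame_index, ch)[r0:r1, c0:c1]
        vals = img[m].astype(float)
        fv[f"mean_{ch}"] = float(vals.mean())
        fv[f"max_{ch}"] = float(vals.max())
        fv[f"area_{ch}"] = float(m.sum() * px_area)
        fv[f"empty_{ch}"] = False

    ck = obj.mask("ck")
    if ck.any():
        n_px = int(ck.sum())
        perim = boundary_pixel_count(ck)
        fv["size_ck"] = fv["area_ck"]
        fv["eccentricity_ck"] = mask_eccentricity(ck)
        fv["perimeter_ck"] = float(perim)
        fv["perimeter_to_area_ck"] = perim / n_px
        dapi = obj.mask("dapi")
        inter = int((ck & dapi).sum())
        if overlay_denominator == "ck":
            denom = n_px
        elif overlay_denominator == "dapi":
            denom = int(dapi.sum())
        elif overlay_denominator == "union":
            denom = int((ck | dapi).sum())
        else:
            raise CartridgeError(
                f"unknown overlay_denominator {overlay_denominator!r}"
            )
        fv["overlay_ck_dapi"] = inter / denom if denom else 0.0
    return fv


def measure_events(
    events: Iterable[DetectedObject],
    stack: CartridgeStack,
    overlay_denominator: str = "ck",
) -> pd.DataFrame:
    """Feature table: one row per event, ``ID_COLUMNS + FEATURE_COLUMNS``."""
    rows = []
    for obj in events:
        fv = measure_object(obj, stack, overlay_denominator)
        r0, r1, c0, c1 = obj.bbox
        rows.append(
            {
                "object_id": obj.object_id,
                "frame": obj.frame_index,
                "bbox_r0": r0,
                "bbox_r1": r1,
                "bbox_c0": c0,
                "bbox_c1": c1,
                **fv,
            }
        )
    return pd.DataFrame(rows, columns=ID_COLUMNS + FEATURE_COLUMNS)


# --------------------------------------------------------------------------
# idealized (analytic) features
# --------------------------------------------------------------------------

def idealized_features(
    spec,
    pixel_size: float,
    background: float = 2.0,
    overlay_denominator: str = "ck",
) -> dict[str, float]:
    """Closed-form FeatureVector of an object archetype.

    ``spec`` is any object exposing ``components(pixel_size) -> list[Disc]``
    (the synthetic generator's ObjectSpec).  Areas come from ``pi r^2`` of
    the disc layout, intensities from plateau + background, channel overlap
    from circle-lens geometry; the CK perimeter and perimeter-to-area ratio
    are taken from an origin-centred rasterization of the footprint (they
    are pixel-count conventions with no continuous analogue).
    """
    discs: list[Disc] = list(spec.components(pixel_size))
    # pixel-count features (perimeter, overlay) depend on the sub-pixel
    # phase of the object centre; use the spec's planted position so the
    # oracle counts exactly the geometry that gets rendered
    from dataclasses import replace

    ph_r = float(getattr(spec, "row", 0.0)) % 1.0
    ph_c = float(getattr(spec, "col", 0.0)) % 1.0
    if ph_r or ph_c:
        discs = [replace(d, dr=d.dr + ph_r, dc=d.dc + ph_c) for d in discs]
    px_area = pixel_size**2
    by_ch: dict[str, list[Disc]] = {}
    for d in discs:
        by_ch.setdefault(d.channel, []).append(d)

    fv = _empty_features()
    for ch, ds in by_ch.items():
        areas = np.array([np.pi * d.radius**2 for d in ds])
        peaks = np.array([d.peak for d in ds])
        cvs = np.array([d.cv for d in ds])
        fv[f"area_{ch}"] = float(areas.sum() * px_area)
        fv[f"mean_{ch}"] = float(
            np.average(peaks, weights=areas) + background
        )
        fv[f"max_{ch}"] = float(
            min(ADU_MAX, (peaks * (1 + np.sqrt(2) * cvs)).max() + background)
        )
        fv[f"empty_{ch}"] = False

    ck = by_ch.get("ck", [])
    if ck:
        fv["size_ck"] = fv["area_ck"]
        # analytic inertia of the disc union (components assumed disjoint
        # within a channel, which the generator guarantees)
        areas = np.array([np.pi * d.radius**2 for d in ck])
        centres = np.array([[d.dr, d.dc] for d in ck])
        total = areas.sum()
        mean = (areas[:, None] * centres).sum(0) / total
        cov = np.zeros((2, 2))
        for a, d, c in zip(areas, ck, centres):
            off = c - mean
            cov += a * (np.eye(2) * d.radius**2 / 4 + np.outer(off, off))
        cov /= total
        fv["eccentricity_ck"] = eccentricity_from_cov(cov)

        raster = rasterize_discs(ck)
        n_px = int(raster.sum())
        perim = boundary_pixel_count(raster)
        fv["perimeter_ck"] = float(perim)
        fv["perimeter_to_area_ck"] = perim / n_px if n_px else 0.0

        # overlay on the shared raster grid: the measured overlay is a
        # pixel-count ratio, so the oracle pixel-counts the same geometry
        dapi = by_ch.get("dapi", [])
        bounds = ck + dapi
        ck_r = rasterize_discs(ck, bounds)
        dapi_r = rasterize_discs(dapi, bounds)
        inter = int((ck_r & dapi_r).sum())
        if overlay_denominator == "ck":
            denom = int(ck_r.sum())
        elif overlay_denominator == "dapi":
            denom = int(dapi_r.sum())
        elif overlay_denominator == "union":
            denom = int((ck_r | dapi_r).sum())
        else:
            raise CartridgeError(
                f"unknown overlay_denominator {overlay_denominator!r}"
            )
        fv["overlay_ck_dapi"] = inter / denom if denom else 0.0
    return fv


def feature_value(fv: Mapping[str, float], feature: str, channel: str) -> float:
    """Look up a (feature, channel) pair in a FeatureVector mapping."""
    key = (feature, channel)
    if key not in COLUMN_FOR:
        raise CartridgeError(f"unknown feature {feature!r} / channel {channel!r}")
    col = COLUMN_FOR[key]
    if col not in fv:
        raise CartridgeError(f"feature vector is missing {col!r}")
    return float(fv[col])
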