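"""Synthetic cartridges and cohorts with known ground truth.

Image model
-----------
Every planted object is a set of uniform-intensity discs (one per stained
structure) on a flat background (default 2 AU), optionally with additive
Gaussian noise.  A mean-preserving multiplicative sinusoidal texture of
target coefficient of variation ``ck_cv_target`` models staining
heterogeneity.  Discs keep footprint area, channel overlap and image
moments in closed form, so each object's idealized FeatureVector — and
therefore its expected gate outcome — is computed analytically through the
*same* gate set used downstream; there is no independent labelling path.

Archetypes (all sizes in micrometres, sampled in windows chosen so that
rendering, segmentation and measurement land on the same side of every
gate threshold as the analytic features):

* ``CTC_PRETTY`` — one nucleus inside one smooth CK disc (CV ~ 0.05).
* ``CTC_HETEROGENEOUS`` — same geometry, CK CV ~ 0.5.
* ``CTC_CLUSTER`` — 2-4 intact, well-separated nuclei under one CK disc.
* ``CTC_CLEAVED`` — intact nucleus; CK reduced to 3-4 round speckles, one
  centred on the nucleus (keeping CK-DAPI overlay high), the rest on a ring
  overlapping the nuclear rim (keeping the event connected).
* ``CTC_FRAGMENTED`` — intact CK disc; nucleus split into two small
  fragments with a >= 2 px gap.
* ``CTC_CLEAVED_FRAGMENTED`` — two nuclear fragments chained by a central
  CK speckle, plus outer speckles overlapping the fragment tips.
* ``TDEV`` — anucleate CK disc, 1-12 um diameter.
* ``LEUKOCYTE`` — nucleus plus CD45 membrane disc, no CK.
* ``DEBRIS`` — large anucleate CK smear (fails both gates on size).

Cohort model
------------
Per patient a latent log-scale tumour burden drives both counts:
``ctc = floor(exp(L + eps_c))`` and ``tdev = floor(m * exp(L + eps_t))``
with a per-patient log-normal tdEV multiplier ``m``; the shared latent
induces the strong CTC-tdEV rank correlation, and floor() of the wide
log-normal produces the realistic mass at zero CTCs.  An optional
structural zero-inflation probability exists (default 0).  Follow-up
(post-ADT) patients get a log-normal decline factor per marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ADU_MAX,
    CHANNEL_ORDER,
    CartridgeError,
    CartridgeStack,
    DEFAULT_PIXEL_SIZE_UM,
    Disc,
)
from .gating import GateSet, LABEL_CTC, LABEL_NEITHER, LABEL_TDEV, apply_gate, default_gateset
from .morphometry import idealized_features

_GOLDEN = 2.399963  # angle increment decorrelating per-disc texture phases


class ObjectKind(str, Enum):
    CTC_CLUSTER = "CTC_CLUSTER"
    CTC_PRETTY = "CTC_PRETTY"
    CTC_HETEROGENEOUS = "CTC_HETEROGENEOUS"
    CTC_CLEAVED = "CTC_CLEAVED"
    CTC_FRAGMENTED = "CTC_FRAGMENTED"
    CTC_CLEAVED_FRAGMENTED = "CTC_CLEAVED_FRAGMENTED"
    TDEV = "TDEV"
    LEUKOCYTE = "LEUKOCYTE"
    DEBRIS = "DEBRIS"


CTC_KINDS = frozenset(
    {
        ObjectKind.CTC_CLUSTER,
        ObjectKind.CTC_PRETTY,
        ObjectKind.CTC_HETEROGENEOUS,
        ObjectKind.CTC_CLEAVED,
        ObjectKind.CTC_FRAGMENTED,
        ObjectKind.CTC_CLEAVED_FRAGMENTED,
    }
)

#: morphological subclass planted by each CTC archetype
SUBCLASS_FOR_KIND = {
    ObjectKind.CTC_CLUSTER: "CLUSTER",
    ObjectKind.CTC_PRETTY: "PRETTY",
    ObjectKind.CTC_HETEROGENEOUS: "HETEROGENEOUS_CK",
    ObjectKind.CTC_CLEAVED: "CLEAVED_CK",
    ObjectKind.CTC_FRAGMENTED: "FRAGMENTED",
    ObjectKind.CTC_CLEAVED_FRAGMENTED: "CLEAVED_CK_FRAGMENTED_DNA",
}

_PHYS_INDEX = {"dapi": 0, "ck": 1, "cd45": 2, "m2": 3}


@dataclass
class ObjectSpec:
    """Parameters of one planted object; the disc layout is a pure function
    of these fields (plus pixel size), so specs round-trip through CSV."""

    object_id: int
    kind: ObjectKind
    frame: int = 0
    row: float = 0.0
    col: float = 0.0
    nucleus_count: int = 1
    ck_diameter: float = 0.0      # um; main CK disc (0 = no CK disc)
    dapi_diameter: float = 0.0    # um; nucleus diameter
    cd45_diameter: float = 0.0    # um; leukocyte membrane disc
    fragment_diameter: float = 0.0  # um; nuclear fragment diameter
    speckle_diameter: float = 0.0   # um; outer CK speckle diameter
    central_speckle_diameter: float = 0.0  # um; nucleus-centred CK speckle
    peak_dapi: float = 0.0
    peak_ck: float = 0.0
    peak_cd45: float = 0.0
    speckle_count: int = 0
    ck_cv_target: float = 0.05
    orientation: float = 0.0

    def __post_init__(self) -> None:
        self.kind = ObjectKind(self.kind)
        k = self.kind
        if k is ObjectKind.CTC_CLUSTER and self.nucleus_count < 2:
            raise CartridgeError("CTC_CLUSTER requires nucleus_count >= 2")
        if k is ObjectKind.TDEV:
            if self.nucleus_count != 0:
                raise CartridgeError("TDEV must have nucleus_count == 0")
            if not (1.0 <= self.ck_diameter <= 12.0):
                raise CartridgeError(
                    f"TDEV ck_diameter {self.ck_diameter} um outside [1, 12]"
                )
        if k is ObjectKind.LEUKOCYTE:
            if self.peak_cd45 <= 0:
                raise CartridgeError("LEUKOCYTE requires peak_cd45 > 0")
            if self.peak_ck != 0:
                raise CartridgeError("LEUKOCYTE must have peak_ck == 0")
        for name in ("peak_dapi", "peak_ck", "peak_cd45"):
            v = getattr(self, name)
            if not (0 <= v <= ADU_MAX):
                raise CartridgeError(f"{name}={v} outside 12-bit range")

    # -- layout ------------------------------------------------------------

    def components(self, pixel_size: float) -> list[Disc]:
        """Disc layout in pixel units, offsets relative to the object centre."""
        ps = pixel_size
        phi = self.orientation
        u = np.array([math.sin(phi), math.cos(phi)])  # (dr, dc)

        def um(r: float) -> float:
            return r / 2.0 / ps  # diameter um -> radius px

        k = self.kind
        discs: list[Disc] = []
        if k in (ObjectKind.CTC_PRETTY, ObjectKind.CTC_HETEROGENEOUS):
            discs.append(Disc("ck", 0, 0, um(self.ck_diameter), self.peak_ck,
                              self.ck_cv_target))
            discs.append(Disc("dapi", 0, 0, um(self.dapi_diameter),
                              self.peak_dapi, 0.05))
        elif k is ObjectKind.CTC_CLUSTER:
            rn = um(self.dapi_diameter)
            n = self.nucleus_count
            sep = 2 * rn + 2.2  # centre-to-centre, >= 2 px rim gap
            if n == 2:
                offs = [(sep / 2) * u, -(sep / 2) * u]
            else:
                circ = sep / (2 * math.sin(math.pi / n))
                offs = [
                    circ
                    * np.array(
                        [math.sin(phi + 2 * math.pi * i / n + math.pi / 2),
                         math.cos(phi + 2 * math.pi * i / n + math.pi / 2)]
                    )
                    for i in range(n)
                ]
            rck = max(float(np.hypot(*o)) for o in offs) + rn + 1.2
            discs.append(Disc("ck", 0, 0, rck, self.peak_ck, self.ck_cv_target))
            for o in offs:
                discs.append(Disc("dapi", o[0], o[1], rn, self.peak_dapi, 0.05))
        elif k is ObjectKind.CTC_CLEAVED:
            rn = um(self.dapi_diameter)
            rc = um(self.central_speckle_diameter)
            rs = um(self.speckle_diameter)
            discs.append(Disc("dapi", 0, 0, rn, self.peak_dapi, 0.05))
            discs.append(Disc("ck", 0, 0, rc, self.peak_ck, self.ck_cv_target))
            ring = rn + rs - 1.5  # overlap nuclear rim by 1.5 px: stays chained
            n_outer = self.speckle_count - 1
            for i in range(n_outer):
                a = phi + math.pi / 2 + 2 * math.pi * i / n_outer
                discs.append(
                    Disc("ck", ring * math.sin(a), ring * math.cos(a), rs,
                         self.peak_ck, self.ck_cv_target)
                )
        elif k is ObjectKind.CTC_FRAGMENTED:
            rf = um(self.fragment_diameter)
            off = rf + 1.0
            discs.append(Disc("ck", 0, 0, um(self.ck_diameter), self.peak_ck,
                              self.ck_cv_target))
            discs.append(Disc("dapi", off * u[0], off * u[1], rf,
                              self.peak_dapi, 0.05))
            discs.append(Disc("dapi", -off * u[0], -off * u[1], rf,
                              self.peak_dapi, 0.05))
        elif k is ObjectKind.CTC_CLEAVED_FRAGMENTED:
            rf = um(self.fragment_diameter)
            rc = um(self.central_speckle_diameter)
            rs = um(self.speckle_diameter)
            off = rf + 1.0
            for s in (1, -1):
                discs.append(Disc("dapi", s * off * u[0], s * off * u[1], rf,
                                  self.peak_dapi, 0.05))
            # central speckle bridges the two fragments
            discs.append(Disc("ck", 0, 0, rc, self.peak_ck, self.ck_cv_target))
            ring = off + rf + rs - 2.0  # overlap fragment tips by 2 px
            for s in (1, -1):
                discs.append(Disc("ck", s * ring * u[0], s * ring * u[1], rs,
                                  self.peak_ck, self.ck_cv_target))
        elif k is ObjectKind.TDEV:
            discs.append(Disc("ck", 0, 0, um(self.ck_diameter), self.peak_ck,
                              self.ck_cv_target))
        elif k is ObjectKind.LEUKOCYTE:
            discs.append(Disc("cd45", 0, 0, um(self.cd45_diameter),
                              self.peak_cd45, 0.05))
            discs.append(Disc("dapi", 0, 0, um(self.dapi_diameter),
                              self.peak_dapi, 0.05))
        elif k is ObjectKind.DEBRIS:
            discs.append(Disc("ck", 0, 0, um(self.ck_diameter), self.peak_ck,
                              self.ck_cv_target))
        else:  # pragma: no cover
            raise CartridgeError(f"unhandled kind {k}")
        return discs

    def bounding_radius(self, pixel_size: float) -> float:
        """Radius (px) of the smallest origin-centred circle containing all
        discs."""
        return max(
            float(np.hypot(d.dr, d.dc)) + d.radius
            for d in self.components(pixel_size)
        )

    def to_row(self) -> dict:
        row = asdict(self)
        row["kind"] = self.kind.value
        return row

    @classmethod
    def from_row(cls, row: dict) -> "ObjectSpec":
        names = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in dict(row).items() if k in names}
        kwargs["kind"] = ObjectKind(kwargs["kind"])
        for intf in ("object_id", "frame", "nucleus_count", "speckle_count"):
            kwargs[intf] = int(kwargs[intf])
        return cls(**kwargs)


# --------------------------------------------------------------------------
# random archetypes
# --------------------------------------------------------------------------

def random_object_spec(
    kind: ObjectKind | str,
    rng: np.random.Generator,
    object_id: int = 0,
) -> ObjectSpec:
    """Sample an archetype with randomized sizes/intensities.

    Windows are chosen so every archetype separates cleanly from the gate
    and subclass thresholds (see docs/methods.md for the margins).
    """
    kind = ObjectKind(kind)
    u = rng.uniform
    common = dict(
        object_id=object_id,
        kind=kind,
        peak_dapi=float(u(300, 600)),
        peak_ck=float(u(250, 450)),
        peak_cd45=0.0,
        orientation=float(u(0, 2 * math.pi)),
        ck_cv_target=float(u(0.03, 0.07)),
    )
    if kind is ObjectKind.CTC_PRETTY or kind is ObjectKind.CTC_HETEROGENEOUS:
        dapi_d = float(u(6.5, 8.5))
        spec = ObjectSpec(
            **common,
            nucleus_count=1,
            dapi_diameter=dapi_d,
            ck_diameter=dapi_d + float(u(2.5, 4.5)),
        )
        if kind is ObjectKind.CTC_HETEROGENEOUS:
            spec.ck_cv_target = float(u(0.40, 0.60))
        return spec
    if kind is ObjectKind.CTC_CLUSTER:
        return ObjectSpec(
            **common,
            nucleus_count=int(rng.choice([2, 3, 4], p=[0.5, 0.35, 0.15])),
            dapi_diameter=float(u(6.0, 7.5)),
        )
    if kind is ObjectKind.CTC_CLEAVED:
        return ObjectSpec(
            **common,
            nucleus_count=1,
            dapi_diameter=float(u(8.5, 9.5)),
            central_speckle_diameter=float(u(3.7, 4.0)),
            speckle_diameter=float(u(2.8, 3.2)),
            speckle_count=int(rng.choice([3, 4], p=[0.4, 0.6])),
        )
    if kind is ObjectKind.CTC_FRAGMENTED:
        frag_d = float(u(3.6, 4.2))
        rf_px = frag_d / 2 / DEFAULT_PIXEL_SIZE_UM
        rck_px = 2 * rf_px + 1.5 + float(u(0.2, 0.8))
        return ObjectSpec(
            **common,
            nucleus_count=1,
            fragment_diameter=frag_d,
            ck_diameter=2 * rck_px * DEFAULT_PIXEL_SIZE_UM,
        )
    if kind is ObjectKind.CTC_CLEAVED_FRAGMENTED:
        return ObjectSpec(
            **common,
            nucleus_count=1,
            fragment_diameter=float(u(3.8, 4.2)),
            central_speckle_diameter=float(u(3.2, 3.4)),
            speckle_diameter=float(u(3.1, 3.3)),
            speckle_count=3,
        )
    if kind is ObjectKind.TDEV:
        common["peak_dapi"] = 0.0
        return ObjectSpec(
            **common, nucleus_count=0, ck_diameter=float(u(5.0, 9.5))
        )
    if kind is ObjectKind.LEUKOCYTE:
        common["peak_ck"] = 0.0
        common["peak_cd45"] = float(u(150, 350))
        return ObjectSpec(
            **common,
            nucleus_count=1,
            dapi_diameter=float(u(7.0, 9.0)),
            cd45_diameter=float(u(10.0, 13.0)),
        )
    if kind is ObjectKind.DEBRIS:
        common["peak_dapi"] = 0.0
        common["ck_cv_target"] = float(u(0.1, 0.2))
        return ObjectSpec(
            **common, nucleus_count=0, ck_diameter=float(u(27.0, 31.0))
        )
    raise CartridgeError(f"unhandled kind {kind}")  # pragma: no cover


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_object(
    spec: ObjectSpec, canvas: np.ndarray, pixel_size: float
) -> np.ndarray:
    """Additively render one object onto a float canvas ``(4, H, W)``.

    Rendering is a pure function of the spec (texture phase comes from
    ``orientation``); an object whose footprint leaves the canvas raises,
    naming the offending object.
    """
    if canvas.ndim != 3 or canvas.shape[0] != len(CHANNEL_ORDER):
        raise CartridgeError(f"canvas must be (4, H, W); got {canvas.shape}")
    h, w = canvas.shape[1:]
    for i, d in enumerate(spec.components(pixel_size)):
        cr = spec.row + d.dr
        cc = spec.col + d.dc
        r = d.radius
        if cr - r < 0 or cr + r > h - 1 or cc - r < 0 or cc + r > w - 1:
            raise CartridgeError(
                f"object {spec.object_id} ({spec.kind.value}) extends outside "
                f"the {h}x{w} canvas at frame {spec.frame}"
            )
        r0, r1 = int(math.floor(cr - r)), int(math.ceil(cr + r)) + 1
        c0, c1 = int(math.floor(cc - r)), int(math.ceil(cc + r)) + 1
        rr, cc_grid = np.meshgrid(
            np.arange(r0, r1), np.arange(c0, c1), indexing="ij"
        )
        inside = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= r * r
        if d.cv > 0:
            theta = spec.orientation + _GOLDEN * i
            coord = math.cos(theta) * (rr - cr) + math.sin(theta) * (cc_grid - cc)
            tex = 1.0 + math.sqrt(2) * d.cv * np.sin(
                2 * math.pi * coord / 4.0 + _GOLDEN * (i + 1)
            )
        else:
            tex = 1.0
        patch = np.where(inside, d.peak * tex, 0.0)
        canvas[_PHYS_INDEX[d.channel], r0:r1, c0:c1] += patch
    return canvas


# --------------------------------------------------------------------------
# cartridge generation
# --------------------------------------------------------------------------

def _default_mix() -> dict[str, int]:
    return {
        ObjectKind.CTC_PRETTY.value: 2,
        ObjectKind.CTC_HETEROGENEOUS.value: 2,
        ObjectKind.CTC_CLUSTER.value: 1,
        ObjectKind.CTC_CLEAVED.value: 1,
        ObjectKind.CTC_FRAGMENTED.value: 1,
        ObjectKind.CTC_CLEAVED_FRAGMENTED.value: 1,
        ObjectKind.TDEV.value: 30,
        ObjectKind.LEUKOCYTE.value: 40,
        ObjectKind.DEBRIS.value: 3,
    }


@dataclass
class CartridgeConfig:
    """Generation parameters for one synthetic cartridge.

    The full-scale instrument scans 175 frames per cartridge; the default
    here is scaled down to 4 frames for tractable tests and is fully
    configurable.
    """

    n_frames: int = 4
    frame_shape: tuple[int, int] = (512, 512)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    background: float = 2.0
    noise_sd: float = 0.0
    object_mix: dict[str, int] = field(default_factory=_default_mix)
    spacing_margin_px: float = 8.0
    border_pad_px: float = 4.0
    max_placement_tries: int = 5000
    cartridge_id: str = "synthetic"


@dataclass
class GroundTruth:
    """Planted objects with their expected gate outcome and subclass.

    ``expected_gate`` is obtained by pushing each object's idealized
    FeatureVector through the downstream gate set — by construction there
    is no independent labelling path.
    """

    specs: list[ObjectSpec]
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def expected_counts(self) -> dict[str, int]:
        g = self.table["expected_gate"]
        return {
            "ctc": int((g == LABEL_CTC).sum()),
            "tdev": int((g == LABEL_TDEV).sum()),
            "neither": int((g == LABEL_NEITHER).sum()),
        }

    def to_csv(self, path: str | Path) -> None:
        # %.17g keeps the float fields bit-exact through the round trip
        self.table.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruth":
        table = pd.read_csv(path, float_precision="round_trip")
        specs = [ObjectSpec.from_row(r) for r in table.to_dict("records")]
        return cls(specs=specs, table=table)


def build_ground_truth(
    specs: list[ObjectSpec],
    pixel_size: float,
    background: float,
    gateset: GateSet | None = None,
) -> GroundTruth:
    """Label specs with expected gate outcomes via idealized features."""
    if gateset is None:
        gateset = default_gateset()
    rows = []
    for spec in specs:
        fv = idealized_features(spec, pixel_size, background)
        expected = LABEL_NEITHER
        for gate in gateset.gates:
            if apply_gate(fv, gate):
                expected = {"ctc": LABEL_CTC, "tdev": LABEL_TDEV}.get(
                    gate.name, gate.name
                )
                break
        row = spec.to_row()
        row["expected_gate"] = expected
        row["expected_subclass"] = SUBCLASS_FOR_KIND.get(spec.kind, "")
        rows.append(row)
    return GroundTruth(specs=specs, table=pd.DataFrame(rows))


def generate_cartridge(
    config: CartridgeConfig | None = None,
    seed: int = 0,
    gateset: GateSet | None = None,
) -> tuple[CartridgeStack, GroundTruth]:
    """Generate a four-channel cartridge stack with planted ground truth.

    Deterministic for fixed (config, seed).  Objects are placed by rejection
    sampling with a minimum centre-to-centre spacing of the two bounding
    radii plus ``spacing_margin_px``; an infeasible packing raises an error
    naming the frame.
    """
    if config is None:
        config = CartridgeConfig()
    rng = np.random.default_rng(seed)
    h, w = config.frame_shape
    ps = config.pixel_size

    specs: list[ObjectSpec] = []
    object_id = 0
    for kind, count in sorted(config.object_mix.items()):
        for _ in range(int(count)):
            spec = random_object_spec(kind, rng, object_id=object_id)
            spec.frame = int(rng.integers(config.n_frames))
            specs.append(spec)
            object_id += 1

    # place objects frame by frame
    for f in range(config.n_frames):
        placed: list[tuple[float, float, float]] = []
        for spec in specs:
            if spec.frame != f:
                continue
            radius = spec.bounding_radius(ps)
            pad = config.border_pad_px + radius
            if pad * 2 >= min(h, w):
                raise CartridgeError(
                    f"object {spec.object_id} too large for frame {f}"
                )
            for _ in range(config.max_placement_tries):
                r = rng.uniform(pad, h - 1 - pad)
                c = rng.uniform(pad, w - 1 - pad)
                if all(
                    np.hypot(r - pr, c - pc)
                    >= radius + prad + config.spacing_margin_px
                    for pr, pc, prad in placed
                ):
                    spec.row, spec.col = float(r), float(c)
                    placed.append((r, c, radius))
                    break
            else:
                raise CartridgeError(
                    f"could not place object {spec.object_id} in frame {f} "
                    f"after {config.max_placement_tries} tries"
                )

    canvas = np.full(
        (config.n_frames, len(CHANNEL_ORDER), h, w),
        float(config.background),
    )
    for spec in specs:
        render_object(spec, canvas[spec.frame], ps)
    if config.noise_sd > 0:
        canvas += rng.normal(0.0, config.noise_sd, size=canvas.shape)
    frames = np.rint(np.clip(canvas, 0, ADU_MAX)).astype(np.uint16)

    stack = CartridgeStack(
        frames=frames,
        pixel_size=ps,
        cartridge_id=config.cartridge_id,
    )
    truth = build_ground_truth(specs, ps, config.background, gateset)
    return stack, truth


def single_object_stack(
    spec: ObjectSpec,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    background: float = 2.0,
    pad: int = 8,
) -> CartridgeStack:
    """Render one object centred on its own minimal single-frame stack."""
    radius = spec.bounding_radius(pixel_size)
    size = 2 * int(math.ceil(radius + pad))  # even: integer centre
    spec = ObjectSpec.from_row({**spec.to_row(), "frame": 0,
                                "row": size / 2.0, "col": size / 2.0})
    canvas = np.full((len(CHANNEL_ORDER), size, size), float(background))
    render_object(spec, canvas, pixel_size)
    frames = np.rint(np.clip(canvas, 0, ADU_MAX)).astype(np.uint16)[None]
    return CartridgeStack(frames=frames, pixel_size=pixel_size,
                          cartridge_id=f"single-{spec.kind.value}")


def match_events_to_truth(
    events, truth: GroundTruth, max_dist_px: float = 10.0
) -> pd.DataFrame:
    """Greedy nearest-centroid matching of detected events to planted objects.

    Returns a frame with columns ``object_id`` (detected) and
    ``truth_object_id`` (planted; -1 for unmatched detections).
    """
    rows = []
    used: set[int] = set()
    for ev in events:
        r, c = ev.centroid
        best, best_d = -1, max_dist_px
        for spec in truth.specs:
            if spec.frame != ev.frame_index or spec.object_id in used:
                continue
            d = float(np.hypot(spec.row - r, spec.col - c))
            if d < best_d:
                best, best_d = spec.object_id, d
        if best >= 0:
            used.add(best)
        rows.append({"object_id": ev.object_id, "truth_object_id": best})
    return pd.DataFrame(rows, columns=["object_id", "truth_object_id"])


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

STAGE_CNPC = "CNPC"
STAGE_CRPC = "CRPC"
TIMEPOINT_BASELINE = "BASELINE"
TIMEPOINT_POST = "POST_ADT_6M"

SUBCLASS_COLUMNS = [
    "cluster",
    "pretty",
    "heterogeneous_ck",
    "cleaved_ck",
    "fragmented",
    "cleaved_ck_fragmented_dna",
]


@dataclass
class CohortModel:
    """Zero-inflated log-normal burden model for one disease stage.

    ``log_burden_mu``/``log_burden_sigma`` parametrize the latent log
    burden; CTC and tdEV counts are floors of log-normal functions of one
    latent draw plus independent noise, which induces the strong CTC-tdEV
    rank correlation.  Follow-up parameters describe the narrower burden
    distribution of the inclusion-restricted post-ADT sub-cohort and the
    log-normal treatment decline factor.
    """

    stage: str
    log_burden_mu: float
    log_burden_sigma: float
    ctc_noise_sd: float = 0.5
    tdev_noise_sd: float = 0.5
    log_tdev_multiplier_mu: float = math.log(9.0)
    log_tdev_multiplier_sigma: float = 0.25
    zero_inflation: float = 0.0
    followup_log_mu: float = math.log(8.0)
    followup_log_sigma: float = 1.0
    log_decline_mu: float = math.log(0.15)
    log_decline_sigma: float = 0.4
    subclass_props: tuple[float, ...] = (
        0.06, 0.22, 0.34, 0.15, 0.13, 0.10,
    )
    spearman_target_band: tuple[float, float] = (0.80, 0.95)

    def __post_init__(self) -> None:
        for name in (
            "log_burden_sigma",
            "ctc_noise_sd",
            "tdev_noise_sd",
            "log_tdev_multiplier_sigma",
            "followup_log_sigma",
            "log_decline_sigma",
        ):
            if getattr(self, name) <= 0:
                raise CartridgeError(f"{name} must be positive")
        if not 0 <= self.zero_inflation <= 1:
            raise CartridgeError("zero_inflation must be in [0, 1]")
        if abs(sum(self.subclass_props) - 1.0) > 1e-9:
            raise CartridgeError("subclass_props must sum to 1")

    @classmethod
    def cnpc(cls) -> "CohortModel":
        return cls(
            stage=STAGE_CNPC,
            log_burden_mu=math.log(1.6),
            log_burden_sigma=2.0,
            log_tdev_multiplier_mu=math.log(7.0),
            subclass_props=(0.06, 0.22, 0.34, 0.15, 0.13, 0.10),
        )

    @classmethod
    def crpc(cls) -> "CohortModel":
        return cls(
            stage=STAGE_CRPC,
            log_burden_mu=math.log(4.2),
            log_burden_sigma=1.9,
            log_tdev_multiplier_mu=math.log(12.0),
            subclass_props=(0.11, 0.19, 0.35, 0.15, 0.11, 0.09),
        )


def default_cohort_models() -> dict[str, CohortModel]:
    return {STAGE_CNPC: CohortModel.cnpc(), STAGE_CRPC: CohortModel.crpc()}


def simulate_cohort(
    models: dict[str, CohortModel] | None = None,
    n_per_stage: int = 500,
    seed: int = 0,
    n_paired: int = 0,
) -> pd.DataFrame:
    """Simulate per-patient CTC/tdEV/subclass counts for each stage.

    ``n_paired`` patients of the CNPC stage additionally get a
    ``POST_ADT_6M`` row drawn with the model's decline factor; their
    baseline burden uses the follow-up (inclusion-restricted) parameters.
    """
    if models is None:
        models = default_cohort_models()
    if n_per_stage < 2:
        raise CartridgeError("n_per_stage must be >= 2")
    if n_paired < 0:
        raise CartridgeError("n_paired must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for stage in sorted(models):
        m = models[stage]
        paired_here = n_paired if stage == STAGE_CNPC else 0
        if paired_here > n_per_stage:
            raise CartridgeError("n_paired exceeds n_per_stage")
        for i in range(n_per_stage):
            pid = f"{stage}-{i:04d}"
            paired = i < paired_here
            if paired:
                latent = rng.normal(m.followup_log_mu, m.followup_log_sigma)
            else:
                latent = rng.normal(m.log_burden_mu, m.log_burden_sigma)
            mult = math.exp(
                rng.normal(m.log_tdev_multiplier_mu, m.log_tdev_multiplier_sigma)
            )
            structural_zero = rng.random() < m.zero_inflation
            ctc_cont = math.exp(latent + rng.normal(0, m.ctc_noise_sd))
            tdev_cont = mult * math.exp(
                latent + rng.normal(0, m.tdev_noise_sd)
            )
            ctc = 0 if structural_zero else int(ctc_cont)
            tdev = 0 if structural_zero else int(tdev_cont)
            sub = rng.multinomial(ctc, m.subclass_props)
            rows.append(
                {
                    "patient_id": pid,
                    "stage": stage,
                    "timepoint": TIMEPOINT_BASELINE,
                    "ctc": ctc,
                    "tdev": tdev,
                    **dict(zip(SUBCLASS_COLUMNS, sub.tolist())),
                }
            )
            if paired:
                d_ctc = math.exp(
                    rng.normal(m.log_decline_mu, m.log_decline_sigma)
                )
                d_tdev = math.exp(
                    rng.normal(m.log_decline_mu, m.log_decline_sigma)
                )
                pc = 0 if structural_zero else int(ctc_cont * d_ctc)
                pt = 0 if structural_zero else int(tdev_cont * d_tdev)
                sub_p = rng.multinomial(pc, m.subclass_props)
                rows.append(
                    {
                        "patient_id": pid,
                        "stage": stage,
                        "timepoint": TIMEPOINT_POST,
                        "ctc": pc,
                        "tdev": pt,
                        **dict(zip(SUBCLASS_COLUMNS, sub_p.tolist())),
                    }
                )
    return pd.DataFrame(rows)
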