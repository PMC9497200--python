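"""Rule-based assignment of CTC events to six morphological subclasses.

The classes follow the standard morphological reading of cytokeratin (CK)
and DAPI staining in CellSearch-type images:

1. ``CLUSTER`` — two or more intact nuclei within the CK staining;
2. ``PRETTY`` — intact nucleus, homogeneous strong CK;
3. ``HETEROGENEOUS_CK`` — non-uniform CK distribution or irregular shape;
4. ``CLEAVED_CK`` — apoptotic CK reduced to round speckles;
5. ``FRAGMENTED`` — fragmented nucleus or fragmented CK;
6. ``CLEAVED_CK_FRAGMENTED_DNA`` — speckled CK together with broken nuclei.

The original assignment was done by human reviewers; every numeric
threshold here (CV cut, solidity cut, speckle area/roundness, minimum
nucleus area) is an explicit operationalization of the verbal criteria,
surfaced in :class:`SubclassParams`.  The decision cascade is first-match
and total, so every CTC event receives exactly one label; the cascade
order is part of the contract (permuting the speckle/fragment steps
changes labels on edge cases).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.morphology import convex_hull_image

from .core import CartridgeError, CartridgeStack, DetectedObject
from .gating import LABEL_CTC
from .morphometry import mask_eccentricity

SUBCLASS_LABELS = (
    "CLUSTER",
    "PRETTY",
    "HETEROGENEOUS_CK",
    "CLEAVED_CK",
    "FRAGMENTED",
    "CLEAVED_CK_FRAGMENTED_DNA",
)

EVIDENCE_COLUMNS = (
    "nuclei_in_ck",
    "ck_cv",
    "ck_component_count",
    "speckle_flag",
    "dna_fragment_count",
    "shape_irregularity",
)


@dataclass
class SubclassParams:
    """Operationalized thresholds for the six-class cascade.

    tau_cv : CK intensity CV above which staining counts as heterogeneous.
    tau_shape : 1 - solidity above which the CK shape counts as irregular.
    speckle_area_um2 : maximum area of one CK component to count as a speckle.
    speckle_ecc_max : maximum eccentricity of a speckle (roundness).
    min_speckles : number of small round CK components that sets the
        speckle flag.
    min_nucleus_area_um2 : DAPI components at least this large count as
        intact nuclei; smaller ones are treated as fragments of a broken
        nucleus.  Without the size cut, a nucleus split in two inside an
        intact CK disc would be indistinguishable from a two-nucleus
        cluster.
    """

    tau_cv: float = 0.25
    tau_shape: float = 0.15
    speckle_area_um2: float = 16.0
    speckle_ecc_max: float = 0.8
    min_speckles: int = 3
    min_nucleus_area_um2: float = 20.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Evidence:
    """Quantities the decision cascade used for one event."""

    nuclei_in_ck: int
    ck_cv: float
    ck_component_count: int
    speckle_flag: bool
    dna_fragment_count: int
    shape_irregularity: float


def count_nuclei_in_ck(
    obj: DetectedObject,
    pixel_size: float,
    params: SubclassParams | None = None,
) -> int:
    """Number of intact nuclei under the CK staining.

    Counts DAPI connected components whose centroid falls inside the CK
    mask and whose area reaches ``min_nucleus_area_um2``.
    """
    if params is None:
        params = SubclassParams()
    ck = obj.mask("ck")
    if not ck.any():
        raise CartridgeError(
            f"object {obj.object_id}: empty CK mask (not a CTC)"
        )
    dapi = obj.mask("dapi")
    labels = cc_label(dapi, connectivity=2)
    n = 0
    for i in range(1, labels.max() + 1):
        comp = labels == i
        if comp.sum() * pixel_size**2 < params.min_nucleus_area_um2:
            continue
        rr, cc = np.nonzero(comp)
        r = int(round(rr.mean()))
        c = int(round(cc.mean()))
        r = min(max(r, 0), ck.shape[0] - 1)
        c = min(max(c, 0), ck.shape[1] - 1)
        if ck[r, c]:
            n += 1
    return n


def ck_texture(
    obj: DetectedObject, stack: CartridgeStack
) -> dict[str, float]:
    """CK intensity CV and shape irregularity (1 - solidity) of the event."""
    ck = obj.mask("ck")
    if not ck.any():
        raise CartridgeError(f"object {obj.object_id}: empty CK mask")
    r0, r1, c0, c1 = obj.bbox
    img = stack.logical_channel(obj.frame_index, "ck")[r0:r1, c0:c1]
    vals = img[ck].astype(float)
    mean = vals.mean()
    cv = float(vals.std() / mean) if mean > 0 else 0.0
    hull = convex_hull_image(ck)
    irregularity = float(1.0 - ck.sum() / hull.sum()) if hull.any() else 0.0
    return {"ck_cv": cv, "shape_irregularity": irregularity}


def speckle_and_fragmentation(
    obj: DetectedObject,
    pixel_size: float,
    params: SubclassParams | None = None,
) -> dict[str, int | bool]:
    """CK component count, speckle flag and DAPI fragment count.

    The speckle flag is set when at least ``min_speckles`` CK components
    are individually small (area <= ``speckle_area_um2``) and round
    (eccentricity <= ``speckle_ecc_max``).
    """
    if params is None:
        params = SubclassParams()
    ck_labels = cc_label(obj.mask("ck"), connectivity=2)
    n_ck = int(ck_labels.max())
    n_speckle = 0
    for i in range(1, n_ck + 1):
        comp = ck_labels == i
        if comp.sum() * pixel_size**2 > params.speckle_area_um2:
            continue
        if mask_eccentricity(comp) > params.speckle_ecc_max:
            continue
        n_speckle += 1
    dna = int(cc_label(obj.mask("dapi"), connectivity=2).max())
    return {
        "ck_component_count": n_ck,
        "speckle_flag": n_speckle >= params.min_speckles,
        "dna_fragment_count": dna,
    }


def gather_evidence(
    obj: DetectedObject,
    stack: CartridgeStack,
    params: SubclassParams | None = None,
) -> Evidence:
    if params is None:
        params = SubclassParams()
    tex = ck_texture(obj, stack)
    frag = speckle_and_fragmentation(obj, stack.pixel_size, params)
    return Evidence(
        nuclei_in_ck=count_nuclei_in_ck(obj, stack.pixel_size, params),
        ck_cv=tex["ck_cv"],
        ck_component_count=int(frag["ck_component_count"]),
        speckle_flag=bool(frag["speckle_flag"]),
        dna_fragment_count=int(frag["dna_fragment_count"]),
        shape_irregularity=tex["shape_irregularity"],
    )


def classify_subclass(
    evidence: Evidence, params: SubclassParams | None = None
) -> str:
    """First-match cascade mapping evidence to one of the six labels.

    1. >= 2 intact nuclei, none broken -> CLUSTER;
    2. speckled CK and >= 2 DNA fragments -> CLEAVED_CK_FRAGMENTED_DNA;
    3. speckled CK -> CLEAVED_CK;
    4. fragmented DNA or fragmented (non-speckle) CK -> FRAGMENTED;
    5. heterogeneous CK intensity or irregular shape -> HETEROGENEOUS_CK;
    6. otherwise -> PRETTY.
    """
    if params is None:
        params = SubclassParams()
    e = evidence
    for name in EVIDENCE_COLUMNS:
        if getattr(e, name, None) is None:
            raise CartridgeError(f"incomplete evidence: missing {name}")
    if e.nuclei_in_ck >= 2 and e.dna_fragment_count == e.nuclei_in_ck:
        return "CLUSTER"
    if e.speckle_flag and e.dna_fragment_count >= 2:
        return "CLEAVED_CK_FRAGMENTED_DNA"
    if e.speckle_flag:
        return "CLEAVED_CK"
    if e.dna_fragment_count >= 2 or e.ck_component_count >= 2:
        return "FRAGMENTED"
    if e.ck_cv > params.tau_cv or e.shape_irregularity > params.tau_shape:
        return "HETEROGENEOUS_CK"
    return "PRETTY"


def classify_events(
    events: Iterable[DetectedObject],
    stack: CartridgeStack,
    gated: pd.DataFrame,
    params: SubclassParams | None = None,
) -> pd.DataFrame:
    """Attach ``subclass`` and evidence columns to CTC-labelled rows.

    Non-CTC rows keep an empty subclass and NaN evidence; tdEV events never
    carry a subclass.
    """
    if params is None:
        params = SubclassParams()
    by_id = {ev.object_id: ev for ev in events}
    out = gated.copy()
    labels: dict = {}
    evidence: dict = {}
    for idx, row in out.iterrows():
        if row["gate_label"] != LABEL_CTC:
            continue
        obj = by_id.get(row["object_id"])
        if obj is None:
            raise CartridgeError(
                f"gated table references unknown object {row['object_id']}"
            )
        ev = gather_evidence(obj, stack, params)
        labels[idx] = classify_subclass(ev, params)
        evidence[idx] = ev
    out["subclass"] = pd.Series(labels, dtype="object").reindex(
        out.index, fill_value=""
    )
    for col in EVIDENCE_COLUMNS:
        out[col] = pd.Series(
            {i: getattr(e, col) for i, e in evidence.items()}
        ).reindex(out.index)
    return out
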