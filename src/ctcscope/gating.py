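"""Linear gates: named conjunctions of one-sided threshold predicates.

A gate passes an object when *all* of its predicates hold.  Only the two
operators that occur in the instrument's gate table are allowed: ``<=``
(inclusive) and ``>`` (strict).  The shipped default (``gates/table1.yaml``)
encodes the CTC gate (8 predicates) and the tdEV gate (11 predicates)
bit-exact as printed; under these defaults the two gates are mutually
exclusive (the CTC gate requires mean DAPI > 45 AU, the tdEV gate
mean DAPI <= 5 AU).

Events are labelled CTC if they pass the CTC gate, else tdEV if they pass
the tdEV gate, else NEITHER; a review annotation layer can then exclude
CTC-gate passers identified as debris/artifacts, yielding the corrected
CTC count (tdEV counts are never review-corrected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import CartridgeError
from .morphometry import COLUMN_FOR

log = logging.getLogger(__name__)

ALLOWED_OPS = ("<=", ">")

GATE_CTC = "ctc"
GATE_TDEV = "tdev"
LABEL_CTC = "CTC"
LABEL_TDEV = "TDEV"
LABEL_NEITHER = "NEITHER"

REVIEW_UNREVIEWED = "UNREVIEWED"
REVIEW_CONFIRMED = "CONFIRMED"
REVIEW_EXCLUDED = "EXCLUDED_ARTIFACT"


@dataclass(frozen=True)
class Predicate:
    feature: str
    channel: str
    op: str
    threshold: float
    units: str = "AU"

    def __post_init__(self) -> None:
        if self.op not in ALLOWED_OPS:
            raise CartridgeError(
                f"operator {self.op!r} not allowed (use one of {ALLOWED_OPS})"
            )
        if not np.isfinite(self.threshold):
            raise CartridgeError("predicate threshold must be finite")
        if (self.feature, self.channel) not in COLUMN_FOR:
            raise CartridgeError(
                f"unknown feature/channel pair "
                f"({self.feature!r}, {self.channel!r})"
            )

    @property
    def column(self) -> str:
        return COLUMN_FOR[(self.feature, self.channel)]

    def evaluate(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value > self.threshold


@dataclass(frozen=True)
class Gate:
    name: str
    predicates: tuple[Predicate, ...]

    def __post_init__(self) -> None:
        if not self.predicates:
            raise CartridgeError(f"gate {self.name!r} has no predicates")


@dataclass
class GateSet:
    """Ordered gates; the first listed gate has labelling priority."""

    gates: tuple[Gate, ...]

    def __post_init__(self) -> None:
        names = [g.name for g in self.gates]
        if len(set(names)) != len(names):
            raise CartridgeError(f"duplicate gate names in {names}")

    def __getitem__(self, name: str) -> Gate:
        for g in self.gates:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.gates)

    def to_dict(self) -> dict:
        return {
            "gates": [
                {
                    "name": g.name,
                    "predicates": [
                        {
                            "feature": p.feature,
                            "channel": p.channel,
                            "op": p.op,
                            "threshold": p.threshold,
                            "units": p.units,
                        }
                        for p in g.predicates
                    ],
                }
                for g in self.gates
            ]
        }


def _gateset_from_dict(doc: dict, source: str) -> GateSet:
    try:
        raw_gates = doc["gates"]
    except (TypeError, KeyError):
        raise CartridgeError(f"{source}: no top-level 'gates' list") from None
    gates = []
    for gi, g in enumerate(raw_gates):
        preds = []
        for pi, p in enumerate(g.get("predicates", [])):
            where = f"{source}: gate #{gi} ({g.get('name')!r}) predicate #{pi}"
            try:
                preds.append(
                    Predicate(
                        feature=str(p["feature"]),
                        channel=str(p["channel"]),
                        op=str(p["op"]),
                        threshold=float(p["threshold"]),
                        units=str(p.get("units", "AU")),
                    )
                )
            except (KeyError, TypeError, ValueError, CartridgeError) as e:
                raise CartridgeError(f"{where}: {e}") from None
        gates.append(Gate(name=str(g["name"]), predicates=tuple(preds)))
    return GateSet(gates=tuple(gates))


def load_gateset(path: str | Path) -> GateSet:
    """Load a YAML gate configuration; malformed predicates are reported
    with the offending gate/predicate index."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _gateset_from_dict(doc, str(path))


def save_gateset(gateset: GateSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(gateset.to_dict(), fh, sort_keys=False)


def default_gateset() -> GateSet:
    """The shipped CTC/tdEV gate table."""
    text = (
        resources.files("ctcscope").joinpath("gates/table1.yaml").read_text()
    )
    return _gateset_from_dict(yaml.safe_load(text), "gates/table1.yaml")


# --------------------------------------------------------------------------
# application
# --------------------------------------------------------------------------

def apply_gate(fv: Mapping[str, float], gate: Gate) -> bool:
    """Conjunction of all predicates on a single feature vector.

    Missing features raise; they are never treated as a silent fail.
    """
    for p in gate.predicates:
        if p.column not in fv:
            raise CartridgeError(
                f"feature vector is missing {p.column!r} required by gate "
                f"{gate.name!r}"
            )
        if not p.evaluate(float(fv[p.column])):
            return False
    return True


def apply_gate_table(table: pd.DataFrame, gate: Gate) -> pd.Series:
    """Vectorized gate evaluation: boolean Series indexed like ``table``."""
    ok = pd.Series(True, index=table.index)
    for p in gate.predicates:
        if p.column not in table.columns:
            raise CartridgeError(
                f"feature table is missing column {p.column!r} required by "
                f"gate {gate.name!r}"
            )
        col = table[p.column].astype(float)
        ok &= (col <= p.threshold) if p.op == "<=" else (col > p.threshold)
    return ok


@dataclass
class GateCounts:
    ctc_accept: int
    tdev_accept: int
    ctc_accept_corrected: int | None = None


def enumerate_events(
    table: pd.DataFrame, gateset: GateSet | None = None
) -> tuple[pd.DataFrame, GateCounts]:
    """Label every feature-table row and count CTC / tdEV events.

    Labelling priority follows gate order (CTC before tdEV); under the
    default gates the order is irrelevant because the gates are mutually
    exclusive on mean DAPI.
    """
    if gateset is None:
        gateset = default_gateset()
    if table["object_id"].duplicated().any():
        dupes = table.loc[table["object_id"].duplicated(), "object_id"].tolist()
        raise CartridgeError(f"duplicate object_id values: {dupes[:5]}")
    out = table.copy()
    label = pd.Series(LABEL_NEITHER, index=out.index)
    assigned = pd.Series(False, index=out.index)
    for gate in gateset.gates:
        passed = apply_gate_table(out, gate) & ~assigned
        if gate.name == GATE_CTC:
            label[passed] = LABEL_CTC
        elif gate.name == GATE_TDEV:
            label[passed] = LABEL_TDEV
        else:
            label[passed] = gate.name
        assigned |= passed
    out["gate_label"] = label
    out["review_status"] = REVIEW_UNREVIEWED
    counts = GateCounts(
        ctc_accept=int((label == LABEL_CTC).sum()),
        tdev_accept=int((label == LABEL_TDEV).sum()),
    )
    return out, counts


def apply_review(
    events: pd.DataFrame, annotations: pd.DataFrame | None
) -> tuple[pd.DataFrame, GateCounts]:
    """Apply per-object review labels and compute corrected counts.

    ``annotations`` has columns ``object_id`` and ``review_status``
    (CONFIRMED or EXCLUDED_ARTIFACT).  Unannotated events default to
    CONFIRMED.  Only CTC counts are corrected; excluding a non-CTC event
    leaves the counts unchanged (a warning is logged).
    """
    out = events.copy()
    out["review_status"] = REVIEW_CONFIRMED
    if annotations is not None and len(annotations):
        known = set(out["object_id"])
        unknown = set(annotations["object_id"]) - known
        if unknown:
            raise CartridgeError(
                f"annotations for unknown object ids: {sorted(unknown)[:5]}"
            )
        bad = set(annotations["review_status"]) - {
            REVIEW_CONFIRMED,
            REVIEW_EXCLUDED,
        }
        if bad:
            raise CartridgeError(f"unknown review labels: {sorted(bad)}")
        status = annotations.set_index("object_id")["review_status"]
        idx = out["object_id"].map(status)
        out.loc[idx.notna(), "review_status"] = idx[idx.notna()]
        stray = out[
            (out["review_status"] == REVIEW_EXCLUDED)
            & (out["gate_label"] != LABEL_CTC)
        ]
        if len(stray):
            log.warning(
                "review excluded %d non-CTC event(s); counts unchanged: %s",
                len(stray),
                stray["object_id"].tolist()[:5],
            )
    ctc = out["gate_label"] == LABEL_CTC
    excluded = ctc & (out["review_status"] == REVIEW_EXCLUDED)
    counts = GateCounts(
        ctc_accept=int(ctc.sum()),
        tdev_accept=int((out["gate_label"] == LABEL_TDEV).sum()),
        ctc_accept_corrected=int(ctc.sum() - excluded.sum()),
    )
    return out, counts


def flag_suspect_events(
    events: pd.DataFrame, max_ck_size_um2: float = 400.0
) -> pd.DataFrame:
    """Optional heuristic pre-reviewer (off by default in the pipeline).

    Flags CTC-labelled events whose CK footprint touches the frame border or
    exceeds ``max_ck_size_um2`` as candidate artifacts; output has the shape
    of an annotation table.
    """
    ctc = events[events["gate_label"] == LABEL_CTC]
    suspect = ctc[ctc["size_ck"] > max_ck_size_um2]
    return pd.DataFrame(
        {
            "object_id": suspect["object_id"],
            "review_status": REVIEW_EXCLUDED,
        }
    )
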