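"""Gate configuration, application, enumeration and review correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctcscope import (
    CartridgeError,
    ObjectKind,
    apply_gate,
    apply_gate_table,
    apply_review,
    default_gateset,
    enumerate_events,
    idealized_features,
    load_gateset,
    random_object_spec,
    save_gateset,
)
from ctcscope.gating import GATE_CTC, GATE_TDEV, LABEL_CTC, LABEL_TDEV
from ctcscope.morphometry import FEATURE_COLUMNS


def random_feature_table(n, rng):
    """Random but schema-consistent feature vectors spanning the thresholds."""
    df = pd.DataFrame({"object_id": np.arange(n), "frame": 0,
                       "bbox_r0": 0, "bbox_r1": 1, "bbox_c0": 0,
                       "bbox_c1": 1})
    for ch in ("dapi", "ck", "cd45", "m1", "m2"):
        mean = rng.uniform(0, 120, n)
        df[f"mean_{ch}"] = mean
        df[f"max_{ch}"] = mean + rng.uniform(0, 80, n)
        df[f"area_{ch}"] = rng.uniform(0, 500, n)
        df[f"empty_{ch}"] = False
    df["size_ck"] = df["area_ck"]
    df["eccentricity_ck"] = rng.uniform(0, 1, n)
    df["perimeter_ck"] = rng.integers(0, 40, n).astype(float)
    df["perimeter_to_area_ck"] = rng.uniform(0, 3, n)
    df["overlay_ck_dapi"] = rng.uniform(0, 1, n)
    return df


def brute_force_labels(df, gateset):
    """Per-row, per-predicate Python evaluation (oracle path)."""
    labels = []
    for _, row in df.iterrows():
        lab = "NEITHER"
        for gate in gateset.gates:
            ok = all(
                (row[p.column] <= p.threshold)
                if p.op == "<="
                else (row[p.column] > p.threshold)
                for p in gate.predicates
            )
            if ok:
                lab = {"ctc": LABEL_CTC, "tdev": LABEL_TDEV}[gate.name]
                break
        labels.append(lab)
    return labels


class TestGateConfig:
    def test_default_gate_predicate_counts(self):
        gs = default_gateset()
        assert len(gs[GATE_CTC].predicates) == 8
        assert len(gs[GATE_TDEV].predicates) == 11

    def test_strictness_as_printed(self):
        gs = default_gateset()
        ops = {
            (p.feature, p.channel, p.op) for p in gs[GATE_CTC].predicates
        }
        assert ("mean_intensity", "dapi", ">") in ops
        assert ("mean_intensity", "cd45", "<=") in ops

    def test_unknown_operator_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            "gates:\n- name: g\n  predicates:\n"
            "  - {feature: mean_intensity, channel: ck, op: '<',"
            " threshold: 5}\n"
        )
        with pytest.raises(CartridgeError, match="predicate #0"):
            load_gateset(bad)

    def test_unknown_feature_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            "gates:\n- name: g\n  predicates:\n"
            "  - {feature: sparkle, channel: ck, op: '>', threshold: 5}\n"
        )
        with pytest.raises(CartridgeError):
            load_gateset(bad)

    def test_round_trip_is_identical(self, tmp_path):
        gs = default_gateset()
        path = tmp_path / "gates.yaml"
        save_gateset(gs, path)
        back = load_gateset(path)
        assert back.to_dict() == gs.to_dict()


class TestApplyGate:
    def _passing_ctc_vector(self):
        return {
            "mean_cd45": 0.0, "mean_dapi": 200.0, "mean_ck": 150.0,
            "size_ck": 80.0, "overlay_ck_dapi": 0.5, "mean_m1": 0.0,
            "mean_m2": 0.0,
        }

    def test_boundary_mean_ck_60_fails_strict(self):
        gs = default_gateset()
        fv = self._passing_ctc_vector()
        fv["mean_ck"] = 60.0
        assert not apply_gate(fv, gs[GATE_CTC])

    def test_boundary_mean_cd45_5_passes_inclusive(self):
        gs = default_gateset()
        fv = self._passing_ctc_vector()
        fv["mean_cd45"] = 5.0
        assert apply_gate(fv, gs[GATE_CTC])

    def test_missing_feature_raises(self):
        gs = default_gateset()
        fv = self._passing_ctc_vector()
        del fv["overlay_ck_dapi"]
        with pytest.raises(CartridgeError, match="overlay_ck_dapi"):
            apply_gate(fv, gs[GATE_CTC])

    def test_tdev_archetype_passes_tdev_not_ctc(self):
        gs = default_gateset()
        spec = random_object_spec(ObjectKind.TDEV, np.random.default_rng(0))
        fv = idealized_features(spec, 0.64)
        assert apply_gate(fv, gs[GATE_TDEV])
        assert not apply_gate(fv, gs[GATE_CTC])

    def test_default_gates_mutually_exclusive_on_random_vectors(self, rng):
        gs = default_gateset()
        df = random_feature_table(2000, rng)
        both = apply_gate_table(df, gs[GATE_CTC]) & apply_gate_table(
            df, gs[GATE_TDEV]
        )
        assert not both.any()

    @settings(max_examples=50, derandomize=True)
    @given(delta=st.floats(0.1, 50), which=st.integers(0, 7))
    def test_tightening_a_threshold_never_admits_more(self, delta, which):
        from ctcscope.gating import Gate, Predicate

        rng = np.random.default_rng(7)
        df = random_feature_table(300, rng)
        gs = default_gateset()
        gate = gs[GATE_CTC]
        before = int(apply_gate_table(df, gate).sum())
        preds = list(gate.predicates)
        p = preds[which]
        moved = Predicate(
            feature=p.feature, channel=p.channel, op=p.op,
            threshold=p.threshold + delta if p.op == ">" else
            p.threshold - delta,
            units=p.units,
        )
        preds[which] = moved
        after = int(
            apply_gate_table(df, Gate(name="t", predicates=tuple(preds))).sum()
        )
        assert after <= before


class TestEnumerateAndReview:
    def test_empty_table_counts_zero(self):
        empty = pd.DataFrame(
            columns=["object_id", "frame", "bbox_r0", "bbox_r1",
                     "bbox_c0", "bbox_c1"] + FEATURE_COLUMNS
        )
        _, counts = enumerate_events(empty)
        assert counts.ctc_accept == 0 and counts.tdev_accept == 0

    def test_duplicate_object_id_rejected(self, rng):
        df = random_feature_table(4, rng)
        df.loc[3, "object_id"] = 0
        with pytest.raises(CartridgeError, match="duplicate"):
            enumerate_events(df)

    def test_leukocyte_archetypes_count_nothing(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            spec = random_object_spec(ObjectKind.LEUKOCYTE, rng, object_id=i)
            fv = idealized_features(spec, 0.64)
            rows.append({"object_id": i, **fv})
        _, counts = enumerate_events(pd.DataFrame(rows))
        assert counts.ctc_accept == 0 and counts.tdev_accept == 0

    def test_vectorized_equals_brute_force(self, rng):
        gs = default_gateset()
        df = random_feature_table(1500, rng)
        gated, _ = enumerate_events(df, gs)
        assert gated["gate_label"].tolist() == brute_force_labels(df, gs)

    def test_planted_counts_recovered(self, detected):
        truth = detected["truth"].expected_counts
        counts = detected["counts"]
        assert counts.ctc_accept == truth["ctc"]
        assert counts.tdev_accept == truth["tdev"]

    def test_review_defaults_and_arithmetic(self, rng):
        df = random_feature_table(30, rng)
        # force 10 rows into the CTC gate
        ctc_ids = list(range(10))
        for i in ctc_ids:
            df.loc[i, ["mean_cd45", "mean_dapi", "mean_ck", "size_ck",
                       "overlay_ck_dapi", "mean_m1", "mean_m2"]] = [
                0, 200, 150, 80, 0.5, 0, 0]
        gated, counts = enumerate_events(df)
        assert counts.ctc_accept == 10
        # no annotations: corrected equals accept
        reviewed, c0 = apply_review(gated, None)
        assert c0.ctc_accept_corrected == c0.ctc_accept
        # exclude 3 of the CTCs
        ann = pd.DataFrame(
            {"object_id": ctc_ids[:3],
             "review_status": ["EXCLUDED_ARTIFACT"] * 3}
        )
        _, c1 = apply_review(gated, ann)
        assert c1.ctc_accept_corrected == 7
        assert 0 <= c1.ctc_accept_corrected <= c1.ctc_accept

    def test_excluding_tdev_leaves_counts_and_warns(self, rng, caplog):
        df = random_feature_table(10, rng)
        df.loc[0, ["mean_cd45", "mean_dapi", "mean_ck", "max_ck", "area_ck",
                   "eccentricity_ck", "perimeter_to_area_ck", "perimeter_ck",
                   "size_ck", "mean_m1", "mean_m2"]] = [
            0, 0, 150, 200, 50, 0.2, 0.5, 20, 50, 0, 0]
        gated, counts = enumerate_events(df)
        assert counts.tdev_accept >= 1
        tdev_id = gated.loc[gated["gate_label"] == LABEL_TDEV,
                            "object_id"].iloc[0]
        ann = pd.DataFrame({"object_id": [tdev_id],
                            "review_status": ["EXCLUDED_ARTIFACT"]})
        with caplog.at_level("WARNING"):
            _, c = apply_review(gated, ann)
        assert c.tdev_accept == counts.tdev_accept
        assert any("non-CTC" in r.message for r in caplog.records)

    def test_annotation_for_unknown_id_rejected(self, rng):
        df = random_feature_table(5, rng)
        gated, _ = enumerate_events(df)
        ann = pd.DataFrame({"object_id": [999],
                            "review_status": ["EXCLUDED_ARTIFACT"]})
        with pytest.raises(CartridgeError, match="unknown"):
            apply_review(gated, ann)
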