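"""Tests for outcome labelling, splits, and clinical encoding."""

import numpy as np
import pandas as pd
import pytest

from hncnet.cohort import (
    EXCLUDED,
    NEGATIVE,
    POSITIVE,
    OutcomeSpec,
    PatientRecord,
    cohort_split,
    derive_label,
    encode_clinical,
    encode_cohort,
    fit_clinical_encoding,
    frame_to_records,
    quartile_bin,
    records_to_frame,
    stratified_kfold,
)
from hncnet.errors import ConfigurationError, DataError, StratificationError


def make_record(pid="P0", *, event_dm=0, time_dm=None, followup=800.0, institution="A",
                t_stage="T2", n_stage="N1", volume=5000.0, area=400.0, age=60.0,
                hpv="positive", sex="male"):
    return PatientRecord(
        patient_id=pid, age=age, sex=sex, hpv_status=hpv, site="oropharynx",
        t_stage=t_stage, n_stage=n_stage, overall_stage="III", treatment="chemoradiation",
        event_dm=event_dm, time_dm_days=time_dm, event_lrf=0, time_lrf_days=None,
        event_death=0, time_death_days=None, followup_days=followup,
        gtv_area_mm2=area, gtv_volume_mm3=volume, institution=institution,
    )


DM730 = OutcomeSpec("DM", 730)


class TestDeriveLabel:
    @pytest.mark.parametrize(
        "event, etime, followup, expected",
        [
            (1, 500.0, 500.0, POSITIVE),    # event inside the frame
            (1, 730.0, 730.0, POSITIVE),    # boundary counts as within
            (1, 900.0, 900.0, NEGATIVE),    # event after the frame
            (0, None, 800.0, NEGATIVE),     # event-free, followed past the frame
            (0, None, 730.0, NEGATIVE),     # boundary follow-up suffices
            (0, None, 600.0, EXCLUDED),     # censored before the frame
        ],
    )
    def test_trichotomy(self, event, etime, followup, expected):
        rec = make_record(event_dm=event, time_dm=etime, followup=followup)
        assert derive_label(rec, DM730) == expected

    def test_missing_followup_on_event_free_rejected(self):
        rec = make_record(followup=None)
        with pytest.raises(DataError):
            derive_label(rec, DM730)

    def test_exactly_one_label_for_random_records(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            event = int(rng.random() < 0.4)
            etime = float(rng.uniform(1, 1500)) if event else None
            rec = make_record(event_dm=event, time_dm=etime,
                              followup=etime if event else float(rng.uniform(1, 1500)))
            labels = [derive_label(rec, DM730)]
            assert labels[0] in (POSITIVE, NEGATIVE, EXCLUDED)

    def test_default_frames(self):
        assert OutcomeSpec("DM").time_frame_days == 730
        assert OutcomeSpec("LRF").time_frame_days == 730
        assert OutcomeSpec("OS").time_frame_days == 1460


class TestCohortSplit:
    def test_partition_over_institutions(self):
        recs = [make_record(f"P{i}", institution=inst)
                for i, inst in enumerate(["A", "A", "B", "C", "D", "E", "E"])]
        plan = cohort_split(recs, {"A": "train", "B": "train", "C": "validation",
                                   "D": "validation", "E": "test"})
        roles = [plan.assignment[r.patient_id] for r in recs]
        assert roles == ["train", "train", "train", "validation", "validation", "test", "test"]

    def test_missing_role_rejected(self):
        recs = [make_record("P0", institution="A")]
        with pytest.raises(ConfigurationError):
            cohort_split(recs, {"A": "train"})  # no validation/test institutions

    def test_unknown_institution_rejected(self):
        recs = [make_record("P0", institution="X")]
        with pytest.raises(ConfigurationError):
            cohort_split(recs, {"A": "train", "B": "validation", "C": "test"})

    def test_multicenter_sizes_191_106_137(self):
        # five centers of 91/100/41/65/137 patients mapped 2+2+1
        sizes = {"HGJ": 91, "CHUS": 100, "HMR": 41, "CHUM": 65, "MAASTRO": 137}
        recs = [make_record(f"{inst}_{i}", institution=inst)
                for inst, n in sizes.items() for i in range(n)]
        plan = cohort_split(recs, {"HGJ": "train", "CHUS": "train", "HMR": "validation",
                                   "CHUM": "validation", "MAASTRO": "test"})
        counts = pd.Series(list(plan.assignment.values())).value_counts()
        assert counts["train"] == 191
        assert counts["validation"] == 106
        assert counts["test"] == 137


class TestStratifiedKFold:
    def _cohort(self, n, n_pos):
        recs = []
        for i in range(n):
            event = int(i < n_pos)
            recs.append(make_record(f"P{i}", event_dm=event,
                                    time_dm=300.0 if event else None, followup=900.0))
        return recs

    def test_exact_positive_counts_when_divisible(self):
        recs = self._cohort(297, 40)
        plan = stratified_kfold(recs, 5, DM730, seed=0)
        labels = {r.patient_id: r.event_dm for r in recs}
        folds = pd.Series(plan.assignment)
        for fold in range(5):
            pos = sum(labels[pid] for pid in folds[folds == fold].index)
            assert pos == 8

    def test_tiny_balanced_cohort(self):
        recs = self._cohort(10, 5)
        plan = stratified_kfold(recs, 5, DM730, seed=1)
        labels = {r.patient_id: r.event_dm for r in recs}
        folds = pd.Series(plan.assignment)
        for fold in range(5):
            ids = folds[folds == fold].index
            assert len(ids) == 2
            assert sum(labels[pid] for pid in ids) == 1

    def test_deterministic_under_seed(self):
        recs = self._cohort(60, 12)
        p1 = stratified_kfold(recs, 5, DM730, seed=7)
        p2 = stratified_kfold(recs, 5, DM730, seed=7)
        assert p1.assignment == p2.assignment

    def test_excluded_records_never_assigned(self):
        recs = self._cohort(40, 10) + [make_record("CENSORED", followup=100.0)]
        plan = stratified_kfold(recs, 5, DM730, seed=0)
        assert "CENSORED" not in plan.assignment

    def test_proportion_deviation_bound(self):
        recs = self._cohort(103, 23)
        plan = stratified_kfold(recs, 5, DM730, seed=3)
        labels = {r.patient_id: r.event_dm for r in recs}
        folds = pd.Series(plan.assignment)
        overall = 23 / 103
        for fold in folds.unique():
            ids = folds[folds == fold].index
            frac = sum(labels[pid] for pid in ids) / len(ids)
            assert abs(frac - overall) <= 1.0 / len(ids)

    def test_too_few_positives_rejected(self):
        recs = self._cohort(30, 3)
        with pytest.raises(StratificationError):
            stratified_kfold(recs, 5, DM730, seed=0)


class TestClinicalEncoding:
    def _train_records(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(40):
            recs.append(make_record(
                f"P{i}", t_stage=rng.choice(["T1", "T2", "T3", "T4a", "T4b"]),
                n_stage=rng.choice(["N0", "N1", "N2a"]),
                volume=float(rng.uniform(1000, 9000)), area=float(rng.uniform(100, 900)),
                age=float(rng.uniform(40, 80)),
            ))
        return recs

    def test_stage_aggregation(self):
        recs = self._train_records()
        enc = fit_clinical_encoding(recs)
        rec = make_record("X", t_stage="T4a")
        vec = encode_clinical(rec, enc)
        names = enc.feature_names
        assert vec[names.index("t_stage=T4")] == 1.0
        assert "t_stage=T4a" not in names

    def test_quartile_bin_lookup(self):
        recs = self._train_records()
        enc = fit_clinical_encoding(recs)
        vols = sorted(r.gtv_volume_mm3 for r in recs)
        v60 = float(np.quantile(vols, 0.6))  # 60th percentile -> 3rd quartile bin
        assert quartile_bin(v60, enc.quartiles["gtv_volume_mm3"]) == 3

    def test_age_scaling(self):
        enc = fit_clinical_encoding(self._train_records())
        vec = encode_clinical(make_record("X", age=65.0), enc)
        assert vec[0] == pytest.approx(0.65)

    def test_identical_records_identical_vectors(self):
        enc = fit_clinical_encoding(self._train_records())
        v1 = encode_clinical(make_record("A"), enc)
        v2 = encode_clinical(make_record("B"), enc)
        assert np.array_equal(v1, v2)

    def test_one_hot_blocks_sum_to_one(self):
        enc = fit_clinical_encoding(self._train_records())
        vec = encode_clinical(make_record("X"), enc)
        pos = 1  # skip age
        from hncnet.cohort import CATEGORICAL_VARS

        for var in CATEGORICAL_VARS:
            block = vec[pos : pos + len(enc.levels[var])]
            assert block.sum() == 1.0
            pos += len(enc.levels[var])

    def test_unseen_level_routes_to_unknown(self):
        enc = fit_clinical_encoding(self._train_records())
        rec = make_record("X", hpv="equivocal")  # never in training
        vec = encode_clinical(rec, enc)
        names = enc.feature_names
        assert vec[names.index("hpv_status=unknown")] == 1.0

    def test_no_leakage_from_test_records(self):
        train = self._train_records()
        enc1 = fit_clinical_encoding(train)
        probe = make_record("X", volume=4000.0)
        v1 = encode_clinical(probe, enc1)
        # wildly different test-set records must not alter the encoding
        enc2 = fit_clinical_encoding(train)
        _ = encode_cohort([make_record("Z", volume=1e9, t_stage="T9")], enc2)
        v2 = encode_clinical(probe, enc2)
        assert np.array_equal(v1, v2)
        assert enc1.quartiles == enc2.quartiles

    def test_fixed_length(self):
        enc = fit_clinical_encoding(self._train_records())
        assert len(encode_clinical(make_record("X"), enc)) == enc.dim


def test_clinical_csv_with_column_mapping(tmp_path):
    from hncnet.cohort import load_clinical_csv

    frame = records_to_frame([make_record("P0")]).rename(columns={"hpv": "hpv_result"})
    frame.to_csv(tmp_path / "clin.csv", index=False)
    (tmp_path / "map.yaml").write_text("hpv_result: hpv\n")
    with pytest.raises(DataError):
        load_clinical_csv(tmp_path / "clin.csv")  # unmapped schema
    recs = load_clinical_csv(tmp_path / "clin.csv", tmp_path / "map.yaml")
    assert recs[0].hpv_status == "positive"
    (tmp_path / "bad.yaml").write_text("hpv_result: nonsense_column\n")
    with pytest.raises(DataError):
        load_clinical_csv(tmp_path / "clin.csv", tmp_path / "bad.yaml")


def test_csv_round_trip():
    recs = [make_record("P0", event_dm=1, time_dm=120.0, followup=120.0),
            make_record("P1")]
    frame = records_to_frame(recs)
    back = frame_to_records(frame)
    assert back[0].event_dm == 1 and back[0].time_dm_days == 120.0
    assert back[1].time_dm_days is None
    assert [r.patient_id for r in back] == ["P0", "P1"]
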